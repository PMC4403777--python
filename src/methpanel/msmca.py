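"""Methylation-specific melting curve analysis (MS-MCA).

Bisulfite PCR with methylation-independent primers amplifies every
epiallele of a CpG island; sequence differences introduced by bisulfite
conversion (unmethylated CpG cytosines become thymine, lowering GC
content) then separate the products during the melting stage.  In the
negative-derivative representation -dF/dT each epiallele population
appears as a peak at its melting temperature, and a sample is classified
qualitatively against two controls run on the same plate: whole-genome
amplified DNA (WGA, fully unmethylated, low Tm) and in vitro methylated
DNA (IVM, fully methylated, high Tm).

Classes
-------
``unmethylated``  single peak at the WGA Tm
``methylated``    single peak at the IVM Tm
``mixed``         peaks at both control Tms (e.g. monoallelic methylation)
``intermediate``  any peak matching neither control (partially methylated
                  epialleles or heteroduplexes)
``no_call``       no peak above threshold (no amplification)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks
from sklearn.base import BaseEstimator

__all__ = [
    "MeltProfile",
    "MeltPeaks",
    "MsmcaCall",
    "negative_derivative",
    "call_tm_peaks",
    "classify",
    "MeltCurveClassifier",
    "classify_melt_table",
    "read_melt_csv",
]

MSMCA_CLASSES = ("unmethylated", "methylated", "mixed", "intermediate", "no_call")


@dataclass
class MeltProfile:
    """A fluorescence-vs-temperature series on a uniform grid."""

    temperature: np.ndarray
    fluorescence: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.ndim != 1 or self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence must be equal-length 1-D arrays")
        if self.temperature.size < 10:
            raise ValueError("melt profile needs at least 10 points")
        steps = np.diff(self.temperature)
        if np.any(steps <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("temperature grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.temperature[1] - self.temperature[0])


@dataclass
class MeltPeaks:
    """Called -dF/dT peaks, sorted by melting temperature."""

    peaks: list[tuple[float, float]]  # (Tm degC, height)
    smoothing_window: int
    height_threshold: float

    @property
    def tms(self) -> list[float]:
        return [tm for tm, _ in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class MsmcaCall:
    """Epiallele classification of one sample against the plate controls."""

    sample_id: str
    label: str  # one of MSMCA_CLASSES
    tms: list[float] = field(default_factory=list)
    tm_wga: float = float("nan")
    tm_ivm: float = float("nan")


def negative_derivative(
    profile: MeltProfile, window: int = 11
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed -dF/dT of a melt profile.

    Fluorescence is smoothed with a centred moving average of odd length
    ``window`` (edges use a shrinking one-sided window), then differenced
    centrally.  Returns (temperature grid, derivative values).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    n = profile.temperature.size
    if window >= n:
        raise ValueError(f"window {window} must be smaller than the grid length {n}")
    fl = profile.fluorescence
    if window > 1:
        kernel = np.ones(window) / window
        smoothed = np.convolve(fl, kernel, mode="same")
        # fix edge shrinkage: renormalise by the actual kernel mass in range
        coverage = np.convolve(np.ones(n), kernel, mode="same")
        smoothed = smoothed / coverage
    else:
        smoothed = fl
    deriv = -np.gradient(smoothed, profile.temperature)
    return profile.temperature.copy(), deriv


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid vertex of the parabola through (x[i-1..i+1], y[i-1..i+1])."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = x[1] - x[0]
    return float(x[i] + delta * step), float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)


def call_tm_peaks(
    temperature: np.ndarray,
    derivative: np.ndarray,
    min_height_frac: float = 0.2,
    min_separation: float = 1.0,
    smoothing_window: int = 11,
) -> MeltPeaks:
    """Local maxima of -dF/dT above a relative height threshold.

    Peaks must reach ``min_height_frac`` of the global maximum in both
    height and topographic prominence (the prominence requirement rejects
    noise wiggles riding on the flank of a real peak) and be at least
    ``min_separation`` degC apart.  An empty list signals no
    amplification.  Tm positions are refined by parabolic interpolation
    around the grid maximum.
    """
    temperature = np.asarray(temperature, dtype=float)
    derivative = np.asarray(derivative, dtype=float)
    top = float(derivative.max(initial=0.0))
    if top <= 0.0:
        return MeltPeaks([], smoothing_window, 0.0)
    threshold = min_height_frac * top
    step = float(temperature[1] - temperature[0])
    distance = max(int(np.ceil(min_separation / step)), 1)
    idx, _ = _scipy_find_peaks(
        derivative, height=threshold, distance=distance, prominence=threshold
    )
    peaks = [_parabolic_refine(temperature, derivative, int(i)) for i in idx]
    peaks.sort(key=lambda p: p[0])
    return MeltPeaks(peaks, smoothing_window, threshold)


def classify(
    peaks: MeltPeaks,
    tm_wga: float,
    tm_ivm: float,
    tolerance: float = 1.0,
    sample_id: str = "",
) -> MsmcaCall:
    """Classify called peaks against the control melting temperatures.

    Any peak matching neither control (within ``tolerance`` degC) forces
    ``intermediate``; otherwise presence near both controls gives
    ``mixed``, and a match to exactly one control gives that class.
    """
    if not tm_wga < tm_ivm:
        raise ValueError("tm_wga must be below tm_ivm")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    tms = peaks.tms
    if not tms:
        return MsmcaCall(sample_id, "no_call", [], tm_wga, tm_ivm)
    near_u = [abs(t - tm_wga) <= tolerance for t in tms]
    near_m = [abs(t - tm_ivm) <= tolerance for t in tms]
    if any(not (u or m) for u, m in zip(near_u, near_m)):
        label = "intermediate"
    elif any(near_u) and any(near_m):
        label = "mixed"
    elif any(near_u):
        label = "unmethylated"
    else:
        label = "methylated"
    return MsmcaCall(sample_id, label, tms, tm_wga, tm_ivm)


class MeltCurveClassifier(BaseEstimator):
    """Classify melt profiles into epiallele categories against plate controls.

    fit() takes the WGA (unmethylated) and IVM (methylated) control
    profiles of the run and records their melting temperatures as
    ``tm_wga_`` and ``tm_ivm_``; predict() classifies sample profiles.
    The classifier is invariant to uniform scaling of fluorescence (only
    relative peak heights matter).

    Parameters
    ----------
    tolerance : float
        Tm match window against each control, degC.
    min_height_frac : float
        Peak threshold as a fraction of the tallest -dF/dT peak.
    window : int
        Odd moving-average smoothing window (grid points).
    """

    def __init__(
        self,
        tolerance: float = 1.0,
        min_height_frac: float = 0.2,
        window: int = 11,
        min_separation: float = 1.0,
    ) -> None:
        self.tolerance = tolerance
        self.min_height_frac = min_height_frac
        self.window = window
        self.min_separation = min_separation

    def _single_tm(self, profile: MeltProfile, role: str) -> float:
        temps, deriv = negative_derivative(profile, self.window)
        peaks = call_tm_peaks(
            temps, deriv, self.min_height_frac, self.min_separation, self.window
        )
        if len(peaks) == 0:
            raise ValueError(f"{role} control shows no melt peak")
        # control wells are pure populations: use the dominant peak
        return max(peaks.peaks, key=lambda p: p[1])[0]

    def fit(self, X: Mapping[str, MeltProfile], y=None) -> "MeltCurveClassifier":
        """``X`` maps control roles to profiles: keys ``WGA`` and ``IVM``."""
        missing = {"WGA", "IVM"} - set(X)
        if missing:
            raise ValueError(f"missing control profiles: {sorted(missing)}")
        tm_wga = self._single_tm(X["WGA"], "WGA")
        tm_ivm = self._single_tm(X["IVM"], "IVM")
        if not tm_wga < tm_ivm:
            raise ValueError(
                f"control Tms out of order: WGA {tm_wga:.2f} >= IVM {tm_ivm:.2f}"
            )
        self.tm_wga_ = tm_wga
        self.tm_ivm_ = tm_ivm
        return self

    def predict_calls(self, profiles: Iterable[MeltProfile]) -> list[MsmcaCall]:
        if not hasattr(self, "tm_wga_"):
            raise ValueError("MeltCurveClassifier is not fitted; call fit() first")
        calls = []
        for prof in profiles:
            temps, deriv = negative_derivative(prof, self.window)
            peaks = call_tm_peaks(
                temps, deriv, self.min_height_frac, self.min_separation, self.window
            )
            calls.append(
                classify(peaks, self.tm_wga_, self.tm_ivm_, self.tolerance, prof.sample_id)
            )
        return calls

    def predict(self, profiles: Iterable[MeltProfile]) -> np.ndarray:
        return np.array([c.label for c in self.predict_calls(profiles)])


def read_melt_csv(path) -> dict[str, MeltProfile]:
    """Read a long-format melt CSV (sample, temperature, fluorescence)."""
    df = pd.read_csv(path)
    profiles = {}
    for sample, grp in df.groupby("sample", sort=False):
        grp = grp.sort_values("temperature")
        profiles[str(sample)] = MeltProfile(
            grp["temperature"].to_numpy(), grp["fluorescence"].to_numpy(), str(sample)
        )
    return profiles


def classify_melt_table(
    profiles: Mapping[str, MeltProfile],
    tolerance: float = 1.0,
    min_height_frac: float = 0.2,
    window: int = 11,
) -> pd.DataFrame:
    """Classify every non-control profile against the run's WGA/IVM wells.

    ``profiles`` must contain the reserved ids ``WGA`` and ``IVM``.
    Returns a table (sample, class, tm_list).
    """
    clf = MeltCurveClassifier(
        tolerance=tolerance, min_height_frac=min_height_frac, window=window
    ).fit({k: v for k, v in profiles.items() if k in ("WGA", "IVM")})
    samples = [p for k, p in profiles.items() if k not in ("WGA", "IVM")]
    calls = clf.predict_calls(samples)
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "class": [c.label for c in calls],
            "tm_list": [";".join(f"{t:.2f}" for t in c.tms) for c in calls],
        }
    )
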