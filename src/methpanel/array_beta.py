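"""Methylation-array beta values and peak-based correction (PBC).

Beta = M/(M+U) from the methylated/unmethylated probe intensities, with
unreliable measurements (detection p-value > 0.05 or fewer than 3 beads)
set missing.  Because Infinium type I and type II probes have different
dynamic ranges, each sample is corrected per assay type: the unmethylated
and methylated modes of the Epanechnikov-smoothed beta density are
located, the unmethylated peak is moved to 0 and the methylated peak to 1
by linear scaling, and values outside [0, 1] are clipped back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BetaMatrix",
    "PeakEstimate",
    "DegenerateDistributionError",
    "compute_beta",
    "mask_unreliable",
    "epanechnikov_density",
    "silverman_bandwidth",
    "find_peaks",
    "pbc_transform",
    "PeakBasedCorrector",
    "correct_cohort",
]

DETECTION_P_MAX = 0.05
MIN_BEADS = 3
BANDWIDTH_FLOOR = 0.02
DEFAULT_GRID_SIZE = 512
ASSAY_TYPES = ("I", "II")


class DegenerateDistributionError(ValueError):
    """The smoothed beta density lacks a local maximum on one side of the
    unmethylated/methylated boundary, so peak anchors cannot be placed."""


def compute_beta(M, U):
    """Beta value M/(M+U), elementwise; zero total intensity gives NaN
    (a flagged missing value, not an exception)."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("intensities must be non-negative")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / np.where(total > 0, total, 1.0), np.nan)
    return beta if beta.ndim else float(beta)


def mask_unreliable(beta, detection_p, beads):
    """Set beta missing where detection p > 0.05 or bead count < 3."""
    beta = np.asarray(beta, dtype=float)
    bad = (np.asarray(detection_p, dtype=float) > DETECTION_P_MAX) | (
        np.asarray(beads) < MIN_BEADS
    )
    out = np.where(bad, np.nan, beta)
    return out if out.ndim else float(out)


def silverman_bandwidth(values: np.ndarray, floor: float = BANDWIDTH_FLOOR) -> float:
    """Rule-of-thumb bandwidth rescaled to the Epanechnikov kernel.

    h = 2.34 * min(sd, IQR/1.34) * n^(-1/5), floored at ``floor`` so a
    near-degenerate stratum still yields a usable density.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("bandwidth needs >= 2 values")
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    scale = min(x for x in (sd, iqr / 1.34) if x > 0) if max(sd, iqr) > 0 else 0.0
    return max(2.34 * scale * v.size ** (-0.2), floor)


def epanechnikov_density(
    values: Sequence[float],
    bandwidth: float,
    grid: Optional[np.ndarray] = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density estimate with the Epanechnikov kernel.

    density(x) = (1/(n h)) * sum_i K((x - v_i)/h),  K(u) = 0.75 (1 - u^2)
    on |u| <= 1.  Returns (grid, density); the default grid is
    ``grid_size`` evenly spaced points on [0, 1].
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values for density estimation")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(0.0, 1.0, grid_size)
    grid = np.asarray(grid, dtype=float)
    density = np.zeros_like(grid)
    # chunk over values to bound the broadcast at ~1e6 floats
    chunk = max(1_000_000 // max(grid.size, 1), 1)
    for start in range(0, v.size, chunk):
        u = (grid[None, :] - v[start : start + chunk, None]) / bandwidth
        k = 0.75 * (1.0 - u * u)
        k[np.abs(u) > 1.0] = 0.0
        density += k.sum(axis=0)
    density /= v.size * bandwidth
    return grid, density


@dataclass(frozen=True)
class PeakEstimate:
    """Locations of the unmethylated and methylated density modes."""

    peak_u: float
    peak_m: float
    bandwidth: float
    grid_size: int = DEFAULT_GRID_SIZE

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_u < self.peak_m <= 1.0:
            raise ValueError(
                f"peaks must satisfy 0 <= peak_u < peak_m <= 1, got "
                f"({self.peak_u:.4f}, {self.peak_m:.4f})"
            )


def find_peaks(
    density: np.ndarray,
    grid: np.ndarray,
    boundary: float = 0.5,
    bandwidth: float = float("nan"),
) -> PeakEstimate:
    """Locate the unmethylated and methylated modes of a beta density.

    The unmethylated peak is the highest local maximum of the smoothed
    density on [0, boundary), the methylated peak on [boundary, 1]; grid
    endpoints count as local maxima (an already-anchored distribution has
    its modes at 0 and 1).  A side with no local maximum raises
    :class:`DegenerateDistributionError`.
    """
    d = np.asarray(density, dtype=float)
    g = np.asarray(grid, dtype=float)
    if d.size != g.size or d.size < 3:
        raise ValueError("density and grid must be equal-length with >= 3 points")
    interior = (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:])
    is_max = np.r_[d[0] > d[1], interior, d[-1] > d[-2]]
    maxima = np.flatnonzero(is_max)
    if maxima.size == 0:
        raise DegenerateDistributionError("density has no local maximum")

    def best(side: np.ndarray) -> float:
        cand = maxima[side[maxima]]
        if cand.size == 0:
            raise DegenerateDistributionError(
                "no local maximum on one side of the boundary; "
                "distribution is not bimodal"
            )
        return float(g[cand[np.argmax(d[cand])]])

    peak_u = best(g < boundary)
    peak_m = best(g >= boundary)
    return PeakEstimate(peak_u, peak_m, bandwidth, d.size)


def pbc_transform(beta, peaks: PeakEstimate):
    """Linear peak anchoring: (beta - peak_u)/(peak_m - peak_u), clipped to
    [0, 1].  Missing values stay missing."""
    beta = np.asarray(beta, dtype=float)
    out = (beta - peaks.peak_u) / (peaks.peak_m - peaks.peak_u)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass
class BetaMatrix:
    """Probes x samples beta values with probe annotation.

    ``values`` is a DataFrame indexed by probe with one column per sample;
    NaN encodes masked/missing measurements.  ``probe_info`` carries at
    least an ``assay_type`` column ("I"/"II") and optionally
    ``is_promoter`` / CpG-island flags.
    """

    values: pd.DataFrame
    probe_info: pd.DataFrame

    def __post_init__(self) -> None:
        if "assay_type" not in self.probe_info.columns:
            raise ValueError("probe_info must have an 'assay_type' column")
        missing = self.values.index.difference(self.probe_info.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack annotation")
        bad = set(self.probe_info["assay_type"].unique()) - set(ASSAY_TYPES)
        if bad:
            raise ValueError(f"unknown assay types: {sorted(bad)}")
        finite = self.values.to_numpy()
        finite = finite[np.isfinite(finite)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @classmethod
    def from_signals(cls, signals: pd.DataFrame) -> "BetaMatrix":
        """Build from a long table (probe, sample, M, U, detection_p,
        beads, assay_type): compute betas and mask unreliable entries."""
        df = signals.copy()
        beta = compute_beta(df["M"].to_numpy(), df["U"].to_numpy())
        df["beta"] = mask_unreliable(beta, df["detection_p"], df["beads"])
        values = df.pivot(index="probe", columns="sample", values="beta")
        info = df.drop_duplicates("probe").set_index("probe")[["assay_type"]]
        return cls(values, info.loc[values.index])

    @classmethod
    def read_signals_tsv(cls, path) -> "BetaMatrix":
        return cls.from_signals(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe")


class PeakBasedCorrector(BaseEstimator, TransformerMixin):
    """Per-sample, per-assay-type peak-based correction of beta values.

    This is a within-sample normalisation: fit() estimates, for every
    sample and assay type independently (peaks never mix assay types), the
    unmethylated and methylated modes of the Epanechnikov-smoothed beta
    density; transform() anchors those modes to 0 and 1 by linear scaling
    with clipping.  A stratum whose density is not bimodal is passed
    through uncorrected and flagged in ``report_``.

    Parameters
    ----------
    bandwidth : "auto" or float
        Kernel bandwidth on the beta scale; "auto" uses Silverman's rule
        rescaled to the Epanechnikov kernel, floored at 0.02.
    grid_size : int
        Density evaluation points on [0, 1].
    boundary : float
        Beta value separating the unmethylated and methylated search
        ranges for the two modes.

    Attributes
    ----------
    peaks_ : dict mapping (sample, assay_type) -> PeakEstimate or None
    report_ : DataFrame of peak estimates and correction flags
    """

    def __init__(
        self,
        bandwidth: Union[str, float] = "auto",
        grid_size: int = DEFAULT_GRID_SIZE,
        boundary: float = 0.5,
    ) -> None:
        self.bandwidth = bandwidth
        self.grid_size = grid_size
        self.boundary = boundary

    def fit(self, X: BetaMatrix, y=None) -> "PeakBasedCorrector":
        peaks: dict[tuple[str, str], Optional[PeakEstimate]] = {}
        rows = []
        grid = np.linspace(0.0, 1.0, self.grid_size)
        type_index = {
            t: X.probe_info.index[X.probe_info["assay_type"] == t] for t in ASSAY_TYPES
        }
        for sample in X.values.columns:
            col = X.values[sample]
            for assay_type, probes in type_index.items():
                if len(probes) == 0:
                    continue
                vals = col.loc[probes].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                est, note = None, ""
                if vals.size < 2:
                    note = "too few values"
                else:
                    h = (
                        silverman_bandwidth(vals)
                        if self.bandwidth == "auto"
                        else float(self.bandwidth)
                    )
                    try:
                        _, dens = epanechnikov_density(vals, h, grid=grid)
                        est = find_peaks(dens, grid, self.boundary, bandwidth=h)
                    except DegenerateDistributionError as exc:
                        note = str(exc)
                peaks[(sample, assay_type)] = est
                rows.append(
                    {
                        "sample": sample,
                        "assay_type": assay_type,
                        "peak_u": est.peak_u if est else np.nan,
                        "peak_m": est.peak_m if est else np.nan,
                        "bandwidth": est.bandwidth if est else np.nan,
                        "corrected": est is not None,
                        "note": note,
                    }
                )
        self.peaks_ = peaks
        self.report_ = pd.DataFrame(rows)
        return self

    def transform(self, X: BetaMatrix) -> BetaMatrix:
        if not hasattr(self, "peaks_"):
            raise ValueError("PeakBasedCorrector is not fitted; call fit() first")
        out = X.values.copy()
        for (sample, assay_type), est in self.peaks_.items():
            if est is None or sample not in out.columns:
                continue
            probes = X.probe_info.index[X.probe_info["assay_type"] == assay_type]
            probes = probes.intersection(out.index)
            out.loc[probes, sample] = pbc_transform(
                out.loc[probes, sample].to_numpy(dtype=float), est
            )
        return BetaMatrix(out, X.probe_info)

    def report_json(self) -> str:
        return json.dumps(self.report_.to_dict(orient="records"), indent=2)


def correct_cohort(
    matrix: BetaMatrix,
    bandwidth: Union[str, float] = "auto",
    grid_size: int = DEFAULT_GRID_SIZE,
    boundary: float = 0.5,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Fit-and-apply wrapper over :class:`PeakBasedCorrector`; returns the
    corrected matrix and the peak report."""
    corrector = PeakBasedCorrector(
        bandwidth=bandwidth, grid_size=grid_size, boundary=boundary
    ).fit(matrix)
    return corrector.transform(matrix), corrector.report_
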