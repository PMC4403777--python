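"""MethyLight percent-methylated-reference (PMR) quantification.

MethyLight is a methylation-specific real-time PCR assay: a primer/probe
set amplifies only fully methylated bisulfite-converted alleles of the
target, an ALU repeat reaction controls for input DNA, and a dilution
series of in vitro methylated DNA (IVM) provides both the standard curve
and the fully methylated reference.  Methylation is reported as

    PMR = ((target_sample / ALU_sample) / (target_IVM / ALU_IVM)) * 100

with concentrations read off the standard curve, duplicates averaged on
the concentration scale, and a promoter called unmethylated when PMR falls
below a threshold (default 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "StandardCurve",
    "PMRResult",
    "MethyLightError",
    "fit_standard_curve",
    "quantify",
    "average_duplicates",
    "compute_pmr",
    "MethyLightQuantifier",
    "pmr_from_table",
]

CT_MAX = 40.0
TARGET = "SOX11"
CONTROL = "ALUC4"
REFERENCE_SAMPLE = "IVM"


class MethyLightError(ValueError):
    """Raised when a control, reference or curve is unusable."""


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct = intercept + slope * log10(quantity).

    A valid qPCR curve has negative slope (about -3.32 per decade at 100%
    efficiency); ``r_squared`` records fit quality.
    """

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise MethyLightError(
                f"standard curve slope must be negative, got {self.slope:.3f}"
            )


@dataclass
class PMRResult:
    """PMR value with its classification and component concentrations."""

    sample_id: str
    pmr: float
    classification: str  # "methylated" | "unmethylated"
    target_sample: float
    control_sample: float
    target_reference: float
    control_reference: float


def fit_standard_curve(
    dilutions: Sequence[float], cts: Sequence[float], ct_max: float = CT_MAX
) -> StandardCurve:
    """Fit Ct against log10(dilution) for an IVM dilution series.

    Requires at least three distinct dilutions with uncensored Ct; exact on
    noise-free collinear input.
    """
    dil = np.asarray(dilutions, dtype=float)
    ct = np.asarray(cts, dtype=float)
    ok = np.isfinite(ct) & (ct < ct_max) & (dil > 0)
    dil, ct = dil[ok], ct[ok]
    if np.unique(dil).size < 3:
        raise MethyLightError(
            "standard curve needs >= 3 distinct uncensored dilution points"
        )
    res = stats.linregress(np.log10(dil), ct)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else float("nan")
    if not res.slope < 0:
        raise MethyLightError(
            f"standard curve slope must be negative, got {res.slope:.3f}"
        )
    return StandardCurve(float(res.slope), float(res.intercept), r2)


def quantify(ct: float, curve: StandardCurve, ct_max: float = CT_MAX) -> float:
    """Invert the standard curve: quantity = 10**((Ct - intercept)/slope).

    A censored reaction (NaN Ct or Ct at/above ``ct_max``) means no
    amplification and maps to quantity 0.
    """
    if not np.isfinite(ct) or ct >= ct_max:
        return 0.0
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def average_duplicates(quantities: Iterable[float]) -> float:
    """Mean of replicate concentrations (averaging happens on the
    concentration scale, not the Ct scale)."""
    q = np.asarray(list(quantities), dtype=float)
    if q.size == 0:
        raise ValueError("no replicate quantities to average")
    return float(q.mean())


def compute_pmr(
    target_sample: float,
    control_sample: float,
    target_reference: float,
    control_reference: float,
    threshold: float = 1.0,
    sample_id: str = "",
) -> PMRResult:
    """Percent methylated reference for one sample.

    PMR = ((target_sample/control_sample) / (target_reference/control_reference)) * 100.
    Values above 100 are reported as-is with a warning.  A sample whose ALU
    input control did not amplify, or a reference that failed, is an error
    rather than a silent zero.
    """
    if control_sample <= 0:
        raise MethyLightError(f"input control failed for sample {sample_id!r} (ALU = 0)")
    if control_reference <= 0:
        raise MethyLightError("input control failed for the methylated reference")
    if target_reference <= 0:
        raise MethyLightError("reference failed (methylated reference target = 0)")
    pmr = (target_sample / control_sample) / (target_reference / control_reference) * 100.0
    if pmr > 100.0:
        warnings.warn(
            f"PMR {pmr:.1f} exceeds 100 for sample {sample_id!r}; reported uncapped"
        )
    classification = "unmethylated" if pmr < threshold else "methylated"
    return PMRResult(
        sample_id,
        float(pmr),
        classification,
        target_sample,
        control_sample,
        target_reference,
        control_reference,
    )


class MethyLightQuantifier(BaseEstimator):
    """Estimate PMR per sample from a long-format qPCR table.

    fit() consumes the reference wells (sample id ``IVM`` with a dilution
    column) and fits one standard curve per target; a target without its
    own dilution series borrows the other target's slope, anchored at the
    target's highest-concentration well.  predict() quantifies sample
    wells, averages duplicates on the concentration scale and returns one
    :class:`PMRResult` per sample.

    Parameters
    ----------
    pmr_threshold : float
        Classification cutoff; PMR below it is called unmethylated.
    ct_max : float
        Censoring limit in cycles; Ct at/above it means no amplification.
    """

    def __init__(
        self,
        pmr_threshold: float = 1.0,
        ct_max: float = CT_MAX,
        target: str = TARGET,
        control: str = CONTROL,
        reference_sample: str = REFERENCE_SAMPLE,
    ) -> None:
        self.pmr_threshold = pmr_threshold
        self.ct_max = ct_max
        self.target = target
        self.control = control
        self.reference_sample = reference_sample

    def _reference_rows(self, df: pd.DataFrame) -> pd.DataFrame:
        return df[(df["sample"] == self.reference_sample) & df["dilution"].notna()]

    def fit(self, X: pd.DataFrame, y=None) -> "MethyLightQuantifier":
        ref = self._reference_rows(X)
        if ref.empty:
            raise MethyLightError(
                f"no {self.reference_sample} dilution-series wells in the table"
            )
        curves: dict[str, StandardCurve] = {}
        for tgt in (self.target, self.control):
            rows = ref[ref["target"] == tgt]
            if rows["dilution"].nunique() >= 3:
                curves[tgt] = fit_standard_curve(
                    rows["dilution"], rows["Ct"], self.ct_max
                )
        if not curves:
            raise MethyLightError("no target has a usable dilution series")
        for tgt in (self.target, self.control):
            if tgt not in curves:  # borrow the other curve's slope
                donor = curves[self.target if tgt == self.control else self.control]
                rows = ref[ref["target"] == tgt]
                if rows.empty:
                    curves[tgt] = donor
                else:
                    top = rows.loc[rows["dilution"].idxmax()]
                    intercept = float(top["Ct"]) - donor.slope * np.log10(
                        float(top["dilution"])
                    )
                    curves[tgt] = StandardCurve(donor.slope, intercept, float("nan"))
        self.curves_ = curves
        # reference concentrations: measured undiluted IVM wells per target
        self.reference_quantities_ = {}
        for tgt, curve in curves.items():
            rows = ref[ref["target"] == tgt]
            if rows.empty:
                self.reference_quantities_[tgt] = 1.0
                continue
            top_dil = rows["dilution"].max()
            top = rows[rows["dilution"] == top_dil]
            q = average_duplicates(
                quantify(ct, curve, self.ct_max) for ct in top["Ct"]
            ) / float(top_dil)
            self.reference_quantities_[tgt] = q
        return self

    def predict(self, X: pd.DataFrame) -> list[PMRResult]:
        if not hasattr(self, "curves_"):
            raise ValueError("MethyLightQuantifier is not fitted; call fit() first")
        rows = X[X["sample"] != self.reference_sample]
        results = []
        for sample, grp in rows.groupby("sample", sort=False):
            quantities = {}
            for tgt in (self.target, self.control):
                wells = grp[grp["target"] == tgt]
                if wells.empty:
                    raise MethyLightError(f"sample {sample!r} lacks {tgt} wells")
                quantities[tgt] = average_duplicates(
                    quantify(ct, self.curves_[tgt], self.ct_max) for ct in wells["Ct"]
                )
            results.append(
                compute_pmr(
                    quantities[self.target],
                    quantities[self.control],
                    self.reference_quantities_[self.target],
                    self.reference_quantities_[self.control],
                    threshold=self.pmr_threshold,
                    sample_id=str(sample),
                )
            )
        return results

    def fit_predict(self, X: pd.DataFrame) -> list[PMRResult]:
        return self.fit(X).predict(X)


def pmr_from_table(
    qpcr: pd.DataFrame, pmr_threshold: float = 1.0, ct_max: float = CT_MAX
) -> pd.DataFrame:
    """One-call wrapper: fit curves on the IVM series and return a tidy
    (sample, pmr, classification) table."""
    results = MethyLightQuantifier(
        pmr_threshold=pmr_threshold, ct_max=ct_max
    ).fit_predict(qpcr)
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "pmr": [r.pmr for r in results],
            "classification": [r.classification for r in results],
        }
    )
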