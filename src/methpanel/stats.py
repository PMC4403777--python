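"""Methylation-expression-clinical integration statistics.

Expression preprocessing (RT-qPCR 2^-dCt with a detection cutoff; RNA-seq
log2(count+1)), Spearman and per-CpG Pearson correlation between
methylation and expression, unpaired two-sided Wilcoxon rank-sum
comparison of ER-positive vs ER-negative tumors, and the ChIP-qPCR
enrichment call against GAPDH (negative) and TSH2B (positive) controls.

The rank-sum test is implemented directly: exact enumeration of all rank
assignments when the pooled size is small (handles ties exactly),
tie-corrected normal approximation with continuity correction otherwise.
Spearman p-values use exact permutation for very small n and the t
approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionRecord",
    "CorrelationResult",
    "GroupComparison",
    "expression_from_ct",
    "log2_count",
    "spearman",
    "pearson_per_cpg",
    "wilcoxon_two_sided",
    "er_methylation_report",
    "chip_enrichment_call",
]

CT_DETECTION_CUTOFF = 35.0
SPEARMAN_EXACT_MAX_N = 9
RANKSUM_EXACT_MAX_N = 12


@dataclass
class ExpressionRecord:
    sample_id: str
    source: str  # "rtqpcr" | "rnaseq"
    value: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.below_detection and self.value != 0.0:
            raise ValueError("below-detection records must have value 0")


@dataclass
class CorrelationResult:
    method: str  # "spearman" | "pearson"
    estimate: float
    p_value: float
    n: int
    stratum: str = ""
    flag: str = ""


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group a
    p_value: float
    flag: str = ""


def expression_from_ct(
    ct_target: float,
    ct_reference: float,
    cutoff: float = CT_DETECTION_CUTOFF,
    sample_id: str = "",
) -> ExpressionRecord:
    """Relative expression 2^-(Ct_target - Ct_reference) against a
    housekeeping gene; target Ct above ``cutoff`` is below the detection
    limit and the level is set to zero."""
    if not np.isfinite(ct_reference):
        raise ValueError("reference Ct is missing")
    if not np.isfinite(ct_target) or ct_target > cutoff:
        return ExpressionRecord(sample_id, "rtqpcr", 0.0, below_detection=True)
    return ExpressionRecord(
        sample_id, "rtqpcr", float(2.0 ** -(ct_target - ct_reference))
    )


def log2_count(count):
    """log2(normalized count + 1); negative counts are an error."""
    c = np.asarray(count, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    out = np.log2(c + 1.0)
    return out if out.ndim else float(out)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration."""
    n = rx.size
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum())
    perms = np.array(list(permutations(ry)))
    ry_c = perms - perms.mean(axis=1, keepdims=True)
    norms = np.sqrt((ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / (norms * denom)
    return float(np.mean(np.abs(rhos) >= abs(observed) - 1e-12))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    stratum: str = "",
    exact_max_n: int = SPEARMAN_EXACT_MAX_N,
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    p-value by exact permutation for n <= ``exact_max_n``, otherwise the
    t approximation.  Zero variance in either vector yields a NaN estimate
    with a flag rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            "spearman", float("nan"), float("nan"), x.size, stratum, "zero variance"
        )
    rho, p_t = sps.spearmanr(x, y)
    if x.size <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = float(p_t)
    return CorrelationResult("spearman", float(rho), p, int(x.size), stratum)


def _ranksum_exact_p(pooled_ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum W of group a by enumerating all
    C(n, n_a) assignments of the pooled (tie-averaged) ranks."""
    n = pooled_ranks.size
    sums = np.fromiter(
        (sum(c) for c in combinations(pooled_ranks, n_a)),
        dtype=float,
        count=comb(n, n_a),
    )
    eps = 1e-9
    p_low = np.mean(sums <= w_obs + eps)
    p_high = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_two_sided(
    a: Sequence[float],
    b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
    exact_max_n: int = RANKSUM_EXACT_MAX_N,
) -> GroupComparison:
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact enumeration over all rank partitions when the pooled size is at
    most ``exact_max_n`` (ties handled exactly via average ranks);
    otherwise the normal approximation with tie correction and continuity
    correction.  All values tied across both groups gives p = 1, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one observation")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    u = w - n_a * (n_a + 1) / 2.0
    if np.ptp(pooled) == 0:
        return GroupComparison(group_a, group_b, n_a, n_b, u, 1.0, "all values tied")
    if n <= exact_max_n:
        p = _ranksum_exact_p(ranks, n_a, w)
    else:
        mean_u = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * (n + 1 - tie_term)
        diff = u - mean_u
        z = (diff - np.sign(diff) * 0.5) / np.sqrt(var_u)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return GroupComparison(group_a, group_b, n_a, n_b, u, p)


def pearson_per_cpg(
    betas: pd.DataFrame,
    expression: pd.Series,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Per-CpG-site Pearson correlation between beta values and expression.

    ``betas`` is sites x samples; missing betas are pairwise-deleted per
    site, and sites with fewer than ``min_pairs`` complete pairs are
    skipped (logged in the output).  Returns the per-site table
    (site, r, p, n, std_methylation) plus one overall expression standard
    deviation -- the dispersion summary that accompanies the correlations.
    """
    expr = expression.reindex(betas.columns)
    rows = []
    for site, values in betas.iterrows():
        pair_ok = values.notna() & expr.notna()
        n = int(pair_ok.sum())
        if n < min_pairs:
            rows.append(
                {
                    "site": site,
                    "r": np.nan,
                    "p_value": np.nan,
                    "n": n,
                    "std_methylation": np.nan,
                    "note": f"skipped: {n} complete pairs",
                }
            )
            continue
        x = values[pair_ok].to_numpy(dtype=float)
        y = expr[pair_ok].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = np.nan, np.nan
            note = "zero variance"
        else:
            r, p = sps.pearsonr(x, y)
            note = ""
        rows.append(
            {
                "site": site,
                "r": float(r),
                "p_value": float(p),
                "n": n,
                "std_methylation": float(np.std(x, ddof=1)),
                "note": note,
            }
        )
    expr_clean = expr.dropna().to_numpy(dtype=float)
    std_expression = float(np.std(expr_clean, ddof=1)) if expr_clean.size > 1 else float("nan")
    return pd.DataFrame(rows), std_expression


def er_methylation_report(
    betas: pd.DataFrame,
    annotations: pd.DataFrame,
    sites: Optional[Sequence[str]] = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-site ER-positive vs ER-negative comparison of (corrected) betas.

    ``annotations`` is indexed by sample with an ``er_status`` column
    ("positive"/"negative"); samples without annotation are excluded and
    counted.  Each site gets a two-sided rank-sum p and a direction
    ("ER+ higher" / "ER- higher" by mean difference).  Raw p-values are
    reported; a Bonferroni column is added on request (off by default:
    per-site values are conventionally reported uncorrected).
    """
    if "er_status" not in annotations.columns:
        raise ValueError("annotations must have an 'er_status' column")
    er = annotations["er_status"].reindex(betas.columns)
    n_unannotated = int(er.isna().sum())
    pos_samples = er.index[er == "positive"]
    neg_samples = er.index[er == "negative"]
    site_list = list(sites) if sites is not None else list(betas.index)
    rows = []
    for site in site_list:
        vals = betas.loc[site]
        a = vals[pos_samples].dropna().to_numpy(dtype=float)
        b = vals[neg_samples].dropna().to_numpy(dtype=float)
        if a.size < 1 or b.size < 1:
            rows.append(
                {
                    "site": site,
                    "n_er_pos": a.size,
                    "n_er_neg": b.size,
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "direction": "",
                    "n_unannotated": n_unannotated,
                    "flag": "missing group",
                }
            )
            continue
        cmp = wilcoxon_two_sided(a, b, "ER-positive", "ER-negative")
        flag = cmp.flag
        if a.size < 2 or b.size < 2:
            flag = (flag + "; " if flag else "") + "underpowered"
        direction = "ER+ higher" if a.mean() > b.mean() else "ER- higher"
        rows.append(
            {
                "site": site,
                "n_er_pos": a.size,
                "n_er_neg": b.size,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "direction": direction,
                "n_unannotated": n_unannotated,
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    if bonferroni and out["p_value"].notna().any():
        mask = out["p_value"].notna()
        corrected = multipletests(out.loc[mask, "p_value"], method="bonferroni")[1]
        out.loc[mask, "p_bonferroni"] = corrected
    return out


def chip_enrichment_call(
    target_signal: float,
    gapdh_signals: Sequence[float],
    tsh2b_signal: float,
) -> str:
    """ChIP-qPCR enrichment call with control gating.

    Background is the largest observed GAPDH (negative control) signal.
    If the TSH2B positive control does not rise above background the run
    is ``uninterpretable``; otherwise the target is ``enriched`` when
    strictly above background and ``background`` otherwise.
    """
    gapdh = np.asarray(list(gapdh_signals), dtype=float)
    if gapdh.size < 1:
        raise ValueError("need at least one GAPDH measurement")
    background = float(gapdh.max())
    if tsh2b_signal <= background:
        return "uninterpretable"
    return "enriched" if target_signal > background else "background"
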