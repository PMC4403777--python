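"""Synthetic data generators for every assay in the panel.

Each generator emulates the statistical structure one of the downstream
analyses assumes, with the ground truth recorded alongside, so the whole
pipeline can be exercised with known answers:

* a promoter-like reference sequence with a fixed number of CpG sites,
* bisulfite clone reads derived from epiallele patterns with an imperfect
  conversion rate and seeded PCR duplicates,
* methylation-specific qPCR panels (target + ALU input control + a fully
  methylated reference dilution series) on the Ct scale,
* ER-stratified probe-level beta-value cohorts with bimodal, assay-type-
  specific intensity distributions and expression anti-coupled to promoter
  methylation through a Gaussian copula,
* melt curves built from logistic transitions at control melting
  temperatures.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clones import ReferenceRegion
from .msmca import MeltProfile

__all__ = [
    "SimTruth",
    "BetaCohort",
    "gen_reference",
    "gen_clones",
    "gen_qpcr_panel",
    "gen_beta_cohort",
    "gen_melt_curve",
    "gen_expression_panel",
    "spearman_to_pearson",
]

# Cohort-shape defaults: the breast-tumor cohort the analyses are sized for.
N_ER_POSITIVE = 460
N_ER_NEGATIVE = 139

# Promoter amplicon defaults: a 273 bp region holding 28 CpG sites.
DEFAULT_REGION_BP = 273
DEFAULT_N_CPG = 28
DEFAULT_N_CLONES = 15  # clones sequenced per sample (10-20 in practice)

_QPCR_SLOPE = -3.32  # Ct per log10 dilution at 100% PCR efficiency
_QPCR_INTERCEPTS = {"SOX11": 30.0, "ALUC4": 24.0}
CT_MAX = 40.0  # cycles; at/above this a reaction is censored ("no amplification")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters shared across the generators.

    ``peak_u``/``peak_m`` are the unmethylated/methylated beta-density modes
    for Illumina type II probes; ``peak_u_type1``/``peak_m_type1`` for the
    wider-dynamic-range type I probes.  ``target_rho`` is the intended
    Spearman correlation between promoter methylation and expression,
    ``er_effect`` the additive beta shift on promoter probes in ER-positive
    samples, and ``tm_u``/``tm_m`` the melting temperatures of the fully
    unmethylated (WGA) and fully methylated (IVM) controls.
    """

    seed: int = 0
    allele_patterns: tuple[tuple[int, ...], ...] = ()
    conversion_rate: float = 0.99
    peak_u: float = 0.25
    peak_m: float = 0.75
    peak_u_type1: float = 0.15
    peak_m_type1: float = 0.85
    target_rho: float = -0.7
    er_effect: float = 0.3
    tm_u: float = 78.0
    tm_m: float = 83.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must be in [0, 1]")
        for u, m, label in (
            (self.peak_u, self.peak_m, "type II"),
            (self.peak_u_type1, self.peak_m_type1, "type I"),
        ):
            if not 0.0 < u < m < 1.0:
                raise ValueError(f"{label} peaks must satisfy 0 < peak_u < peak_m < 1")
        if not self.tm_u < self.tm_m:
            raise ValueError("tm_u must be below tm_m")
        if not -1.0 <= self.target_rho <= 1.0:
            raise ValueError("target_rho must be in [-1, 1]")
        if self.allele_patterns:
            lengths = {len(p) for p in self.allele_patterns}
            if len(lengths) != 1:
                raise ValueError("all allele patterns must have equal length")
            if any(v not in (0, 1) for p in self.allele_patterns for v in p):
                raise ValueError("allele patterns must be binary")

    def peaks_for(self, assay_type: str) -> tuple[float, float]:
        if assay_type == "I":
            return self.peak_u_type1, self.peak_m_type1
        if assay_type == "II":
            return self.peak_u, self.peak_m
        raise ValueError(f"unknown assay type {assay_type!r}")


def spearman_to_pearson(rho: float) -> float:
    """Pearson correlation of a bivariate normal whose Spearman rank
    correlation equals ``rho`` (Gaussian-copula inversion)."""
    return float(2.0 * np.sin(np.pi * rho / 6.0))


# ---------------------------------------------------------------------------
# reference sequence


def gen_reference(
    seed: int,
    length_bp: int = DEFAULT_REGION_BP,
    n_cpg: int = DEFAULT_N_CPG,
) -> ReferenceRegion:
    """Random promoter-like sequence with exactly ``n_cpg`` CG dinucleotides.

    The sequence also carries at least one non-CpG cytosine whenever
    ``n_cpg > 0`` room allows, so conversion-rate QC is always defined.

    Raises
    ------
    ValueError
        If the CpG sites cannot fit (``2*n_cpg >= length_bp`` for
        ``n_cpg > 0``; a spare position is needed for the non-CpG C).
    """
    if length_bp < 1 or n_cpg < 0:
        raise ValueError("length_bp must be >= 1 and n_cpg >= 0")
    if n_cpg > 0 and length_bp < 2 * n_cpg + 1:
        raise ValueError(
            f"infeasible: {n_cpg} non-overlapping CpG sites plus a non-CpG "
            f"cytosine do not fit in {length_bp} bp"
        )
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length_bp))
    planned: set[int] = set()
    if n_cpg > 0:
        # place k non-overlapping CG dominoes: choose k of (L-k) slots, shift
        slots = np.sort(rng.choice(length_bp - n_cpg, size=n_cpg, replace=False))
        starts = slots + np.arange(n_cpg)
        for s in starts:
            seq[s], seq[s + 1] = "C", "G"
            planned.update((s, s + 1))
    # remove accidental CG dinucleotides in the fill (both positions are
    # always fill positions: planned C is always followed by planned G)
    for i in range(length_bp - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in planned:
            seq[i + 1] = str(rng.choice(list("AT")))
    # guarantee a non-CpG cytosine for conversion QC
    if not any(
        seq[i] == "C" and (i + 1 >= length_bp or seq[i + 1] != "G")
        for i in range(length_bp)
    ):
        candidates = [
            i
            for i in range(length_bp)
            if i not in planned and (i + 1 >= length_bp or seq[i + 1] != "G")
        ]
        if not candidates:  # pragma: no cover - excluded by the feasibility check
            raise ValueError("infeasible: no room for a non-CpG cytosine")
        seq[int(rng.choice(candidates))] = "C"
    return ReferenceRegion.from_sequence("".join(seq), name=f"sim_region_seed{seed}")


# ---------------------------------------------------------------------------
# bisulfite clones


def _clone_from_pattern(
    ref: ReferenceRegion,
    pattern: Sequence[int],
    conversion_rate: float,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Bisulfite top-strand read of one allele; returns (sequence, realized rate)."""
    seq = list(ref.sequence)
    for p, meth in zip(ref.cpg_positions, pattern):
        seq[p] = "C" if meth else "T"
    n_conv = 0
    for p in ref.non_cpg_c_positions:
        if rng.random() < conversion_rate:
            seq[p] = "T"
            n_conv += 1
    realized = n_conv / len(ref.non_cpg_c_positions) if ref.non_cpg_c_positions else float("nan")
    return "".join(seq), realized


def gen_clones(
    ref: ReferenceRegion,
    truth: SimTruth,
    n_clones: int = DEFAULT_N_CLONES,
    dup_fraction: float = 0.0,
    seed: Optional[int] = None,
    pattern_weights: Optional[Sequence[float]] = None,
    exact_proportions: bool = False,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate cloned bisulfite reads from the truth's epiallele patterns.

    A ``round(dup_fraction * n_clones)`` tail of the clone list consists of
    exact copies of earlier clones (seeded PCR duplicates); the generator
    retries base-clone draws so that, whenever the conversion noise makes it
    possible, base clones are pairwise distinct and sequence-level dedup
    recovers them exactly.

    With ``exact_proportions=True`` the base clones follow
    ``pattern_weights`` deterministically (largest-remainder apportionment)
    rather than by multinomial sampling, so per-CpG fractions equal the
    mixture proportions exactly in the noise-free limit.

    Returns the clones as (id, sequence) pairs plus a truth table with the
    source pattern, realized conversion rate and duplicate origin per clone.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not 0.0 <= dup_fraction <= 1.0:
        raise ValueError("dup_fraction must be in [0, 1]")
    patterns = truth.allele_patterns
    if not patterns:
        raise ValueError("truth.allele_patterns is empty")
    if any(len(p) != ref.n_cpg for p in patterns):
        raise ValueError("allele pattern length must equal the reference CpG count")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    weights = None
    if pattern_weights is not None:
        w = np.asarray(pattern_weights, dtype=float)
        weights = w / w.sum()

    n_dup = int(round(dup_fraction * n_clones))
    n_dup = min(n_dup, n_clones - 1)
    n_base = n_clones - n_dup

    pattern_choice: Optional[list[int]] = None
    if exact_proportions:
        w = weights if weights is not None else np.full(len(patterns), 1 / len(patterns))
        quota = w * n_base
        counts = np.floor(quota).astype(int)
        remainder = quota - counts
        for k in np.argsort(-remainder)[: n_base - counts.sum()]:
            counts[k] += 1
        pattern_choice = [k for k, c in enumerate(counts) for _ in range(c)]
        rng.shuffle(pattern_choice)

    records = []
    clones: list[tuple[str, str]] = []
    base_seqs: set[str] = set()
    for i in range(n_base):
        k = pattern_choice[i] if pattern_choice is not None else int(
            rng.choice(len(patterns), p=weights)
        )
        seq, realized = _clone_from_pattern(ref, patterns[k], truth.conversion_rate, rng)
        for _ in range(200):  # distinct base clones whenever noise allows it
            if seq not in base_seqs:
                break
            seq, realized = _clone_from_pattern(ref, patterns[k], truth.conversion_rate, rng)
        base_seqs.add(seq)
        cid = f"clone_{i:03d}"
        clones.append((cid, seq))
        records.append(
            {
                "clone_id": cid,
                "pattern": "".join(map(str, patterns[k])),
                "realized_conversion_rate": realized,
                "duplicate_of": "",
            }
        )
    for j in range(n_dup):
        src = int(rng.integers(n_base))
        cid = f"clone_{n_base + j:03d}"
        clones.append((cid, clones[src][1]))
        rec = records[src]
        records.append(
            {
                "clone_id": cid,
                "pattern": rec["pattern"],
                "realized_conversion_rate": rec["realized_conversion_rate"],
                "duplicate_of": rec["clone_id"],
            }
        )
    return clones, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# methylation-specific qPCR


def gen_qpcr_panel(
    truth_pmr_by_sample: Mapping[str, float],
    dilutions: Sequence[float] = (1.0, 0.1, 0.01, 0.001),
    noise_sd: float = 0.2,
    seed: int = 0,
    slope: float = _QPCR_SLOPE,
    intercepts: Mapping[str, float] = _QPCR_INTERCEPTS,
    n_replicates: int = 2,
    ct_max: float = CT_MAX,
) -> pd.DataFrame:
    """Simulate a MethyLight qPCR plate on the Ct scale.

    For every sample, duplicate reactions for the methylation target
    (SOX11) and the ALU input control are emitted, plus a dilution series
    of the fully methylated reference (sample id ``IVM``) for each target.
    Ct follows ``intercept + slope*log10(quantity) + N(0, noise_sd)``; the
    target quantity of a sample with truth PMR ``p`` is ``p/100`` of its
    ALU quantity, so noise-free recovery is exact.  Quantity zero (and any
    Ct reaching ``ct_max``) is censored at ``ct_max``.
    """
    dil = np.asarray(dilutions, dtype=float)
    if dil.size < 1 or np.any(dil <= 0):
        raise ValueError("dilutions must be positive")
    if np.any(np.diff(dil) >= 0):
        raise ValueError("dilutions must be strictly descending")
    rng = np.random.default_rng(seed)

    def ct_of(quantity: float, target: str) -> float:
        if quantity <= 0:
            return ct_max
        ct = intercepts[target] + slope * np.log10(quantity) + rng.normal(0.0, noise_sd)
        return float(min(ct, ct_max))

    rows = []
    for target in intercepts:
        for d in dil:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": "IVM",
                        "target": target,
                        "replicate": rep,
                        "dilution": d,
                        "Ct": ct_of(d, target),
                    }
                )
    for sample, pmr in truth_pmr_by_sample.items():
        if pmr < 0:
            raise ValueError(f"truth PMR must be >= 0 (sample {sample})")
        quantities = {"SOX11": pmr / 100.0, "ALUC4": 1.0}
        for target, q in quantities.items():
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "target": target,
                        "replicate": rep,
                        "dilution": np.nan,
                        "Ct": ct_of(q, target),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# array beta cohort


def _beta_params_from_mode(mode: float, concentration: float) -> tuple[float, float]:
    """Beta(a, b) with the given mode and a+b = concentration (>2)."""
    a = mode * (concentration - 2.0) + 1.0
    return a, concentration - a


@dataclass
class BetaCohort:
    """A simulated probe x sample methylation cohort with its truth."""

    betas: pd.DataFrame  # probes x samples, in [0, 1], NaN = masked
    probe_info: pd.DataFrame  # index probe; assay_type, is_promoter, true_state
    annotations: pd.DataFrame  # index sample; er_status, entity
    expression: pd.Series  # per sample, log2(count+1) scale
    truth: SimTruth
    latent: pd.Series = field(default=None)  # per-sample promoter methylation latent

    def to_signals_frame(
        self, seed: int = 0, total_intensity: float = 5000.0
    ) -> pd.DataFrame:
        """Long-format probe-signal table (probe, sample, M, U, detection_p,
        beads, assay_type) whose implied beta values reproduce ``betas``.
        Masked entries are encoded as failed detections."""
        rng = np.random.default_rng(seed)
        long = self.betas.stack(future_stack=True).rename("beta").reset_index()
        long.columns = ["probe", "sample", "beta"]
        n = len(long)
        total = total_intensity * rng.lognormal(0.0, 0.25, size=n)
        beta = long["beta"].to_numpy()
        masked = ~np.isfinite(beta)
        beta_fill = np.where(masked, 0.5, beta)
        long["M"] = beta_fill * total
        long["U"] = (1.0 - beta_fill) * total
        long["detection_p"] = np.where(
            masked, 0.2, rng.uniform(0.0, 0.01, size=n)
        )
        long["beads"] = rng.integers(8, 25, size=n)
        long["assay_type"] = self.probe_info.loc[long["probe"], "assay_type"].to_numpy()
        return long


def gen_beta_cohort(
    n_samples: int,
    n_probes: int,
    truth: SimTruth,
    seed: Optional[int] = None,
    n_promoter: int = 5,
    er_pos_fraction: float = N_ER_POSITIVE / (N_ER_POSITIVE + N_ER_NEGATIVE),
    n_er_pos: Optional[int] = None,
    concentration: float = 50.0,
    missing_fraction: float = 0.0,
    expression_mu: float = 6.0,
    expression_sd: float = 2.42,
) -> BetaCohort:
    """Simulate an ER-stratified beta-value cohort with coupled expression.

    Background probes carry a fixed unmethylated/methylated state and draw
    betas from Beta-distribution components whose modes sit at the
    assay-type-specific truth peaks.  Promoter probes share a per-sample
    latent methylation level (uniform between the assay's peaks); ER-positive
    samples additionally receive ``truth.er_effect`` on promoter probes,
    clipped to [0, 1].  Expression is generated on the log2(count+1) scale,
    coupled to the promoter latent through a Gaussian copula calibrated so
    the rank correlation with promoter methylation equals
    ``truth.target_rho``.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if n_promoter > n_probes:
        raise ValueError("n_promoter cannot exceed n_probes")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    samples = [f"S{i:04d}" for i in range(n_samples)]
    if n_er_pos is None:
        n_er_pos = int(round(er_pos_fraction * n_samples))
    n_er_pos = min(max(n_er_pos, 0), n_samples)
    er = np.array(["positive"] * n_er_pos + ["negative"] * (n_samples - n_er_pos))
    rng.shuffle(er)

    promoter_names = [f"cg_prom_{k:02d}" for k in range(n_promoter)]
    background_names = [f"cg_bg_{k:05d}" for k in range(n_probes - n_promoter)]
    probes = promoter_names + background_names
    # alternate assay types over all probes so both strata are populated
    assay = np.array(["I", "II"])[np.arange(n_probes) % 2]
    is_prom = np.array([p.startswith("cg_prom") for p in probes])

    # latent per-sample promoter methylation and coupled expression
    r = spearman_to_pearson(truth.target_rho)
    z = rng.standard_normal(n_samples)
    w = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n_samples)
    u = stats.norm.cdf(z)  # uniform latent; high = more methylated
    expression = expression_mu + expression_sd * w
    expression = np.clip(expression, 0.0, None)  # log2(count+1) is non-negative

    bg_state = rng.random(len(background_names)) < 0.5  # True = methylated
    betas = np.empty((n_probes, n_samples))
    for i, probe in enumerate(probes):
        pu, pm = truth.peaks_for(assay[i])
        if is_prom[i]:
            mode = pu + u * (pm - pu)
            mode = np.where(er == "positive", mode + truth.er_effect, mode)
            mode = np.clip(mode, 0.02, 0.98)
            a = mode * (concentration - 2.0) + 1.0
            betas[i] = rng.beta(a, concentration - a)
        else:
            mode = pm if bg_state[i - n_promoter] else pu
            a, b = _beta_params_from_mode(mode, concentration)
            betas[i] = rng.beta(a, b, size=n_samples)
    betas = np.clip(betas, 0.0, 1.0)
    if missing_fraction > 0:
        mask = rng.random(betas.shape) < missing_fraction
        betas[mask] = np.nan

    beta_df = pd.DataFrame(betas, index=probes, columns=samples)
    probe_info = pd.DataFrame(
        {
            "assay_type": assay,
            "is_promoter": is_prom,
            "true_state": np.where(
                is_prom, "latent", np.where(np.r_[np.zeros(n_promoter, bool), bg_state], "M", "U")
            ),
        },
        index=probes,
    )
    annotations = pd.DataFrame(
        {"er_status": er, "entity": "breast"}, index=samples
    )
    return BetaCohort(
        betas=beta_df,
        probe_info=probe_info,
        annotations=annotations,
        expression=pd.Series(expression, index=samples, name="log2_expression"),
        truth=truth,
        latent=pd.Series(u, index=samples, name="promoter_latent"),
    )


# ---------------------------------------------------------------------------
# melt curves

MELT_CLASSES = ("unmethylated", "methylated", "mixed")


def gen_melt_curve(
    class_label: str,
    truth: SimTruth,
    noise_sd: float = 0.01,
    seed: int = 0,
    t_min: float = 65.0,
    t_max: float = 95.0,
    step: float = 0.2,
    transition_scale: float = 0.5,
    weights: Optional[tuple[float, float]] = None,
    sample_id: str = "sim",
) -> MeltProfile:
    """Simulate a SYBR-type melt curve as a sum of logistic transitions.

    The fluorescence of an epiallele population melting at ``tm`` follows a
    falling logistic ``w / (1 + exp((T - tm)/s))`` so the negative
    derivative peaks exactly at ``tm``.  Class weights on the (tm_u, tm_m)
    transitions: unmethylated (1, 0), methylated (0, 1), mixed (0.5, 0.5)
    or as given.  Noise is additive Gaussian on a unit dynamic range; the
    noise-free curve is monotone non-increasing.
    """
    default_weights = {
        "unmethylated": (1.0, 0.0),
        "methylated": (0.0, 1.0),
        "mixed": (0.5, 0.5),
    }
    if class_label not in default_weights:
        raise ValueError(
            f"unknown class_label {class_label!r}; expected one of {MELT_CLASSES}"
        )
    w_u, w_m = weights if weights is not None else default_weights[class_label]
    rng = np.random.default_rng(seed)
    temps = np.arange(t_min, t_max + step / 2, step)
    fl = w_u / (1.0 + np.exp((temps - truth.tm_u) / transition_scale))
    fl = fl + w_m / (1.0 + np.exp((temps - truth.tm_m) / transition_scale))
    fl = fl + 0.05  # instrument baseline
    if noise_sd > 0:
        fl = fl + rng.normal(0.0, noise_sd, size=temps.size)
    return MeltProfile(temperature=temps, fluorescence=fl, sample_id=sample_id)


# ---------------------------------------------------------------------------
# joint methylation + expression panel (cell-line style, n ~ 19)


def gen_expression_panel(
    n_samples: int = 19,
    truth: SimTruth = SimTruth(),
    noise_sd: float = 0.2,
    seed: int = 0,
    ct_reference: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell-line-style panel: qPCR methylation plate plus RT-qPCR expression.

    Per-sample truth PMR (uniform on [0, 100] through the copula latent)
    and RT-qPCR target Ct are anti-coupled so the rank correlation between
    true PMR and true expression equals ``truth.target_rho``.  Returns
    (MethyLight qPCR table, expression Ct table, truth table).
    """
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson(truth.target_rho)
    z = rng.standard_normal(n_samples)
    w = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n_samples)
    pmr_truth = 100.0 * stats.norm.cdf(z)
    ct_target = 28.0 - 3.0 * w  # higher expression = lower Ct

    samples = [f"CL{i:02d}" for i in range(n_samples)]
    qpcr = gen_qpcr_panel(
        dict(zip(samples, pmr_truth)),
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    expr = pd.DataFrame(
        {
            "sample": samples,
            "source": "rtqpcr",
            "ct_target": ct_target + rng.normal(0.0, noise_sd, size=n_samples),
            "ct_reference": ct_reference,
        }
    )
    truth_table = pd.DataFrame(
        {"sample": samples, "true_pmr": pmr_truth, "true_ct_target": ct_target}
    )
    return qpcr, expr, truth_table
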