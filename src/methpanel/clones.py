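"""Bisulfite clone-sequencing analysis of a promoter CpG island.

After sodium-bisulfite treatment, unmethylated cytosines read as thymine
while 5-methyl-cytosines stay cytosine.  Sequencing individual cloned
amplicons therefore reports the methylation state of each CpG site on each
allele.  This module calls per-CpG methylation from clone sequences,
applies the two standard QC filters (bisulfite-conversion rate on non-CpG
cytosines, and removal of identical clones as presumed PCR duplicates) and
summarises the retained alleles into per-site methylated fractions and a
sample mean.

Coordinates are 0-based; a CpG site is identified by the position of its C
on the top strand.  Clones are expected to be full-length amplicon reads:
no gapped alignment is performed (mismatched bases at a CpG give a missing
call rather than an alignment attempt).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceRegion",
    "CloneCall",
    "CloneCallSet",
    "MethylationMatrix",
    "call_clone",
    "filter_by_conversion",
    "dedup_clones",
    "build_matrix",
    "average_pyro_replicates",
    "process_clones",
    "read_fasta",
    "write_fasta",
]

# call codes
METHYLATED = 1
UNMETHYLATED = 0
MISSING = -1

_VALID_BASES = frozenset("ACGT")


class CloneQCError(ValueError):
    """Raised for structurally invalid clone/reference input."""


@dataclass(frozen=True)
class ReferenceRegion:
    """A genomic reference segment with its CpG landmarks.

    ``cpg_positions`` holds the 0-based index of the C of every CG
    dinucleotide; ``non_cpg_c_positions`` the remaining cytosines, which
    are the substrate of the bisulfite-conversion QC (a fully converted
    clone reads T at all of them).
    """

    sequence: str
    cpg_positions: tuple[int, ...]
    non_cpg_c_positions: tuple[int, ...]
    name: str = "region"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            raise CloneQCError(f"reference contains non-ACGT characters: {bad}")
        for name in ("cpg_positions", "non_cpg_c_positions"):
            pos = getattr(self, name)
            if list(pos) != sorted(set(pos)):
                raise CloneQCError(f"{name} must be strictly increasing")
        if set(self.cpg_positions) & set(self.non_cpg_c_positions):
            raise CloneQCError("CpG and non-CpG C position lists overlap")
        for p in self.cpg_positions:
            if not (0 <= p < len(seq) - 1 and seq[p] == "C" and seq[p + 1] == "G"):
                raise CloneQCError(f"position {p} is not the C of a CG dinucleotide")
        for p in self.non_cpg_c_positions:
            if not (0 <= p < len(seq)) or seq[p] != "C":
                raise CloneQCError(f"position {p} is not a cytosine")
            if p + 1 < len(seq) and seq[p + 1] == "G":
                raise CloneQCError(f"position {p} is a CpG cytosine, not a non-CpG C")

    @classmethod
    def from_sequence(cls, sequence: str, name: str = "region") -> "ReferenceRegion":
        """Locate CpG and non-CpG cytosines in ``sequence``."""
        seq = sequence.upper()
        cpg, non_cpg = [], []
        for i, base in enumerate(seq):
            if base != "C":
                continue
            if i + 1 < len(seq) and seq[i + 1] == "G":
                cpg.append(i)
            else:
                non_cpg.append(i)
        return cls(seq, tuple(cpg), tuple(non_cpg), name=name)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CloneCall:
    """Per-clone methylation calls and QC state."""

    clone_id: str
    sequence: str
    calls: np.ndarray  # int8 vector over CpG sites: 1/0/-1
    conversion_rate: float  # NaN if no informative non-CpG C position
    conversion_ok: bool = True
    duplicate_of: Optional[str] = None

    @property
    def retained(self) -> bool:
        return self.conversion_ok and self.duplicate_of is None


@dataclass
class CloneCallSet:
    """All clone calls for one sample against one reference."""

    ref: ReferenceRegion
    clones: list[CloneCall] = field(default_factory=list)
    conversion_threshold: Optional[float] = None

    def __iter__(self):
        return iter(self.clones)

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def retained(self) -> list[CloneCall]:
        return [c for c in self.clones if c.retained]

    def qc_report(self) -> dict:
        rates = [c.conversion_rate for c in self.clones]
        return {
            "n_clones": len(self.clones),
            "n_retained": len(self.retained),
            "n_poor_conversion": sum(not c.conversion_ok for c in self.clones),
            "n_duplicates": sum(c.duplicate_of is not None for c in self.clones),
            "conversion_threshold": self.conversion_threshold,
            "conversion_rates": rates,
        }

    def qc_json(self) -> str:
        return json.dumps(self.qc_report(), indent=2)


@dataclass
class MethylationMatrix:
    """Retained alleles x CpG sites, with per-site fractions and a sample mean.

    ``per_cpg_fraction[j]`` is methylated calls over non-missing calls at
    site j (NaN when every call is missing); ``sample_mean`` averages the
    defined site fractions.  ``no_data`` marks the degenerate case of zero
    retained alleles -- fractions are then NaN, never silently zero.
    """

    calls: np.ndarray  # (n_alleles, n_sites) int8
    allele_ids: list[str]
    per_cpg_fraction: np.ndarray
    sample_mean: float
    no_data: bool = False

    def to_lollipop_frame(self) -> pd.DataFrame:
        """Alleles x sites table with 1/0/NA entries (lollipop-plot layout)."""
        data = self.calls.astype(float)
        data[data == MISSING] = np.nan
        return pd.DataFrame(
            data,
            index=self.allele_ids,
            columns=[f"cpg_{j}" for j in range(self.calls.shape[1])],
        )

    def to_lollipop_tsv(self, path) -> None:
        self.to_lollipop_frame().to_csv(path, sep="\t", na_rep="NA", index_label="allele")

    def fractions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_index": np.arange(self.per_cpg_fraction.size),
                "methylated_fraction": self.per_cpg_fraction,
            }
        )


def call_clone(ref: ReferenceRegion, clone: str) -> tuple[np.ndarray, float]:
    """Call per-CpG methylation for one clone and compute its conversion rate.

    At each CpG position, C reads as methylated, T as unmethylated and any
    other base as missing.  The conversion rate is the fraction of non-CpG
    cytosine positions read as T among those read as C or T; positions with
    other bases are uninformative and excluded from the denominator.

    Raises
    ------
    CloneQCError
        If the clone length differs from the reference, or the reference
        has no non-CpG cytosine (the rate would be undefined for every
        clone).
    """
    seq = clone.upper()
    if len(seq) != len(ref):
        raise CloneQCError(
            f"clone length {len(seq)} != reference length {len(ref)}; "
            "clones must be untrimmed full-length amplicons"
        )
    if not ref.non_cpg_c_positions:
        raise CloneQCError(
            "reference has no non-CpG cytosine: conversion rate undefined"
        )
    calls = np.full(ref.n_cpg, MISSING, dtype=np.int8)
    for j, p in enumerate(ref.cpg_positions):
        base = seq[p]
        if base == "C":
            calls[j] = METHYLATED
        elif base == "T":
            calls[j] = UNMETHYLATED
    converted = unconverted = 0
    for p in ref.non_cpg_c_positions:
        base = seq[p]
        if base == "T":
            converted += 1
        elif base == "C":
            unconverted += 1
    denom = converted + unconverted
    rate = converted / denom if denom else float("nan")
    return calls, rate


def filter_by_conversion(callset: CloneCallSet, threshold: float = 0.95) -> CloneCallSet:
    """Flag clones whose bisulfite conversion rate falls below ``threshold``.

    Removal is strict: a clone at exactly the threshold is retained.
    Clones with an undefined rate (no informative non-CpG C read) fail QC.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    clones = [
        replace(
            c,
            conversion_ok=bool(np.isfinite(c.conversion_rate) and c.conversion_rate >= threshold),
        )
        for c in callset.clones
    ]
    return CloneCallSet(callset.ref, clones, conversion_threshold=threshold)


def dedup_clones(callset: CloneCallSet) -> CloneCallSet:
    """Flag later exact-sequence copies of earlier clones (presumed PCR duplicates).

    Keys on the full nucleotide sequence, not the call pattern: two alleles
    with the same methylation pattern but different conversion errors are
    plausibly independent.  Input order is preserved; the first occurrence
    is kept.
    """
    seen: dict[str, str] = {}
    clones = []
    for c in callset.clones:
        first = seen.get(c.sequence)
        if first is None:
            seen[c.sequence] = c.clone_id
            clones.append(replace(c, duplicate_of=None))
        else:
            clones.append(replace(c, duplicate_of=first))
    return CloneCallSet(callset.ref, clones, conversion_threshold=callset.conversion_threshold)


def build_matrix(callset: CloneCallSet) -> MethylationMatrix:
    """Summarise retained clones into per-site fractions and a sample mean.

    Sites where every retained call is missing get a NaN fraction and are
    excluded from the sample mean.  Zero retained clones yields an explicit
    ``no_data`` result.
    """
    retained = callset.retained
    n_sites = callset.ref.n_cpg
    if not retained:
        return MethylationMatrix(
            calls=np.empty((0, n_sites), dtype=np.int8),
            allele_ids=[],
            per_cpg_fraction=np.full(n_sites, np.nan),
            sample_mean=float("nan"),
            no_data=True,
        )
    calls = np.vstack([c.calls for c in retained])
    meth = (calls == METHYLATED).sum(axis=0)
    informative = (calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(informative > 0, meth / np.maximum(informative, 1), np.nan)
    mean = float(np.nanmean(frac)) if np.isfinite(frac).any() else float("nan")
    return MethylationMatrix(
        calls=calls,
        allele_ids=[c.clone_id for c in retained],
        per_cpg_fraction=frac,
        sample_mean=mean,
    )


def average_pyro_replicates(runs: Sequence[Sequence[float]]) -> np.ndarray:
    """Average per-site percent methylation over replicate sequencing runs.

    With fewer than two runs the single run is passed through with a
    warning -- replicate averaging is the intended use.
    """
    arrays = [np.asarray(r, dtype=float) for r in runs]
    if not arrays:
        raise ValueError("no runs provided")
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"runs disagree on site count: {sorted(lengths)}")
    if len(arrays) < 2:
        warnings.warn("fewer than 2 replicate runs; returning the single run unchanged")
        return arrays[0].copy()
    return np.mean(arrays, axis=0)


def process_clones(
    ref: ReferenceRegion,
    clones: Iterable[tuple[str, str]],
    conversion_threshold: float = 0.95,
    dedup: bool = True,
) -> tuple[CloneCallSet, MethylationMatrix]:
    """Full clone pipeline: call, conversion-filter, optionally dedup, summarise.

    ``dedup=False`` keeps sequence-identical clones; useful when clone
    multiplicity is known to be real (e.g. noise-free simulation) rather
    than a PCR artifact.
    """
    callset = CloneCallSet(ref)
    for clone_id, seq in clones:
        calls, rate = call_clone(ref, seq)
        callset.clones.append(CloneCall(clone_id, seq.upper(), calls, rate))
    callset = filter_by_conversion(callset, conversion_threshold)
    if dedup:
        callset = dedup_clones(callset)
    return callset, build_matrix(callset)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")
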