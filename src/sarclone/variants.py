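"""Somatic variant post-calling filter cascade.

Starting from call-level records of a tumor/normal pair, a variant is kept as
a non-synonymous exonic somatic variant (ESV) when it meets every clause of
the cascade: read depth >=20 in tumor and >=10 in the matched normal, mean
base quality >=20, mutated allele frequency (MAF) >=10% in the tumor and
strictly <1% in the normal, a non-synonymous exonic consequence, and at least
2 supporting reads in each sequencing orientation (the in-silico stand-in for
manual inspection of strand balance).

One cross-sample rescue pass follows: if the identical variant fully passes in
some other sample of the same patient, it is kept in a sample where it has
merely >=3 supporting reads (any orientation split). Rescued records are
labelled and can never themselves rescue a third sample.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal

CONSEQUENCES = (
    "synonymous", "missense", "stop_gain", "stop_loss", "frameshift",
    "inframe_indel", "splice_site", "other_noncoding",
)

#: Consequence classes counted as non-synonymous exonic. splice_site is
#: excluded on a literal reading (splice sites are intronic).
NONSYNONYMOUS_EXONIC = frozenset(
    {"missense", "stop_gain", "stop_loss", "frameshift", "inframe_indel"})

VariantKey = tuple[str, int, str, str]
ProvenanceLabel = Literal["full_pass", "rescued"]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic call in one sample, with everything the cascade needs."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    tumor_depth: int
    normal_depth: int
    tumor_alt_fwd: int
    tumor_alt_rev: int
    normal_alt: int
    mean_base_quality: float
    consequence: str
    sample_id: str
    patient_id: str

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if min(self.tumor_depth, self.normal_depth, self.tumor_alt_fwd,
               self.tumor_alt_rev, self.normal_alt) < 0:
            raise ValueError("read counts must be non-negative")
        if self.tumor_alt_fwd + self.tumor_alt_rev > self.tumor_depth:
            raise ValueError("tumor alt reads exceed tumor depth")
        if self.normal_alt > self.normal_depth:
            raise ValueError("normal alt reads exceed normal depth")

    @property
    def identity(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_alt(self) -> int:
        return self.tumor_alt_fwd + self.tumor_alt_rev


@dataclass(frozen=True)
class FilterThresholds:
    min_tumor_depth: int = 20
    min_normal_depth: int = 10
    min_base_quality: float = 20.0
    min_tumor_maf: float = 0.10        # inclusive
    max_normal_maf: float = 0.01       # exclusive
    min_reads_per_orientation: int = 2
    rescue_min_reads: int = 3

    def __post_init__(self):
        if min(self.min_tumor_depth, self.min_normal_depth,
               self.min_base_quality, self.min_tumor_maf,
               self.max_normal_maf, self.min_reads_per_orientation,
               self.rescue_min_reads) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_tumor_maf <= self.max_normal_maf:
            raise ValueError("min_tumor_maf must exceed max_normal_maf")


def tumor_maf(v: VariantRecord) -> float:
    """Mutated allele frequency in the tumor; NaN when depth is 0 (fails filter)."""
    if v.tumor_depth == 0:
        return math.nan
    return v.tumor_alt / v.tumor_depth


def normal_maf(v: VariantRecord) -> float:
    """MAF in the matched normal; NaN when depth is 0 (somatic status unverifiable)."""
    if v.normal_depth == 0:
        return math.nan
    return v.normal_alt / v.normal_depth


def passes_full_criteria(v: VariantRecord,
                         t: FilterThresholds = FilterThresholds()) -> bool:
    """True iff the record meets every clause of the full cascade."""
    n_maf = normal_maf(v)
    t_maf = tumor_maf(v)
    return (
        v.tumor_depth >= t.min_tumor_depth
        and v.normal_depth >= t.min_normal_depth
        and v.mean_base_quality >= t.min_base_quality
        and not math.isnan(t_maf) and t_maf >= t.min_tumor_maf
        and not math.isnan(n_maf) and n_maf < t.max_normal_maf
        and v.consequence in NONSYNONYMOUS_EXONIC
        and v.tumor_alt_fwd >= t.min_reads_per_orientation
        and v.tumor_alt_rev >= t.min_reads_per_orientation
    )


def filter_patient_variants(
    records: Iterable[VariantRecord],
    t: FilterThresholds = FilterThresholds(),
) -> dict[str, dict[VariantKey, ProvenanceLabel]]:
    """Apply the cascade plus one cross-sample rescue pass to one patient.

    Returns, per sample id, the kept variant identities mapped to their
    provenance label (``full_pass`` or ``rescued``). The kept set is the fixed
    point of a single rescue pass: a rescued record cannot rescue another
    sample.
    """
    records = list(records)
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValueError(
            f"records mix patients {sorted(patients)}; filter one patient at a time")

    kept: dict[str, dict[VariantKey, ProvenanceLabel]] = defaultdict(dict)
    by_identity: dict[VariantKey, list[VariantRecord]] = defaultdict(list)
    for r in records:
        by_identity[r.identity].append(r)

    for identity, recs in by_identity.items():
        full = {r.sample_id for r in recs if passes_full_criteria(r, t)}
        for r in recs:
            if r.sample_id in full:
                kept[r.sample_id][identity] = "full_pass"
            elif full - {r.sample_id} and r.tumor_alt >= t.rescue_min_reads:
                kept[r.sample_id][identity] = "rescued"
    return dict(kept)


def kept_sets(filtered: dict[str, dict[VariantKey, ProvenanceLabel]]
              ) -> dict[str, set[VariantKey]]:
    """Collapse a filter result to plain identity sets per sample."""
    return {s: set(m) for s, m in filtered.items()}
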