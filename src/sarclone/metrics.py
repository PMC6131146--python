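"""Patient-level longitudinal statistics.

Given filtered variant sets and copy-number profiles per lesion, these
functions classify each variant as trunk / shared / private across a
patient's lesions, quantify intra-lesional heterogeneity, convert per-cell
cytogenetic counts to non-clonal fractions, and weigh the evidence on whether
a metastasis arose from the primary tumor or from a local recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .genome import GenomeModel, default_genome
from .intervals import (SegmentProfile, jaccard_index, shared_breakpoints,
                        _span_dict, _intersect_spans, _total)
from .io import CytoSummary
from .variants import VariantKey

TrunkLabel = str  # "trunk" | "shared" | "private"


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise similarity between two samples or lesions."""

    sample_pair: tuple[str, str]
    jaccard: float
    shared_breakpoint_count: int = 0
    shared_breakpoint_fraction_a: float = 0.0
    shared_breakpoint_fraction_b: float = 0.0
    shared_esv: frozenset[VariantKey] = frozenset()
    private_esv_a: frozenset[VariantKey] = frozenset()
    private_esv_b: frozenset[VariantKey] = frozenset()


def compare_pair(name_a: str, name_b: str,
                 segments_a: Optional[SegmentProfile],
                 segments_b: Optional[SegmentProfile],
                 variants_a: Optional[set[VariantKey]] = None,
                 variants_b: Optional[set[VariantKey]] = None,
                 tolerance: Optional[int] = None) -> ComparisonResult:
    """Assemble the pairwise GCS + ESV comparison between two samples/lesions."""
    jac = 0.0
    n_sh, fa, fb = 0, 0.0, 0.0
    if segments_a is not None and segments_b is not None:
        if segments_a.intervals or segments_b.intervals:
            jac = jaccard_index(segments_a, segments_b)
        n_sh, fa, fb = shared_breakpoints(segments_a, segments_b,
                                          tolerance=tolerance)
    va = set(variants_a or ())
    vb = set(variants_b or ())
    return ComparisonResult(
        sample_pair=(name_a, name_b), jaccard=jac,
        shared_breakpoint_count=n_sh,
        shared_breakpoint_fraction_a=fa, shared_breakpoint_fraction_b=fb,
        shared_esv=frozenset(va & vb),
        private_esv_a=frozenset(va - vb), private_esv_b=frozenset(vb - va))


def classify_trunk(lesion_variant_sets: Mapping[str, Iterable[VariantKey]]
                   ) -> dict[VariantKey, TrunkLabel]:
    """Partition a patient's variant identities by how many lesions carry them.

    trunk = present in every lesion; shared = in >=2 lesions but not all;
    private = in exactly one. Lesion-level sets should already be the union
    over that lesion's samples.
    """
    sets = {l: set(v) for l, v in lesion_variant_sets.items()}
    if len(sets) < 2:
        raise ValueError("trunk classification needs at least 2 lesions "
                         "with variant data")
    n = len(sets)
    counts: dict[VariantKey, int] = {}
    for s in sets.values():
        for key in s:
            counts[key] = counts.get(key, 0) + 1
    return {key: ("trunk" if c == n else "shared" if c >= 2 else "private")
            for key, c in counts.items()}


def intra_lesional_esv_concordance(sample_sets: Sequence[Iterable[VariantKey]]
                                   ) -> float:
    """Fraction of a lesion's variants present in all of its k>=2 samples.

    |intersection| / |union| over the samples' variant sets; an empty union
    counts as full concordance (1.0).
    """
    sets = [set(s) for s in sample_sets]
    if len(sets) < 2:
        raise ValueError("concordance needs at least 2 samples from the lesion")
    union = set().union(*sets)
    if not union:
        return 1.0
    inter = set.intersection(*sets)
    return len(inter) / len(union)


def nonclonal_cell_fraction(c: CytoSummary) -> float:
    """Percent of assessed cells with non-clonal structural aberrations (1 dp)."""
    if c.cells_assessed == 0:
        raise ValueError("cells_assessed must be positive")
    return round(100.0 * c.cells_nonclonal_structural / c.cells_assessed, 1)


@dataclass(frozen=True)
class OriginReport:
    uniquely_shared_pt: int
    uniquely_shared_lr: int
    jaccard_pt_met: float
    jaccard_lr_met: float
    verdict: str  # "LR-origin" | "PT-origin" | "inconclusive"


def infer_relapse_origin(pt_variants: Iterable[VariantKey],
                         lr_variants: Iterable[VariantKey],
                         met_variants: Iterable[VariantKey],
                         pt_segments: SegmentProfile,
                         lr_segments: SegmentProfile,
                         met_segments: SegmentProfile,
                         met_mafs: Optional[Mapping[VariantKey, float]] = None,
                         maf_floor: float = 0.05) -> OriginReport:
    """Did the metastasis arise from the PT or from the local recurrence?

    Counts the Met's variants uniquely shared with each candidate parent
    (variants below ``maf_floor`` in the Met are excluded when MAFs are
    supplied) and compares the GCS Jaccard of each candidate pair. The verdict
    names a parent only when both evidence lines agree; ties or disagreement
    are inconclusive.
    """
    for name, val in (("PT", pt_segments), ("LR", lr_segments),
                      ("Met", met_segments)):
        if val is None:
            raise ValueError(f"missing {name} lesion segments")
    pt, lr, met = set(pt_variants), set(lr_variants), set(met_variants)
    if met_mafs is not None:
        met = {v for v in met if met_mafs.get(v, 0.0) > maf_floor}
    uniq_pt = len((met & pt) - lr)
    uniq_lr = len((met & lr) - pt)
    j_pt = jaccard_index(pt_segments, met_segments) \
        if pt_segments.intervals or met_segments.intervals else 0.0
    j_lr = jaccard_index(lr_segments, met_segments) \
        if lr_segments.intervals or met_segments.intervals else 0.0
    if uniq_lr > uniq_pt and j_lr > j_pt:
        verdict = "LR-origin"
    elif uniq_pt > uniq_lr and j_pt > j_lr:
        verdict = "PT-origin"
    else:
        verdict = "inconclusive"
    return OriginReport(uniq_pt, uniq_lr, round(j_pt, 4), round(j_lr, 4), verdict)


def chromosome_level_count(profile: Optional[SegmentProfile] = None,
                           banding_events: Optional[Sequence[tuple[str, str]]] = None,
                           genome: Optional[GenomeModel] = None,
                           arm_cover_fraction: float = 0.5) -> int:
    """Distinct chromosome-level events from SNP-array segments and G-banding.

    ``banding_events`` are (chrom, arm) pairs from karyotyping. A banding
    event is counted as a duplicate of the array data when the profile's
    merged segments cover at least ``arm_cover_fraction`` of that arm.
    """
    if profile is None and banding_events is None:
        raise ValueError("need at least one of profile or banding_events")
    count = 0
    spans = {}
    if profile is not None:
        norm = profile.normalized()
        count += len(norm.intervals)
        spans = _span_dict(norm.intervals)
    if banding_events:
        genome = genome or default_genome()
        for chrom, arm in banding_events:
            lo, hi = genome.arm_bounds(chrom, arm)
            covered = _total(_intersect_spans(spans.get(chrom, []), [(lo, hi)]))
            if covered < arm_cover_fraction * (hi - lo):
                count += 1
    return count


def lesion_variant_union(kept_per_sample: Mapping[str, set[VariantKey]],
                         sample_to_lesion: Mapping[str, str],
                         strict_intersection: bool = False
                         ) -> dict[str, set[VariantKey]]:
    """Collapse per-sample kept sets to lesion-level sets.

    Default is the union of the lesion's samples; ``strict_intersection``
    keeps only variants found in every sample of the lesion.
    """
    by_lesion: dict[str, list[set[VariantKey]]] = {}
    for sid, kept in kept_per_sample.items():
        by_lesion.setdefault(sample_to_lesion[sid], []).append(set(kept))
    op = set.intersection if strict_intersection else set.union
    return {l: op(*sets) for l, sets in by_lesion.items()}
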