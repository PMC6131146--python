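"""Copy-number interval algebra.

Implements the chromosome-level half of the analysis: size filtering of
genomic changes seen at SNP array (GCS), base-pair Jaccard similarity between
two samples' segment sets, shared-breakpoint counting under the same-probe-gap
rule, the minimal common region across samples (core amplicons), and total
altered length per state.

All coordinates are 0-based half-open; interval length is ``end - start``.
Segment sets are normalised before any arithmetic: per chromosome and state,
overlapping or book-ended intervals are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .genome import ProbeMap

#: Recognised copy-number states. ``cnLOH`` is copy-neutral loss of
#: heterozygosity: allelic imbalance without a copy-number change.
STATES = ("gain", "loss", "cnLOH", "amplification")

#: States treated as amplified when hunting for core amplicons.
AMPLIFIED_STATES = frozenset({"gain", "amplification"})

#: Minimum segment length retained as a GCS (strictly greater than 500 kb).
GCS_MIN_LENGTH_BP = 500_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One copy-number event on one chromosome."""

    chrom: str
    start: int
    end: int
    state: str
    copy_number: Optional[float] = None

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(
                f"unknown copy state {self.state!r}; expected one of {STATES}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentProfile:
    """A sample's set of copy-number events (its GCS), with optional probes."""

    sample_id: str
    intervals: tuple[GenomicInterval, ...] = ()
    probe_map: Optional[ProbeMap] = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def normalized(self) -> "SegmentProfile":
        """Merge overlapping or book-ended intervals of the same state."""
        merged: list[GenomicInterval] = []
        by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_key.setdefault((iv.chrom, iv.state), []).append(iv)
        for (chrom, state), ivs in sorted(by_key.items()):
            for start, end in merge_spans([(iv.start, iv.end) for iv in ivs]):
                # copy_number of merged pieces is not meaningful; keep it only
                # when a run of merged intervals agrees on the value
                cns = {iv.copy_number for iv in ivs
                       if iv.start < end and iv.end > start}
                cn = cns.pop() if len(cns) == 1 else None
                merged.append(GenomicInterval(chrom, start, end, state, cn))
        merged.sort()
        return replace(self, intervals=tuple(merged))

    def filtered(self, states: Iterable[str] | None = None,
                 chrom: str | None = None) -> tuple[GenomicInterval, ...]:
        states = None if states is None else set(states)
        return tuple(iv for iv in self.intervals
                     if (states is None or iv.state in states)
                     and (chrom is None or iv.chrom == chrom))


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended (start, end) spans; returns sorted list."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def _span_dict(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: merge_spans(s) for c, s in by_chrom.items()}


def _intersect_spans(a: Sequence[tuple[int, int]],
                     b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two merged, sorted span lists (two-pointer sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _total(spans: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in spans)


def _as_intervals(x) -> tuple[Iterable[GenomicInterval], Optional[ProbeMap]]:
    if isinstance(x, SegmentProfile):
        return x.normalized().intervals, x.probe_map
    return tuple(x), None


def filter_gcs(profile: SegmentProfile,
               min_len_bp: int = GCS_MIN_LENGTH_BP) -> SegmentProfile:
    """Retain only segments strictly longer than ``min_len_bp`` (default >500 kb)."""
    norm = profile.normalized()
    kept = tuple(iv for iv in norm.intervals if iv.length > min_len_bp)
    return replace(norm, intervals=kept)


@dataclass(frozen=True)
class JaccardStats:
    """bedtools-jaccard style summary of two interval sets."""

    intersection: int
    union: int
    jaccard: float
    n_intersections: int


def jaccard_stats(a, b, match_state: bool = False) -> JaccardStats:
    """Base-pair overlap statistics between two segment sets.

    By default states are ignored: a gain in one sample overlapping a loss in
    the other still counts as overlap. With ``match_state`` each state is
    compared separately and the per-state intersections/unions summed.
    """
    ivs_a, _ = _as_intervals(a)
    ivs_b, _ = _as_intervals(b)
    if match_state:
        states = {iv.state for iv in ivs_a} | {iv.state for iv in ivs_b}
        inter = union = n_pieces = 0
        for st in sorted(states):
            sa = _span_dict(iv for iv in ivs_a if iv.state == st)
            sb = _span_dict(iv for iv in ivs_b if iv.state == st)
            i, u, n = _jaccard_spans(sa, sb)
            inter, union, n_pieces = inter + i, union + u, n_pieces + n
    else:
        inter, union, n_pieces = _jaccard_spans(_span_dict(ivs_a), _span_dict(ivs_b))
    if union == 0:
        warnings.warn("Jaccard of two empty segment sets is undefined; "
                      "returning 0.0", stacklevel=2)
        return JaccardStats(0, 0, 0.0, 0)
    return JaccardStats(inter, union, inter / union, n_pieces)


def _jaccard_spans(sa, sb) -> tuple[int, int, int]:
    inter = n_pieces = 0
    len_a = sum(_total(s) for s in sa.values())
    len_b = sum(_total(s) for s in sb.values())
    for chrom in set(sa) & set(sb):
        pieces = _intersect_spans(sa[chrom], sb[chrom])
        inter += _total(pieces)
        n_pieces += len(pieces)
    return inter, len_a + len_b - inter, n_pieces


def jaccard_index(a, b, match_state: bool = False) -> float:
    """Overlapping base pairs divided by union base pairs (0 = disjoint, 1 = identical)."""
    return jaccard_stats(a, b, match_state=match_state).jaccard


def breakpoints_of(profile: SegmentProfile) -> set[tuple[str, int]]:
    """Distinct (chrom, position) breakpoints: each segment contributes start and end."""
    norm = profile.normalized()
    bps: set[tuple[str, int]] = set()
    for iv in norm.intervals:
        bps.add((iv.chrom, iv.start))
        bps.add((iv.chrom, iv.end))
    return bps


def shared_breakpoints(a: SegmentProfile, b: SegmentProfile,
                       probe_map: Optional[ProbeMap] = None,
                       tolerance: Optional[int] = None
                       ) -> tuple[int, float, float]:
    """Count breakpoints placed identically in two samples.

    With a probe map, two breakpoints are shared iff the copy-number shift
    falls in the same inter-probe gap (identical flanking probe pair). Without
    one, a positional tolerance in bp may be supplied instead; breakpoints are
    then matched one-to-one greedily if within ``tolerance``.

    Returns ``(n_shared, fraction_of_a, fraction_of_b)``.
    """
    pm = probe_map or a.probe_map or b.probe_map
    bps_a, bps_b = breakpoints_of(a), breakpoints_of(b)
    if pm is not None:
        gaps_a = {(c, pm.gap_index(c, p)) for c, p in bps_a}
        gaps_b = {(c, pm.gap_index(c, p)) for c, p in bps_b}
        shared = gaps_a & gaps_b
        n_shared = len(shared)
        frac_a = n_shared / len(gaps_a) if gaps_a else 0.0
        frac_b = n_shared / len(gaps_b) if gaps_b else 0.0
        return n_shared, frac_a, frac_b
    if tolerance is None:
        raise ValueError(
            "shared_breakpoints needs a probe map (pass probe_map= or attach "
            "one to a profile) or an explicit positional tolerance=")
    n_shared = 0
    chroms = {c for c, _ in bps_a} | {c for c, _ in bps_b}
    for chrom in chroms:
        pa = sorted(p for c, p in bps_a if c == chrom)
        pb = sorted(p for c, p in bps_b if c == chrom)
        i = j = 0
        while i < len(pa) and j < len(pb):
            if abs(pa[i] - pb[j]) <= tolerance:
                n_shared += 1
                i += 1
                j += 1
            elif pa[i] < pb[j]:
                i += 1
            else:
                j += 1
    frac_a = n_shared / len(bps_a) if bps_a else 0.0
    frac_b = n_shared / len(bps_b) if bps_b else 0.0
    return n_shared, frac_a, frac_b


def minimal_common_region(profiles: Sequence[SegmentProfile],
                          state_filter: Iterable[str] = AMPLIFIED_STATES,
                          chrom: Optional[str] = None
                          ) -> tuple[list[tuple[str, int, int]], int]:
    """Region altered (default: amplified) in *every* profile.

    Returns the per-chromosome base-pair intersection across all profiles of
    intervals whose state is in ``state_filter``, optionally restricted to one
    chromosome, together with its combined length. Anti-monotone: adding a
    profile can only shrink the result.
    """
    if len(profiles) < 2:
        raise ValueError("minimal_common_region needs at least 2 profiles")
    state_filter = set(state_filter)
    spans = None
    for prof in profiles:
        ivs = prof.normalized().filtered(states=state_filter, chrom=chrom)
        d = _span_dict(ivs)
        if spans is None:
            spans = d
        else:
            spans = {c: _intersect_spans(spans[c], d[c])
                     for c in set(spans) & set(d)}
        spans = {c: s for c, s in spans.items() if s}
        if not spans:
            return [], 0
    regions = [(c, s, e) for c in sorted(spans) for s, e in spans[c]]
    return regions, sum(e - s for _, s, e in regions)


def total_state_length(profile: SegmentProfile,
                       state_filter: Iterable[str] = AMPLIFIED_STATES,
                       chrom: Optional[str] = None) -> int:
    """Total bp covered by the profile's intervals matching ``state_filter``.

    Overlapping raw inputs are merged first, so no base is counted twice.
    """
    ivs = profile.normalized().filtered(states=set(state_filter), chrom=chrom)
    return sum(_total(s) for s in _span_dict(ivs).values())
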