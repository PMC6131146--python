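"""Brute-force base-by-base oracles for the interval algebra.

Everything here works on tiny genomes (a few kb) by materialising one boolean
membership array per chromosome (and per state where states matter), so it is
independent of the package's sweep-line implementation.
"""

from __future__ import annotations

import numpy as np

from sarclone.intervals import GenomicInterval, SegmentProfile, STATES


def membership(intervals, genome: dict[str, int], states=None
               ) -> dict[str, np.ndarray]:
    """Boolean per-base membership arrays, one per chromosome."""
    arrays = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    for iv in intervals:
        if states is None or iv.state in states:
            arrays[iv.chrom][iv.start:iv.end] = True
    return arrays


def oracle_jaccard(a, b, genome) -> float:
    ma, mb = membership(a, genome), membership(b, genome)
    inter = sum(int((ma[c] & mb[c]).sum()) for c in genome)
    union = sum(int((ma[c] | mb[c]).sum()) for c in genome)
    return 0.0 if union == 0 else inter / union


def oracle_total_length(intervals, genome, states) -> int:
    return sum(int(m.sum()) for m in membership(intervals, genome, states).values())


def oracle_minimal_common_region(profiles, genome, states
                                 ) -> tuple[list[tuple[str, int, int]], int]:
    """Base-wise AND across profiles, then extract runs of True."""
    acc = {c: np.ones(n, dtype=bool) for c, n in genome.items()}
    for prof in profiles:
        m = membership(prof.intervals, genome, states)
        for c in genome:
            acc[c] &= m[c]
    regions = []
    for c in sorted(genome):
        arr = acc[c]
        padded = np.concatenate([[False], arr, [False]]).astype(int)
        d = np.diff(padded)
        starts, ends = np.where(d == 1)[0], np.where(d == -1)[0]
        regions.extend((c, int(s), int(e)) for s, e in zip(starts, ends))
    return regions, sum(e - s for _, s, e in regions)


def oracle_breakpoints(intervals, genome) -> set[tuple[str, int]]:
    """Breakpoints = positions where any state's per-base membership flips."""
    bps = set()
    for state in STATES:
        m = membership(intervals, genome, {state})
        for c, arr in m.items():
            padded = np.concatenate([[False], arr, [False]]).astype(int)
            for pos in np.where(np.diff(padded) != 0)[0]:
                bps.add((c, int(pos)))
    return bps


def oracle_shared_breakpoints(a, b, genome, probes: dict[str, list[int]]
                              ) -> tuple[int, float, float]:
    """Same-probe-gap sharing computed by linear probe counting."""
    def gaps(intervals):
        out = set()
        for c, pos in oracle_breakpoints(intervals, genome):
            out.add((c, sum(1 for q in probes[c] if q < pos)))
        return out

    ga, gb = gaps(a), gaps(b)
    shared = ga & gb
    fa = len(shared) / len(ga) if ga else 0.0
    fb = len(shared) / len(gb) if gb else 0.0
    return len(shared), fa, fb


def random_profile(rng: np.random.Generator, genome: dict[str, int],
                   sample_id: str, max_intervals: int = 8,
                   probe_map=None) -> SegmentProfile:
    """A random (possibly overlapping, multi-state) small-genome profile."""
    n = int(rng.integers(0, max_intervals + 1))
    ivs = []
    chroms = list(genome)
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        clen = genome[c]
        start = int(rng.integers(0, clen - 1))
        end = int(rng.integers(start + 1, clen + 1))
        state = STATES[rng.integers(0, len(STATES))]
        ivs.append(GenomicInterval(c, start, end, state))
    return SegmentProfile(sample_id, tuple(ivs), probe_map=probe_map)
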