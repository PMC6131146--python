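"""Reference genome model: chromosome set, probe grids, arm coordinates.

The default model is the 22 human autosomes with hg19 lengths and a uniform
SNP-array probe grid with 1,150 bp spacing (~2.6 million markers genome-wide,
the density of the CytoScan HD array). A :class:`ProbeMap` answers the only
question breakpoint comparison needs: which inter-probe gap does a genomic
position fall into.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: hg19 autosome lengths in bp.
HG19_AUTOSOMES: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566,
}

#: Approximate hg19 centromere midpoints in bp; p arm = [0, centromere).
HG19_CENTROMERES: dict[str, int] = {
    "chr1": 125000000, "chr2": 93300000, "chr3": 91000000,
    "chr4": 50400000, "chr5": 48400000, "chr6": 61000000,
    "chr7": 59900000, "chr8": 45600000, "chr9": 49000000,
    "chr10": 40200000, "chr11": 53700000, "chr12": 35800000,
    "chr13": 17900000, "chr14": 17600000, "chr15": 19000000,
    "chr16": 36600000, "chr17": 24000000, "chr18": 17200000,
    "chr19": 26500000, "chr20": 27500000, "chr21": 13200000,
    "chr22": 14700000,
}

#: Default probe spacing in bp (CytoScan HD-like density).
DEFAULT_PROBE_SPACING = 1150


class ProbeMap:
    """Positions of array probes, either a uniform grid or explicit arrays.

    A uniform grid places probes at 0, s, 2s, ... on every chromosome and is
    represented arithmetically (the ~2.6M genome-wide positions are never
    materialised). Explicit maps hold a sorted position array per chromosome.
    """

    def __init__(self, spacing: int | None = None,
                 positions: dict[str, np.ndarray] | None = None):
        if (spacing is None) == (positions is None):
            raise ValueError("provide exactly one of spacing or positions")
        if spacing is not None and spacing <= 0:
            raise ValueError("spacing must be positive")
        self.spacing = spacing
        self.positions = None
        if positions is not None:
            self.positions = {
                c: np.asarray(sorted(p), dtype=np.int64)
                for c, p in positions.items()
            }

    @classmethod
    def uniform(cls, spacing: int = DEFAULT_PROBE_SPACING) -> "ProbeMap":
        return cls(spacing=spacing)

    @classmethod
    def from_positions(cls, positions: dict[str, "np.ndarray | list[int]"]) -> "ProbeMap":
        return cls(positions=positions)

    def gap_index(self, chrom: str, pos: int) -> int:
        """Index of the inter-probe gap containing a copy-number shift at ``pos``.

        A shift at 0-based boundary ``pos`` (between base pos-1 and pos) lies
        between the last probe < pos and the first probe >= pos; the gap is
        identified by the index of that first right-hand probe.
        """
        if self.spacing is not None:
            return int(-(-pos // self.spacing))
        arr = self.positions.get(chrom)
        if arr is None:
            raise KeyError(f"no probes for chromosome {chrom!r}")
        return int(np.searchsorted(arr, pos, side="left"))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        if self.spacing is not None or other.spacing is not None:
            return self.spacing == other.spacing
        if set(self.positions) != set(other.positions):
            return False
        return all(np.array_equal(self.positions[c], other.positions[c])
                   for c in self.positions)


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths plus probe spacing and arm boundaries."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(HG19_AUTOSOMES))
    centromeres: dict[str, int] = field(default_factory=lambda: dict(HG19_CENTROMERES))
    probe_spacing: int = DEFAULT_PROBE_SPACING

    def probe_map(self) -> ProbeMap:
        return ProbeMap.uniform(self.probe_spacing)

    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        """0-based half-open coordinates of a chromosome arm ('p' or 'q')."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        cen = self.centromeres.get(chrom)
        if cen is None:
            raise KeyError(f"no centromere position for {chrom!r}")
        if arm == "p":
            return 0, cen
        if arm == "q":
            return cen, self.chrom_lengths[chrom]
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def default_genome() -> GenomeModel:
    return GenomeModel()
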