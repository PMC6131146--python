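"""Three-mode clonal-evolution simulator with full ground truth.

The generator emulates the statistical structure the longitudinal analysis
assumes, at three levels:

* **lesion lineage** — lesions form a tree rooted at the primary tumor (PT);
  each branch accrues new exonic variants as a Poisson process in time
  (``snv_rate_per_month``) and, in fusion/complex modes, new copy-number
  segment events whose breakpoints arrive at ``bp_rate_per_month`` (each
  focal event contributes two breakpoints);
* **cell population (amplicon mode)** — ring-chromosome content is evolved
  per cell: every division toggles each amplicon segment with ``flux_prob``
  and cells missing a core segment die with probability ``selection_penalty``;
  the lesion's consensus profile keeps segments present in >=50% of sampled
  cells, so extensive single-cell variation coexists with a stable stemline;
* **reads** — each variant is emitted as a tumor/normal call record with
  Poisson depths, binomial alt counts at the clone's allele fraction
  (0.5 x purity for a clonal heterozygous variant), a Binomial(alt, 0.5)
  orientation split, Bernoulli base-quality failures, and low-rate
  contamination alt reads in the normal. Sequencing-artifact records with a
  true allele fraction of zero are mixed in so the downstream filter has
  something to reject.

Mode summary: ``fusion`` — genetically quiet, 0-6 chromosome-level events per
patient, optional subclone-replacement scenario where the metastasis-founding
subclone sits at low cancer-cell fraction in the PT; ``amplicon`` — events
concentrated on one chromosome around a core amplicon carried on unstable
rings; ``complex`` — many events genome-wide, accruing steadily.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .genome import GenomeModel, default_genome
from .intervals import GenomicInterval, SegmentProfile
from .io import SampleMeta, write_sample_sheet, write_segments, write_variants
from .variants import CONSEQUENCES, VariantRecord, VariantKey

MODES = ("amplicon", "fusion", "complex")

#: Default core amplicon: two 12q14-15 segments totalling 856 kb, around the
#: CDK4 and MDM2 loci (hg19 coordinates).
DEFAULT_CORE_AMPLICON = (
    GenomicInterval("chr12", 58_142_000, 58_642_000, "amplification"),
    GenomicInterval("chr12", 69_202_000, 69_558_000, "amplification"),
)

_TRUE_CONSEQUENCES = ("missense", "stop_gain", "frameshift", "inframe_indel")
_TRUE_CONSEQ_P = (0.80, 0.10, 0.05, 0.05)
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated multi-lesion patient."""

    mode: str
    n_lesions: int = 3
    sample_times_months: tuple[float, ...] = (0.0, 60.0, 120.0)
    snv_rate_per_month: float = 0.15
    bp_rate_per_month: float = 0.10
    core_amplicon: tuple[GenomicInterval, ...] = ()
    flux_prob: float = 0.10
    selection_penalty: float = 0.95
    n_cells_sampled: int = 50
    mean_depth_tumor: int = 98
    mean_depth_normal: int = 60
    subclone_replacement: bool = False
    subclone_ccf: float = 0.15
    ploidy_shift_prob: float = 0.05
    seed: int = 0
    # cohort structure
    patient_id: str = "SIM-1"
    lesion_types: Optional[tuple[str, ...]] = None
    origin: Optional[tuple[Optional[int], ...]] = None  # parent index per lesion
    samples_per_lesion: int = 1
    # founder state
    founder_snvs: int = 20
    founder_events: int = 40
    pt_excess_snvs: int = 150
    n_peripheral: int = 12
    # cell-population knobs (amplicon mode)
    divisions_per_month: float = 0.5
    within_lesion_divisions: int = 30
    # read model
    purity: float = 1.0
    bq_fail_prob: float = 0.02
    contamination_af: float = 5e-4
    error_af: float = 2e-3
    noise_variants_per_sample: float = 20.0
    synonymous_per_sample: float = 3.0
    genome: GenomeModel = field(default_factory=default_genome, compare=False)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be a positive integer")
        t = tuple(float(x) for x in self.sample_times_months)
        object.__setattr__(self, "sample_times_months", t)
        if len(t) != self.n_lesions:
            raise ValueError("sample_times_months length must equal n_lesions")
        if t and t[0] != 0:
            raise ValueError("sample_times_months must start at 0 (the PT)")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sample_times_months must be strictly increasing")
        for name in ("snv_rate_per_month", "bp_rate_per_month"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("flux_prob", "selection_penalty", "ploidy_shift_prob",
                     "bq_fail_prob", "purity"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("n_cells_sampled", "mean_depth_tumor", "mean_depth_normal",
                     "samples_per_lesion"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.subclone_replacement:
            if self.mode != "fusion":
                raise ValueError("subclone_replacement is a fusion-mode scenario")
            if not 0 < self.subclone_ccf < 1:
                raise ValueError("subclone_ccf must lie in (0, 1)")
        if self.mode == "amplicon":
            core = self.core_amplicon or DEFAULT_CORE_AMPLICON
            object.__setattr__(self, "core_amplicon", tuple(core))
            spans = sorted((iv.chrom, iv.start, iv.end) for iv in core)
            for (c1, _, e1), (c2, s2, _) in zip(spans, spans[1:]):
                if c1 == c2 and s2 < e1:
                    raise ValueError("core_amplicon intervals must be disjoint")
            if not core:
                raise ValueError("amplicon mode requires a non-empty core_amplicon")
        if self.origin is not None:
            if len(self.origin) != self.n_lesions or self.origin[0] is not None:
                raise ValueError("origin must list one parent index per lesion, "
                                 "None for the PT")
            for i, p in enumerate(self.origin[1:], start=1):
                if not 0 <= p < i:
                    raise ValueError("origin must be a tree rooted at the PT "
                                     "(parents precede children)")

    @classmethod
    def for_mode(cls, mode: str, seed: int = 0, **overrides) -> "SimConfig":
        """A config with mode-typical defaults for rates and founder state."""
        presets = {
            "fusion": dict(founder_events=3, founder_snvs=15,
                           snv_rate_per_month=0.08, bp_rate_per_month=0.07),
            "amplicon": dict(founder_events=0, founder_snvs=2,
                             snv_rate_per_month=0.05, bp_rate_per_month=0.0,
                             core_amplicon=DEFAULT_CORE_AMPLICON),
            "complex": dict(founder_events=40, founder_snvs=20,
                            snv_rate_per_month=0.15, bp_rate_per_month=0.10),
        }
        if mode not in presets:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        kwargs = {**presets[mode], **overrides}
        return cls(mode=mode, seed=seed, **kwargs)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated patient."""

    trunk_variants: frozenset[VariantKey]
    private_variants: dict[str, frozenset[VariantKey]]
    true_segments: dict[str, tuple[tuple[str, int, int, str], ...]]
    origin: dict[str, Optional[str]]
    lesion_variants: dict[str, frozenset[VariantKey]]
    ploidy_shifts: dict[str, tuple[str, ...]] = field(default_factory=dict)
    single_cell_profiles: Optional[dict[str, tuple[frozenset, ...]]] = None


@dataclass
class SimulatedLesion:
    lesion_id: str
    lesion_type: str
    months: float
    segments: SegmentProfile
    variants: dict[str, list[VariantRecord]]  # per sample id
    single_cells: Optional[list[frozenset]] = None

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.variants)


@dataclass
class SimulatedPatient:
    patient_id: str
    config: SimConfig
    lesions: list[SimulatedLesion]
    truth: SimTruth

    def lesion(self, lesion_id: str) -> SimulatedLesion:
        for l in self.lesions:
            if l.lesion_id == lesion_id:
                return l
        raise KeyError(lesion_id)


# ---------------------------------------------------------------------------
# helpers

def _default_lesion_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    if cfg.lesion_types is not None:
        types = list(cfg.lesion_types)
        if len(types) != cfg.n_lesions or (types and types[0] != "PT"):
            raise ValueError("lesion_types must start with 'PT' and have one "
                             "entry per lesion")
    else:
        types = ["PT"]
        for i in range(1, cfg.n_lesions):
            types.append("Met" if i == cfg.n_lesions - 1 and cfg.n_lesions > 2
                         else "LR")
    counters: dict[str, int] = {}
    ids = []
    for t in types:
        if t == "PT":
            ids.append("PT")
        else:
            counters[t] = counters.get(t, 0) + 1
            ids.append(f"{t}{counters[t]}")
    return ids, types


def _weighted_chrom(rng: np.random.Generator, genome: GenomeModel) -> str:
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]


def _new_variant(rng: np.random.Generator, genome: GenomeModel,
                 used: set[VariantKey], consequence: Optional[str] = None
                 ) -> tuple[VariantKey, str]:
    while True:
        chrom = _weighted_chrom(rng, genome)
        pos = int(rng.integers(0, genome.chrom_lengths[chrom]))
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[rng.integers(0, 4)]
        if alt == ref:
            alt = _BASES[(_BASES.index(ref) + 1) % 4]
        key = (chrom, pos, ref, alt)
        if key not in used:
            used.add(key)
            break
    if consequence is None:
        consequence = str(rng.choice(_TRUE_CONSEQUENCES, p=_TRUE_CONSEQ_P))
    return key, consequence


def _new_event(rng: np.random.Generator, genome: GenomeModel,
               existing: list[tuple[str, int, int, str]],
               state_p: dict[str, float]) -> tuple[str, int, int, str]:
    """A random segment event, disjoint from existing same-state events.

    Boundaries snap to the probe grid so breakpoints sit cleanly between two
    probes; lengths are uniform on 1-30 Mb (always above the GCS size filter).
    """
    states = list(state_p)
    probs = np.array([state_p[s] for s in states])
    spacing = genome.probe_spacing
    for _ in range(1000):
        chrom = _weighted_chrom(rng, genome)
        clen = genome.chrom_lengths[chrom]
        length = int(rng.integers(1_000_000, 30_000_000)) // spacing * spacing
        length = min(length, clen - 2 * spacing)
        start = int(rng.integers(0, (clen - length) // spacing)) * spacing
        state = states[rng.choice(len(states), p=probs / probs.sum())]
        span = (chrom, start, start + length, state)
        if all(not (c == chrom and st == state and s < span[2] and span[1] < e)
               for c, s, e, st in existing):
            return span
    raise RuntimeError("could not place a disjoint segment event")


# ---------------------------------------------------------------------------
# ring-chromosome cell population (amplicon mode)

def _toggle(rng: np.random.Generator, cells: np.ndarray, flux: float) -> np.ndarray:
    return cells ^ (rng.random(cells.shape) < flux)


def simulate_ring_population(config: SimConfig, n_divisions: int,
                             founder: Optional[np.ndarray] = None,
                             universe: Optional[list[GenomicInterval]] = None,
                             rng: Optional[np.random.Generator] = None
                             ) -> list[frozenset]:
    """Evolve a population of cells carrying amplicon segments on rings.

    Each division round, every cell produces one daughter whose segment
    content toggles (gain/loss) per segment with ``flux_prob``; any cell
    missing a core segment dies with probability ``selection_penalty``, and
    the population is then resampled to ``n_cells_sampled``. Returns each
    sampled cell's amplicon content as a frozenset of (chrom, start, end).
    """
    if config.mode != "amplicon":
        raise ValueError("simulate_ring_population requires amplicon mode")
    if n_divisions < 0:
        raise ValueError("n_divisions must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if universe is None:
        universe = list(config.core_amplicon) + _peripheral_segments(
            np.random.default_rng(config.seed), config)
    n_seg = len(universe)
    n_core = len(config.core_amplicon)  # universe lists core segments first
    if founder is None:
        founder = np.ones(n_seg, dtype=bool)
    pop = np.tile(founder, (config.n_cells_sampled, 1))
    for _ in range(n_divisions):
        daughters = _toggle(rng, pop, config.flux_prob)
        both = np.vstack([pop, daughters])
        lacks_core = ~both[:, :n_core].all(axis=1)
        dies = lacks_core & (rng.random(len(both)) < config.selection_penalty)
        survivors = both[~dies]
        if len(survivors) == 0:
            raise RuntimeError("ring population went extinct")
        idx = rng.choice(len(survivors), size=config.n_cells_sampled,
                         replace=len(survivors) < config.n_cells_sampled)
        pop = survivors[np.sort(idx)]
    keys = [(iv.chrom, iv.start, iv.end) for iv in universe]
    return [frozenset(k for k, present in zip(keys, cell) if present)
            for cell in pop]


def _peripheral_segments(rng: np.random.Generator, cfg: SimConfig
                         ) -> list[GenomicInterval]:
    """Random peripheral amplicon segments on the core's chromosome."""
    chrom = cfg.core_amplicon[0].chrom
    clen = cfg.genome.chrom_lengths[chrom]
    taken = [(iv.start, iv.end) for iv in cfg.core_amplicon]
    out: list[GenomicInterval] = []
    while len(out) < cfg.n_peripheral:
        length = int(rng.integers(1_000_000, 5_000_000))
        start = int(rng.integers(0, clen - length))
        if all(not (start < e and s < start + length) for s, e in taken):
            taken.append((start, start + length))
            out.append(GenomicInterval(chrom, start, start + length, "amplification"))
    return out


def _evolve_stemline(rng: np.random.Generator, cfg: SimConfig,
                     cell: np.ndarray, n_divisions: int, n_core: int
                     ) -> np.ndarray:
    """Evolve a single surviving lineage (a lesion's founding cell)."""
    cell = cell.copy()
    for _ in range(n_divisions):
        for _ in range(1000):
            daughter = _toggle(rng, cell[None, :], cfg.flux_prob)[0]
            if daughter[:n_core].all() or rng.random() >= cfg.selection_penalty:
                cell = daughter
                break
        else:
            raise RuntimeError("no surviving daughter lineage found")
    return cell


# ---------------------------------------------------------------------------
# main entry point

def simulate_patient(config: SimConfig) -> SimulatedPatient:
    """Generate one multi-lesion patient plus its ground truth.

    Deterministic given the config (including its seed): identical configs
    yield byte-identical outputs when written to disk.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lesion_ids, lesion_types = _default_lesion_ids(cfg)
    parents = list(cfg.origin) if cfg.origin is not None else \
        [None] + list(range(cfg.n_lesions - 1))
    times = cfg.sample_times_months

    # --- variant identities along the lesion tree
    used: set[VariantKey] = set()
    trunk = [_new_variant(rng, cfg.genome, used) for _ in range(cfg.founder_snvs)]
    branch_vars: list[list[tuple[VariantKey, str]]] = [[] for _ in lesion_ids]
    for i in range(1, cfg.n_lesions):
        dt = times[i] - times[parents[i]]
        k = int(rng.poisson(cfg.snv_rate_per_month * dt))
        branch_vars[i] = [_new_variant(rng, cfg.genome, used) for _ in range(k)]
    pt_excess: list[tuple[VariantKey, str]] = []
    if cfg.subclone_replacement:
        pt_excess = [_new_variant(rng, cfg.genome, used)
                     for _ in range(cfg.pt_excess_snvs)]

    lesion_varsets: list[dict[VariantKey, tuple[str, float]]] = []
    for i in range(cfg.n_lesions):
        af_clonal = 0.5 * cfg.purity
        vs: dict[VariantKey, tuple[str, float]] = {}
        trunk_af = af_clonal
        if cfg.subclone_replacement and i == 0:
            trunk_af = af_clonal * cfg.subclone_ccf
        for key, csq in trunk:
            vs[key] = (csq, trunk_af)
        j = i
        path = []
        while j is not None:
            path.append(j)
            j = parents[j]
        for j in path:
            for key, csq in branch_vars[j]:
                vs[key] = (csq, af_clonal)
        if cfg.subclone_replacement and i == 0:
            for key, csq in pt_excess:
                vs[key] = (csq, af_clonal)
        lesion_varsets.append(vs)

    # --- segment sets
    single_cells: Optional[dict[str, tuple[frozenset, ...]]] = None
    ploidy_shifts: dict[str, tuple[str, ...]] = {}
    lesion_segments: list[list[tuple[str, int, int, str]]] = []
    lesion_cells: list[Optional[list[frozenset]]] = [None] * cfg.n_lesions

    if cfg.mode == "amplicon":
        universe = list(cfg.core_amplicon) + _peripheral_segments(rng, cfg)
        n_core = len(cfg.core_amplicon)
        founders: list[np.ndarray] = [np.ones(len(universe), dtype=bool)]
        for i in range(1, cfg.n_lesions):
            dt = times[i] - times[parents[i]]
            n_div = max(1, round(cfg.divisions_per_month * dt))
            founders.append(_evolve_stemline(rng, cfg, founders[parents[i]],
                                             n_div, n_core))
        single_cells = {}
        for i, lid in enumerate(lesion_ids):
            cells = simulate_ring_population(
                cfg, cfg.within_lesion_divisions, founder=founders[i],
                universe=universe, rng=rng)
            lesion_cells[i] = cells
            single_cells[lid] = tuple(cells)
            keys = [(iv.chrom, iv.start, iv.end) for iv in universe]
            frac = [np.mean([k in c for c in cells]) for k in keys]
            lesion_segments.append(
                [(c, s, e, "amplification")
                 for (c, s, e), f in zip(keys, frac) if f >= 0.5])
    else:
        state_p = ({"gain": 0.7, "loss": 0.2, "cnLOH": 0.1} if cfg.mode == "fusion"
                   else {"gain": 0.45, "loss": 0.35, "cnLOH": 0.2})
        all_events: list[tuple[str, int, int, str]] = []
        n_founder = cfg.founder_events
        if cfg.mode == "fusion":
            n_founder = min(n_founder, 6)
        founder_events = []
        for _ in range(n_founder):
            ev = _new_event(rng, cfg.genome, all_events, state_p)
            all_events.append(ev)
            founder_events.append(ev)
        branch_events: list[list[tuple[str, int, int, str]]] = [[] for _ in lesion_ids]
        total = len(founder_events)
        for i in range(1, cfg.n_lesions):
            dt = times[i] - times[parents[i]]
            k = int(rng.poisson(cfg.bp_rate_per_month * dt / 2.0))
            if cfg.mode == "fusion":
                k = min(k, max(0, 6 - total))
            for _ in range(k):
                ev = _new_event(rng, cfg.genome, all_events, state_p)
                all_events.append(ev)
                branch_events[i].append(ev)
            total += k
            # a ploidy shift on a branch is heritable, like any clonal event
            if cfg.mode == "complex" and rng.random() < cfg.ploidy_shift_prob:
                chroms = sorted(str(c) for c in rng.choice(
                    list(cfg.genome.chrom_lengths), size=3, replace=False))
                ploidy_shifts[lesion_ids[i]] = tuple(chroms)
                branch_events[i].extend(
                    (c, 0, cfg.genome.chrom_lengths[c], "gain") for c in chroms)
        for i, lid in enumerate(lesion_ids):
            evs = list(founder_events)
            j = i
            path = []
            while j is not None:
                path.append(j)
                j = parents[j]
            for j in path:
                evs.extend(branch_events[j])
            lesion_segments.append(sorted(set(evs)))

    # --- read-level emission
    lesions: list[SimulatedLesion] = []
    probe_map = cfg.genome.probe_map()
    for i, lid in enumerate(lesion_ids):
        ivs = tuple(GenomicInterval(c, s, e, st)
                    for c, s, e, st in sorted(lesion_segments[i]))
        profile = SegmentProfile(f"{cfg.patient_id}-{lid}", ivs,
                                 probe_map=probe_map).normalized()
        per_sample: dict[str, list[VariantRecord]] = {}
        for s in range(cfg.samples_per_lesion):
            sid = (f"{cfg.patient_id}-{lid}" if cfg.samples_per_lesion == 1
                   else f"{cfg.patient_id}-{lid}.{s + 1}")
            recs = [_emit_record(rng, cfg, key, csq, af, sid)
                    for key, (csq, af) in sorted(lesion_varsets[i].items())]
            for _ in range(int(rng.poisson(cfg.synonymous_per_sample))):
                key, _ = _new_variant(rng, cfg.genome, used)
                recs.append(_emit_record(rng, cfg, key, "synonymous",
                                         0.5 * cfg.purity, sid))
            for _ in range(int(rng.poisson(cfg.noise_variants_per_sample))):
                key, _ = _new_variant(rng, cfg.genome, used)
                csq = str(rng.choice(CONSEQUENCES))
                recs.append(_emit_record(rng, cfg, key, csq, 0.0, sid,
                                         noise=True))
            per_sample[sid] = sorted(recs, key=lambda r: (r.chrom, r.pos,
                                                          r.ref, r.alt))
        lesions.append(SimulatedLesion(lid, lesion_types[i], times[i],
                                       profile, per_sample, lesion_cells[i]))

    id_sets = [frozenset(vs) for vs in lesion_varsets]
    counts: dict[VariantKey, int] = {}
    for s in id_sets:
        for key in s:
            counts[key] = counts.get(key, 0) + 1
    truth = SimTruth(
        trunk_variants=frozenset(k for k, _ in trunk),
        private_variants={lid: frozenset(k for k in id_sets[i]
                                         if counts[k] == 1)
                          for i, lid in enumerate(lesion_ids)},
        true_segments={lid: tuple(sorted(lesion_segments[i]))
                       for i, lid in enumerate(lesion_ids)},
        origin={lid: (None if parents[i] is None else lesion_ids[parents[i]])
                for i, lid in enumerate(lesion_ids)},
        lesion_variants={lid: id_sets[i] for i, lid in enumerate(lesion_ids)},
        ploidy_shifts=ploidy_shifts,
        single_cell_profiles=single_cells,
    )
    return SimulatedPatient(cfg.patient_id, cfg, lesions, truth)


def _emit_record(rng: np.random.Generator, cfg: SimConfig, key: VariantKey,
                 consequence: str, true_af: float, sample_id: str,
                 noise: bool = False) -> VariantRecord:
    chrom, pos, ref, alt = key
    t_depth = max(1, int(rng.poisson(cfg.mean_depth_tumor)))
    n_depth = max(1, int(rng.poisson(cfg.mean_depth_normal)))
    af = cfg.error_af if noise else true_af
    t_alt = int(rng.binomial(t_depth, min(1.0, af))) if af > 0 else 0
    if noise and t_alt == 0:
        t_alt = min(1, t_depth)  # an artifact call implies >=1 supporting read
    t_fwd = int(rng.binomial(t_alt, 0.5))
    n_alt = int(rng.binomial(n_depth, cfg.error_af if noise
                             else cfg.contamination_af))
    if rng.random() < cfg.bq_fail_prob or (noise and rng.random() < 0.5):
        bq = float(rng.uniform(12.0, 19.5))
    else:
        bq = float(rng.uniform(25.0, 38.0))
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        tumor_depth=t_depth, normal_depth=n_depth,
        tumor_alt_fwd=t_fwd, tumor_alt_rev=t_alt - t_fwd,
        normal_alt=min(n_alt, n_depth),
        mean_base_quality=round(bq, 2), consequence=consequence,
        sample_id=sample_id, patient_id=cfg.patient_id,
    )


def new_focal_breakpoints(truth: SimTruth, lesion_id: str) -> int:
    """Number of breakpoints of focal segment events new on a lesion's branch.

    Each focal event carries two breakpoints; whole-chromosome segments added
    by a ploidy shift are a separate mechanism and are not counted.
    """
    parent = truth.origin[lesion_id]
    if parent is None:
        raise ValueError("the primary tumor has no parental branch")
    shifted = set(truth.ploidy_shifts.get(lesion_id, ()))
    new = set(truth.true_segments[lesion_id]) - set(truth.true_segments[parent])
    focal = [seg for seg in new if not (seg[1] == 0 and seg[0] in shifted)]
    return 2 * len(focal)


# ---------------------------------------------------------------------------
# truth round-trip and full dataset output

def _key_str(key: VariantKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def _key_from_str(s: str) -> VariantKey:
    chrom, pos, ref, alt = s.split(":")
    return (chrom, int(pos), ref, alt)


def write_truth(truth: SimTruth, path) -> None:
    """Serialise ground truth to JSON (lossless round-trip with read_truth)."""
    doc = {
        "trunk_variants": sorted(map(_key_str, truth.trunk_variants)),
        "private_variants": {l: sorted(map(_key_str, v))
                             for l, v in sorted(truth.private_variants.items())},
        "lesion_variants": {l: sorted(map(_key_str, v))
                            for l, v in sorted(truth.lesion_variants.items())},
        "true_segments": {l: [list(seg) for seg in segs]
                          for l, segs in sorted(truth.true_segments.items())},
        "origin": dict(sorted(truth.origin.items())),
        "ploidy_shifts": {l: list(c) for l, c in sorted(truth.ploidy_shifts.items())},
        "single_cell_profiles": None if truth.single_cell_profiles is None else {
            l: [sorted(map(list, cell)) for cell in cells]
            for l, cells in sorted(truth.single_cell_profiles.items())},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> SimTruth:
    doc = json.loads(Path(path).read_text())
    scp = doc.get("single_cell_profiles")
    return SimTruth(
        trunk_variants=frozenset(map(_key_from_str, doc["trunk_variants"])),
        private_variants={l: frozenset(map(_key_from_str, v))
                          for l, v in doc["private_variants"].items()},
        lesion_variants={l: frozenset(map(_key_from_str, v))
                         for l, v in doc["lesion_variants"].items()},
        true_segments={l: tuple(tuple(seg) for seg in segs)
                       for l, segs in doc["true_segments"].items()},
        origin=dict(doc["origin"]),
        ploidy_shifts={l: tuple(c) for l, c in doc.get("ploidy_shifts", {}).items()},
        single_cell_profiles=None if scp is None else {
            l: tuple(frozenset(tuple(k) for k in cell) for cell in cells)
            for l, cells in scp.items()},
    )


def write_patient(sp: SimulatedPatient, outdir) -> None:
    """Write a simulated patient as VCF + SEG per sample, sheet, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas: list[SampleMeta] = []
    group = {"amplicon": "WDLS", "fusion": "MLS", "complex": "CXS"}[sp.config.mode]
    for lesion in sp.lesions:
        for sid in lesion.sample_ids:
            write_variants(lesion.variants[sid], outdir / f"{sid}.vcf",
                           contigs=sp.config.genome.chrom_lengths)
            write_segments(replace(lesion.segments, sample_id=sid),
                           outdir / f"{sid}.seg", dialect="SEG")
            metas.append(SampleMeta(
                patient_id=sp.patient_id, sample_id=sid,
                lesion_id=lesion.lesion_id, lesion_type=lesion.lesion_type,
                months_from_dx=lesion.months, diagnosis_group=group))
    write_sample_sheet(metas, outdir / "samples.tsv")
    write_truth(sp.truth, outdir / "truth.json")
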