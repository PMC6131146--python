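"""The three-mode clonal-evolution simulator and its ground truth."""

import numpy as np
import pytest

from sarclone.intervals import GenomicInterval, jaccard_index
from sarclone.sim import (DEFAULT_CORE_AMPLICON, SimConfig, SimTruth,
                          new_focal_breakpoints, read_truth, simulate_patient,
                          simulate_ring_population, write_patient, write_truth)
from sarclone.variants import tumor_maf


def cells_to_intervals(cell):
    return [GenomicInterval(c, s, e, "amplification") for c, s, e in cell]


class TestConfigValidation:
    def test_times_must_be_strictly_increasing_and_start_at_zero(self):
        with pytest.raises(ValueError, match="sample_times_months"):
            SimConfig(mode="complex", n_lesions=2, sample_times_months=(0, 0))
        with pytest.raises(ValueError, match="sample_times_months"):
            SimConfig(mode="complex", n_lesions=2, sample_times_months=(5, 10))
        with pytest.raises(ValueError, match="length"):
            SimConfig(mode="complex", n_lesions=3, sample_times_months=(0, 10))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            SimConfig(mode="neutral")

    def test_amplicon_core_must_be_disjoint(self):
        core = (GenomicInterval("chr12", 0, 100, "amplification"),
                GenomicInterval("chr12", 50, 150, "amplification"))
        with pytest.raises(ValueError, match="core_amplicon"):
            SimConfig(mode="amplicon", core_amplicon=core)

    def test_subclone_scenario_is_fusion_only(self):
        with pytest.raises(ValueError, match="subclone"):
            SimConfig(mode="complex", subclone_replacement=True)

    def test_origin_must_be_a_rooted_tree(self):
        with pytest.raises(ValueError, match="origin"):
            SimConfig(mode="complex", origin=(None, 2, 1))

    def test_rate_sign_checked(self):
        with pytest.raises(ValueError, match="snv_rate_per_month"):
            SimConfig(mode="complex", snv_rate_per_month=-0.1)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        a = simulate_patient(SimConfig.for_mode("complex", seed=42))
        b = simulate_patient(SimConfig.for_mode("complex", seed=42))
        assert a.truth == b.truth
        for la, lb in zip(a.lesions, b.lesions):
            assert la.variants == lb.variants
            assert la.segments.intervals == lb.segments.intervals

    def test_different_seed_differs(self):
        a = simulate_patient(SimConfig.for_mode("complex", seed=1))
        b = simulate_patient(SimConfig.for_mode("complex", seed=2))
        assert a.truth.trunk_variants != b.truth.trunk_variants

    def test_written_outputs_byte_identical(self, tmp_path):
        for d in ("run1", "run2"):
            write_patient(simulate_patient(SimConfig.for_mode("fusion", seed=9)),
                          tmp_path / d)
        for f in sorted((tmp_path / "run1").iterdir()):
            assert f.read_bytes() == (tmp_path / "run2" / f.name).read_bytes()


class TestLineage:
    def test_zero_rates_give_pure_trunk_everywhere(self):
        cfg = SimConfig.for_mode("fusion", seed=3, n_lesions=2,
                                 sample_times_months=(0.0, 40.0),
                                 snv_rate_per_month=0.0, bp_rate_per_month=0.0)
        sp = simulate_patient(cfg)
        assert sp.truth.lesion_variants["LR1"] == sp.truth.lesion_variants["PT"]
        assert sp.truth.lesion_variants["LR1"] == sp.truth.trunk_variants

    @pytest.mark.parametrize("mode", ["fusion", "amplicon", "complex"])
    def test_trunk_conserved_in_every_lesion_pre_noise(self, mode):
        for seed in range(5):
            sp = simulate_patient(SimConfig.for_mode(mode, seed=seed))
            for lid, ids in sp.truth.lesion_variants.items():
                assert sp.truth.trunk_variants <= ids

    def test_origin_graph_is_a_tree_rooted_at_pt(self):
        sp = simulate_patient(SimConfig.for_mode("complex", seed=5, n_lesions=4,
                                                 sample_times_months=(0, 30, 60, 90),
                                                 origin=(None, 0, 0, 2)))
        assert sp.truth.origin == {"PT": None, "LR1": "PT", "LR2": "PT",
                                   "Met1": "LR2"}

    def test_private_variants_appear_in_exactly_one_lesion(self):
        sp = simulate_patient(SimConfig.for_mode("complex", seed=6))
        for lid, priv in sp.truth.private_variants.items():
            for other, ids in sp.truth.lesion_variants.items():
                if other != lid:
                    assert not (priv & ids)

    def test_fusion_mode_caps_chromosome_events_at_six(self):
        for seed in range(10):
            sp = simulate_patient(SimConfig.for_mode("fusion", seed=seed))
            events = set().union(*sp.truth.true_segments.values())
            assert len(events) <= 6

    def test_new_breakpoints_counts_focal_events_only(self):
        cfg = SimConfig.for_mode("complex", seed=11, n_lesions=2,
                                 sample_times_months=(0.0, 50.0),
                                 ploidy_shift_prob=1.0)
        sp = simulate_patient(cfg)
        n = new_focal_breakpoints(sp.truth, "LR1")
        new = set(sp.truth.true_segments["LR1"]) - set(sp.truth.true_segments["PT"])
        assert n == 2 * (len(new) - len(sp.truth.ploidy_shifts["LR1"]))


class TestReadModel:
    def test_depths_and_orientations_are_consistent(self):
        sp = simulate_patient(SimConfig.for_mode("complex", seed=8))
        for lesion in sp.lesions:
            for recs in lesion.variants.values():
                for r in recs:
                    assert r.tumor_alt_fwd + r.tumor_alt_rev <= r.tumor_depth
                    assert r.normal_alt <= r.normal_depth

    def test_subclone_replacement_reproduces_low_af_trunk_in_pt(self):
        """Trunk sits at ~ccf/2 in the PT but at clonal fractions in the Mets."""
        cfg = SimConfig.for_mode("fusion", seed=12, subclone_replacement=True,
                                 lesion_types=("PT", "Met", "Met"))
        sp = simulate_patient(cfg)
        trunk = sp.truth.trunk_variants
        pt_recs = sp.lesions[0].variants[sp.lesions[0].sample_ids[0]]
        pt_mafs = [tumor_maf(r) for r in pt_recs if r.identity in trunk]
        met_recs = sp.lesions[1].variants[sp.lesions[1].sample_ids[0]]
        met_mafs = [tumor_maf(r) for r in met_recs if r.identity in trunk]
        assert np.mean(pt_mafs) == pytest.approx(cfg.subclone_ccf / 2, abs=0.02)
        assert 0.05 <= np.mean(pt_mafs) <= 0.10  # the case-4 band
        assert np.mean(met_mafs) == pytest.approx(0.5, abs=0.03)
        # the PT's dominant clone carries its own large private burden
        assert len(sp.truth.private_variants["PT"]) >= 100


class TestRingPopulation:
    def test_zero_flux_keeps_population_identical_to_founder(self):
        cfg = SimConfig.for_mode("amplicon", seed=1, flux_prob=0.0)
        cells = simulate_ring_population(cfg, 25)
        assert len(set(cells)) == 1
        core = {(iv.chrom, iv.start, iv.end) for iv in cfg.core_amplicon}
        assert core <= cells[0]

    def test_zero_divisions_returns_founder_population(self):
        cfg = SimConfig.for_mode("amplicon", seed=1, flux_prob=0.5)
        cells = simulate_ring_population(cfg, 0)
        assert len(set(cells)) == 1 and len(cells) == cfg.n_cells_sampled

    def test_lethal_core_loss_keeps_core_in_every_cell(self):
        cfg = SimConfig.for_mode("amplicon", seed=2, selection_penalty=1.0,
                                 flux_prob=0.2)
        sp = simulate_patient(cfg)
        core = {(iv.chrom, iv.start, iv.end) for iv in cfg.core_amplicon}
        for lid, cells in sp.truth.single_cell_profiles.items():
            for cell in cells:
                assert core <= cell
        for lesion in sp.lesions:
            covered = {(iv.chrom, iv.start, iv.end)
                       for iv in lesion.segments.intervals}
            # consensus merges book-ended pieces; check containment by span
            for c, s, e in core:
                assert any(cc == c and ss <= s and e <= ee
                           for cc, ss, ee in covered)

    def test_core_only_founder_with_full_penalty_never_loses_core(self):
        cfg = SimConfig.for_mode("amplicon", seed=3, selection_penalty=1.0,
                                 flux_prob=0.3, n_peripheral=0)
        cells = simulate_ring_population(cfg, 30)
        core = {(iv.chrom, iv.start, iv.end) for iv in cfg.core_amplicon}
        assert all(core <= cell for cell in cells)

    def test_cellular_variation_exceeds_stemline_drift(self):
        """Single cells vary widely while the consensus tracks the founder."""
        cfg = SimConfig.for_mode("amplicon", seed=4, flux_prob=0.3,
                                 selection_penalty=0.9)
        cells = simulate_ring_population(cfg, 30)  # founder = full universe
        n = len(cells)
        pair_j = []
        r2 = np.random.default_rng(99)
        for _ in range(200):
            i, j = r2.integers(0, n, size=2)
            if i == j or not (cells[i] or cells[j]):
                continue
            pair_j.append(jaccard_index(cells_to_intervals(cells[i]),
                                        cells_to_intervals(cells[j])))
        keys = sorted(set().union(*cells))
        consensus = [k for k in keys
                     if sum(k in c for c in cells) / n >= 0.5]
        founder = sorted(set().union(*cells) | {
            (iv.chrom, iv.start, iv.end) for iv in cfg.core_amplicon})
        j_cons = jaccard_index(cells_to_intervals(consensus),
                               cells_to_intervals(founder))
        assert np.median(pair_j) < j_cons


class TestTruthRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        for mode in ("amplicon", "complex"):
            sp = simulate_patient(SimConfig.for_mode(mode, seed=13))
            f = tmp_path / f"{mode}.json"
            write_truth(sp.truth, f)
            assert read_truth(f) == sp.truth

    def test_empty_truth_is_valid(self, tmp_path):
        t = SimTruth(frozenset(), {}, {}, {}, {})
        f = tmp_path / "empty.json"
        write_truth(t, f)
        assert read_truth(f) == t

    def test_three_lesion_origin_tree_preserved(self, tmp_path):
        sp = simulate_patient(SimConfig.for_mode("fusion", seed=14))
        f = tmp_path / "t.json"
        write_truth(sp.truth, f)
        assert read_truth(f).origin == {"PT": None, "LR1": "PT", "Met1": "LR1"}


def test_complex_mode_divergence_grows_with_time():
    """Replicate-averaged PT-relapse Jaccard is non-increasing in the gap."""
    means = []
    for dt in (20.0, 80.0, 200.0):
        js = []
        for seed in range(25):
            cfg = SimConfig.for_mode("complex", seed=seed, n_lesions=2,
                                     sample_times_months=(0.0, dt))
            sp = simulate_patient(cfg)
            js.append(jaccard_index(sp.lesions[0].segments,
                                    sp.lesions[1].segments))
        means.append(np.mean(js))
    assert means[0] >= means[1] >= means[2]
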