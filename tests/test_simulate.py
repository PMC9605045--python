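"""Simulator: insertion surgery, determinism, truth invariants, event draws."""

import numpy as np
import pytest
from scipy import stats

from alushare import (
    CATEGORY_LABELS,
    GENOMES,
    OUTGROUP,
    CohortData,
    SimulationConfig,
    default_category_weights,
    pattern_of,
    plant_insertion,
    simulate_cohort,
    simulate_truth,
)
from alushare.simulate import ABSENT_LABEL, SimulationConfigError


class TestPlantInsertion:
    def test_string_surgery_by_hand(self):
        out = plant_insertion("ACGTACGTAC", position=5, alu="TTTT", tsd_len=2, a_tail_len=0)
        assert out == "ACGTACG" + "TTTT" + "CGTAC"
        assert len(out) == 10 + 4 + 0 + 2
        # the two bases 5' of the insertion are duplicated 3' of it
        assert out[5:7] == out[11:13] == "CG"

    def test_length_arithmetic(self):
        backbone = "ACGT" * 750
        out = plant_insertion(backbone, 1500, "G" * 300, tsd_len=12, a_tail_len=20)
        assert len(out) == 3000 + 300 + 20 + 12

    def test_a_tail_is_planted_after_alu(self):
        out = plant_insertion("ACGTACGTAC", 5, "TTTT", tsd_len=2, a_tail_len=3)
        assert out[7:14] == "TTTTAAA"

    @pytest.mark.parametrize(
        "position,tsd_len",
        [(0, 1), (10, 1), (2, 3), (9, 2)],
        ids=["position-zero", "position-at-end", "tsd-underflows-start", "tsd-overflows-end"],
    )
    def test_invalid_geometry_rejected(self, position, tsd_len):
        with pytest.raises(ValueError):
            plant_insertion("ACGTACGTAC", position, "TT", tsd_len, 0)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(SimulationConfigError, match="sum to 1"):
            SimulationConfig(category_weights={"CMOS": 0.5}).validate()

    def test_short_flanks_rejected(self):
        with pytest.raises(SimulationConfigError, match="600"):
            SimulationConfig(flank_unique_length=500).validate()

    def test_empty_library_rejected(self):
        with pytest.raises(SimulationConfigError, match="library"):
            SimulationConfig(subfamily_library={}).validate()

    def test_inverted_range_rejected(self):
        with pytest.raises(SimulationConfigError, match="tsd_length_range"):
            SimulationConfig(tsd_length_range=(16, 8)).validate()

    def test_default_weights_are_a_distribution(self):
        assert abs(sum(default_category_weights().values()) - 1.0) < 1e-12


class TestDeterminismAndOutputs:
    def _cfg(self, **kw):
        base = dict(seed=7, n_loci=8, per_lineage_divergence=0.01)
        base.update(kw)
        return SimulationConfig(**base)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            simulate_cohort(self._cfg(), tmp_path / d)
        for sub in ("genomes", "annotations", "anchors"):
            files_a = sorted((tmp_path / "a" / sub).iterdir())
            files_b = sorted((tmp_path / "b" / sub).iterdir())
            assert [f.name for f in files_a] == [f.name for f in files_b]
            for fa, fb in zip(files_a, files_b):
                assert fa.read_bytes() == fb.read_bytes(), fa.name
        assert (tmp_path / "a" / "truth.tsv").read_bytes() == (tmp_path / "b" / "truth.tsv").read_bytes()

    def test_roundtrip_through_files(self, tmp_path):
        cohort = simulate_cohort(self._cfg(), tmp_path / "c")
        loaded = CohortData.read(tmp_path / "c")
        assert loaded.genomes == cohort.genomes
        assert loaded.annotations == cohort.annotations
        assert loaded.anchors == cohort.anchors
        assert loaded.truth == cohort.truth

    def test_degenerate_weights_all_cmos(self):
        weights = {"CMOS": 1.0}
        cohort = simulate_cohort(
            SimulationConfig(seed=1, n_loci=12, per_lineage_divergence=0.0,
                             category_weights=weights,
                             np_event_rate=0, n_run_rate=0, truncation_rate=0, fragment_rate=0)
        )
        for t in cohort.truth:
            assert t.true_category == "CMOS"
            assert t.true_pattern == (True, True, True, True)

    def test_truth_only_matches_full_simulation(self):
        cfg = self._cfg()
        assert simulate_truth(cfg) == simulate_cohort(cfg).truth


class TestTruthInvariants:
    def test_category_label_matches_pattern(self, corrupt_cohort):
        for t in corrupt_cohort.truth:
            assert t.true_pattern == pattern_of(t.true_category)

    def test_near_parallel_loci_have_offset_or_distinct_tsd(self, corrupt_cohort):
        for t in corrupt_cohort.truth:
            if t.event_type != "near_parallel":
                continue
            assert len(t.carriers) >= 2
            positions = set(t.insertion_position.values())
            assert len(positions) > 1 and abs(t.np_offset) >= 10

    def test_outgroup_never_carries_ingroup_private_insertions(self, clean_cohort):
        backbone_len = 3000
        for t in clean_cohort.truth:
            outgroup_contig = clean_cohort.genomes[OUTGROUP][t.locus_id]
            if t.true_category == ABSENT_LABEL:
                assert len(outgroup_contig) > backbone_len  # outgroup-private insertion
            else:
                assert len(outgroup_contig) == backbone_len

    def test_carrier_contigs_gain_insert_length(self, clean_cohort):
        for t in clean_cohort.truth:
            if t.true_category == ABSENT_LABEL:
                continue
            for g in GENOMES:
                contig = clean_cohort.genomes[g][t.locus_id]
                if g in t.carriers:
                    assert len(contig) > 3000
                else:
                    assert len(contig) == 3000


class TestEventDraws:
    def test_np_event_count_matches_independent_replay(self):
        """Replaying the documented per-locus draw streams reproduces the
        near-parallel event count exactly."""
        cfg = SimulationConfig(seed=3, n_loci=200, np_event_rate=0.1,
                               n_run_rate=0.0, truncation_rate=0.0, fragment_rate=0.0)
        truth = simulate_truth(cfg)
        observed = sum(t.event_type == "near_parallel" for t in truth)

        labels = list(CATEGORY_LABELS) + [ABSENT_LABEL]
        w = np.array([cfg.category_weights.get(l, 0.0) for l in labels])
        w = w / w.sum()
        replayed = 0
        for i in range(cfg.n_loci):
            cat = labels[np.random.default_rng([cfg.seed, i, 2]).choice(len(labels), p=w)]
            u = float(np.random.default_rng([cfg.seed, i, 3]).random())
            carriers = sum(pattern_of(cat))
            if cat != ABSENT_LABEL and u < cfg.np_event_rate and carriers >= 2:
                replayed += 1
        assert observed == replayed
        # sanity: plausibly Binomial(200, ~0.1 * P(>=2 carriers))
        assert 0 < observed < 60

    def test_category_frequencies_converge_to_weights(self):
        cfg = SimulationConfig(seed=5, n_loci=2000, backbone_length=1400,
                               flank_unique_length=700)
        truth = simulate_truth(cfg)
        labels = list(CATEGORY_LABELS) + [ABSENT_LABEL]
        counts = np.array([sum(t.true_category == l for t in truth) for l in labels])
        expected = np.array([cfg.category_weights.get(l, 0.0) for l in labels]) * cfg.n_loci
        keep = expected > 0
        _, p = stats.chisquare(counts[keep], expected[keep])
        assert p > 0.01
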