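import numpy as np
import pytest

from conftest import MB, flat_profile, make_profile
from hrdscore.genome_model import SegmentProfile, normalize_profile
from hrdscore.scores import (
    InvalidProfileError,
    ScarScores,
    ScoringConfig,
    classify_hrd,
    gis,
    loh_score,
    lst_score,
    tai_score,
)
from hrdscore.synthetic_cohort import SimPlan, construct_profile
from oracles import loh_oracle, lst_oracle, random_profile, split_segments, tai_oracle


class TestScoringConfig:
    def test_defaults(self, cfg):
        assert cfg.loh_min_len == 15 * MB
        assert cfg.tai_min_len == 11 * MB
        assert cfg.lst_min_flank == 10 * MB
        assert cfg.lst_filter_len == 3 * MB
        assert cfg.gis_cap == 100
        assert cfg.hrd_cutoff == 42

    def test_validation(self):
        with pytest.raises(ValueError):
            ScoringConfig(loh_min_len=0)
        with pytest.raises(ValueError):
            ScoringConfig(hrd_cutoff=101)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("hrd_cutoff: 33\nloh_min_len: 12000000\n")
        c = ScoringConfig.from_yaml(p)
        assert c.hrd_cutoff == 33 and c.loh_min_len == 12 * MB


class TestLoh:
    def test_all_balanced_is_zero(self, toy_genome, cfg):
        assert loh_score(flat_profile("s", toy_genome), toy_genome, cfg) == 0

    def test_interior_run_counts_whole_chromosome_excluded(self, toy_genome, cfg):
        # chrA: 20 Mb LOH tract; chrB: LOH over the entire chromosome
        p = make_profile(
            "s",
            ("chrA", 0, 20, 1, 0),
            ("chrA", 20, 200, 1, 1),
            ("chrB", 0, 150, 1, 0),
        )
        assert loh_score(p, toy_genome, cfg) == 1

    def test_strictly_longer_than_threshold(self, toy_genome, cfg):
        exactly = make_profile(
            "s", ("chrA", 0, 15, 1, 0), ("chrA", 15, 200, 1, 1)
        )
        assert loh_score(exactly, toy_genome, cfg) == 0

    def test_run_may_cross_centromere(self, toy_genome, cfg):
        # 20 Mb tract straddling chrA's centromere [90, 100) Mb
        p = make_profile(
            "s",
            ("chrA", 0, 85, 1, 1),
            ("chrA", 85, 105, 1, 0),
            ("chrA", 105, 200, 1, 1),
        )
        assert loh_score(p, toy_genome, cfg) == 1

    def test_split_invariance(self, toy_genome, cfg):
        p = make_profile(
            "s",
            ("chrA", 0, 20, 1, 0),
            ("chrA", 20, 200, 1, 1),
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert loh_score(split_segments(p, rng), toy_genome, cfg) == 1

    def test_state_change_within_run_is_one_region(self, toy_genome, cfg):
        # 1/0 then 2/0: still one contiguous minor-zero region
        p = make_profile(
            "s",
            ("chrA", 0, 10, 1, 0),
            ("chrA", 10, 20, 2, 0),
            ("chrA", 20, 200, 1, 1),
        )
        assert loh_score(p, toy_genome, cfg) == 1

    def test_invalid_profile_raises(self, toy_genome, cfg):
        bad = SegmentProfile("s", [], valid=False)
        with pytest.raises(InvalidProfileError):
            loh_score(bad, toy_genome, cfg)


class TestTai:
    def test_q_telomere_imbalance(self, toy_genome, cfg):
        p = make_profile(
            "s", ("chrA", 0, 180, 1, 1), ("chrA", 180, 200, 2, 1)
        )
        assert tai_score(p, toy_genome, cfg) == 1

    def test_whole_chromosome_crosses_centromere(self, toy_genome, cfg):
        p = make_profile("s", ("chrA", 0, 200, 2, 1))
        assert tai_score(p, toy_genome, cfg) == 0

    def test_interior_imbalance_not_telomeric(self, toy_genome, cfg):
        p = make_profile(
            "s",
            ("chrA", 0, 30, 1, 1),
            ("chrA", 30, 80, 2, 1),
            ("chrA", 80, 200, 1, 1),
        )
        assert tai_score(p, toy_genome, cfg) == 0

    def test_strictly_longer_than_11mb(self, toy_genome, cfg):
        p = make_profile(
            "s", ("chrA", 0, 11, 2, 1), ("chrA", 11, 200, 1, 1)
        )
        assert tai_score(p, toy_genome, cfg) == 0

    def test_both_telomeres_count_separately(self, toy_genome, cfg):
        p = make_profile(
            "s",
            ("chrA", 0, 20, 2, 1),
            ("chrA", 20, 180, 1, 1),
            ("chrA", 180, 200, 3, 1),
        )
        assert tai_score(p, toy_genome, cfg) == 2


class TestLst:
    def test_single_state_per_arm(self, toy_genome, cfg):
        assert lst_score(flat_profile("s", toy_genome), toy_genome, cfg) == 0

    def test_one_junction_on_p_arm(self, toy_genome, cfg):
        p = make_profile(
            "s",
            ("chrA", 0, 40, 1, 1),
            ("chrA", 40, 90, 2, 1),
            ("chrA", 90, 200, 1, 1),
        )
        # p-arm junction at 40 Mb counts; q-arm is single-state
        assert lst_score(p, toy_genome, cfg) == 1

    def test_short_sliver_filtered(self, toy_genome, cfg):
        p = make_profile(
            "s",
            ("chrA", 0, 40, 1, 1),
            ("chrA", 40, 42, 3, 0),
            ("chrA", 42, 90, 2, 1),
            ("chrA", 90, 200, 1, 1),
        )
        assert lst_score(p, toy_genome, cfg) == 1

    def test_filter_then_remerge_kills_junction(self, toy_genome, cfg):
        # sliver splits equal states; removing it must re-merge them
        p = make_profile(
            "s",
            ("chrA", 0, 40, 1, 1),
            ("chrA", 40, 42, 3, 0),
            ("chrA", 42, 90, 1, 1),
            ("chrA", 90, 200, 1, 1),
        )
        assert lst_score(p, toy_genome, cfg) == 0

    def test_centromere_junction_never_counts(self, toy_genome, cfg):
        p = make_profile(
            "s", ("chrA", 0, 90, 1, 1), ("chrA", 90, 200, 2, 1)
        )
        assert lst_score(p, toy_genome, cfg) == 0

    def test_flank_must_exceed_10mb(self, toy_genome, cfg):
        p = make_profile(
            "s",
            ("chrA", 0, 80, 1, 1),
            ("chrA", 80, 90, 2, 1),  # exactly 10 Mb: not a valid flank
            ("chrA", 90, 200, 1, 1),
        )
        assert lst_score(p, toy_genome, cfg) == 0


class TestGis:
    def test_flat_diploid_zero(self, toy_genome, cfg):
        s = gis(flat_profile("s", toy_genome), toy_genome, cfg)
        assert (s.loh, s.tai, s.lst, s.gis, s.valid) == (0, 0, 0, 0, True)

    def test_additive_combination(self, hg19_genome, cfg):
        plan = SimPlan("s", "g", 20, 15, 30)
        p = construct_profile(plan, hg19_genome, cfg, rng_seed=11)
        s = gis(p, hg19_genome, cfg)
        assert (s.loh, s.tai, s.lst) == (20, 15, 30)
        assert s.gis == 65 == s.raw_sum

    def test_cap_applies(self, hg19_genome):
        cfg = ScoringConfig(gis_cap=8, hrd_cutoff=5)
        p = construct_profile(SimPlan("s", "g", 5, 3, 10), hg19_genome, cfg,
                              rng_seed=2)
        s = gis(p, hg19_genome, cfg)
        assert s.raw_sum == 18 and s.gis == 8

    def test_invalid_propagates(self, toy_genome, cfg):
        s = gis(SegmentProfile("s", [], valid=False), toy_genome, cfg)
        assert not s.valid
        assert s.gis is None and s.loh is None

    def test_monotonicity_one_more_loh_run(self, toy_genome, cfg):
        base = make_profile(
            "s",
            ("chrA", 0, 20, 1, 0),
            ("chrA", 20, 200, 1, 1),
            ("chrB", 0, 150, 1, 1),
        )
        more = make_profile(
            "s",
            ("chrA", 0, 20, 1, 0),
            ("chrA", 20, 200, 1, 1),
            ("chrB", 0, 60, 1, 1),
            ("chrB", 60, 80, 1, 0),  # interior 20 Mb run, flanks < whole
            ("chrB", 80, 150, 1, 1),
        )
        s0, s1 = gis(base, toy_genome, cfg), gis(more, toy_genome, cfg)
        assert s1.loh == s0.loh + 1
        assert s1.gis == s0.gis + 1


class TestOracleAgreement:
    def test_random_profiles_match_brute_force(self, toy_genome, cfg):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = normalize_profile(random_profile(rng, toy_genome))
            assert loh_score(p, toy_genome, cfg) == loh_oracle(p, toy_genome)
            assert tai_score(p, toy_genome, cfg) == tai_oracle(p, toy_genome)
            assert lst_score(p, toy_genome, cfg) == lst_oracle(p, toy_genome)


class TestClassifyHrd:
    def scores(self, value):
        if value is None:
            return ScarScores.invalid("s")
        return ScarScores("s", value, 0, 0, value, True, value)

    def test_boundary_inclusive(self, cfg):
        assert classify_hrd(self.scores(42), tbrcam=False, cfg=cfg) == "positive"
        assert classify_hrd(self.scores(41), tbrcam=False, cfg=cfg) == "negative"

    def test_brca_mutation_overrides_assay_failure(self, cfg):
        assert classify_hrd(self.scores(None), tbrcam=True, cfg=cfg) == "positive"

    def test_failure_without_brca_is_unknown(self, cfg):
        assert classify_hrd(self.scores(None), tbrcam=False, cfg=cfg) == "unknown"

    def test_partition(self, cfg):
        for value in (None, 0, 10, 41, 42, 43, 100):
            for tbrcam in (True, False):
                status = classify_hrd(self.scores(value), tbrcam, cfg)
                assert status in {"positive", "negative", "unknown"}
                # exactly one definitional clause fires
                clauses = [
                    tbrcam or (value is not None and value >= 42),
                    not tbrcam and value is not None and value < 42,
                    not tbrcam and value is None,
                ]
                assert sum(clauses) == 1
                assert ["positive", "negative", "unknown"][
                    clauses.index(True)
                ] == status
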