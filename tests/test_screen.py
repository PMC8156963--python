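"""Screen scoring: replicate handling, posterior combination, calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import supmap as sm
from supmap.screen import (ScoringThresholds, batch_correct, combine_bioreps,
                           confirmation_assay, filter_queries,
                           filter_technical, fold_change, nominal_p,
                           normalize_plates, normalize_to_reference,
                           summarize_technical, suppression_score)


class TestNormalizePlates:
    def test_plate_medians_match_batch_median(self):
        rows = []
        for plate, med in ((0, 200.0), (1, 400.0)):
            for i in range(11):
                rows.append((f"q{plate}_{i}", "G", "REF", "permissive", 1, 1,
                             plate, 0, i, med + (i - 5) * 10))
        # keys must be unique: technical_rep varies instead
        df = pd.DataFrame(rows, columns=sm.io_formats.SCREEN_COLUMNS)
        out = normalize_plates(sm.ScreenTable(df)).data
        for plate in (0, 1):
            assert out.loc[out["plate"] == plate, "colony_size"].median() == \
                pytest.approx(300.0)

    def test_zeros_preserved_and_dead_plate_excluded(self):
        rows = [("q1", "G", "REF", "permissive", 1, 1, 0, 0, 0, 0.0),
                ("q2", "G", "REF", "permissive", 1, 1, 0, 0, 1, 100.0),
                ("q3", "G", "REF", "permissive", 1, 1, 1, 0, 0, 0.0),
                ("q4", "G", "REF", "permissive", 1, 1, 1, 0, 1, 0.0)]
        df = pd.DataFrame(rows, columns=sm.io_formats.SCREEN_COLUMNS)
        out = normalize_plates(sm.ScreenTable(df)).data
        assert set(out["plate"]) == {0}
        assert (out.loc[out["query_id"] == "q1", "colony_size"] == 0).all()

    def test_planted_plate_effect_removed(self):
        params = sm.ScreenSimParams(n_queries=192, n_strains=1,
                                    technical_sd=0.1, missing_rate=0.0,
                                    plate_effects={1: 2.0})
        table = sm.simulate_screen(params, seed=6)
        out = normalize_plates(table).data
        meds = out.groupby("plate")["colony_size"].median()
        assert abs(meds[1] / meds[0] - 1.0) < 0.05


class TestFilterTechnical:
    def test_outlier_dominating_variance_removed(self):
        kept = filter_technical([5.0, 5.1, 4.9, 9.0])
        assert kept == [5.0, 5.1, 4.9]
        # oracle: leave-one-out deviation of the outlier vs total SS
        x = np.array([5.0, 5.1, 4.9, 9.0])
        total_ss = np.sum((x - x.mean()) ** 2)
        loo = (9.0 - np.mean([5.0, 5.1, 4.9])) ** 2
        assert loo / total_ss >= 0.90

    def test_constant_replicates_unchanged(self):
        assert filter_technical([5.0] * 4) == [5.0] * 4

    def test_two_replicates_never_filtered(self):
        assert filter_technical([5.0, 9.0]) == [5.0, 9.0]

    def test_at_most_one_removal(self):
        kept = filter_technical([1.0, 1.0, 50.0, 50.0])
        assert len(kept) == 4  # tied shares: nothing removed


class TestSummarizeTechnical:
    def test_mean_and_squared_standard_error(self):
        post = summarize_technical([4.0, 6.0])
        assert post.m == 5.0
        assert post.v == pytest.approx(1.0)  # sample var 2, n=2
        assert post.n_tech == 2

    def test_single_replicate_takes_floor(self):
        post = summarize_technical([5.0], variance_floor=0.01)
        assert post.m == 5.0 and post.v == 0.01

    def test_zero_variance_takes_floor(self):
        post = summarize_technical([5.0] * 4, variance_floor=0.02)
        assert post.v == 0.02

    def test_empty_cell_is_missing(self):
        assert summarize_technical([]) is None


class TestBatchCorrect:
    @staticmethod
    def _frame(means):
        return pd.DataFrame({"m": means, "v": [0.01] * len(means)},
                            index=[f"q{i}" for i in range(len(means))])

    def test_identity_when_replicates_agree(self):
        rep1 = self._frame(np.linspace(8, 12, 20))
        corrected = batch_correct(rep1.copy(), rep1)
        pd.testing.assert_frame_equal(corrected, rep1)

    def test_affine_batch_shift_inverted_exactly(self):
        rep1 = self._frame(np.linspace(8, 12, 20))
        rep2 = rep1.copy()
        rep2["m"] = 0.5 * rep1["m"] + 1.0
        corrected = batch_correct(rep2, rep1)
        assert np.allclose(corrected["m"], rep1["m"])
        assert np.allclose(corrected["v"], rep2["v"] * 4.0)  # slope 2

    def test_few_shared_queries_skips_with_warning(self, caplog):
        rep1 = self._frame([1.0, 2.0])
        rep2 = self._frame([5.0, 6.0])
        with caplog.at_level("WARNING"):
            corrected = batch_correct(rep2, rep1.iloc[:1])
        assert "skipped" in caplog.text
        pd.testing.assert_frame_equal(corrected, rep2)

    def test_planted_batch_shift_reduced_on_synthetic_screen(self):
        rng = np.random.default_rng(13)
        true = rng.normal(10, 1, size=60)
        rep1 = self._frame(true + rng.normal(0, 0.05, 60))
        rep2 = self._frame(0.8 * true - 1.5 + rng.normal(0, 0.05, 60))
        before = np.abs(rep2["m"] - rep1["m"]).mean()
        corrected = batch_correct(rep2, rep1)
        after = np.abs(corrected["m"] - rep1["m"]).mean()
        assert before / after >= 5.0


class TestCombineBioreps:
    def test_equal_replicates_reduce_to_inverse_variance_average(self):
        est = combine_bioreps(sm.ReplicatePosterior(1.0, 0.04, 4),
                              sm.ReplicatePosterior(1.0, 0.04, 4))
        assert est.mean == 1.0
        assert est.sd == pytest.approx(math.sqrt(0.02))

    def test_hand_evaluated_formulas(self):
        est = combine_bioreps(sm.ReplicatePosterior(2.0, 0.01, 4),
                              sm.ReplicatePosterior(0.0, 0.01, 4))
        # v=(2-0)^2/2=2; p1=p2=1/2.01; mean=1; sd=sqrt(2.01/2)
        assert est.mean == pytest.approx(1.0)
        assert est.sd == pytest.approx(math.sqrt(1.005))

    def test_less_noisy_replicate_dominates(self):
        est = combine_bioreps(sm.ReplicatePosterior(1.0, 1e-6, 4),
                              sm.ReplicatePosterior(1.001, 1.0, 4))
        assert abs(est.mean - 1.0) < 1e-4

    def test_single_replicate_passthrough(self):
        est = combine_bioreps(sm.ReplicatePosterior(3.0, 0.09, 4), None)
        assert est.mean == 3.0 and est.sd == pytest.approx(0.3)

    @given(m1=st.floats(-5, 5), m2=st.floats(-5, 5),
           v1=st.floats(1e-6, 1.0), v2=st.floats(1e-6, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_mean_between_replicates_and_sd_bounded(self, m1, m2, v1, v2):
        est = combine_bioreps(sm.ReplicatePosterior(m1, v1, 4),
                              sm.ReplicatePosterior(m2, v2, 4))
        lo, hi = min(m1, m2), max(m1, m2)
        assert lo - 1e-9 <= est.mean <= hi + 1e-9
        v = (m1 - m2) ** 2 / 2
        assert est.sd <= min(math.sqrt(v1 + v), math.sqrt(v2 + v)) + 1e-9


class TestFilterQueries:
    @staticmethod
    def _estimates(rows):
        return pd.DataFrame(rows, columns=["query_id", "strain_id",
                                           "temperature", "mean"])

    def test_temperature_insensitive_dropped(self):
        est = self._estimates([
            ("q1", "REF", "permissive", 10.0), ("q1", "REF", "restrictive", 9.9),
            ("q1", "W01", "restrictive", 9.9),
            ("q2", "REF", "permissive", 10.0), ("q2", "REF", "restrictive", 8.0),
            ("q2", "W01", "restrictive", 9.0)])
        retained, insensitive, log = filter_queries(est, ScoringThresholds())
        assert retained == {"q2"}
        assert insensitive == {"q1"}
        assert log.set_index("query_id").loc["q1", "reason"] == \
            "temperature_insensitive"

    def test_missing_in_reference_dropped(self):
        est = self._estimates([("q1", "W01", "restrictive", 9.0),
                               ("q1", "W01", "permissive", 10.0)])
        retained, _, log = filter_queries(est, ScoringThresholds())
        assert retained == set()
        assert log["reason"].tolist() == ["missing_in_reference"]

    def test_missing_in_all_wild_dropped(self):
        est = self._estimates([("q1", "REF", "permissive", 10.0),
                               ("q1", "REF", "restrictive", 8.0)])
        retained, _, log = filter_queries(est, ScoringThresholds())
        assert retained == set()
        assert log["reason"].tolist() == ["missing_in_all_wild"]

    def test_planted_insensitive_queries_recovered_exactly(self):
        insensitive = frozenset({f"q{i:04d}" for i in range(10)})
        params = sm.ScreenSimParams(n_queries=40, n_strains=1,
                                    technical_sd=0.0, biological_sd=0.0,
                                    missing_rate=0.0,
                                    insensitive_queries=insensitive)
        table = sm.simulate_screen(params, seed=21)
        cells = sm.screen.summarize_cells(table, ScoringThresholds())
        estimates = sm.screen.combine_all(cells)
        retained, found, _ = filter_queries(estimates, ScoringThresholds())
        assert found == set(insensitive)
        assert retained == {f"q{i:04d}" for i in range(10, 40)}


class TestNormalizeToReference:
    @staticmethod
    def _frame(means):
        return pd.DataFrame({"mean": means, "sd": [0.1] * len(means)},
                            index=[f"q{i}" for i in range(len(means))])

    def test_identity(self):
        ref = self._frame(np.linspace(9, 11, 15))
        adjusted, shift, scale = normalize_to_reference(ref.copy(), ref,
                                                        set(ref.index))
        assert shift == pytest.approx(0.0) and scale == pytest.approx(1.0)
        pd.testing.assert_frame_equal(adjusted, ref)

    def test_affine_transform_inverted_exactly(self):
        ref = self._frame(np.linspace(9, 11, 15))
        wild = ref.copy()
        wild["mean"] = 2.0 * ref["mean"] - 3.0
        adjusted, _, scale = normalize_to_reference(wild, ref, set(ref.index))
        assert scale == pytest.approx(0.5)
        assert np.allclose(adjusted["mean"], ref["mean"])
        assert np.allclose(adjusted["sd"], 0.05)

    def test_global_strain_deficit_recentered(self):
        # a wild strain growing uniformly worse scores ~0 after adjustment;
        # anchor count comparable to a real screen's insensitive-query set
        params = sm.ScreenSimParams(n_queries=300, n_strains=1,
                                    technical_sd=0.05, biological_sd=0.02,
                                    missing_rate=0.0, strain_sd=0.5)
        table = sm.simulate_screen(params, seed=17)
        scores = sm.score_screen(table)
        assert abs(scores["score"].median()) < 0.05


class TestSuppressionScore:
    def test_reported_nominal_p_and_fold_change(self):
        assert nominal_p(4.5) == pytest.approx(3.4e-6, rel=0.03)
        assert fold_change(0.75) == pytest.approx(1.68, abs=0.005)

    def test_threshold_logic(self):
        thr = ScoringThresholds()
        wild = sm.FitnessEstimate("q", "W", "restrictive", 0.8, 0.1, 2)
        ref = sm.FitnessEstimate("q", "REF", "restrictive", 0.0, 0.0, 2)
        s = suppression_score(wild, ref, thr, n_tests=100)
        assert s.z == pytest.approx(8.0) and s.called
        wild2 = sm.FitnessEstimate("q", "W", "restrictive", 0.74, 0.01, 2)
        assert not suppression_score(wild2, ref, thr, 100).called

    def test_bonferroni_correction_capped(self):
        thr = ScoringThresholds()
        wild = sm.FitnessEstimate("q", "W", "restrictive", 4.5, 1.0, 2)
        ref = sm.FitnessEstimate("q", "REF", "restrictive", 0.0, 0.0, 2)
        s = suppression_score(wild, ref, thr, n_tests=10_554)
        assert s.p_bonf == pytest.approx(10_554 * s.p)
        weak = sm.FitnessEstimate("q", "W", "restrictive", 0.1, 1.0, 2)
        assert suppression_score(weak, ref, thr, 10_554).p_bonf == 1.0

    def test_antisymmetric_under_swap(self):
        thr = ScoringThresholds()
        a = sm.FitnessEstimate("q", "W", "restrictive", 1.2, 0.1, 2)
        b = sm.FitnessEstimate("q", "REF", "restrictive", 0.3, 0.2, 2)
        s_ab = suppression_score(a, b, thr, 10)
        s_ba = suppression_score(b, a, thr, 10)
        assert s_ab.score == -s_ba.score and s_ab.z == -s_ba.z

    def test_zero_sd_flagged(self):
        thr = ScoringThresholds()
        wild = sm.FitnessEstimate("q", "W", "restrictive", 1.0, 0.0, 1)
        ref = sm.FitnessEstimate("q", "REF", "restrictive", 0.0, 0.0, 1)
        s = suppression_score(wild, ref, thr, 10)
        assert s.degenerate_sd and s.z == math.inf


class TestConfirmationAssay:
    @staticmethod
    def _counts(pair, wild_counts, ref_counts, areas=(100, 100, 100, 100)):
        rows = [
            (pair, "wild", "permissive", wild_counts[0], areas[0]),
            (pair, "wild", "restrictive", wild_counts[1], areas[1]),
            (pair, "reference", "permissive", ref_counts[0], areas[2]),
            (pair, "reference", "restrictive", ref_counts[1], areas[3]),
        ]
        return pd.DataFrame(rows, columns=["pair_id", "cross", "temperature",
                                           "n_colonies", "mean_area"])

    def test_log_ratio_statistic(self):
        out = confirmation_assay(self._counts("p1", (200, 100), (200, 10)))
        stat = out.iloc[0]["count_statistic"]
        assert stat == pytest.approx(-1 - math.log2(10 / 200))
        assert stat == pytest.approx(3.32, abs=0.01)

    def test_sparse_plate_excluded(self):
        out = confirmation_assay(self._counts("p1", (95, 50), (200, 10)))
        assert bool(out.iloc[0]["excluded"])

    def test_null_case_not_confirmed(self):
        out = confirmation_assay(self._counts("p1", (200, 50), (200, 50)))
        assert out.iloc[0]["count_statistic"] == 0.0
        assert not out.iloc[0]["confirmed"]

    def test_zero_restrictive_count_continuity_corrected(self):
        out = confirmation_assay(self._counts("p1", (200, 100), (200, 0)))
        assert bool(out.iloc[0]["zero_corrected"])
        assert np.isfinite(out.iloc[0]["count_statistic"])


class TestScoreScreenEndToEnd:
    def test_planted_suppression_called_others_not(self, noise_free_screen):
        scores = sm.score_screen(noise_free_screen)
        planted = scores[(scores["query_id"] == "q0001") &
                         (scores["strain_id"] == "W01")]
        assert planted["score"].iloc[0] == pytest.approx(1.5, abs=0.01)
        assert bool(planted["called"].iloc[0])
        others = scores.drop(planted.index)
        assert not others["called"].any()
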