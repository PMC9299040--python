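"""Screening metrics, score distributions, cross-validated recall and
the screening-time model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from citescreen import (CorpusSpec, FeatureConfig, ScoredRecord, TrainingRule,
                        band_time_summary, cumulative_includes_curve,
                        estimate_time_saved, generate_corpus, per_band_precision,
                        score_distribution, screening_metrics,
                        stratified_kfold_recall, suitability_check)
from conftest import make_corpus


def sr(rid, score):
    return ScoredRecord(record_id=rid, score=score, probability=score / 100.0)


class TestScreeningMetrics:
    def test_update_search_accounting(self):
        # 21,403 ranked records of which 8,449 were screened finding 62
        m = screening_metrics(21403, 8449, 62)
        assert round(m.screening_reduction_pct) == 61
        assert m.n_unscreened == 12954
        assert round(m.precision_pct, 2) == 0.73
        assert m.recall_pct is None

    def test_title_only_screening_accounting(self):
        m = screening_metrics(1788, 1788, 7)
        assert round(m.precision_pct, 2) == 0.39
        assert m.screening_reduction_pct == 0.0

    def test_identity_case(self):
        m = screening_metrics(100, 100, 100, 100)
        assert (m.precision_pct, m.recall_pct, m.screening_reduction_pct) == (100.0, 100.0, 0.0)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            screening_metrics(10, 0, 3)
        with pytest.raises(ValueError):
            screening_metrics(10, 5, 6)
        with pytest.raises(ValueError):
            screening_metrics(10, 5, 4, 3)

    @given(st.integers(1, 10**6), st.data())
    def test_reduction_and_screened_fraction_sum_to_100(self, total, data):
        screened = data.draw(st.integers(0, total))
        found = data.draw(st.integers(0, screened))
        m = screening_metrics(total, screened, found)
        assert m.screening_reduction_pct + 100.0 * screened / total == pytest.approx(100.0)


class TestScoreDistribution:
    def test_decade_binning(self):
        dist = score_distribution([sr("a", 5), sr("b", 5), sr("c", 15), sr("d", 95)])
        assert dist.counts == [2, 1, 0, 0, 0, 0, 0, 0, 0, 1]
        assert dist.labels[0] == "0-9" and dist.labels[-1] == "90-99"

    def test_empty_input(self):
        assert score_distribution([]).counts == [0] * 10

    @given(st.lists(st.integers(0, 99), max_size=300))
    def test_conservation(self, scores):
        dist = score_distribution([sr(f"r{i}", s) for i, s in enumerate(scores)])
        assert dist.total == len(scores)


class TestSuitability:
    def test_low_relevance_dominated_distribution_is_suitable(self):
        from citescreen import ScoreDistribution
        dist = ScoreDistribution(list(range(0, 100, 10)),
                                 [12000, 4000, 2000, 900, 400, 200, 100, 60, 30, 10])
        ok, why = suitability_check(dist)
        assert ok and "suitable" in why

    def test_mass_above_very_low_scores_is_unsuitable(self):
        from citescreen import ScoreDistribution
        dist = ScoreDistribution(list(range(0, 100, 10)),
                                 [3000, 5000, 5500, 800, 300, 100, 50, 20, 10, 5])
        ok, why = suitability_check(dist)
        assert not ok and "10-19" in why

    def test_uniform_distribution_is_unsuitable(self):
        from citescreen import ScoreDistribution
        dist = ScoreDistribution(list(range(0, 100, 10)), [100] * 10)
        assert not suitability_check(dist)[0]

    def test_high_score_rise_beyond_tolerance_is_flagged(self):
        from citescreen import ScoreDistribution
        dist = ScoreDistribution(list(range(0, 100, 10)),
                                 [1000, 500, 200, 100, 50, 30, 500, 20, 10, 5])
        ok, why = suitability_check(dist)
        assert not ok and "rise" in why


class TestPerBandPrecision:
    def test_band_precision_and_empty_band(self):
        scored = [sr(f"t{i}", 95) for i in range(10)] + [sr("lo", 5)]
        labels = {s.record_id: "exclude" for s in scored}
        for i in range(5):
            labels[f"t{i}"] = "include"
        table = per_band_precision(scored, labels)
        top = table[table.band == "90-99"].iloc[0]
        assert top.precision_pct == 50.0
        mid = table[table.band == "40-49"].iloc[0]
        assert mid.n_records == 0 and np.isnan(mid.precision_pct)

    def test_cumulative_curve_ends_at_totals(self):
        scored = [sr(f"r{i}", s) for i, s in enumerate([90, 70, 50, 30, 10])]
        labels = {"r0": "include", "r1": "exclude", "r2": "include",
                  "r3": "exclude", "r4": "exclude"}
        curve = cumulative_includes_curve(scored, labels)
        assert curve.n_includes_found.is_monotonic_increasing
        assert curve.iloc[-1].n_screened == 5
        assert curve.iloc[-1].n_includes_found == 2


@pytest.fixture(scope="module")
def small_generated():
    return generate_corpus(CorpusSpec(n_records=300, include_prevalence=0.05,
                                      separability=0.95, seed=4), artifacts=False)


class TestStratifiedKFoldRecall:
    def test_separable_corpus_reaches_full_recall(self, small_generated):
        report = stratified_kfold_recall(small_generated.corpus,
                                         TrainingRule({"Include1"}),
                                         k=5, threshold=10, seed=4)
        assert report.mean_recall_pct == 100.0

    def test_fold_stratification_counts(self, small_generated):
        report = stratified_kfold_recall(small_generated.corpus,
                                         TrainingRule({"Include1"}),
                                         k=5, threshold=10, seed=4)
        assert sum(report.fold_n_relevant) == 15      # 5% of 300
        assert max(report.fold_n_relevant) - min(report.fold_n_relevant) <= 1

    def test_two_fold_on_four_positives(self):
        rows = [(f"p{i}", f"zebra stripes {i}", "zebra zebra herds", "include")
                for i in range(4)]
        rows += [(f"n{i}", f"giraffe necks {i}", "giraffe browse height", "exclude")
                 for i in range(8)]
        report = stratified_kfold_recall(make_corpus(rows), k=2, threshold=10, seed=0)
        assert report.fold_n_relevant == [2, 2]

    def test_class_smaller_than_k_is_an_error(self):
        rows = [("p0", "zebra", "z", "include")]
        rows += [(f"n{i}", f"giraffe {i}", "g", "exclude") for i in range(6)]
        with pytest.raises(ValueError, match="stratify"):
            stratified_kfold_recall(make_corpus(rows), k=5, threshold=10, seed=0)

    def test_reported_recall_matches_per_record_check(self, small_generated):
        report = stratified_kfold_recall(small_generated.corpus,
                                         TrainingRule({"Include1"}),
                                         k=3, threshold=50, seed=9)
        for recall, scores in zip(report.fold_recall_pct, report.fold_scores):
            assert recall == pytest.approx(
                100.0 * sum(s >= 50 for s in scores) / len(scores))

    def test_same_seed_reproduces_folds_and_recalls(self, small_generated):
        r1 = stratified_kfold_recall(small_generated.corpus, TrainingRule({"Include1"}),
                                     k=5, threshold=10, seed=7)
        r2 = stratified_kfold_recall(small_generated.corpus, TrainingRule({"Include1"}),
                                     k=5, threshold=10, seed=7)
        assert r1.fold_recall_pct == r2.fold_recall_pct
        assert r1.fold_scores == r2.fold_scores


class TestTimeModel:
    def test_band_summary_totals(self):
        # five samples averaging 214.2 s total exactly 1071 s
        bands = {"90-99": [138, 155, 220, 278, 280]}
        (summary,) = band_time_summary(bands)
        assert summary.mean_s == 214.2
        assert summary.total_s == 1071
        assert summary.min_s == 138 and summary.max_s == 280

    def test_constant_and_single_sample_bands(self):
        out = band_time_summary({"a": [7, 7, 7, 7, 7], "b": [10]})
        assert (out[0].min_s, out[0].max_s, out[0].mean_s, out[0].total_s) == (7, 7, 7.0, 35)
        assert (out[1].min_s, out[1].max_s, out[1].mean_s, out[1].total_s) == (10, 10, 10.0, 10)

    def test_empty_band_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no samples"):
            out = band_time_summary({"empty": [], "ok": [3]})
        assert len(out) == 1

    @given(st.lists(st.floats(1, 500), min_size=1, max_size=40))
    def test_totals_equal_brute_force_sum(self, values):
        (summary,) = band_time_summary({"band": values})
        assert summary.total_s == pytest.approx(sum(values))
        # mean is reported to 1 dp, so allow the rounding slack
        assert summary.min_s - 0.05 <= summary.mean_s <= summary.max_s + 0.05

    @pytest.mark.parametrize("n,secs,hours", [(12954, 7, 25), (0, 7, 0), (3600, 1.0, 1)])
    def test_time_saved_extrapolation(self, n, secs, hours):
        got_hours, got_seconds = estimate_time_saved(n, secs)
        assert got_hours == hours
        assert got_seconds == n * secs


class TestThresholdSweep:
    def test_recall_nonincreasing_reduction_nondecreasing(self):
        gen = generate_corpus(CorpusSpec(n_records=400, include_prevalence=0.05,
                                         separability=0.7, seed=2), artifacts=False)
        from citescreen import rank_records, train_classifier
        ids = [r.record_id for r in gen.corpus]
        train = gen.corpus.subset(ids[:200])
        test = gen.corpus.subset(ids[200:])
        model = train_classifier(train.labelled(), TrainingRule({"Include1"}), seed=2)
        scored = rank_records(model, test)
        gt = gen.ground_truth
        positives = [s for s in scored if gt[s.record_id] == "include"]
        recalls, reductions = [], []
        for cut in range(0, 100, 10):
            recalls.append(sum(1 for s in positives if s.score > cut))
            reductions.append(sum(1 for s in scored if s.score <= cut))
        assert recalls == sorted(recalls, reverse=True)
        assert reductions == sorted(reductions)
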