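"""NN/NI pair statistics, aggregation, outliers, histograms and the
derived reporting utilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combotan.align import MEASURES, SimilarityRecord
from combotan.assays import (
    AssayTable,
    MeasureStats,
    PerAidStats,
    aggregate,
    classify_outcome,
    cross_optimization_deltas,
    enumerate_pairs,
    filter_eligible,
    find_outliers,
    neighbor_probability,
    pair_key,
    per_aid_statistics,
    per_cid_profile,
    percentile_thresholds,
    rank_outliers,
    report_round,
    score_histogram,
    threshold_components,
    zscore,
)
from combotan.transforms import RigidTransform

IDENT = RigidTransform.identity()


def record(a, b, st=0.5, ct=0.1, st_c=None, ct_c=None):
    st_c = st if st_c is None else st_c
    ct_c = ct if ct_c is None else ct_c
    a, b = min(a, b), max(a, b)
    return SimilarityRecord(
        cid_a=a, cid_b=b,
        st_stopt=st, ct_stopt=ct, combo_stopt=st + ct,
        st_ctopt=st_c, ct_ctopt=ct_c, combo_ctopt=st_c + ct_c,
        transform_stopt=IDENT, transform_ctopt=IDENT,
    )


def stats_row(aid, mu_diff_by_measure, category="screening"):
    measures = {
        m: MeasureStats(0.5, 0.1, 0.5 - mu_diff_by_measure.get(m, 0.0), 0.1,
                        mu_diff_by_measure.get(m, 0.0), 0.1)
        for m in MEASURES
    }
    return PerAidStats(aid=aid, category=category, n_nn=6, n_ni=6, measures=measures)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Inactive", "inactive"),
            ("inactive", "inactive"),
            (" INACTIVE ", "inactive"),
            ("Active", "noninactive"),
            ("Inconclusive", "noninactive"),
            ("Probe", "noninactive"),
            ("Unspecified", "noninactive"),
        ],
    )
    def test_examples(self, raw, expected):
        assert classify_outcome(raw) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome("")


class TestEnumeratePairs:
    def test_counts(self):
        assay = AssayTable(1, "screening", {1: "Active", 2: "Active", 3: "Active",
                                            4: "Inactive", 5: "Inactive"})
        ps = enumerate_pairs(assay, {1, 2, 3, 4, 5})
        assert ps.n_nn == 3 and ps.n_ni == 6
        assert all(a < b for a, b in ps.nn_pairs + ps.ni_pairs)
        assert set(ps.nn_pairs).isdisjoint(ps.ni_pairs)

    def test_single_noninactive(self):
        assay = AssayTable(1, "screening", {1: "Active", **{i: "Inactive" for i in range(2, 7)}})
        ps = enumerate_pairs(assay, set(range(1, 7)))
        assert ps.n_nn == 0 and ps.n_ni == 5

    def test_missing_3d_excluded(self):
        assay = AssayTable(1, "screening", {1: "Active", 2: "Active", 3: "Inactive"})
        ps = enumerate_pairs(assay, {1, 3})
        assert ps.n_nn == 0 and ps.n_ni == 1


class TestFilterEligible:
    def test_boundary(self):
        def ps(n_nn, n_ni):
            assay = AssayTable(
                1, "screening",
                {**{i: "Active" for i in range(1, n_nn + 1)},
                 **{100 + i: "Inactive" for i in range(n_ni)}},
            )
            return enumerate_pairs(assay, set(assay.outcomes))

        sets = {1: ps(4, 2), 2: ps(3, 100), 3: ps(1, 50)}
        # 4 noninactives -> 6 NN pairs, 2 inactives * 4 -> 8 NI pairs: kept
        # 3 noninactives -> 3 NN pairs: excluded; 1 noninactive -> 0 NN: excluded
        assert filter_eligible(sets) == [1]


class TestPerAidStatistics:
    def _stats(self, nn_scores, ni_scores):
        non = list(range(1, len(nn_scores) + 2))
        # construct an assay whose NN pair count equals len(nn_scores) is
        # fiddly; instead wire pairs and records directly
        nn_pairs = [(1, 2 + i) for i in range(len(nn_scores))]
        ni_pairs = [(101, 201 + i) for i in range(len(ni_scores))]
        from combotan.assays import PairSet

        pairs = PairSet(tuple(nn_pairs), tuple(ni_pairs))
        records = {p: record(*p, st=s) for p, s in zip(nn_pairs, nn_scores)}
        records.update({p: record(*p, st=s) for p, s in zip(ni_pairs, ni_scores)})
        assay = AssayTable(7, "confirmatory", {})
        return per_aid_statistics(assay, pairs, records)

    def test_constant_scores(self):
        s = self._stats([0.8, 0.8, 0.8], [0.6, 0.6])
        m = s.measures["st_stopt"]
        assert m.mu_diff == pytest.approx(0.2)
        assert m.sd_diff == pytest.approx(0.0)

    def test_hand_computed_sds(self):
        s = self._stats([0.7, 0.9], [0.5, 0.7])
        m = s.measures["st_stopt"]
        assert m.mu_diff == pytest.approx(0.2)
        assert m.sd_nn == pytest.approx(0.1)
        assert m.sd_ni == pytest.approx(0.1)
        assert m.sd_diff == pytest.approx(0.1 * math.sqrt(2))

    def test_mean_difference_equals_cross_difference_mean(self, rng):
        for _ in range(50):
            nn = rng.uniform(0, 1, size=rng.integers(2, 12))
            ni = rng.uniform(0, 1, size=rng.integers(2, 12))
            s = self._stats(list(nn), list(ni))
            brute = float(np.mean(nn[:, None] - ni[None, :]))
            assert s.measures["st_stopt"].mu_diff == pytest.approx(brute, abs=1e-12)

    def test_missing_record_names_pair(self):
        from combotan.assays import PairSet

        pairs = PairSet(((1, 2),), ((1, 3),))
        records = {(1, 2): record(1, 2)}
        with pytest.raises(KeyError, match="pair 1-3"):
            per_aid_statistics(AssayTable(1, "screening", {}), pairs, records)


class TestAggregate:
    def test_single_aid(self):
        s = stats_row(1, {"combo_stopt": 0.3})
        agg = aggregate([s])
        row = agg[(agg.group == "All") & (agg.measure == "combo_stopt") & (agg.pair_class == "diff")]
        assert row.mu_mu.iloc[0] == pytest.approx(0.3)
        assert row.sigma_mu.iloc[0] == 0.0

    def test_two_aids(self):
        agg = aggregate([stats_row(1, {"st_stopt": 0.1}), stats_row(2, {"st_stopt": 0.3})])
        row = agg[(agg.group == "All") & (agg.measure == "st_stopt") & (agg.pair_class == "diff")]
        assert row.mu_mu.iloc[0] == pytest.approx(0.2)
        assert row.sigma_mu.iloc[0] == pytest.approx(0.1)

    def test_category_grouping(self):
        rows = [stats_row(1, {}, "screening"), stats_row(2, {}, "confirmatory")]
        agg = aggregate(rows)
        screening = agg[agg.group == "screening"]
        assert (screening.n_aids == 1).all()
        assert (agg[agg.group == "All"].n_aids == 2).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestOutliers:
    def test_hand_computed_bounds(self):
        rows = [stats_row(i, {"combo_stopt": v}) for i, v in enumerate([0.0, 0.0, 0.0, 1.0])]
        rep = find_outliers(rows)
        lo, hi = rep.bounds["combo_stopt"]
        assert hi == pytest.approx(0.25 + math.sqrt(3) / 4)
        assert rep.upper["combo_stopt"] == (3,)
        assert rep.lower["combo_stopt"] == ()

    def test_all_equal_no_outliers(self):
        rows = [stats_row(i, {"combo_stopt": 0.2}) for i in range(4)]
        rep = find_outliers(rows)
        assert rep.upper["combo_stopt"] == () and rep.lower["combo_stopt"] == ()

    def test_partition_and_category_sums(self, rng):
        rows = [
            stats_row(i, {m: rng.normal() for m in MEASURES},
                      category=("screening" if i % 2 else "confirmatory"))
            for i in range(20)
        ]
        rep = find_outliers(rows)
        for m in MEASURES:
            assert set(rep.lower[m]).isdisjoint(rep.upper[m])
            counts = rep.category_counts
            all_row = counts[counts.group == "All"]
            cat_rows = counts[counts.group != "All"]
            for side in ("lower", "upper"):
                assert cat_rows[f"{m}_{side}"].sum() == all_row[f"{m}_{side}"].iloc[0]

    def test_overlap_counts(self):
        rows = [stats_row(i, {"combo_stopt": v, "combo_ctopt": v})
                for i, v in enumerate([0, 0, 0, 0, 1.0])]
        rep = find_outliers(rows)
        assert rep.overlap("combo_stopt", "combo_ctopt", "upper") == 1


class TestRankOutliers:
    def test_reported_average(self):
        rows = [
            PerAidStats(1475, "summary", 6, 6, {
                **{m: MeasureStats(0, 0, 0, 0, 0, 0) for m in MEASURES},
                "combo_stopt": MeasureStats(1, 0.1, 0.32, 0.1, 0.68, 0.1),
                "combo_ctopt": MeasureStats(1, 0.1, 0.54, 0.1, 0.46, 0.1),
            }),
        ]
        df = rank_outliers(rows)
        assert df.average.iloc[0] == pytest.approx(0.57)

    def test_rounding_of_average(self):
        rows = [stats_row(672, {"combo_stopt": 0.45, "combo_ctopt": 0.50})]
        df = rank_outliers(rows)
        assert df.average.iloc[0] == pytest.approx(0.475)
        assert report_round(df.average.iloc[0]) == 0.48

    def test_sorted_descending_and_equal_values(self):
        rows = [stats_row(1, {"combo_stopt": 0.1, "combo_ctopt": 0.1}),
                stats_row(2, {"combo_stopt": 0.4, "combo_ctopt": 0.4})]
        df = rank_outliers(rows)
        assert list(df.aid) == [2, 1]
        assert df.average.iloc[1] == pytest.approx(0.1)


class TestHistogram:
    def test_half_even_binning(self):
        h = score_histogram([0.615, 0.625])
        # 61.5 rounds to 62 (even), 62.5 rounds to 62 (even)
        assert list(h.bin_index) == [62]
        assert h.counts[0] == 2

    def test_cumulative_reaches_hundred(self, rng):
        h = score_histogram(rng.uniform(0, 1, size=500))
        assert h.cumulative_pct[-1] == pytest.approx(100.0)
        assert (np.diff(h.cumulative_pct) >= 0).all()
        assert h.counts.sum() == 500

    def test_fraction_leq(self):
        h = score_histogram([0.1, 0.2, 0.3, 0.4])
        assert h.fraction_leq(0.2) == pytest.approx(50.0)
        assert h.fraction_leq(0.05) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            score_histogram([0.1, float("nan")])


class TestThresholds:
    def test_reported_threshold_columns(self):
        (t1, _), (t2, _) = percentile_thresholds(0.54, 0.10)
        assert t1 == pytest.approx(0.64)
        assert t2 == pytest.approx(0.74)
        (t1, _), (t2, _) = percentile_thresholds(0.59, 0.14)
        assert t1 == pytest.approx(0.73)
        assert t2 == pytest.approx(0.87)

    def test_k_zero_is_mean(self):
        [(t, cov)] = percentile_thresholds(0.5, 0.2, (0.0,), scores=[0.4, 0.6])
        assert t == 0.5 and cov == pytest.approx(50.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            percentile_thresholds(0.5, -0.1)


class TestNeighborProbability:
    def test_reported_value(self):
        prob, one_in = neighbor_probability(99.32, 99.98)
        assert prob == pytest.approx(0.0136, abs=5e-5)
        assert one_in == 7353

    def test_degenerate_inputs(self):
        assert neighbor_probability(0.0, 0.0) == (100.0, 1)
        prob, one_in = neighbor_probability(100.0, 99.0)
        assert prob == 0.0 and one_in == math.inf

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            neighbor_probability(-1.0, 50.0)


class TestZscore:
    def test_series_threshold(self):
        assert zscore(1.04, 0.59, 0.14) == pytest.approx(3.214, abs=1e-3)

    def test_mean_is_zero(self):
        assert zscore(0.5, 0.5, 0.1) == 0.0

    def test_two_sigma(self):
        assert zscore(0.74, 0.54, 0.10) == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            zscore(1.0, 0.5, 0.0)


def test_cross_optimization_deltas_from_reported_means():
    means = {"st_stopt": 0.54, "ct_stopt": 0.07, "combo_stopt": 0.62,
             "st_ctopt": 0.41, "ct_ctopt": 0.18, "combo_ctopt": 0.59}
    deltas = cross_optimization_deltas(means)
    assert report_round(deltas["st"]) == 0.13
    assert report_round(deltas["ct"]) == 0.11
    assert report_round(deltas["combo"]) == 0.03


class TestPerCidProfile:
    def test_mean_and_sd(self):
        recs = [record(1, 2, st=0.4), record(1, 3, st=0.5), record(1, 4, st=0.6)]
        prof = per_cid_profile(1, recs)
        assert prof["st_stopt"][0] == pytest.approx(0.5)

    def test_single_record_sd_zero(self):
        prof = per_cid_profile(2, [record(1, 2, st=0.4)])
        assert prof["st_stopt"][1] == 0.0

    def test_double_counting_identity(self):
        recs = [record(a, b) for a in range(1, 5) for b in range(a + 1, 5)]
        total = sum(
            len([r for r in recs if c in (r.cid_a, r.cid_b)]) for c in range(1, 5)
        )
        assert total == 2 * len(recs)


class TestThresholdComponents:
    def test_fully_connected(self):
        recs = [record(1, 2, st=0.9), record(1, 3, st=0.9), record(2, 3, st=0.9)]
        assert threshold_components(recs, "st_stopt", 0.8) == [3]

    def test_threshold_above_max_gives_singletons(self):
        recs = [record(1, 2, st=0.3), record(2, 3, st=0.3)]
        assert threshold_components(recs, "st_stopt", 0.9) == [1, 1, 1]

    def test_transitive_chain(self):
        recs = [record(1, 2, st=0.9), record(2, 3, st=0.9), record(1, 3, st=0.1)]
        assert threshold_components(recs, "st_stopt", 0.8) == [3]


class TestConflictResolution:
    def test_noninactive_wins(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            table = AssayTable.from_rows(1, "screening",
                                         [(10, "Active"), (10, "Inactive")])
        assert classify_outcome(table.outcomes[10]) == "noninactive"
        assert any("conflicting" in r.message for r in caplog.records)


@given(st.lists(st.floats(min_value=0, max_value=2), min_size=1, max_size=50))
@settings(deadline=None, max_examples=50)
def test_histogram_counts_conserved(values):
    h = score_histogram(values)
    assert h.counts.sum() == len(values)
    assert h.cumulative_pct[-1] == pytest.approx(100.0)


@given(
    st.floats(min_value=0, max_value=100),
    st.floats(min_value=0, max_value=100),
)
@settings(deadline=None, max_examples=100)
def test_neighbor_probability_bounds(f1, f2):
    prob, _ = neighbor_probability(f1, f2)
    assert 0.0 <= prob <= 100.0


def test_pair_key_orders():
    assert pair_key(5, 2) == (2, 5) == pair_key(2, 5)
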