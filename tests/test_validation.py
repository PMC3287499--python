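"""Validity correlations, unpredictable samples, gap test, KM quantile."""

import numpy as np
import pandas as pd
import pytest
from math import comb

import condegree as cd


def _perf(order, n_models=20):
    """Performance table whose top-10 means follow ``order``."""
    rng = np.random.default_rng(0)
    return cd.PerformanceTable(
        {
            ep: list(np.clip(base + rng.normal(0, 0.01, n_models), -1, 1))
            for ep, base in order.items()
        }
    )


class TestValidity:
    def test_concordant_inputs_give_unit_correlations(self):
        eps = [f"E{i}" for i in range(10)]
        base = np.linspace(0.1, 0.8, 10)
        degrees = {ep: float(b) for ep, b in zip(eps, base)}
        perf = cd.PerformanceTable({ep: [float(b)] * 12 for ep, b in zip(eps, base)})
        rep = cd.validity_test(degrees, perf)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.kendall_tau == pytest.approx(1.0)
        assert rep.spearman_p < 0.01 and rep.kendall_p < 0.01

    def test_anti_ordered_one_sided_p_near_one(self):
        eps = [f"E{i}" for i in range(10)]
        base = np.linspace(0.1, 0.8, 10)
        degrees = {ep: float(b) for ep, b in zip(eps, base)}
        perf = cd.PerformanceTable(
            {ep: [float(b)] * 12 for ep, b in zip(eps, base[::-1])}
        )
        rep = cd.validity_test(degrees, perf)
        assert rep.spearman_rho == pytest.approx(-1.0)
        assert rep.spearman_p > 0.99 and rep.kendall_p > 0.99

    def test_tau_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        eps = [f"E{i}" for i in range(10)]
        d = rng.uniform(0, 1, 10)
        s = rng.uniform(0, 1, 10)
        degrees = {ep: float(v) for ep, v in zip(eps, d)}
        perf = cd.PerformanceTable({ep: [float(v)] * 12 for ep, v in zip(eps, s)})
        rep = cd.validity_test(degrees, perf)
        conc = disc = 0
        for i in range(10):
            for j in range(i + 1, 10):
                sign = (d[i] - d[j]) * (s[i] - s[j])
                conc += sign > 0
                disc += sign < 0
        assert rep.kendall_tau == pytest.approx((conc - disc) / comb(10, 2))

    def test_too_few_endpoints(self):
        with pytest.raises(cd.DegenerateInputError):
            cd.validity_test({"A": 0.5, "B": 0.6}, _perf({"A": 0.1, "B": 0.2}))


class TestErrorRates:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["error_rate", "n_models"])
        df.index = [f"s{i}" for i in range(len(rows))]
        return cd.ErrorRateTable(df)

    def test_low_coverage_imputed_to_half(self):
        tab = self._table([(0.9, 10), (0.9, 50), (0.2, 49)])
        out = cd.impute_low_coverage(tab)
        assert out.data.loc["s0", "error_rate"] == 0.5  # < 50 classifiers
        assert out.data.loc["s1", "error_rate"] == 0.9  # boundary untouched
        assert out.data.loc["s2", "error_rate"] == 0.5

    def test_empty_table_passthrough(self):
        empty = cd.ErrorRateTable(
            pd.DataFrame({"error_rate": [], "n_models": []})
        )
        assert cd.impute_low_coverage(empty).data.empty

    def test_select_unpredictable_cutoffs(self):
        tab = self._table([(0.98, 60), (0.5, 60), (0.91, 60)])
        assert cd.select_unpredictable(tab, 0.97).sample_ids == ["s0"]
        assert cd.select_unpredictable(tab, 0.9).sample_ids == ["s0", "s2"]
        assert len(cd.select_unpredictable(tab, 0.0).sample_ids) == 3

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        tab = self._table([(r, 60) for r in rng.uniform(0, 1, 20)])
        unp = cd.select_unpredictable(tab, 0.0)
        assert sorted(unp.sample_ids) == sorted(tab.sample_ids)

    def test_conjunctive_filters(self):
        tab = self._table([(0.99, 10), (0.98, 60), (0.97, 15)])
        got = cd.select_unpredictable(tab, 0.9, max_models=20)
        assert got.sample_ids == ["s0", "s2"]
        got = cd.select_unpredictable(tab, 0.9, top_k=1)
        assert got.sample_ids == ["s0"]


class TestGapTest:
    def test_complete_separation_exact_tail(self):
        # unpredictable gaps all 0, others all 1000: the only assignment at
        # or below the observed rank sum is the observed one -> 1 / C(20,10)
        os_days = np.concatenate([np.full(10, 500.0), np.full(10, 2000.0)])
        efs = np.concatenate([np.full(10, 500.0), np.full(10, 1000.0)])
        mask = np.array([True] * 10 + [False] * 10)
        p = cd.os_efs_gap_test(os_days, efs, mask)
        assert p == pytest.approx(1.0 / comb(20, 10), rel=1e-12)

    def test_identical_distributions_p_centred(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(30):
            gaps = rng.normal(1000, 100, 30)
            mask = np.zeros(30, dtype=bool)
            mask[rng.choice(30, 10, replace=False)] = True
            ps.append(cd.os_efs_gap_test(gaps + 500, np.full(30, 500.0), mask))
        assert 0.3 < np.mean(ps) < 0.7

    def test_large_groups_use_asymptotic(self):
        rng = np.random.default_rng(4)
        os_days = rng.uniform(500, 3000, 80)
        efs = os_days - rng.uniform(0, 800, 80)
        mask = np.zeros(80, dtype=bool)
        mask[:30] = True
        p = cd.os_efs_gap_test(os_days, efs, mask)
        assert 0.0 <= p <= 1.0

    def test_empty_group_errors(self):
        with pytest.raises(cd.DegenerateInputError):
            cd.os_efs_gap_test([1.0, 2.0], [0.0, 0.0], [False, False])


class TestKMQuantile:
    def test_all_events_product_limit_oracle(self):
        times = np.arange(1.0, 11.0)
        # S(1)=.9, S(2)=.8, S(3)=.7 <= .75 -> 3
        assert cd.km_quantile(times, np.ones(10), 0.75) == 3.0
        assert cd.km_quantile(times, np.ones(10), 0.5) == 5.0
        # hand-computed product-limit with censoring:
        # events at t=1 (risk 5), t=2 (risk 4), t=4 (risk 2)
        # -> S = 0.8, 0.6, 0.3
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 0])
        assert cd.km_quantile(t, e, 0.65) == 2.0
        assert cd.km_quantile(t, e, 0.45) == 4.0

    def test_no_events_undefined(self):
        assert np.isnan(cd.km_quantile([1.0, 2.0, 3.0], [0, 0, 0], 0.75))

    def test_mass_at_single_time(self):
        for q in (0.1, 0.5, 0.9):
            assert cd.km_quantile([7.0] * 5, [1] * 5, q) == 7.0


class TestScorePositionReport:
    def _inputs(self):
        ids = [f"s{i}" for i in range(8)]
        scores = cd.SampleScores(ids, np.array([0.0, 0.1, -0.2, 0.2, 5.0, 5.2, 4.8, 5.1]))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        post = cd.ChangePointPosterior(
            np.array([0.01, 0.01, 0.01, 0.99, 0.01, 0.01, 0.01]),
            np.array([0.0, 0.0, 0.0, 0.1, 5.0, 5.0, 5.0, 5.0]),
        )
        return scores, y, post, np.arange(8)

    def test_flags_sides(self):
        scores, y, post, ordering = self._inputs()
        unp = cd.UnpredictableSet(["s4"], np.array([0.98]), 0.97)
        rep = cd.score_position_report(scores, y, post, ordering, unp)
        row = rep.iloc[0]
        assert row["score"] == pytest.approx(5.0)
        assert row["class0_posterior_mean"] == pytest.approx(0.025)
        assert row["class1_posterior_mean"] == pytest.approx(5.0)
        assert row["above_class0_mean"]
        assert not row["above_class1_mean"]  # 5.0 is not strictly above 5.0

    def test_mislabeled_samples_on_wrong_side(self):
        # class-0-labelled samples planted in the class-1 cluster
        ids = [f"s{i}" for i in range(10)]
        sc = np.array([0.0, 0.1, -0.1, 4.9, 5.1, 5.0, 4.8, 5.2, 4.9, 5.0])
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])  # s3,s4 mislabeled
        scores = cd.SampleScores(ids, sc)
        post = cd.ChangePointPosterior(
            np.full(9, 0.1), np.where(np.arange(10) < 5, 2.0, 5.0)
        )
        unp = cd.UnpredictableSet(["s3", "s4"], np.array([0.99, 0.99]), 0.97)
        rep = cd.score_position_report(scores, y, post, np.arange(10), unp)
        assert rep["above_class0_mean"].all()

    def test_empty_set_empty_table(self):
        scores, y, post, ordering = self._inputs()
        unp = cd.UnpredictableSet([], np.array([]), 0.97)
        rep = cd.score_position_report(scores, y, post, ordering, unp)
        assert rep.empty

    def test_unknown_id_rejected(self):
        scores, y, post, ordering = self._inputs()
        unp = cd.UnpredictableSet(["nope"], np.array([0.99]), 0.97)
        with pytest.raises(cd.ValidationError):
            cd.score_position_report(scores, y, post, ordering, unp)
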