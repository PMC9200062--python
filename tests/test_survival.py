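"""Kaplan–Meier, log-rank, and maximally selected cut-point behaviour."""

import numpy as np
import pandas as pd
import pytest

import lncmeth as L
from lncmeth.survival import km_curve_table, logrank_scores


def _surv(times, events, ids=None):
    if ids is None:
        ids = [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=ids)


class TestKaplanMeier:
    def test_all_censored_gives_flat_one(self):
        s = L.km_estimate(_surv([1, 2, 3], [False, False, False]))
        assert (s == 1.0).all()

    def test_hand_product_limit_with_censoring(self):
        s = L.km_estimate(_surv([1, 2, 3], [True, False, True]))
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_distinct_event_times_step_by_quarters(self):
        s = L.km_estimate(_surv([1, 2, 3, 4], [True] * 4))
        np.testing.assert_allclose(
            s.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0]
        )

    def test_non_positive_times_rejected(self):
        with pytest.raises(L.ValidationError, match="positive"):
            L.km_estimate(_surv([0.0, 1.0], [True, True]))

    def test_estimate_is_monotone_nonincreasing_starting_at_one(self):
        rng = np.random.default_rng(0)
        s = L.km_estimate(
            _surv(rng.exponential(5, size=40), rng.random(40) < 0.7)
        )
        assert s.iloc[0] == 1.0
        assert (np.diff(s.to_numpy()) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        a = _surv([1, 2, 3, 4], [True, True, False, True])
        b = _surv([1, 2, 3, 4], [True, True, False, True], ids=list("wxyz"))
        stat, p = L.logrank_test(a, b)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_planted_hazard_ratio_is_detected(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            a = _surv(rng.exponential(1.0, 100), [True] * 100)
            b = _surv(rng.exponential(3.0, 100), [True] * 100, ids=[f"b{i}" for i in range(100)])
            _, p = L.logrank_test(a, b)
            hits += p < 0.05
        assert hits >= 90

    def test_no_events_rejected(self):
        a = _surv([1, 2], [False, False])
        b = _surv([3, 4], [False, False], ids=["x", "y"])
        with pytest.raises(L.ValidationError, match="events"):
            L.logrank_test(a, b)


def brute_maxstat(x, time, event, min_group_frac):
    """Independent exhaustive scan: per-sample Nelson–Aalen scores computed
    from first principles, standardized statistic evaluated at every
    admissible cut value by explicit group sums."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    n = len(x)
    a = np.empty(n)
    for i in range(n):
        ch = 0.0
        for t in sorted(set(time)):
            if t <= time[i]:
                d = sum(1 for j in range(n) if time[j] == t and event[j])
                at_risk = sum(1 for j in range(n) if time[j] >= t)
                ch += d / at_risk
        a[i] = float(event[i]) - ch
    abar = a.mean()
    ssq = ((a - abar) ** 2).sum()
    min_size = int(np.ceil(n * min_group_frac))
    best = (-np.inf, None)
    for c in sorted(set(x))[:-1]:
        low = x <= c
        m = low.sum()
        if m < min_size or n - m < min_size:
            continue
        t_high = (a[~low] - abar).sum()
        var = m * (n - m) / (n * (n - 1.0)) * ssq
        z = abs(t_high) / np.sqrt(var)
        if z > best[0] + 1e-12:
            xs = np.sort(x)
            cut = 0.5 * (xs[m - 1] + xs[m])
            best = (z, cut)
    return best


class TestMaxstat:
    def test_separated_toy_cut_lies_between_groups(self):
        e = pd.Series([1, 2, 3, 10, 11, 12], index=list("abcdef"))
        sv = _surv([10, 11, 12, 1, 2, 3], [True] * 6, ids=list("abcdef"))
        res = L.maxstat_cutpoint(e, sv, min_group_frac=0.3, n_perm=100, seed=0, min_n=6)
        assert 3 < res.cutpoint < 10
        assert res.n_low == 3 and res.n_high == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        x = rng.normal(size=n)
        time = rng.exponential(1 + (x > 0), size=n)
        event = rng.random(n) < 0.8
        sv = _surv(time, event)
        res = L.maxstat_cutpoint(pd.Series(x, index=sv.index), sv, n_perm=0, seed=0)
        z_ref, cut_ref = brute_maxstat(x, time, event, 0.1)
        assert res.statistic == pytest.approx(z_ref, rel=1e-9)
        assert res.cutpoint == pytest.approx(cut_ref)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(size=40))
        sv = _surv(rng.exponential(2, 40), [True] * 40, ids=x.index.astype(str))
        x.index = sv.index
        r1 = L.maxstat_cutpoint(x, sv, n_perm=200, seed=9)
        r2 = L.maxstat_cutpoint(np.exp(x), sv, n_perm=200, seed=9)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)
        assert r1.n_high == r2.n_high

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        sv = _surv(rng.exponential(2, 30), [True] * 30)
        r1 = L.maxstat_cutpoint(x, sv, seed=7)
        r2 = L.maxstat_cutpoint(x, sv, seed=7)
        assert r1 == r2

    def test_too_few_admissible_cuts_rejected(self):
        x = pd.Series([1.0] * 12, index=[f"s{i}" for i in range(12)])
        sv = _surv(np.arange(1.0, 13.0), [True] * 12)
        with pytest.raises(L.ValidationError, match="admissible"):
            L.maxstat_cutpoint(x, sv, seed=0)

    def test_scores_sum_to_zero_when_complete(self):
        """Log-rank scores over fully observed data are centered."""
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 30)
        a = logrank_scores(t, np.ones(30, dtype=bool))
        assert a.sum() == pytest.approx(0.0, abs=1e-9)


class TestSurvivalScreen:
    def test_planted_prognostic_lnc_flagged_high_worse(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(150)]
        x = pd.Series(rng.normal(5, 1, size=150), index=ids)
        sv = L.simulate_survival(x, hazard_ratio=3.0, censoring_rate=0.2, seed=2)
        expr = L.FeatureMatrix(
            pd.DataFrame(
                np.vstack([x.to_numpy(), rng.normal(5, 1, size=150)]),
                index=["prognostic", "null"], columns=ids,
            ),
            None, "log2rpkm",
        )
        res = L.survival_screen(["prognostic", "null"], expr, sv, n_perm=500, seed=3)
        assert res["prognostic"].significant
        assert res["prognostic"].risk_direction == "high_worse"

    def test_null_candidates_flagged_at_alpha(self):
        rng = np.random.default_rng(6)
        flags, total = 0, 0
        for rep in range(40):
            ids = [f"s{i}" for i in range(60)]
            expr = L.FeatureMatrix(
                pd.DataFrame(rng.normal(5, 1, size=(5, 60)),
                             index=[f"f{i}" for i in range(5)], columns=ids),
                None, "log2rpkm",
            )
            sv = _surv(rng.exponential(2, 60), rng.random(60) < 0.8, ids=ids)
            res = L.survival_screen(
                [f"f{i}" for i in range(5)], expr, sv, n_perm=99, seed=rep
            )
            flags += sum(r.significant for r in res.values())
            total += 5
        assert flags / total == pytest.approx(0.05, abs=0.035)

    def test_missing_candidate_skipped(self, small_cohort):
        data = small_cohort.cancers["CANCER00"]
        expr = L.normalize_expression(data.lnc_expression).subset_samples(
            data.survival.index
        )
        res = L.survival_screen(["NOT_A_GENE"], expr, data.survival, n_perm=10, seed=0)
        assert res == {}

    def test_empty_candidate_list_gives_empty_result(self, small_cohort):
        data = small_cohort.cancers["CANCER00"]
        expr = L.normalize_expression(data.lnc_expression).subset_samples(
            data.survival.index
        )
        assert L.survival_screen([], expr, data.survival, seed=0) == {}


def test_km_curve_table_has_both_groups(small_cohort):
    data = small_cohort.cancers["CANCER00"]
    expr = L.normalize_expression(data.lnc_expression)
    x = expr.values.loc["LNC0000", data.survival.index]
    table = km_curve_table(x, data.survival, float(x.median()))
    assert set(table["group"]) == {"high", "low"}
    assert ((table["survival"] >= 0) & (table["survival"] <= 1)).all()
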