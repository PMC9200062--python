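"""Moderated-t machinery, BH FDR, and direction calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lncmeth as L
from lncmeth.diff import _direction_calls  # noqa: F401  (sanity: internal exists)
from conftest import group_series


def _fm(values: np.ndarray, n_tumor: int, n_normal: int, scale="log2rpkm"):
    groups = group_series(n_tumor, n_normal)
    df = pd.DataFrame(
        values, index=[f"f{i}" for i in range(values.shape[0])], columns=groups.index
    )
    return L.FeatureMatrix(df, groups, scale)


class TestDeltaBeta:
    @pytest.mark.parametrize(
        "t_mean,n_mean,expected",
        [(0.55, 0.40, 0.15), (0.40, 0.40, 0.0), (0.20, 0.50, 0.30)],
    )
    def test_absolute_mean_difference(self, t_mean, n_mean, expected):
        vals = np.array([[t_mean] * 4 + [n_mean] * 3])
        m = _fm(vals, 4, 3, scale="beta")
        assert L.delta_beta(m).iloc[0] == pytest.approx(expected)

    def test_empty_group_rejected(self):
        df = pd.DataFrame([[0.1, 0.2]], index=["f"], columns=["a", "b"])
        m = L.FeatureMatrix(df, pd.Series(["tumor", "tumor"], index=["a", "b"]), "beta")
        with pytest.raises(L.ValidationError, match="non-empty"):
            L.delta_beta(m)


class TestModeratedT:
    def test_zero_prior_df_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, rng.uniform(0.5, 2.0, size=(200, 1)), size=(200, 25))
        vals[:50, :15] += 1.0
        m = _fm(vals, 15, 10)
        res = L.moderated_t_test(m, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(
            vals[:, :15], vals[:, 15:], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)

    def test_shared_true_variance_shrinks_to_pooled_estimate(self):
        """If all features share one variance, posterior variances collapse to
        its global estimate (within 10% at 5000 features)."""
        rng = np.random.default_rng(1)
        vals = rng.normal(0.0, 1.0, size=(5000, 20))
        m = _fm(vals, 10, 10)
        res = L.moderated_t_test(m)
        global_mean = res["s2"].mean()
        rel_dev = (res["s2_post"] - global_mean).abs() / global_mean
        assert rel_dev.max() < 0.10

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(5.0, 1.0, size=(2000, 30))
        m = _fm(vals, 18, 12)
        res = L.moderated_t_test(m)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_single_sample_group_rejected(self):
        vals = np.random.default_rng(0).normal(size=(5, 3))
        m = _fm(vals, 1, 2)
        with pytest.raises(L.ValidationError, match="at least 2"):
            L.moderated_t_test(m)

    def test_all_constant_features_rejected(self):
        vals = np.ones((5, 10))
        m = _fm(vals, 5, 5)
        with pytest.raises(L.ValidationError, match="constant"):
            L.moderated_t_test(m)

    def test_direction_antisymmetry_under_label_swap(self, make_expr_matrix):
        m = make_expr_matrix(n_features=100, shift=0.0, seed=3)
        m.values.iloc[:10, :20] += 2.0  # plant up in tumor
        m.values.iloc[10:20, :20] -= 2.0
        res = L.call_de_lncs(m)
        swapped = L.FeatureMatrix(
            m.values, m.groups.map({"tumor": "normal", "normal": "tumor"}), m.scale
        )
        res_sw = L.call_de_lncs(swapped)
        flip = {"up": "down", "down": "up", "none": "none"}
        assert list(res_sw["direction"]) == [flip[d] for d in res["direction"]]


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            L.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert L.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(L.bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(L.ValidationError):
            L.bh_fdr([0.5, 1.5])

    def test_never_more_discoveries_than_raw_alpha(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=500) ** 2
        q = L.bh_fdr(p)
        assert (q < 0.05).sum() <= (p < 0.05).sum()

    def test_q_in_unit_interval(self):
        rng = np.random.default_rng(5)
        q = L.bh_fdr(rng.uniform(size=200))
        assert (q >= 0).all() and (q <= 1).all()


class TestCallDmlncs:
    def test_small_delta_beta_is_never_called(self):
        """Δβ below the candidate threshold forces direction none even with a
        tiny p-value."""
        rng = np.random.default_rng(6)
        # a strong, consistent but small shift: Δβ=0.05
        vals = np.concatenate(
            [rng.normal(0.55, 0.01, size=(1, 30)), rng.normal(0.50, 0.01, size=(1, 20))],
            axis=1,
        ).clip(0, 1)
        filler = rng.uniform(0.2, 0.8, size=(50, 50))
        m = _fm(np.vstack([vals, filler]), 30, 20, scale="beta")
        res = L.call_dmlncs(m)
        assert res["q"].iloc[0] < 0.05  # highly significant...
        assert res["direction"].iloc[0] == "none"  # ...but not a candidate

    def test_planted_up_features_recovered(self):
        hits = 0
        total = 0
        for seed in range(20):
            cfg = L.SimulationConfig(
                n_cancers=1, n_tumor=50, n_normal=20, n_lnc=60, n_mrna=5, n_mirna=5,
                planted_dm=[L.PlantedDM((0, 1, 2), 0.3, "up", coupled=False)],
                seed=100 + seed,
            )
            cohort = L.simulate_cohort(cfg)
            m = L.promoter_beta(
                L.impute_probe_missing(
                    L.filter_probes(cohort.cancers["CANCER00"].methylation)
                ),
                cohort.promoter_map,
            )
            res = L.call_dmlncs(m)
            hits += (res.loc[["LNC0000", "LNC0001", "LNC0002"], "direction"] == "up").sum()
            total += 3
        assert hits / total >= 0.9

    def test_logfc_filter_is_conjunctive(self):
        """Features passing Δβ and FDR but with |logfc| at or below the
        threshold stay none (checked by raising the logfc threshold)."""
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(0.62, 0.02, size=(1, 30)), rng.normal(0.40, 0.02, size=(1, 20))],
            axis=1,
        ).clip(0, 1)
        filler = rng.uniform(0.2, 0.8, size=(50, 50))
        m = _fm(np.vstack([vals, filler]), 30, 20, scale="beta")
        res_default = L.call_dmlncs(m)
        assert res_default["direction"].iloc[0] == "up"
        strict = L.TestConfig(logfc_min=abs(res_default["logfc"].iloc[0]))
        res_strict = L.call_dmlncs(m, strict)
        assert res_strict["direction"].iloc[0] == "none"


class TestCallDeLncs:
    def test_planted_overexpression_recovered(self, make_expr_matrix):
        hits, total = 0, 0
        for seed in range(20):
            m = make_expr_matrix(n_features=60, n_tumor=50, n_normal=20, seed=seed)
            m.values.iloc[:3, :50] += 2.0  # logfc = 2
            res = L.call_de_lncs(m)
            hits += (res["direction"].iloc[:3] == "up").sum()
            total += 3
        assert hits / total >= 0.9

    def test_null_features_rarely_called(self, make_expr_matrix):
        m = make_expr_matrix(n_features=500, n_tumor=40, n_normal=30, seed=9)
        res = L.call_de_lncs(m)
        assert (res["direction"] != "none").mean() <= 0.01

    def test_exact_threshold_logfc_is_none(self):
        """A feature with |logfc| exactly 1 fails the strict filter."""
        vals = np.vstack(
            [
                np.array([6.0] * 10 + [5.0] * 10),
                np.random.default_rng(10).normal(5, 1, size=(30, 20)),
            ]
        )
        # zero within-group variance on feature 0 is fine: shrinkage gives
        # it a pooled variance, and logfc stays exactly 1
        m = _fm(vals, 10, 10)
        res = L.call_de_lncs(m)
        assert res["logfc"].iloc[0] == pytest.approx(1.0)
        assert res["direction"].iloc[0] == "none"


def test_fit_variance_prior_recovers_simulated_hyperparameters():
    """Variances drawn from s0^2 * chi2_d0 / d0 scaled inverse-chi2 prior:
    moment matching recovers (d0, s0^2) roughly."""
    rng = np.random.default_rng(12)
    d0_true, s0_true, d = 8.0, 2.0, 18
    true_var = d0_true * s0_true / rng.chisquare(d0_true, size=20000)
    s2 = true_var * rng.chisquare(d, size=20000) / d
    d0, s0 = L.fit_variance_prior(s2, d)
    assert d0 == pytest.approx(d0_true, rel=0.15)
    assert s0 == pytest.approx(s0_true, rel=0.1)
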