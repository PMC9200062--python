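"""Two-group differential methylation / expression calls.

The test statistic is an empirical-Bayes moderated t: per-feature pooled
variances s_g^2 (d residual df each) are shrunk toward a prior s0^2 with d0
prior df, fitted by moment-matching a scaled inverse-chi^2 to the observed
variances on the log scale,

    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d),
    t~_g   = logFC_g / (s~_g sqrt(1/n1 + 1/n2)),   df = d0 + d.

With d0 = 0 this is the ordinary pooled two-sample t.  Methylation is tested
on the M-value scale log2(β/(1−β)) by default, because a |log2 fold-change|
cut-off is degenerate on raw β values bounded by [0,1]; Δβ itself is always
computed on the raw β scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import NORMAL, TUMOR, FeatureMatrix, ValidationError

_M_EPS = 1e-6  # clamp for the logit transform at the β boundaries


@dataclasses.dataclass
class TestConfig:
    """Thresholds for direction calls (all strict inequalities)."""

    delta_beta_min: float = 0.1
    logfc_min: float = 1.0
    fdr_max: float = 0.05
    methylation_test_scale: str = "m-value"  # 'm-value' | 'log2beta' | 'beta'

    def __post_init__(self):
        if self.delta_beta_min < 0 or self.logfc_min < 0:
            raise ValidationError("thresholds must be non-negative")
        if not 0.0 < self.fdr_max < 1.0:
            raise ValidationError("fdr_max must be in (0,1)")
        if self.methylation_test_scale not in ("m-value", "log2beta", "beta"):
            raise ValidationError(
                f"unknown methylation test scale {self.methylation_test_scale!r}"
            )


def delta_beta(m: FeatureMatrix) -> pd.Series:
    """|mean β tumor − mean β normal| per feature (raw β scale)."""
    if m.scale != "beta":
        raise ValidationError(f"delta_beta needs a beta-scale matrix, got {m.scale}")
    t, n = m.samples_in(TUMOR), m.samples_in(NORMAL)
    if not t or not n:
        raise ValidationError("both tumor and normal groups must be non-empty")
    return (m.values[t].mean(axis=1) - m.values[n].mean(axis=1)).abs()


def m_values(beta: pd.DataFrame, eps: float = _M_EPS) -> pd.DataFrame:
    """Logit transform log2(β/(1−β)) with a boundary clamp."""
    b = beta.clip(lower=eps, upper=1 - eps)
    return np.log2(b / (1 - b))


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Newton inversion of the trigamma function (vectorised)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi^2 prior (d0, s0^2) to per-feature
    sample variances with ``df`` residual df, on the log scale.

    Returns ``(d0, s0_squared)``; ``d0`` is ``inf`` when the observed
    log-variances are no more dispersed than sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all features constant: no variance to fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if ok.sum() < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = float(2.0 * _trigamma_inverse(np.array([e_var]))[0])
    s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def moderated_t_test(
    m: FeatureMatrix, prior_df: float | None = None
) -> pd.DataFrame:
    """Moderated two-group t-test, tumor vs normal, on the matrix scale.

    ``prior_df`` overrides the fitted d0 (0 gives the ordinary pooled t).
    Returns a DataFrame with mean_tumor, mean_normal, logfc, s2, s2_post,
    t, df, p, q.
    """
    t_ids, n_ids = m.samples_in(TUMOR), m.samples_in(NORMAL)
    n1, n2 = len(t_ids), len(n_ids)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"need at least 2 samples per group, got {n1} tumor / {n2} normal"
        )
    x1 = m.values[t_ids].to_numpy(dtype=float)
    x2 = m.values[n_ids].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    if prior_df is None:
        d0, s0 = fit_variance_prior(s2, d)
    elif prior_df == 0:
        d0, s0 = 0.0, 0.0
        if (s2 == 0).any():
            raise ValidationError("zero-variance feature with no shrinkage (prior_df=0)")
    else:
        d0 = float(prior_df)
        _, s0 = fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    logfc = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    return pd.DataFrame(
        {
            "mean_tumor": m1,
            "mean_normal": m2,
            "logfc": logfc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t_stat,
            "df": df_total,
            "p": p,
            "q": bh_fdr(p),
        },
        index=m.values.index,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction_calls(
    res: pd.DataFrame, cfg: TestConfig, db: pd.Series | None
) -> pd.Series:
    passing = (res["logfc"].abs() > cfg.logfc_min) & (res["q"] < cfg.fdr_max)
    if db is not None:
        passing &= db > cfg.delta_beta_min
    direction = pd.Series("none", index=res.index)
    direction[passing & (res["logfc"] > 0)] = "up"
    direction[passing & (res["logfc"] < 0)] = "down"
    return direction


def call_dmlncs(beta_matrix: FeatureMatrix, config: TestConfig | None = None) -> pd.DataFrame:
    """Differentially methylated lncRNA calls on a promoter-level β matrix.

    A feature is up-methylated iff Δβ exceeds the candidate threshold, the
    moderated-test |logFC| (on the configured test scale) exceeds its
    threshold, the BH FDR is below its threshold, and the tumor mean exceeds
    the normal mean; down-methylated symmetric; otherwise none.
    """
    cfg = config or TestConfig()
    if beta_matrix.scale != "beta":
        raise ValidationError("call_dmlncs expects a beta-scale matrix")
    db = delta_beta(beta_matrix)
    scale = cfg.methylation_test_scale
    if scale == "m-value":
        test_vals = m_values(beta_matrix.values)
    elif scale == "log2beta":
        test_vals = np.log2(beta_matrix.values.clip(lower=_M_EPS))
    else:
        test_vals = beta_matrix.values
    test_matrix = FeatureMatrix(test_vals, beta_matrix.groups, "mvalue")
    res = moderated_t_test(test_matrix)
    # report means and Δβ on the raw β scale
    t_ids, n_ids = beta_matrix.samples_in(TUMOR), beta_matrix.samples_in(NORMAL)
    res["mean_tumor"] = beta_matrix.values[t_ids].mean(axis=1)
    res["mean_normal"] = beta_matrix.values[n_ids].mean(axis=1)
    res["delta_beta"] = db
    res["direction"] = _direction_calls(res, cfg, db)
    return res


def call_de_lncs(expr_matrix: FeatureMatrix, config: TestConfig | None = None) -> pd.DataFrame:
    """Differential expression calls on a log2(RPKM+1) matrix: |logFC| and
    FDR thresholds only (no Δβ filter)."""
    cfg = config or TestConfig()
    if expr_matrix.scale != "log2rpkm":
        raise ValidationError("call_de_lncs expects a log2rpkm-scale matrix")
    res = moderated_t_test(expr_matrix)
    res["direction"] = _direction_calls(res, cfg, None)
    return res


def catalog_from_calls(results: dict[str, pd.DataFrame]) -> dict[str, dict[str, set[str]]]:
    """Collect per-cancer direction calls into an up/down catalog."""
    return {
        cancer: {
            "up": set(res.index[res["direction"] == "up"]),
            "down": set(res.index[res["direction"] == "down"]),
        }
        for cancer, res in results.items()
    }
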