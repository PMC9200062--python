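"""Competing-endogenous-RNA (ceRNA) network screening.

An lncRNA–mRNA pair is a ceRNA candidate when the two share strictly more
than ``min_shared`` target miRNAs; sharing is tested for enrichment with an
upper-tail hypergeometric test over the miRNA universe (all distinct miRNAs
in the union of both target maps), and surviving pairs must additionally be
co-expressed in tumor samples (Pearson r above threshold with a significant
two-sided p from the t-approximation on n−2 df).  The filters are a pure
conjunction: relaxing any one can only grow the pair set.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import TUMOR, FeatureMatrix, TargetMap, ValidationError, logger

EDGE_COLUMNS = ["lnc", "mrna", "shared_k", "hyper_p", "r", "corr_p"]


@dataclasses.dataclass
class CeRNAThresholds:
    """All comparisons strict, matching the screening rules."""

    min_shared: int = 2          # keep pairs with shared_k > min_shared
    max_hyper_p: float = 0.05
    min_r: float = 0.3
    max_corr_p: float = 0.05
    correct_hyper_p: bool = False  # optional BH on the hypergeometric step
    correct_corr_p: bool = False


def hypergeom_shared_test(k: int, K: int, M: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, M): the chance that
    two target sets of sizes K and M drawn from N miRNAs share >= k."""
    if not (0 <= K <= N and 0 <= M <= N):
        raise ValidationError(f"need K,M <= N, got K={K} M={M} N={N}")
    if not 0 <= k <= min(K, M):
        raise ValidationError(f"need 0 <= k <= min(K,M), got k={k} K={K} M={M}")
    return float(stats.hypergeom.sf(k - 1, N, K, M))


def expression_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from t = r sqrt((n−2)/(1−r²)) on n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    return r, _corr_pvalue(np.array([r]), len(x))[0]


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def shared_mirna_counts(targets: TargetMap) -> tuple[pd.DataFrame, pd.Series, pd.Series, int]:
    """Shared-miRNA count matrix (lnc x mrna) plus per-RNA target sizes and
    the universe size, computed by boolean incidence-matrix products."""
    universe = sorted(targets.universe)
    idx = {m: i for i, m in enumerate(universe)}
    lncs = sorted(targets.lnc_targets)
    mrnas = sorted(targets.mrna_targets)
    L = np.zeros((len(lncs), len(universe)), dtype=np.int32)
    R = np.zeros((len(mrnas), len(universe)), dtype=np.int32)
    for i, lnc in enumerate(lncs):
        for m in targets.lnc_targets[lnc]:
            L[i, idx[m]] = 1
    for j, mr in enumerate(mrnas):
        for m in targets.mrna_targets[mr]:
            R[j, idx[m]] = 1
    shared = pd.DataFrame(L @ R.T, index=lncs, columns=mrnas)
    return (
        shared,
        pd.Series(L.sum(axis=1), index=lncs),
        pd.Series(R.sum(axis=1), index=mrnas),
        len(universe),
    )


def build_cerna_network(
    targets: TargetMap,
    lnc_expr: FeatureMatrix,
    mrna_expr: FeatureMatrix,
    thresholds: CeRNAThresholds | None = None,
    tumor_only: bool = True,
) -> pd.DataFrame:
    """Screen all lncRNA–mRNA pairs and return the surviving edges.

    Correlation is computed on tumor samples (shared between the two
    expression matrices).  Returns a DataFrame with columns
    lnc, mrna, shared_k, hyper_p, r, corr_p.
    """
    th = thresholds or CeRNAThresholds()
    if not targets.lnc_targets and not targets.mrna_targets:
        logger.warning("build_cerna_network: empty target map")
        return pd.DataFrame(columns=EDGE_COLUMNS)
    shared, k_lnc, k_mrna, n_universe = shared_mirna_counts(targets)
    if n_universe == 0:
        logger.warning("build_cerna_network: no miRNAs in the universe")
        return pd.DataFrame(columns=EDGE_COLUMNS)

    li, mj = np.nonzero(shared.to_numpy() > th.min_shared)
    if li.size == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    lnc_ids = shared.index.to_numpy(dtype=object)[li]
    mrna_ids = shared.columns.to_numpy(dtype=object)[mj]
    k = shared.to_numpy()[li, mj]
    K = k_lnc.to_numpy()[li]
    M = k_mrna.to_numpy()[mj]
    hyper_p = stats.hypergeom.sf(k - 1, n_universe, K, M)
    hyper_crit = _maybe_bh(hyper_p, th.correct_hyper_p)
    keep = hyper_crit < th.max_hyper_p
    if not keep.any():
        return pd.DataFrame(columns=EDGE_COLUMNS)
    lnc_ids, mrna_ids, k, hyper_p = lnc_ids[keep], mrna_ids[keep], k[keep], hyper_p[keep]

    samples = _correlation_samples(lnc_expr, mrna_expr, tumor_only)
    r, corr_p = _pairwise_correlation(lnc_expr, mrna_expr, samples, lnc_ids, mrna_ids)
    corr_crit = _maybe_bh(corr_p, th.correct_corr_p)
    keep = (r > th.min_r) & (corr_crit < th.max_corr_p)
    edges = pd.DataFrame(
        {
            "lnc": lnc_ids[keep],
            "mrna": mrna_ids[keep],
            "shared_k": k[keep],
            "hyper_p": hyper_p[keep],
            "r": r[keep],
            "corr_p": corr_p[keep],
        }
    )
    return edges.reset_index(drop=True)


def _maybe_bh(p: np.ndarray, do: bool) -> np.ndarray:
    if not do:
        return p
    from .diff import bh_fdr

    return bh_fdr(p)


def _correlation_samples(
    lnc_expr: FeatureMatrix, mrna_expr: FeatureMatrix, tumor_only: bool
) -> list[str]:
    if tumor_only and lnc_expr.groups is not None:
        shared = [s for s in lnc_expr.samples_in(TUMOR) if s in mrna_expr.values.columns]
    else:
        shared = [s for s in lnc_expr.values.columns if s in mrna_expr.values.columns]
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared samples for correlation")
    return shared


def _pairwise_correlation(
    lnc_expr: FeatureMatrix,
    mrna_expr: FeatureMatrix,
    samples: list[str],
    lnc_ids: np.ndarray,
    mrna_ids: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(samples)

    def standardized(fm: FeatureMatrix, ids: Iterable[str]) -> pd.DataFrame:
        vals = fm.values.loc[list(dict.fromkeys(ids)), samples].to_numpy(dtype=float)
        vals = vals - vals.mean(axis=1, keepdims=True)
        norm = np.sqrt((vals**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = np.nan  # constant vector: correlation undefined
        return pd.DataFrame(vals / norm, index=list(dict.fromkeys(ids)))

    zl = standardized(lnc_expr, lnc_ids)
    zm = standardized(mrna_expr, mrna_ids)
    r = np.einsum("ij,ij->i", zl.loc[lnc_ids].to_numpy(), zm.loc[mrna_ids].to_numpy())
    r = np.clip(r, -1.0, 1.0)
    p = np.where(np.isnan(r), 1.0, _corr_pvalue(np.nan_to_num(r), n))
    return np.nan_to_num(r), p


def map_candidates(edges: pd.DataFrame, candidates: Iterable[str]) -> pd.DataFrame:
    """Induced subnetwork: exactly the edges whose lncRNA is a candidate."""
    cand = set(candidates)
    if edges.empty:
        return edges.copy()
    return edges[edges["lnc"].isin(cand)].reset_index(drop=True)


def pan_cancer_subnetwork(
    nets: Mapping[str, pd.DataFrame],
    candidates: Iterable[str],
    min_cancers: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pan-cancer ceRNA subnetwork of candidate lncRNAs.

    Restricts each cancer's candidate subnetwork to mRNAs that partner a
    candidate in strictly more than ``min_cancers`` cancers.  Returns
    ``(edges, mrna_summary)`` where edges carry a ``cancer`` column and the
    summary holds, per (mrna, cancer), the partner count and mean correlation
    plus the number of cancers sharing the mRNA.
    """
    if len(nets) < 2:
        raise ValidationError("pan-cancer subnetwork needs >= 2 cancers")
    cand = set(candidates)
    per_cancer = {
        cancer: map_candidates(edges, cand) for cancer, edges in nets.items()
    }
    frames = [df.assign(cancer=cancer) for cancer, df in per_cancer.items() if not df.empty]
    if not frames:
        empty = pd.DataFrame(columns=EDGE_COLUMNS + ["cancer"])
        return empty, pd.DataFrame(columns=["mrna", "cancer", "n_lnc", "mean_r", "n_cancers_shared"])
    alledges = pd.concat(frames, ignore_index=True)
    cancers_per_mrna = alledges.groupby("mrna")["cancer"].nunique()
    keep_mrnas = set(cancers_per_mrna.index[cancers_per_mrna > min_cancers])
    edges = alledges[alledges["mrna"].isin(keep_mrnas)].reset_index(drop=True)
    if edges.empty:
        return edges, pd.DataFrame(columns=["mrna", "cancer", "n_lnc", "mean_r", "n_cancers_shared"])
    summary = (
        edges.groupby(["mrna", "cancer"])
        .agg(n_lnc=("lnc", "nunique"), mean_r=("r", "mean"))
        .reset_index()
    )
    summary["n_cancers_shared"] = summary["mrna"].map(cancers_per_mrna)
    return edges, summary
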