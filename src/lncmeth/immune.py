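"""Immune scoring, consensus clustering of key-lncRNA expression, and
subtype comparisons.

The three sample-level scores are plain means over fixed gene panels on the
log2(RPKM+1) scale: antigen presentation (MHC, nine genes), cytolytic
activity (CYT: GZMA, PRF1), and cytotoxic-T-lymphocyte effector function
(CTL: GZMA, PRF1, GZMB).  Subtypes come from consensus clustering of the key
lncRNAs' expression (subsampled k-means, k swept over a range, k picked by
the relative change in the area under the consensus CDF), and scores or
mutation burdens are compared between subtypes with the Wilcoxon rank-sum
test.
"""

from __future__ import annotations

import dataclasses
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

from .core import FeatureMatrix, ValidationError


@dataclasses.dataclass(frozen=True)
class GenePanel:
    mhc_genes: tuple[str, ...] = (
        "HLA-A", "PSMB9", "HLA-B", "PSMB8", "HLA-C", "B2M", "TAP2", "NLRC5", "TAP1",
    )
    cyt_genes: tuple[str, ...] = ("GZMA", "PRF1")
    ctl_genes: tuple[str, ...] = ("GZMA", "PRF1", "GZMB")

    def __post_init__(self):
        if len(self.mhc_genes) != 9 or len(self.cyt_genes) != 2 or len(self.ctl_genes) != 3:
            raise ValidationError("panel sizes must be 9 (MHC), 2 (CYT), 3 (CTL)")


def _panel_mean(expr, genes: Sequence[str]) -> pd.Series:
    values = expr.values if isinstance(expr, FeatureMatrix) else expr
    for g in genes:
        if g not in values.index:
            raise ValidationError(f"panel gene {g} missing from expression matrix")
    return values.loc[list(genes)].mean(axis=0)


def mhc_score(expr, panel: GenePanel | None = None) -> pd.Series:
    """Mean expression of the nine MHC-I core genes, per sample."""
    return _panel_mean(expr, (panel or GenePanel()).mhc_genes)


def cyt_score(expr, panel: GenePanel | None = None) -> pd.Series:
    """Mean expression of GZMA and PRF1, per sample."""
    return _panel_mean(expr, (panel or GenePanel()).cyt_genes)


def ctl_score(expr, panel: GenePanel | None = None) -> pd.Series:
    """Mean expression of GZMA, PRF1 and GZMB, per sample."""
    return _panel_mean(expr, (panel or GenePanel()).ctl_genes)


def immune_score_table(expr, panel: GenePanel | None = None) -> pd.DataFrame:
    p = panel or GenePanel()
    return pd.DataFrame(
        {"mhc": mhc_score(expr, p), "cyt": cyt_score(expr, p), "ctl": ctl_score(expr, p)}
    )


# -----------------------------------------------------------------------------
# consensus clustering


@dataclasses.dataclass
class ClusterAssignment:
    labels: pd.Series                 # sample -> subtype in 1..chosen_k
    chosen_k: int
    consensus_matrix: pd.DataFrame    # co-clustering frequencies at chosen_k
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]
    stable: bool = True


def consensus_cluster(
    expr,
    k_range: Iterable[int] = range(2, 7),
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    min_samples: int = 20,
) -> ClusterAssignment:
    """Consensus clustering of samples on (few) feature rows.

    For each k, samples are repeatedly subsampled and clustered with k-means;
    the consensus matrix holds co-assignment frequencies among co-sampled
    pairs.  k is chosen by the largest relative change in the area under the
    consensus CDF (the k=2 area counts as its own change), and final labels
    come from average-linkage clustering of the consensus dissimilarity.
    Deterministic for a given seed.
    """
    values = expr.values if isinstance(expr, FeatureMatrix) else pd.DataFrame(expr)
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 features to cluster on")
    n = values.shape[1]
    if n < min_samples:
        raise ValidationError(f"need at least {min_samples} samples, got {n}")
    X = values.to_numpy(dtype=float).T  # samples x features
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValidationError("degenerate input: all samples identical")
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    sub_n = max(2, int(np.floor(subsample_frac * n)))
    consensus: dict[int, np.ndarray] = {}
    for k in ks:
        co = np.zeros((n, n))
        together = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=sub_n, replace=False)
            km = KMeans(
                n_clusters=k, n_init=3,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[idx])
            labels = km.labels_
            sampled = np.zeros(n, dtype=bool)
            sampled[idx] = True
            together[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                members = idx[labels == c]
                co[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = np.where(together > 0, co / together, 0.0)
        np.fill_diagonal(cm, 1.0)
        consensus[k] = cm

    areas = {k: _consensus_cdf_area(cm) for k, cm in consensus.items()}
    deltas: dict[int, float] = {}
    prev = None
    for k in ks:
        if prev is None:
            deltas[k] = areas[k]
        else:
            deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    chosen_k = max(ks, key=lambda k: (deltas[k], -k))

    cm = consensus[chosen_k]
    model = AgglomerativeClustering(
        n_clusters=chosen_k, metric="precomputed", linkage="average"
    ).fit(1.0 - cm)
    labels = pd.Series(model.labels_ + 1, index=values.columns, name="subtype")
    off_diag = cm[~np.eye(n, dtype=bool)]
    stable = bool(np.mean((off_diag < 0.1) | (off_diag > 0.9)) > 0.5)
    return ClusterAssignment(
        labels=labels,
        chosen_k=chosen_k,
        consensus_matrix=pd.DataFrame(cm, index=values.columns, columns=values.columns),
        cdf_areas=areas,
        delta_areas=deltas,
        stable=stable,
    )


def _consensus_cdf_area(cm: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    n = cm.shape[0]
    vals = np.sort(cm[np.triu_indices(n, k=1)])
    if vals.size == 0:
        return 0.0
    grid = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.searchsorted(vals, grid[:-1], side="right") / vals.size
    return float(np.sum(np.diff(grid) * cdf))


# -----------------------------------------------------------------------------
# group comparisons


def compare_groups(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of ``values`` between subtype labels.

    Two subtypes give one row; more give all pairwise rows (uncorrected).
    The test is exact (exhaustive permutation) when both groups have <= 10
    samples, and the tie-corrected normal approximation otherwise.
    """
    values = pd.Series(values)
    labels = pd.Series(labels).reindex(values.index)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("need at least two subtypes to compare")
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            x = values[labels == ga].to_numpy(dtype=float)
            y = values[labels == gb].to_numpy(dtype=float)
            stat, p = rank_sum_test(x, y)
            rows.append({"group_a": ga, "group_b": gb, "statistic": stat, "p": p})
    return pd.DataFrame(rows)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    if len(x) <= 10 and len(y) <= 10:
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if not ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        else:
            n_exact = comb(len(x) + len(y), len(x))
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided",
                method=stats.PermutationMethod(
                    n_resamples=max(n_exact, 1), random_state=0
                ),
            )
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))
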