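"""Survival screening: Kaplan–Meier, log-rank, maximally selected cut-points.

The cut-point scan uses the rank-statistic formulation: each sample receives
a log-rank (Nelson–Aalen) score a_i = δ_i − Λ̂(t_i); for a cut that places the
m lowest-expression samples in the low group the standardized statistic is

    z_m = (Σ_{high} (a_i − ā)) / sqrt( m(n−m)/(n(n−1)) · Σ_i (a_i − ā)² )

and the maximally selected statistic is max_m |z_m| over all admissible cuts
(cuts between distinct expression values leaving at least a minimum fraction
of samples on each side).  Its p-value is estimated by permuting the
expression labels and recomputing the maximum, which is exact in distribution
at any sample size and makes the whole screen invariant to strictly monotone
transforms of expression.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .core import FeatureMatrix, ValidationError, logger, validate_survival


def km_estimate(surv: pd.DataFrame) -> pd.Series:
    """Product-limit survival estimate; right-continuous step function
    returned as a Series indexed by time (including time 0)."""
    surv = validate_survival(surv)
    if surv.empty:
        raise ValidationError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"])
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    return s


def logrank_test(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    a, b = validate_survival(a), validate_survival(b)
    if a.empty or b.empty:
        raise ValidationError("both groups must be non-empty")
    if not (a["event"].any() or b["event"].any()):
        raise ValidationError("log-rank test undefined without any events")
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank (Nelson–Aalen) scores a_i = δ_i − Λ̂(t_i), ties allowed."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="stable")
    n = len(time)
    scores = np.empty(n)
    cumhaz = 0.0
    i = 0
    at_risk = n
    while i < n:
        j = i
        d = 0
        while j < n and time[order[j]] == time[order[i]]:
            d += int(event[order[j]])
            j += 1
        if d:
            cumhaz += d / at_risk
        for k in range(i, j):
            scores[order[k]] = float(event[order[k]]) - cumhaz
        at_risk -= j - i
        i = j
    return scores


@dataclasses.dataclass
class CutpointResult:
    cutpoint: float
    statistic: float          # maximal standardized |log-rank| statistic
    p: float                  # permutation p-value
    n_high: int
    n_low: int


def _admissible_cuts(expr_sorted: np.ndarray, n: int, min_group_frac: float) -> np.ndarray:
    """Indices m such that the m lowest samples form the low group: both
    groups at least ceil(n*frac) and the cut falls between distinct values."""
    min_size = max(1, int(np.ceil(n * min_group_frac)))
    ms = np.arange(min_size, n - min_size + 1)
    distinct = expr_sorted[ms - 1] < expr_sorted[ms]
    return ms[distinct]


def maxstat_cutpoint(
    expr: pd.Series | np.ndarray,
    surv: pd.DataFrame,
    min_group_frac: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    min_n: int = 10,
) -> CutpointResult:
    """Maximally selected log-rank statistic over expression cut-points with a
    permutation p-value.  Ties in expression always share a side; the reported
    cut is the midpoint between the two straddling distinct values, and among
    equal maxima the lowest cut is returned."""
    surv = validate_survival(surv)
    expr = pd.Series(expr)
    if not expr.index.equals(surv.index):
        expr = expr.reindex(surv.index)
        if expr.isna().any():
            raise ValidationError("expression missing for some survival samples")
    n = len(expr)
    if n < min_n:
        raise ValidationError(f"need n >= {min_n} samples, got {n}")
    if not 0.0 < min_group_frac < 0.5:
        raise ValidationError("min_group_frac must be in (0, 0.5)")
    x = expr.to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ms = _admissible_cuts(xs, n, min_group_frac)
    if len(ms) < 2:
        raise ValidationError("fewer than 2 admissible cut-points")

    a = logrank_scores(surv["time"].to_numpy(), surv["event"].to_numpy())
    ac = a - a.mean()
    ssq = float((ac**2).sum())
    if ssq <= 0:
        raise ValidationError("log-rank scores are constant (no events)")
    denom = np.sqrt(ms * (n - ms) / (n * (n - 1.0)) * ssq)
    csum = np.cumsum(ac[order])
    z = np.abs(-csum[ms - 1]) / denom
    best = int(np.argmax(z))
    m_star = int(ms[best])
    statistic = float(z[best])
    cutpoint = float(0.5 * (xs[m_star - 1] + xs[m_star]))

    rng = np.random.default_rng(seed)
    if n_perm > 0:
        perm = rng.permuted(np.broadcast_to(ac, (n_perm, n)).copy(), axis=1)
        pcsum = np.cumsum(perm, axis=1)
        pz = np.abs(-pcsum[:, ms - 1]) / denom
        pmax = pz.max(axis=1)
        p = float((1 + np.sum(pmax >= statistic)) / (n_perm + 1))
    else:
        p = float("nan")
    return CutpointResult(cutpoint, statistic, p, n_high=n - m_star, n_low=m_star)


@dataclasses.dataclass
class ScreenResult:
    cutpoint: CutpointResult
    significant: bool
    risk_direction: str  # 'high_worse' | 'high_better'


def survival_screen(
    candidates: Iterable[str],
    expr: FeatureMatrix,
    surv: pd.DataFrame,
    alpha: float = 0.05,
    min_group_frac: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, ScreenResult]:
    """Run the cut-point screen for each candidate lncRNA.

    A candidate is survival-associated iff its permutation p < alpha.  The
    risk direction records whether the high-expression group accumulates
    excess events (carcinogenic reading) or the reverse.
    """
    surv = validate_survival(surv)
    samples = [s for s in surv.index if s in expr.values.columns]
    if not samples:
        raise ValidationError("no overlap between expression and survival samples")
    sub_surv = surv.loc[samples]
    dropped = len(surv) - len(samples)
    if dropped:
        logger.info("survival_screen: %d survival samples missing expression", dropped)
    results: dict[str, ScreenResult] = {}
    ss = np.random.SeedSequence(seed)
    candidates = list(candidates)
    children = ss.spawn(len(candidates)) if candidates else []
    a = logrank_scores(sub_surv["time"].to_numpy(), sub_surv["event"].to_numpy())
    ac = a - a.mean()
    for cand, child in zip(candidates, children):
        if cand not in expr.values.index:
            logger.warning("survival_screen: candidate %s missing from matrix; skipped", cand)
            continue
        x = expr.values.loc[cand, samples]
        try:
            res = maxstat_cutpoint(
                x, sub_surv, min_group_frac=min_group_frac, n_perm=n_perm,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        except ValidationError as err:
            # near-constant expression admits no cut: not testable, not fatal
            logger.warning("survival_screen: %s skipped (%s)", cand, err)
            continue
        high = x.to_numpy(dtype=float) > res.cutpoint
        direction = "high_worse" if ac[high].sum() > 0 else "high_better"
        results[cand] = ScreenResult(res, bool(res.p < alpha), direction)
    return results


def km_curve_table(
    expr: pd.Series, surv: pd.DataFrame, cutpoint: float
) -> pd.DataFrame:
    """KM curve coordinates (time, survival, group) for the two cut groups,
    suitable for external plotting."""
    surv = validate_survival(surv)
    high = expr.reindex(surv.index) > cutpoint
    frames = []
    for label, mask in (("high", high), ("low", ~high)):
        if mask.sum() == 0:
            continue
        s = km_estimate(surv[mask.to_numpy()])
        frames.append(pd.DataFrame({"time": s.index, "survival": s.to_numpy(), "group": label}))
    return pd.concat(frames, ignore_index=True)
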