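"""Synthetic multi-cancer cohort generator with planted ground truth.

Emulates the statistical regimes the analysis assumes: bounded Beta-distributed
probe β-values with group-shifted means for planted differentially methylated
lncRNAs, log-scale expression negatively coupled to promoter methylation,
bipartite miRNA target maps with planted shared-target ceRNA pairs that are
co-expressed, exponential survival with expression-dependent hazard under
independent censoring, and integer mutation burdens differing by planted
immune subtype.  Every planted signal is recorded in a truth object so that
each downstream stage can be scored against what was planted.

No attempt is made to mimic probe chemistry, batch effects, or copy-number
confounding.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    NORMAL,
    TUMOR,
    FeatureMatrix,
    TargetMap,
    ValidationError,
    logger,
    validate_promoter_map,
    write_groups_tsv,
    write_json,
    write_matrix_tsv,
    write_promoter_map_tsv,
    write_survival_tsv,
    write_target_map_tsv,
)

#: Gene symbols given to the first mRNAs so that immune scoring is exercised
#: end-to-end on simulated cohorts (9 antigen-presentation genes, then the
#: cytolysis/effector genes).
IMMUNE_GENES = (
    "HLA-A", "PSMB9", "HLA-B", "PSMB8", "HLA-C", "B2M", "TAP2", "NLRC5", "TAP1",
    "GZMA", "PRF1", "GZMB",
)


@dataclasses.dataclass(frozen=True)
class PlantedDM:
    """A planted differential-methylation effect on a set of lncRNAs.

    ``delta_beta`` is the shift of the tumor-group mean β relative to normal
    (direction 'up' raises tumor methylation).  When ``coupled`` the affected
    lncRNAs' expression follows promoter methylation through the cohort's
    coupling slope, which makes them negatively correlated lncRNAs.
    """

    lnc_indices: tuple[int, ...]
    delta_beta: float
    direction: str  # 'up' | 'down'
    coupled: bool = True

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be up/down, got {self.direction!r}")
        if not 0.0 <= self.delta_beta <= 1.0:
            raise ValidationError(f"delta_beta {self.delta_beta} outside [0,1]")


@dataclasses.dataclass(frozen=True)
class PlantedCeRNA:
    lnc_index: int
    mrna_index: int
    n_shared: int
    r: float

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError("planted correlation must be in [-1,1]")
        if self.n_shared < 1:
            raise ValidationError("n_shared must be positive")


@dataclasses.dataclass
class SimulationConfig:
    """Everything that shapes a simulated cohort; identical config + seed
    reproduces the cohort bit for bit."""

    n_cancers: int = 3
    n_tumor: int = 50
    n_normal: int = 20
    n_lnc: int = 300
    n_mrna: int = 150
    n_mirna: int = 150
    probes_per_promoter: int = 3
    #: Beta(a, b) from which each lncRNA's baseline mean β is drawn.
    baseline_beta_params: tuple[float, float] = (2.0, 3.0)
    #: Concentration (α+β) of the per-sample Beta draws around each mean;
    #: larger means tighter per-sample β.
    beta_concentration: float = 30.0
    #: Planted DM effects; either one list applied to every cancer or a
    #: mapping cancer-index -> list.
    planted_dm: Sequence[PlantedDM] | Mapping[int, Sequence[PlantedDM]] = ()
    #: Slope of log2-expression per unit promoter β (negative couples
    #: methylation gain to expression loss).
    coupling_strength: float = -8.0
    expr_noise_sd: float = 0.5
    planted_cerna: Sequence[PlantedCeRNA] = ()
    background_density: float = 0.02
    survival_hr: float = 3.0
    #: lncRNA indices whose expression drives the hazard (per cancer or shared).
    planted_prognostic: Sequence[int] | Mapping[int, Sequence[int]] = ()
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.1
    missing_rate: float = 0.05
    #: Mean mutation count per planted immune subtype (len = number of subtypes).
    tmb_params: tuple[float, ...] = (2.0, 8.0)
    #: Expression shift (log2 scale) separating subtypes on the key lncRNAs.
    subtype_shift: float = 3.0
    #: The first ``n_key_lncs`` lncRNAs carry the subtype expression shift.
    n_key_lncs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_cancers=self.n_cancers, n_tumor=self.n_tumor, n_normal=self.n_normal,
            n_lnc=self.n_lnc, n_mrna=self.n_mrna, n_mirna=self.n_mirna,
            probes_per_promoter=self.probes_per_promoter,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValidationError("censoring_rate must be in [0,1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0,1)")
        if not 0.0 <= self.background_density <= 1.0:
            raise ValidationError("background_density must be in [0,1]")
        if self.survival_hr <= 0:
            raise ValidationError("survival_hr must be positive")
        a, b = self.baseline_beta_params
        if a <= 0 or b <= 0:
            raise ValidationError("baseline_beta_params must be positive")
        for effect in self._all_dm_effects():
            for idx in effect.lnc_indices:
                if not 0 <= idx < self.n_lnc:
                    raise ValidationError(f"planted DM index {idx} >= n_lnc for {effect}")
            if self.delta_margin(effect.delta_beta) is None:
                raise ValidationError(
                    f"planted effect {effect} pushes mean beta outside [0,1]: "
                    f"no baseline window admits a shift of {effect.delta_beta}"
                )
        for pc in self.planted_cerna:
            if not 0 <= pc.lnc_index < self.n_lnc or not 0 <= pc.mrna_index < self.n_mrna:
                raise ValidationError(f"planted ceRNA pair {pc} references missing ids")
            if pc.n_shared > self.n_mirna:
                raise ValidationError(f"planted ceRNA {pc} requests more shared miRNAs than exist")
        mrnas = [pc.mrna_index for pc in self.planted_cerna]
        if len(mrnas) != len(set(mrnas)):
            raise ValidationError("each mRNA may appear in at most one planted ceRNA pair")

    # margin kept between a shifted mean β and the [0,1] boundary
    _EDGE = 0.05

    def delta_margin(self, delta: float) -> tuple[float, float] | None:
        """Feasible [lo, hi] window for the baseline mean given a shift of
        ``delta`` in either direction, or None if no window exists."""
        lo, hi = self._EDGE + delta, 1.0 - self._EDGE - delta
        return (lo, hi) if lo < hi else None

    def _all_dm_effects(self) -> list[PlantedDM]:
        if isinstance(self.planted_dm, Mapping):
            return [e for effects in self.planted_dm.values() for e in effects]
        return list(self.planted_dm)

    def dm_effects_for(self, cancer_index: int) -> list[PlantedDM]:
        if isinstance(self.planted_dm, Mapping):
            return list(self.planted_dm.get(cancer_index, ()))
        return list(self.planted_dm)

    def prognostic_for(self, cancer_index: int) -> list[int]:
        if isinstance(self.planted_prognostic, Mapping):
            return list(self.planted_prognostic.get(cancer_index, ()))
        return list(self.planted_prognostic)


@dataclasses.dataclass
class SyntheticTruth:
    """Planted labels used as the oracle for downstream recovery tests."""

    dm_labels: dict[str, dict[str, str]]      # cancer -> lnc -> up/down
    de_labels: dict[str, dict[str, str]]      # cancer -> lnc -> up/down
    nclnc_labels: dict[str, dict[str, str]]   # cancer -> lnc -> UMLE/DMOE
    cerna_pairs: set[tuple[str, str]]
    prognostic: dict[str, set[str]]           # cancer -> lnc set
    subtype: dict[str, pd.Series]             # cancer -> tumor sample -> int


@dataclasses.dataclass
class CancerData:
    name: str
    methylation: FeatureMatrix      # probe-level β, zeros are missing
    lnc_expression: FeatureMatrix   # RPKM scale
    mrna_expression: FeatureMatrix  # RPKM scale
    survival: pd.DataFrame          # tumor samples: time, event
    mutation_counts: pd.Series      # tumor samples


@dataclasses.dataclass
class SyntheticCohort:
    cancers: dict[str, CancerData]
    promoter_map: dict[str, list[str]]
    targets: TargetMap
    truth: SyntheticTruth
    config: SimulationConfig


# -----------------------------------------------------------------------------
# target map


def simulate_target_map(
    n_lnc: int,
    n_mrna: int,
    n_mirna: int,
    background_density: float,
    planted_cerna: Sequence[PlantedCeRNA] = (),
    seed: int = 0,
    lnc_ids: Sequence[str] | None = None,
    mrna_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
) -> TargetMap:
    """Random bipartite target relations plus guaranteed shared miRNAs for
    every planted ceRNA pair.

    Background edges are independent Bernoulli(``background_density``), so a
    random lncRNA/mRNA pair shares ``n_mirna * density^2`` miRNAs in
    expectation; planted pairs additionally receive ``n_shared`` dedicated
    miRNAs added to both sides.
    """
    if not 0.0 <= background_density <= 1.0:
        raise ValidationError("background_density must be in [0,1]")
    for pc in planted_cerna:
        if pc.n_shared > n_mirna:
            raise ValidationError(
                f"planted pair ({pc.lnc_index},{pc.mrna_index}) requests "
                f"{pc.n_shared} shared miRNAs but only {n_mirna} exist"
            )
    rng = np.random.default_rng(seed)
    lnc_ids = list(lnc_ids) if lnc_ids is not None else [f"LNC{i:04d}" for i in range(n_lnc)]
    mrna_ids = list(mrna_ids) if mrna_ids is not None else [f"MRNA{i:04d}" for i in range(n_mrna)]
    mirna_ids = list(mirna_ids) if mirna_ids is not None else [f"MIR{i:04d}" for i in range(n_mirna)]

    lnc_adj = rng.random((n_lnc, n_mirna)) < background_density
    mrna_adj = rng.random((n_mrna, n_mirna)) < background_density
    for pc in planted_cerna:
        shared = rng.choice(n_mirna, size=pc.n_shared, replace=False)
        lnc_adj[pc.lnc_index, shared] = True
        mrna_adj[pc.mrna_index, shared] = True

    mir = np.asarray(mirna_ids, dtype=object)
    lnc_targets = {
        lnc_ids[i]: frozenset(mir[lnc_adj[i]]) for i in range(n_lnc)
    }
    mrna_targets = {
        mrna_ids[j]: frozenset(mir[mrna_adj[j]]) for j in range(n_mrna)
    }
    return TargetMap(lnc_targets, mrna_targets)


# -----------------------------------------------------------------------------
# survival


def simulate_survival(
    expression_values: pd.Series | np.ndarray,
    hazard_ratio: float,
    censoring_rate: float,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential event times with hazard multiplied by ``hazard_ratio`` for
    samples above the expression median; censoring times uniform on (0, H)
    with H tuned so the expected censored fraction equals ``censoring_rate``.
    """
    if hazard_ratio <= 0:
        raise ValidationError("hazard_ratio must be positive")
    expr = pd.Series(expression_values)
    if expr.empty:
        raise ValidationError("empty expression vector")
    rng = np.random.default_rng(seed)
    high = (expr.to_numpy(dtype=float) > np.median(expr.to_numpy(dtype=float)))
    hazards = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    return _survival_from_hazards(hazards, censoring_rate, rng, expr.index)


def _survival_from_hazards(
    hazards: np.ndarray, censoring_rate: float, rng: np.random.Generator, index
) -> pd.DataFrame:
    event_times = rng.exponential(1.0 / hazards)
    if censoring_rate <= 0.0:
        time, event = event_times, np.ones(len(event_times), dtype=bool)
    else:
        horizon = _censoring_horizon(event_times, censoring_rate)
        censor_times = rng.uniform(0.0, horizon, size=len(event_times))
        event = event_times <= censor_times
        time = np.minimum(event_times, censor_times)
    time = np.maximum(time, 1e-9)  # keep times strictly positive
    return pd.DataFrame({"time": time, "event": event}, index=index)


def _censoring_horizon(event_times: np.ndarray, rate: float) -> float:
    """Solve for H such that mean_i P(U(0,H) < E_i) = rate (bisection;
    P(C<E|E) = min(E/H, 1), monotone decreasing in H)."""
    lo, hi = 1e-9, float(event_times.max()) / max(rate, 1e-9) + 1.0

    def frac(h: float) -> float:
        return float(np.mean(np.minimum(event_times / h, 1.0)))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -----------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a multi-cancer cohort with the planted structure recorded in
    ``truth``.  Deterministic for a given config (seed included)."""
    root = np.random.SeedSequence(config.seed)
    # one child stream per concern, spawned in a fixed order
    ss_targets, ss_baseline, *ss_cancers = root.spawn(2 + config.n_cancers)

    lnc_ids = [f"LNC{i:04d}" for i in range(config.n_lnc)]
    mrna_ids = [
        IMMUNE_GENES[i] if i < len(IMMUNE_GENES) and i < config.n_mrna else f"MRNA{i:04d}"
        for i in range(config.n_mrna)
    ]
    mirna_ids = [f"MIR{i:04d}" for i in range(config.n_mirna)]
    promoter_map = {
        lnc: [f"cg_{lnc}_{j}" for j in range(config.probes_per_promoter)]
        for lnc in lnc_ids
    }
    validate_promoter_map(promoter_map)

    targets = simulate_target_map(
        config.n_lnc, config.n_mrna, config.n_mirna, config.background_density,
        config.planted_cerna, seed=ss_targets.generate_state(1)[0] % (2**31),
        lnc_ids=lnc_ids, mrna_ids=mrna_ids, mirna_ids=mirna_ids,
    )

    # Baseline mean β per lncRNA, shared across cancers so pan-cancer set
    # logic sees consistent features.
    rng_base = np.random.default_rng(ss_baseline)
    a, b = config.baseline_beta_params
    baseline_mu = rng_base.beta(a, b, size=config.n_lnc)
    baseline_mu = np.clip(baseline_mu, SimulationConfig._EDGE, 1 - SimulationConfig._EDGE)

    truth = SyntheticTruth({}, {}, {}, set(), {}, {})
    for pc in config.planted_cerna:
        truth.cerna_pairs.add((lnc_ids[pc.lnc_index], mrna_ids[pc.mrna_index]))

    cancers: dict[str, CancerData] = {}
    for ci in range(config.n_cancers):
        name = f"CANCER{ci:02d}"
        rng = np.random.default_rng(ss_cancers[ci])
        data, dm_lab, de_lab, nc_lab, prog, subtype = _simulate_one_cancer(
            name, ci, config, rng, lnc_ids, mrna_ids, promoter_map, baseline_mu
        )
        cancers[name] = data
        truth.dm_labels[name] = dm_lab
        truth.de_labels[name] = de_lab
        truth.nclnc_labels[name] = nc_lab
        truth.prognostic[name] = prog
        truth.subtype[name] = subtype

    return SyntheticCohort(cancers, promoter_map, targets, truth, config)


def _simulate_one_cancer(
    name: str,
    ci: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    lnc_ids: list[str],
    mrna_ids: list[str],
    promoter_map: dict[str, list[str]],
    baseline_mu: np.ndarray,
):
    n_lnc, n_t, n_n = config.n_lnc, config.n_tumor, config.n_normal
    tumor_ids = [f"{name}_T{i:03d}" for i in range(n_t)]
    normal_ids = [f"{name}_N{i:03d}" for i in range(n_n)]
    sample_ids = tumor_ids + normal_ids
    groups = pd.Series([TUMOR] * n_t + [NORMAL] * n_n, index=sample_ids)

    effects = config.dm_effects_for(ci)
    delta = np.zeros(n_lnc)        # signed tumor-minus-normal mean shift
    coupled = np.zeros(n_lnc, dtype=bool)
    dm_lab: dict[str, str] = {}
    for eff in effects:
        sign = 1.0 if eff.direction == "up" else -1.0
        for idx in eff.lnc_indices:
            delta[idx] = sign * eff.delta_beta
            coupled[idx] = eff.coupled
            dm_lab[lnc_ids[idx]] = eff.direction

    # Keep shifted means inside (0,1): re-anchor planted baselines into the
    # feasible window for their shift (deterministic affine squeeze).
    mu_normal = baseline_mu.copy()
    for idx in np.nonzero(delta)[0]:
        window = config.delta_margin(abs(delta[idx]))
        lo, hi = window
        span = 1.0 - 2 * SimulationConfig._EDGE
        mu_normal[idx] = lo + (baseline_mu[idx] - SimulationConfig._EDGE) / span * (hi - lo)
        if delta[idx] > 0:
            mu_normal[idx] = min(mu_normal[idx], 1.0 - SimulationConfig._EDGE - delta[idx])
        else:
            mu_normal[idx] = max(mu_normal[idx], SimulationConfig._EDGE - delta[idx])
    mu_tumor = mu_normal + delta

    kappa = config.beta_concentration
    # per-sample probe β draws: each promoter probe follows the lncRNA mean
    probes, rows = [], []
    mu_matrix = np.empty((n_lnc, n_t + n_n))
    mu_matrix[:, :n_t] = mu_tumor[:, None]
    mu_matrix[:, n_t:] = mu_normal[:, None]
    for li, lnc in enumerate(lnc_ids):
        mu = mu_matrix[li]
        for probe in promoter_map[lnc]:
            vals = rng.beta(mu * kappa, (1 - mu) * kappa)
            probes.append(probe)
            rows.append(vals)
    beta = np.vstack(rows)
    promoter_beta_true = beta.reshape(n_lnc, config.probes_per_promoter, -1).mean(axis=1)

    if config.missing_rate > 0:
        mask = rng.random(beta.shape) < config.missing_rate
        beta = np.where(mask, 0.0, beta)
    meth = FeatureMatrix(pd.DataFrame(beta, index=probes, columns=sample_ids), groups, "beta")

    # lncRNA expression on the log2(RPKM+1) scale; baselines sit high enough
    # that the strongest planted down-coupling cannot clip expression at zero
    base_l = rng.uniform(3.0, 7.0, size=n_lnc)
    noise = rng.normal(0.0, config.expr_noise_sd, size=(n_lnc, n_t + n_n))
    log_expr = base_l[:, None] + noise
    slope = config.coupling_strength
    log_expr[coupled] += slope * (promoter_beta_true[coupled] - mu_normal[coupled, None])

    # planted immune subtypes shift the key lncRNAs in tumor samples
    n_sub = len(config.tmb_params)
    subtype = pd.Series(
        (np.arange(n_t) * n_sub // n_t) + 1, index=tumor_ids, name="subtype"
    )
    # centered so the tumor-group mean (and hence DE truth) is unchanged
    centered = subtype.to_numpy() - 1 - (n_sub - 1) / 2.0
    for k in range(min(config.n_key_lncs, n_lnc)):
        log_expr[k, :n_t] += centered * config.subtype_shift
    log_expr = np.maximum(log_expr, 0.0)
    lnc_expr = FeatureMatrix(
        pd.DataFrame(np.exp2(log_expr) - 1.0, index=lnc_ids, columns=sample_ids),
        groups, "rpkm",
    )

    # truth labels for expression / negative correlation, implied by coupling
    de_lab: dict[str, str] = {}
    nc_lab: dict[str, str] = {}
    for idx in np.nonzero(delta)[0]:
        if not coupled[idx]:
            continue
        expected_lfc = slope * delta[idx]
        if abs(expected_lfc) > 1.0:
            de_lab[lnc_ids[idx]] = "up" if expected_lfc > 0 else "down"
            nc_lab[lnc_ids[idx]] = "UMLE" if delta[idx] > 0 else "DMOE"

    # mRNA expression; planted ceRNA partners track their lncRNA
    base_m = rng.uniform(2.0, 6.0, size=config.n_mrna)
    m_expr = base_m[:, None] + rng.normal(0.0, 1.0, size=(config.n_mrna, n_t + n_n))
    for pc in config.planted_cerna:
        x = log_expr[pc.lnc_index]
        xs = (x - x.mean()) / max(x.std(), 1e-12)
        z = rng.normal(0.0, 1.0, size=n_t + n_n)
        m_expr[pc.mrna_index] = base_m[pc.mrna_index] + (
            pc.r * xs + np.sqrt(max(0.0, 1 - pc.r**2)) * z
        )
    m_expr = np.maximum(m_expr, 0.0)
    mrna_expr = FeatureMatrix(
        pd.DataFrame(np.exp2(m_expr) - 1.0, index=mrna_ids, columns=sample_ids),
        groups, "rpkm",
    )

    # survival for tumor samples, hazard driven by planted prognostic lncRNAs
    prog_idx = config.prognostic_for(ci)
    hazards = np.full(n_t, config.baseline_hazard)
    for idx in prog_idx:
        x = log_expr[idx, :n_t]
        hazards *= np.where(x > np.median(x), config.survival_hr, 1.0)
    survival = _survival_from_hazards(hazards, config.censoring_rate, rng, tumor_ids)

    tmb_means = np.asarray(config.tmb_params)[subtype.to_numpy() - 1]
    mutation_counts = pd.Series(
        rng.poisson(tmb_means), index=tumor_ids, name="mutation_count"
    )

    data = CancerData(name, meth, lnc_expr, mrna_expr, survival, mutation_counts)
    prog = {lnc_ids[i] for i in prog_idx}
    return data, dm_lab, de_lab, nc_lab, prog, subtype


# -----------------------------------------------------------------------------
# on-disk exchange format


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort as the TSV/JSON exchange files consumed by the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_promoter_map_tsv(cohort.promoter_map, outdir / "promoter_map.tsv")
    write_target_map_tsv(cohort.targets, outdir / "target_map.tsv")
    truth = cohort.truth
    write_json(
        dict(
            dm_labels=truth.dm_labels,
            de_labels=truth.de_labels,
            nclnc_labels=truth.nclnc_labels,
            cerna_pairs=sorted(truth.cerna_pairs),
            prognostic={k: sorted(v) for k, v in truth.prognostic.items()},
            subtype={k: v.to_dict() for k, v in truth.subtype.items()},
        ),
        outdir / "truth.json",
    )
    for name, data in cohort.cancers.items():
        d = outdir / name
        d.mkdir(exist_ok=True)
        write_matrix_tsv(data.methylation, d / "methylation.tsv")
        write_matrix_tsv(data.lnc_expression, d / "lnc_expression.tsv")
        write_matrix_tsv(data.mrna_expression, d / "mrna_expression.tsv")
        write_groups_tsv(data.methylation.groups, d / "groups.tsv")
        write_survival_tsv(data.survival, d / "survival.tsv")
        data.mutation_counts.rename("mutation_count").to_csv(
            d / "mutations.tsv", sep="\t", index_label="sample_id"
        )
    logger.info("wrote cohort with %d cancers to %s", len(cohort.cancers), outdir)


def three_cancer_demo_config(seed: int = 0, noise_free: bool = False) -> SimulationConfig:
    """The package's reference study design: three cancers with planted
    cancer-common lncRNAs (0–4, up-methylated and coupled everywhere),
    cancer-specific triples per cancer, ceRNA pairs, and one prognostic
    lncRNA per cancer.

    ``noise_free`` tightens the β concentration and expression noise so that
    every planted set is recovered deterministically; the default regime uses
    realistic sampling noise.
    """
    common = PlantedDM(tuple(range(5)), 0.25, "up", coupled=True)
    planted = {
        0: [common, PlantedDM((10, 11, 12), 0.3, "down", coupled=True)],
        1: [common, PlantedDM((20, 21, 22), 0.3, "up", coupled=True)],
        2: [common, PlantedDM((30, 31, 32), 0.3, "down", coupled=True)],
    }
    kwargs = dict(beta_concentration=4000.0, expr_noise_sd=0.05, missing_rate=0.0) if noise_free else {}
    return SimulationConfig(
        n_cancers=3, n_tumor=50, n_normal=20, n_lnc=200, n_mrna=100, n_mirna=150,
        planted_dm=planted,
        planted_cerna=[
            PlantedCeRNA(10, 30, 5, 0.6),
            PlantedCeRNA(0, 40, 6, 0.6),
            PlantedCeRNA(20, 50, 5, 0.6),
        ],
        planted_prognostic={0: [10], 1: [20], 2: [30]},
        seed=seed,
        **kwargs,
    )


def read_cohort(indir: str | Path, config: SimulationConfig | None = None) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    import json as _json

    from .core import (
        read_groups_tsv,
        read_matrix_tsv,
        read_promoter_map_tsv,
        read_survival_tsv,
        read_target_map_tsv,
    )

    indir = Path(indir)
    promoter_map = read_promoter_map_tsv(indir / "promoter_map.tsv")
    raw = _json.loads((indir / "truth.json").read_text())
    cancers: dict[str, CancerData] = {}
    for d in sorted(p for p in indir.iterdir() if p.is_dir()):
        name = d.name
        groups = read_groups_tsv(d / "groups.tsv")
        meth = read_matrix_tsv(d / "methylation.tsv", groups, scale="beta")
        lnc = read_matrix_tsv(d / "lnc_expression.tsv", groups, scale="rpkm")
        mrna = read_matrix_tsv(d / "mrna_expression.tsv", groups, scale="rpkm")
        surv = read_survival_tsv(d / "survival.tsv")
        mut = pd.read_csv(d / "mutations.tsv", sep="\t", index_col=0)["mutation_count"]
        cancers[name] = CancerData(name, meth, lnc, mrna, surv, mut)
    some = next(iter(cancers.values()))
    lnc_ids = list(some.lnc_expression.values.index)
    mrna_ids = list(some.mrna_expression.values.index)
    targets = read_target_map_tsv(indir / "target_map.tsv", lnc_ids, mrna_ids)
    truth = SyntheticTruth(
        dm_labels=raw["dm_labels"],
        de_labels=raw["de_labels"],
        nclnc_labels=raw["nclnc_labels"],
        cerna_pairs={tuple(p) for p in raw["cerna_pairs"]},
        prognostic={k: set(v) for k, v in raw["prognostic"].items()},
        subtype={k: pd.Series(v) for k, v in raw["subtype"].items()},
    )
    return SyntheticCohort(cancers, promoter_map, targets, truth, config or SimulationConfig())
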