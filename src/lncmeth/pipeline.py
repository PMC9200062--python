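"""End-to-end orchestration: preprocess -> DM/DE -> set integration -> ceRNA
-> survival -> immune, per cancer and pan-cancer, with a summary report.

Every stage is a pure function of its inputs, the parameter block, and the
seed, so a rerun with the same config reproduces the report byte for byte.
Intermediates are written as TSV when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
import numpy as np
import pandas as pd

from . import cerna, diff, immune, integrate, preprocess, survival as surv_mod
from .core import TUMOR, FeatureMatrix, ValidationError, logger, write_json
from .simulate import SyntheticCohort


@dataclasses.dataclass
class PipelineParams:
    """All tunable thresholds of the full run."""

    dm_test: diff.TestConfig = dataclasses.field(default_factory=diff.TestConfig)
    de_test: diff.TestConfig = dataclasses.field(default_factory=diff.TestConfig)
    cerna_thresholds: cerna.CeRNAThresholds = dataclasses.field(
        default_factory=cerna.CeRNAThresholds
    )
    probe_presence_fraction: float = 0.5
    expr_presence_fraction: float = 0.7
    #: common set keeps lncRNAs DM in strictly more than this many cancers
    min_common_cancers: int = 2
    #: pan-cancer subnetwork keeps mRNAs shared by strictly more than this many cancers
    min_subnetwork_cancers: int = 1
    specificity_strict: bool = True
    survival_alpha: float = 0.05
    survival_n_perm: int = 500
    min_group_frac: float = 0.1
    k_range: tuple[int, int] = (2, 6)
    n_resamples: int = 100
    subsample_frac: float = 0.8
    #: lncRNAs whose expression defines immune subtypes; None = the two most
    #: widely shared common lncRNAs
    key_lncs: tuple[str, ...] | None = None
    seed: int = 0


@dataclasses.dataclass
class RunReport:
    per_cancer: dict[str, dict[str, int]]
    common_lncs: list[str]
    subtype_pvalues: dict[str, dict[str, float]]
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _params_hash(params: PipelineParams) -> str:
    blob = json.dumps(dataclasses.asdict(params), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(
    cohort: SyntheticCohort,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Run the full per-cancer and pan-cancer analysis on a cohort."""
    params = params or PipelineParams()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    dm_results: dict[str, pd.DataFrame] = {}
    de_results: dict[str, pd.DataFrame] = {}
    lnc_expr_norm: dict[str, FeatureMatrix] = {}
    mrna_expr_norm: dict[str, FeatureMatrix] = {}
    for name, data in cohort.cancers.items():
        try:
            promoter = preprocess.promoter_beta(
                preprocess.impute_probe_missing(
                    preprocess.filter_probes(
                        data.methylation, params.probe_presence_fraction
                    )
                ),
                cohort.promoter_map,
            )
            dm_results[name] = diff.call_dmlncs(promoter, params.dm_test)
        except ValidationError as err:
            raise ValidationError(f"methylation stage failed for {name}: {err}") from err
        try:
            lnc_expr_norm[name] = preprocess.normalize_expression(
                data.lnc_expression, params.expr_presence_fraction
            )
            de_results[name] = diff.call_de_lncs(lnc_expr_norm[name], params.de_test)
            mrna_expr_norm[name] = preprocess.normalize_expression(
                data.mrna_expression, params.expr_presence_fraction
            )
        except ValidationError as err:
            raise ValidationError(f"expression stage failed for {name}: {err}") from err

    dm_catalog = diff.catalog_from_calls(dm_results)
    de_catalog = diff.catalog_from_calls(de_results)
    specific = integrate.cancer_specific(dm_catalog, strict=params.specificity_strict)
    common = integrate.cancer_common(dm_catalog, params.min_common_cancers)
    nclncs = integrate.negative_correlated(dm_catalog, de_catalog)
    csnc = integrate.csnclncs(specific, nclncs)

    networks: dict[str, pd.DataFrame] = {}
    for name in cohort.cancers:
        networks[name] = cerna.build_cerna_network(
            cohort.targets, lnc_expr_norm[name], mrna_expr_norm[name],
            params.cerna_thresholds,
        )

    # survival screen: cancer-specific NClncs plus NClncs from the common set
    common_ids = [c for c in common.index]
    surv_results: dict[str, dict[str, surv_mod.ScreenResult]] = {}
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(cohort.cancers))
    for child, (name, data) in zip(children, cohort.cancers.items()):
        candidates = sorted(
            set(csnc.get(name, set()))
            | (set(common_ids) & set(nclncs.get(name, {})))
        )
        expr = lnc_expr_norm[name].subset_samples(data.survival.index)
        if not candidates:
            surv_results[name] = {}
            continue
        try:
            surv_results[name] = surv_mod.survival_screen(
                candidates, expr, data.survival,
                alpha=params.survival_alpha,
                min_group_frac=params.min_group_frac,
                n_perm=params.survival_n_perm,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        except ValidationError as err:
            raise ValidationError(f"survival stage failed for {name}: {err}") from err

    survival_hits = {
        name: sorted(c for c, r in res.items() if r.significant)
        for name, res in surv_results.items()
    }
    all_hits = sorted({c for hits in survival_hits.values() for c in hits})
    subnet_edges, subnet_summary = cerna.pan_cancer_subnetwork(
        networks, all_hits, params.min_subnetwork_cancers
    ) if len(networks) >= 2 else (pd.DataFrame(columns=cerna.EDGE_COLUMNS + ["cancer"]), pd.DataFrame())

    # immune stage
    key_lncs = params.key_lncs
    if key_lncs is None:
        key_lncs = tuple(common.index[:2])
    subtype_pvalues: dict[str, dict[str, float]] = {}
    assignments: dict[str, immune.ClusterAssignment] = {}
    imm_children = np.random.SeedSequence(params.seed + 1).spawn(len(cohort.cancers))
    for child, (name, data) in zip(imm_children, cohort.cancers.items()):
        tumor_samples = [
            s for s in lnc_expr_norm[name].samples_in(TUMOR)
        ]
        key_present = [k for k in key_lncs if k in lnc_expr_norm[name].values.index]
        if len(key_present) < 2:
            logger.warning("immune stage: %s has <2 key lncRNAs; skipped", name)
            continue
        key_expr = lnc_expr_norm[name].subset_features(key_present).subset_samples(tumor_samples)
        try:
            assign = immune.consensus_cluster(
                key_expr,
                k_range=range(params.k_range[0], params.k_range[1] + 1),
                n_resamples=params.n_resamples,
                subsample_frac=params.subsample_frac,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        except ValidationError as err:
            logger.warning("immune stage: clustering skipped for %s: %s", name, err)
            continue
        assignments[name] = assign
        scores = immune.immune_score_table(
            mrna_expr_norm[name].subset_samples(tumor_samples)
        )
        pvals: dict[str, float] = {}
        for col in ("mhc", "cyt", "ctl"):
            cmp_df = immune.compare_groups(scores[col], assign.labels)
            pvals[col] = float(cmp_df["p"].min())
        tmb = data.mutation_counts.reindex(assign.labels.index)
        cmp_df = immune.compare_groups(tmb, assign.labels)
        pvals["tmb"] = float(cmp_df["p"].min())
        subtype_pvalues[name] = pvals

    per_cancer: dict[str, dict[str, int]] = {}
    for name in cohort.cancers:
        dm = dm_results[name]["direction"]
        de = de_results[name]["direction"]
        per_cancer[name] = {
            "dm_up": int((dm == "up").sum()),
            "dm_down": int((dm == "down").sum()),
            "de_up": int((de == "up").sum()),
            "de_down": int((de == "down").sum()),
            "nclncs": len(nclncs.get(name, {})),
            "specific_up": len(specific[name]["specific_up"]),
            "specific_down": len(specific[name]["specific_down"]),
            "csnclncs": len(csnc.get(name, set())),
            "cerna_pairs": int(len(networks[name])),
            "survival_associated": len(survival_hits.get(name, [])),
        }

    report = RunReport(
        per_cancer=per_cancer,
        common_lncs=list(common.index),
        subtype_pvalues=subtype_pvalues,
        config_hash=_params_hash(params),
        seed=params.seed,
    )

    if out is not None:
        _write_outputs(
            out, dm_results, de_results, specific, common, nclncs, csnc,
            networks, surv_results, subnet_edges, subnet_summary, assignments,
            report,
        )
    return report


def _write_outputs(
    out: Path, dm_results, de_results, specific, common, nclncs, csnc,
    networks, surv_results, subnet_edges, subnet_summary, assignments, report,
) -> None:
    for name, res in dm_results.items():
        d = out / name
        d.mkdir(exist_ok=True)
        res.to_csv(d / "dm_calls.tsv", sep="\t", index_label="feature_id")
        de_results[name].to_csv(d / "de_calls.tsv", sep="\t", index_label="feature_id")
        networks[name].to_csv(d / "cerna_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "lncRNA": c,
                    "cutpoint": r.cutpoint.cutpoint,
                    "statistic": r.cutpoint.statistic,
                    "p": r.cutpoint.p,
                    "n_high": r.cutpoint.n_high,
                    "n_low": r.cutpoint.n_low,
                    "significant": r.significant,
                    "risk_direction": r.risk_direction,
                }
                for c, r in surv_results.get(name, {}).items()
            ]
        ).to_csv(d / "survival_screen.tsv", sep="\t", index=False)
        if name in assignments:
            assignments[name].labels.to_csv(
                d / "subtypes.tsv", sep="\t", index_label="sample_id"
            )
    common.to_csv(out / "common_lncs.tsv", sep="\t", index_label="lncRNA")
    write_json(
        {c: {k: sorted(v) for k, v in sets.items()} for c, sets in specific.items()},
        out / "specific_sets.json",
    )
    write_json({c: d for c, d in nclncs.items()}, out / "nclncs.json")
    write_json({c: sorted(s) for c, s in csnc.items()}, out / "csnclncs.json")
    subnet_edges.to_csv(out / "pan_cancer_subnetwork_edges.tsv", sep="\t", index=False)
    if not subnet_summary.empty:
        subnet_summary.to_csv(out / "pan_cancer_subnetwork_summary.tsv", sep="\t", index=False)
    write_json(report.to_dict(), out / "report.json")
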