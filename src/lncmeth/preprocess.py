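"""Probe filtering, imputation, promoter averaging, and expression normalisation.

Methylation enters as probe-level β in [0,1] with zero acting as the missing
sentinel; the fixed order is filter -> impute -> promoter average.  Expression
enters as RPKM with explicit (NaN) missing values and leaves as log2(RPKM+1)
with a presence filter and mean imputation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FeatureMatrix, ValidationError, logger, validate_promoter_map


def filter_probes(m: FeatureMatrix, presence_fraction: float = 0.5) -> FeatureMatrix:
    """Keep probes with β > 0 in strictly more than ``presence_fraction`` of
    samples (default: more than half).  Samples are untouched."""
    if m.n_features == 0 or m.n_samples == 0:
        raise ValidationError("empty probe matrix")
    if m.scale != "beta":
        raise ValidationError(f"expected beta-scale matrix, got {m.scale}")
    frac_positive = (m.values > 0).mean(axis=1)
    keep = frac_positive > presence_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_probes: dropped %d of %d probes", dropped, m.n_features)
    return m.with_values(m.values.loc[keep])


def impute_probe_missing(m: FeatureMatrix) -> FeatureMatrix:
    """Replace each zero entry by the mean of that probe's non-zero entries.

    Probes must have at least one non-zero value (run :func:`filter_probes`
    first); non-zero entries are untouched, so each probe's non-zero mean is
    preserved exactly.
    """
    if m.scale != "beta":
        raise ValidationError(f"expected beta-scale matrix, got {m.scale}")
    vals = m.values.to_numpy(dtype=float)
    nonzero = vals > 0
    n_nonzero = nonzero.sum(axis=1)
    if (n_nonzero == 0).any():
        bad = m.values.index[n_nonzero == 0][:5].tolist()
        raise ValidationError(f"probes with all-zero values (filter first): {bad}")
    row_mean = (vals * nonzero).sum(axis=1) / n_nonzero
    filled = np.where(nonzero, vals, row_mean[:, None])
    return m.with_values(pd.DataFrame(filled, index=m.values.index, columns=m.values.columns))


def promoter_beta(m: FeatureMatrix, promoter_map: Mapping[str, Sequence[str]]) -> FeatureMatrix:
    """Collapse probe β to one row per lncRNA by unweighted promoter-mean.

    lncRNAs whose probes were all filtered out are omitted (logged), not an
    error.  Imputation must already have been applied.
    """
    if m.scale != "beta":
        raise ValidationError(f"expected beta-scale matrix, got {m.scale}")
    validate_promoter_map(promoter_map)
    available = set(m.values.index)
    rows, ids, skipped = [], [], 0
    for lnc, probes in promoter_map.items():
        present = [p for p in probes if p in available]
        if not present:
            skipped += 1
            continue
        rows.append(m.values.loc[present].mean(axis=0))
        ids.append(lnc)
    if skipped:
        logger.info("promoter_beta: %d lncRNAs had no retained probes", skipped)
    values = pd.DataFrame(rows, index=ids) if rows else pd.DataFrame(
        np.empty((0, m.n_samples)), columns=m.values.columns
    )
    return m.with_values(values)


def normalize_expression(
    raw: FeatureMatrix, presence_fraction: float = 0.7
) -> FeatureMatrix:
    """log2(RPKM+1) transform, presence filter, and mean imputation.

    Features observed (non-missing) in strictly more than
    ``presence_fraction`` of samples are retained; their remaining missing
    entries are filled with the feature's mean over observed samples.
    Monotone in the raw values, so ranks are preserved.
    """
    if raw.scale != "rpkm":
        raise ValidationError(f"expected rpkm-scale matrix, got {raw.scale}")
    vals = raw.values.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValidationError("negative RPKM values")
    observed = ~np.isnan(vals)
    keep = observed.mean(axis=1) > presence_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("normalize_expression: dropped %d of %d features", dropped, len(keep))
    vals, observed = vals[keep], observed[keep]
    log = np.log2(np.where(observed, vals, 0.0) + 1.0)
    with np.errstate(invalid="ignore"):
        row_mean = np.where(
            observed.any(axis=1),
            (log * observed).sum(axis=1) / np.maximum(observed.sum(axis=1), 1),
            0.0,
        )
    log = np.where(observed, log, row_mean[:, None])
    out = pd.DataFrame(log, index=raw.values.index[keep], columns=raw.values.columns)
    return raw.with_values(out, scale="log2rpkm")


def harmonize_ids(features: FeatureMatrix, id_map: Mapping[str, str]) -> FeatureMatrix:
    """Rename features to standard gene symbols; unmapped features are dropped
    (logged) and duplicate post-map symbols collapsed by mean."""
    if not id_map:
        raise ValidationError("empty id map")
    mapped = features.values.index.to_series().map(dict(id_map))
    unmapped = int(mapped.isna().sum())
    if unmapped:
        logger.info("harmonize_ids: dropped %d unmapped features", unmapped)
    kept = features.values.loc[~mapped.isna()]
    new_index = mapped.dropna()
    collapsed = kept.groupby(new_index.to_numpy()).mean()
    collapsed.index.name = features.values.index.name
    return features.with_values(collapsed)


def write_bed(
    coords: pd.DataFrame, path
) -> None:
    """Write lncRNA coordinates as BED3+name (0-based half-open) for external
    enrichment tools.  ``coords`` columns: chrom, start, end, name."""
    coords[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )
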