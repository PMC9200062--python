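"""Core data containers and plain-text I/O.

Every matrix in the pipeline is a features x samples pandas DataFrame wrapped
with per-sample group labels (tumor/normal) and a scale tag, so each stage can
check it is operating on the representation it expects (raw β in [0,1],
RPKM, or log2(RPKM+1)).  Everything serialises to TSV/JSON so a full run can
be inspected and rerun from plain text.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lncmeth")

TUMOR = "tumor"
NORMAL = "normal"

#: Recognised scale tags for FeatureMatrix values.
SCALES = ("beta", "rpkm", "log2rpkm", "mvalue")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclasses.dataclass
class FeatureMatrix:
    """A features x samples numeric matrix with group labels and a scale tag.

    Used both for probe-level β matrices (``scale='beta'``, zeros acting as
    the missing-value sentinel) and for promoter-level β or expression
    matrices.

    Parameters
    ----------
    values:
        DataFrame indexed by feature id with one column per sample id.
    groups:
        Per-sample labels, each ``'tumor'`` or ``'normal'``.  May be omitted
        for matrices that never enter a two-group test.
    scale:
        One of ``'beta'``, ``'rpkm'``, ``'log2rpkm'``, ``'mvalue'``.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.values.columns)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()].tolist()
                raise ValidationError(f"samples without a group label: {missing[:5]}")
            bad = set(self.groups.unique()) - {TUMOR, NORMAL}
            if bad:
                raise ValidationError(f"group labels must be tumor/normal, got {sorted(bad)}")
        if self.scale == "beta":
            arr = self.values.to_numpy(dtype=float)
            if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
                raise ValidationError("beta-scale values must lie in [0, 1]")
        if self.scale == "rpkm":
            arr = self.values.to_numpy(dtype=float)
            if arr.size and np.nanmin(arr) < 0.0:
                raise ValidationError("RPKM values must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValidationError("matrix carries no group labels")
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def subset_features(self, features: Iterable[str]) -> "FeatureMatrix":
        keep = [f for f in features if f in self.values.index]
        return FeatureMatrix(self.values.loc[keep], self.groups, self.scale)

    def subset_samples(self, samples: Iterable[str]) -> "FeatureMatrix":
        keep = [s for s in samples if s in self.values.columns]
        groups = self.groups.loc[keep] if self.groups is not None else None
        return FeatureMatrix(self.values[keep], groups, self.scale)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "FeatureMatrix":
        groups = self.groups.loc[values.columns] if self.groups is not None else None
        return FeatureMatrix(values, groups, scale or self.scale)


@dataclasses.dataclass
class TargetMap:
    """Bipartite miRNA-targeting relations for lncRNAs and mRNAs.

    ``lnc_targets`` and ``mrna_targets`` map each RNA id to the set of miRNAs
    it is targeted by; ``universe`` is the union of all miRNAs seen on either
    side and serves as the population for the shared-target hypergeometric
    test.
    """

    lnc_targets: dict[str, frozenset[str]]
    mrna_targets: dict[str, frozenset[str]]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.lnc_targets.values():
            out |= s
        for s in self.mrna_targets.values():
            out |= s
        return frozenset(out)


# -- TSV / JSON round-trips ----------------------------------------------------


def write_matrix_tsv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write values as TSV (feature rows, sample-id header)."""
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(
    path: str | Path,
    groups: pd.Series | None = None,
    scale: str = "beta",
) -> FeatureMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(values, groups, scale)


def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def read_groups_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["group"]


def write_survival_tsv(surv: pd.DataFrame, path: str | Path) -> None:
    out = surv[["time", "event"]].copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_survival(df)


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"} <= set(surv.columns):
        raise ValidationError("survival table needs 'time' and 'event' columns")
    out = surv.copy()
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(bool)
    if (out["time"] <= 0).any():
        raise ValidationError("survival times must be strictly positive")
    return out


def write_promoter_map_tsv(pmap: Mapping[str, Sequence[str]], path: str | Path) -> None:
    rows = [(probe, lnc) for lnc, probes in pmap.items() for probe in probes]
    pd.DataFrame(rows, columns=["probe_id", "lncRNA_id"]).to_csv(path, sep="\t", index=False)


def read_promoter_map_tsv(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    pmap: dict[str, list[str]] = {}
    for probe, lnc in zip(df["probe_id"], df["lncRNA_id"]):
        pmap.setdefault(lnc, []).append(probe)
    validate_promoter_map(pmap)
    return pmap


def validate_promoter_map(pmap: Mapping[str, Sequence[str]]) -> None:
    seen: dict[str, str] = {}
    for lnc, probes in pmap.items():
        for probe in probes:
            if probe in seen and seen[probe] != lnc:
                raise ValidationError(
                    f"probe {probe} mapped to both {seen[probe]} and {lnc}"
                )
            seen[probe] = lnc


def write_target_map_tsv(targets: TargetMap, path: str | Path) -> None:
    rows = [(rna, mir) for rna, mirs in targets.lnc_targets.items() for mir in sorted(mirs)]
    rows += [(rna, mir) for rna, mirs in targets.mrna_targets.items() for mir in sorted(mirs)]
    pd.DataFrame(rows, columns=["rna_id", "mirna_id"]).to_csv(path, sep="\t", index=False)


def read_target_map_tsv(
    path: str | Path, lnc_ids: Iterable[str], mrna_ids: Iterable[str]
) -> TargetMap:
    """Read a two-column (rna_id, mirna_id) TSV, splitting rows by id lists."""
    lnc_ids, mrna_ids = set(lnc_ids), set(mrna_ids)
    df = pd.read_csv(path, sep="\t")
    lnc: dict[str, set[str]] = {i: set() for i in lnc_ids}
    mrna: dict[str, set[str]] = {i: set() for i in mrna_ids}
    for rna, mir in zip(df["rna_id"], df["mirna_id"]):
        if rna in lnc_ids:
            lnc[rna].add(mir)
        elif rna in mrna_ids:
            mrna[rna].add(mir)
    return TargetMap(
        {k: frozenset(v) for k, v in lnc.items()},
        {k: frozenset(v) for k, v in mrna.items()},
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"cannot serialise {type(o)}")
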