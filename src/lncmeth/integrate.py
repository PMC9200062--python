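"""Pan-cancer set integration of differential calls.

A catalog is ``cancer -> {'up': set, 'down': set}`` of feature ids.  From the
methylation and expression catalogs this module derives cancer-specific
lncRNAs, cancer-common lncRNAs (differentially methylated in strictly more
than a given number of cancers), negatively correlated lncRNAs (methylation
and expression moving in opposite directions), and their intersection, the
cancer-specific negatively correlated lncRNAs.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .core import ValidationError, logger

Catalog = Mapping[str, Mapping[str, set]]

UMLE = "UMLE"  # up-methylated, low-expressed
DMOE = "DMOE"  # down-methylated, over-expressed


def _check_catalog(catalog: Catalog) -> None:
    for cancer, sets in catalog.items():
        overlap = set(sets.get("up", ())) & set(sets.get("down", ()))
        if overlap:
            raise ValidationError(
                f"{cancer}: features called both up and down: {sorted(overlap)[:5]}"
            )


def cancer_specific(
    catalog: Catalog, strict: bool = True
) -> dict[str, dict[str, set[str]]]:
    """Per-cancer specific up/down sets.

    With ``strict`` (default) a feature is specific-up for cancer c iff it is
    up in c and not differentially methylated in any other cancer in either
    direction; with ``strict=False`` only same-direction calls elsewhere void
    specificity.
    """
    _check_catalog(catalog)
    if len(catalog) < 2:
        raise ValidationError("specificity needs a catalog covering >= 2 cancers")
    out: dict[str, dict[str, set[str]]] = {}
    for cancer, sets in catalog.items():
        others_up: set = set()
        others_down: set = set()
        for other, osets in catalog.items():
            if other == cancer:
                continue
            others_up |= set(osets.get("up", ()))
            others_down |= set(osets.get("down", ()))
        block_up = others_up | others_down if strict else others_up
        block_down = others_up | others_down if strict else others_down
        out[cancer] = {
            "specific_up": set(sets.get("up", ())) - block_up,
            "specific_down": set(sets.get("down", ())) - block_down,
        }
    return out


def cancer_common(catalog: Catalog, min_cancers: int) -> pd.DataFrame:
    """Features differentially methylated (either direction) in strictly more
    than ``min_cancers`` cancers, with their per-cancer direction profile.

    Returns a feature x cancer DataFrame with values 'up'/'down'/'none' and an
    ``n_cancers`` column.  Raising ``min_cancers`` never grows the result.
    """
    _check_catalog(catalog)
    if min_cancers < 1:
        raise ValidationError("min_cancers must be >= 1")
    cancers = list(catalog)
    features = sorted({f for sets in catalog.values() for d in ("up", "down") for f in sets.get(d, ())})
    profile = pd.DataFrame("none", index=features, columns=cancers)
    for cancer, sets in catalog.items():
        profile.loc[profile.index.isin(sets.get("up", ())), cancer] = "up"
        profile.loc[profile.index.isin(sets.get("down", ())), cancer] = "down"
    n = (profile != "none").sum(axis=1)
    out = profile[n > min_cancers].copy()
    out["n_cancers"] = n[n > min_cancers]
    return out.sort_values("n_cancers", ascending=False)


def negative_correlated(dm: Catalog, de: Catalog) -> dict[str, dict[str, str]]:
    """Negatively correlated lncRNAs per cancer: UMLE = methylation-up and
    expression-down; DMOE = methylation-down and expression-up."""
    _check_catalog(dm)
    _check_catalog(de)
    out: dict[str, dict[str, str]] = {}
    for cancer in dm:
        if cancer not in de:
            logger.warning("negative_correlated: %s has no expression catalog; skipped", cancer)
            continue
        umle = set(dm[cancer].get("up", ())) & set(de[cancer].get("down", ()))
        dmoe = set(dm[cancer].get("down", ())) & set(de[cancer].get("up", ()))
        out[cancer] = {**{f: UMLE for f in umle}, **{f: DMOE for f in dmoe}}
    for cancer in de:
        if cancer not in dm:
            logger.warning("negative_correlated: %s has no methylation catalog; skipped", cancer)
    return out


def csnclncs(
    specific_sets: Mapping[str, Mapping[str, set]],
    nc: Mapping[str, Mapping[str, str]],
) -> dict[str, set[str]]:
    """Cancer-specific negatively correlated lncRNAs: per cancer, the
    intersection of its specific DM sets with its NClncs."""
    out: dict[str, set[str]] = {}
    for cancer, sets in specific_sets.items():
        specific = set(sets.get("specific_up", ())) | set(sets.get("specific_down", ()))
        out[cancer] = specific & set(nc.get(cancer, {}))
    return out
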