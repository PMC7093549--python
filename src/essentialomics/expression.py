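"""Approach 3: protein-expression extremity and tumor/normal IHC discordance.

Two selection rules, combined by union:

* Z-score extremity: one aggregate Z per protein; high if Z >= threshold
  (default 2), low if Z <= -threshold, both inclusive. Per-sample replicate
  input is aggregated to the cohort mean by default (median and max-|z|
  are available; the appropriate aggregation is a modelling choice, mean
  being the least surprising default).
* IHC discordance: expressed (high/medium) in one tissue and not expressed
  (low/not_detected) in the other; tumor_low and tumor_high are the two
  directions and are disjoint by construction.

Provenance (which rule fired) is retained per protein.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .types import IHC_LEVELS, GeneSet

logger = logging.getLogger(__name__)

_EXPRESSED = {"high", "medium"}
_NOT_EXPRESSED = {"low", "not_detected"}


def aggregate_z(
    records: pd.DataFrame,
    method: Literal["mean", "median", "max_abs"] = "mean",
) -> pd.Series:
    """One aggregate z per protein from replicate (protein, z_score) rows."""
    if not np.isfinite(records["z_score"]).all():
        bad = records.loc[~np.isfinite(records["z_score"]), "protein"]
        raise ValidationError(f"non-finite z-scores for {sorted(set(bad))[:10]}")
    grouped = records.groupby("protein")["z_score"]
    if method == "mean":
        return grouped.mean()
    if method == "median":
        return grouped.median()
    if method == "max_abs":
        return grouped.apply(lambda s: s.loc[s.abs().idxmax()])
    raise ValueError(f"unknown aggregation {method!r}")


def zscore_select(z: pd.Series, threshold: float = 2.0) -> tuple[GeneSet, GeneSet]:
    """(high, low) protein sets at |Z| >= threshold (inclusive boundaries)."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if not np.isfinite(z).all():
        raise ValidationError(f"non-finite z-scores for {sorted(z.index[~np.isfinite(z)])[:10]}")
    high = frozenset(z.index[z >= threshold])
    low = frozenset(z.index[z <= -threshold])
    return GeneSet("z_high", high), GeneSet("z_low", low)


def ihc_discordance(records: pd.DataFrame) -> tuple[GeneSet, GeneSet]:
    """(tumor_low, tumor_high) from (protein, tissue, level) rows.

    tumor_low: expressed in normal tissue, not expressed in tumor;
    tumor_high: the converse. Proteins missing either tissue are skipped
    with a logged count; conflicting duplicate levels raise.
    """
    bad_level = set(records["level"]) - set(IHC_LEVELS)
    if bad_level:
        raise ValidationError(f"unknown IHC levels: {sorted(bad_level)}")
    dup = records.groupby(["protein", "tissue"])["level"].nunique()
    conflicts = dup.index[dup > 1].tolist()
    if conflicts:
        raise ValidationError(f"conflicting IHC levels for {conflicts[:10]}")
    levels = (
        records.drop_duplicates(["protein", "tissue"])
        .pivot(index="protein", columns="tissue", values="level")
    )
    for tissue in ("normal", "tumor"):
        if tissue not in levels.columns:
            levels[tissue] = pd.NA
    complete = levels.dropna(subset=["normal", "tumor"])
    skipped = len(levels) - len(complete)
    if skipped:
        logger.info("skipping %d proteins missing a tissue measurement", skipped)
    tumor_low = frozenset(
        complete.index[
            complete["normal"].isin(_EXPRESSED) & complete["tumor"].isin(_NOT_EXPRESSED)
        ]
    )
    tumor_high = frozenset(
        complete.index[
            complete["normal"].isin(_NOT_EXPRESSED) & complete["tumor"].isin(_EXPRESSED)
        ]
    )
    return GeneSet("ihc_tumor_low", tumor_low), GeneSet("ihc_tumor_high", tumor_high)


def approach3_set(
    z_high: Iterable[str],
    z_low: Iterable[str],
    ihc_tumor_low: Iterable[str],
    ihc_tumor_high: Iterable[str],
) -> tuple[GeneSet, pd.DataFrame]:
    """Union of the four expression rules with per-protein provenance."""
    rules = {
        "z_high": set(z_high),
        "z_low": set(z_low),
        "ihc_tumor_low": set(ihc_tumor_low),
        "ihc_tumor_high": set(ihc_tumor_high),
    }
    union = sorted(set().union(*rules.values()))
    provenance = pd.DataFrame(
        {
            "protein": union,
            **{name: [p in members for p in union] for name, members in rules.items()},
        }
    )
    provenance["rules"] = provenance[list(rules)].apply(
        lambda r: ",".join(name for name in rules if r[name]), axis=1
    )
    return GeneSet("protein_expression", frozenset(union)), provenance
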