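"""Approach 1: genomic alteration summaries and the above-average selection.

Summarizes per-sample alteration events (mRNA up/down, CNV amplification /
deep deletion, mutations, fusions) per gene, gene set, molecular subtype
and tumor stage, and selects the alteration-based essential set: genes
whose total event count strictly exceeds the panel mean.

Counting conventions: every summarizer counts event rows exactly as given
(duplicating a row doubles its contribution); callers wanting
one-event-per-(sample, gene, category) semantics apply
:func:`dedupe_events` first, which drops exact duplicates with a logged
count. "Frequency" is always reported as events per sample; printed
per-set means from other sources are comparable only ordinally.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping, Sequence

import pandas as pd

from . import stats
from .exceptions import ValidationError
from .types import CATEGORIES, STAGES, SUBTYPES, FrequencySummary, GeneSet

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["sample_id", "gene", "category", "mutation_subtype", "driver_flag"]


def validate_events(events: pd.DataFrame, cohort: pd.DataFrame | None = None) -> None:
    """Check the event-table invariants.

    Categories from the closed vocabulary; mutation_subtype and driver_flag
    non-NA iff category == mutation; every sample known to the cohort when
    one is supplied.
    """
    bad_cat = set(events["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ValidationError(f"unknown alteration categories: {sorted(bad_cat)}")
    is_mut = events["category"] == "mutation"
    na_driver = events.index[is_mut & (events["driver_flag"] == "NA")]
    if len(na_driver):
        raise ValidationError(f"mutation rows with NA driver_flag at rows {list(na_driver[:10])}")
    na_sub = events.index[is_mut & (events["mutation_subtype"] == "NA")]
    if len(na_sub):
        raise ValidationError(f"mutation rows with NA mutation_subtype at rows {list(na_sub[:10])}")
    stray_flag = events.index[~is_mut & (events["driver_flag"] != "NA")]
    if len(stray_flag):
        raise ValidationError(f"non-mutation rows with driver_flag at rows {list(stray_flag[:10])}")
    if cohort is not None:
        unknown = set(events["sample_id"]) - set(cohort["sample_id"])
        if unknown:
            raise ValidationError(f"events reference unknown samples: {sorted(unknown)[:10]}")


def dedupe_events(events: pd.DataFrame) -> pd.DataFrame:
    """Count a sample once per (gene, category): drop exact duplicate calls."""
    out = events.drop_duplicates(subset=["sample_id", "gene", "category"])
    dropped = len(events) - len(out)
    if dropped:
        logger.info("dropped %d duplicate (sample, gene, category) rows", dropped)
    return out


def filter_driver_mutations(events: pd.DataFrame) -> pd.DataFrame:
    """Discard passenger mutations; keep driver mutations and all non-mutation rows."""
    is_mut = events["category"] == "mutation"
    na_rows = events.index[is_mut & (events["driver_flag"] == "NA")]
    if len(na_rows):
        raise ValidationError(
            f"mutation rows with unpopulated driver_flag at rows {list(na_rows[:10])}"
        )
    keep = ~is_mut | (events["driver_flag"] == "driver")
    return events.loc[keep].reset_index(drop=True)


def _restrict_to_panel(events: pd.DataFrame, panel: Sequence[str]) -> pd.DataFrame:
    if len(panel) == 0:
        raise ValidationError("panel must be non-empty")
    in_panel = events["gene"].isin(set(panel))
    ignored = int((~in_panel).sum())
    if ignored:
        logger.info("ignoring %d events for genes outside the panel", ignored)
    return events.loc[in_panel]


def alteration_totals_per_gene(events: pd.DataFrame, panel: Sequence[str]) -> pd.Series:
    """Event count per panel gene (zeros included; off-panel rows ignored)."""
    retained = _restrict_to_panel(events, panel)
    counts = retained["gene"].value_counts()
    return counts.reindex(list(panel), fill_value=0).rename("n_events").astype(int)


def _grouped_samples(
    cohort: pd.DataFrame, group_by: Literal["subtype", "stage"]
) -> dict[str, set[str]]:
    vocab = SUBTYPES if group_by == "subtype" else STAGES
    # samples with unknown group are excluded from grouped summaries;
    # every named vocabulary value is reported (zero-sample groups become
    # undefined downstream, never silent zeros)
    return {
        value: set(cohort.loc[cohort[group_by] == value, "sample_id"])
        for value in vocab
        if value != "unknown"
    }


def group_ratio(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    panel: Sequence[str],
    group_by: Literal["subtype", "stage"],
) -> FrequencySummary:
    """Events-per-sample ratio per molecular subtype or tumor stage.

    ratio(group) = panel events among the group's samples / group size.
    Groups with zero samples are reported as undefined (NaN), never as 0.
    """
    validate_events(events, cohort)
    retained = _restrict_to_panel(events, panel)
    groups = _grouped_samples(cohort, group_by)
    counts, denoms, ratios, undefined = {}, {}, {}, []
    for value, samples in groups.items():
        c = int(retained["sample_id"].isin(samples).sum())
        counts[value] = c
        denoms[value] = len(samples)
        if samples:
            ratios[value] = c / len(samples)
        else:
            ratios[value] = float("nan")
            undefined.append(value)
    return FrequencySummary(
        unit="group", counts=counts, denominators=denoms, ratios=ratios, undefined=undefined
    )


def category_percentages(
    events: pd.DataFrame,
    group_by: Literal["subtype", "stage"] | None = None,
    cohort: pd.DataFrame | None = None,
    split_mutations: bool = False,
) -> FrequencySummary:
    """Share of each alteration category, overall or per group.

    Shares sum to 100 per group. With ``split_mutations`` the mutation
    share is broken down by consequence subtype instead of one bucket.
    Groups with zero events are flagged undefined (no division by zero).
    """
    if len(events) == 0:
        raise ValidationError("at least one event is required")
    ev = events.copy()
    if split_mutations:
        is_mut = ev["category"] == "mutation"
        ev.loc[is_mut, "category"] = "mutation_" + ev.loc[is_mut, "mutation_subtype"]
    if group_by is None:
        grouped = {"all": ev}
    else:
        if cohort is None:
            raise ValidationError("grouped percentages require a cohort")
        validate_events(events, cohort)
        merged = ev.merge(cohort[["sample_id", group_by]], on="sample_id", how="left")
        grouped = {
            value: merged.loc[merged[group_by] == value]
            for value in _grouped_samples(cohort, group_by)
        }
    percentages: dict[str, dict[str, float]] = {}
    undefined = []
    counts: dict[str, float] = {}
    for key, sub in grouped.items():
        total = len(sub)
        counts[key] = total
        if total == 0:
            undefined.append(key)
            percentages[key] = {}
            continue
        shares = (sub["category"].value_counts() / total * 100.0).to_dict()
        percentages[key] = {c: shares.get(c, 0.0) for c in sorted(set(ev["category"]))}
    return FrequencySummary(
        unit="category", counts=counts, percentages=percentages, undefined=undefined
    )


def geneset_frequency_means(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    sets: Sequence[GeneSet],
) -> tuple[dict[str, float], dict[str, pd.Series]]:
    """Mean per-gene alteration frequency (events per sample) per gene set.

    Returns (set label -> mean frequency, set label -> per-gene frequency
    vector); the vectors feed the pairwise group comparisons.
    """
    n = len(cohort)
    if n == 0:
        raise ValidationError("cohort must be non-empty")
    means: dict[str, float] = {}
    vectors: dict[str, pd.Series] = {}
    for gs in sets:
        if len(gs) == 0:
            raise ValidationError(f"gene set {gs.label!r} is empty")
        totals = alteration_totals_per_gene(events, gs.sorted())
        freq = totals / n
        vectors[gs.label] = freq.rename("events_per_sample")
        means[gs.label] = float(freq.mean())
    return means, vectors


def oncoprint_select(events: pd.DataFrame, panel: Sequence[str]) -> tuple[GeneSet, float]:
    """Approach-1 essential set: genes strictly above the panel-mean event count.

    Ties with the mean are excluded (strict ``>``). Returns the selection
    and the threshold (the mean) actually used.
    """
    totals = alteration_totals_per_gene(events, panel)
    threshold = float(totals.mean())
    selected = frozenset(totals.index[totals > threshold])
    return GeneSet("genomic_alterations", selected), threshold


def compare_groups(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U with Bonferroni adjustment."""
    return stats.bonferroni_pairwise(values, alpha=alpha)
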