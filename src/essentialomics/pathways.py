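"""Pathway enrichment and pathway-level alteration burden.

Enrichment is the standard hypergeometric upper tail of the panel/pathway
overlap against an annotation universe, with Benjamini-Hochberg control
across tested pathways (default q < 0.01). An optional EASE-style offset
(subtract one from the overlap before taking the tail, default off) is
exposed for compatibility with web-tool conventions.

Burden per (pathway, group) is events in member genes among the group's
samples divided by the group's sample count. A gene belonging to k
pathways contributes to all k of them, so burdens over pathways
deliberately double-count events.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from . import stats
from .alterations import compare_groups, group_ratio
from .exceptions import ValidationError
from .types import GeneSet

logger = logging.getLogger(__name__)


def enrich(
    panel: GeneSet,
    pathway_map: Mapping[str, Sequence[str]],
    universe_size: int,
    q_threshold: float = 0.01,
    universe: set[str] | None = None,
    ease_offset: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the panel in each pathway.

    p = P[X >= overlap] with X ~ Hypergeometric(universe_size, |pathway|,
    |panel in universe|); q = Benjamini-Hochberg across all tested
    pathways; selected iff q < q_threshold. Panel genes outside the
    universe (when one is given) are excluded with a logged count.
    """
    members = {pid: set(genes) for pid, genes in pathway_map.items()}
    for pid, genes in members.items():
        if not genes:
            raise ValidationError(f"pathway {pid!r} has no members")
        if universe_size < len(genes):
            raise ValidationError(f"universe smaller than pathway {pid!r}")
    panel_genes = set(panel.members)
    if universe is not None:
        outside = panel_genes - universe
        if outside:
            logger.info("excluding %d panel genes absent from the universe", len(outside))
            panel_genes -= outside
    n = len(panel_genes)
    if universe_size < n:
        raise ValidationError("universe smaller than the panel")
    rows = []
    for pid in sorted(members):
        k = len(panel_genes & members[pid])
        offset = 1 if (ease_offset and k > 0) else 0
        p = float(hypergeom.sf(k - 1 - offset, universe_size, len(members[pid]), n))
        rows.append({"pathway_id": pid, "n_members": len(members[pid]), "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = stats.bh_adjust(out["p"])
    out["selected"] = out["q"] < q_threshold
    return out.sort_values(["q", "p", "pathway_id"], kind="stable").reset_index(drop=True)


def pathway_burden(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    pathway_map: Mapping[str, Sequence[str]],
    group_by: Literal["subtype", "stage"],
) -> pd.DataFrame:
    """Per-(pathway, group) events-per-sample burden (long format).

    Columns: pathway_id, group, n_events, n_samples, burden. Burden for a
    zero-sample group is NaN (undefined, flagged via n_samples == 0).
    """
    if not pathway_map:
        raise ValidationError("pathway map is empty")
    rows = []
    for pid in sorted(pathway_map):
        summary = group_ratio(events, cohort, list(pathway_map[pid]), group_by)
        for group in summary.ratios:
            rows.append(
                {
                    "pathway_id": pid,
                    "group": group,
                    "n_events": summary.counts[group],
                    "n_samples": summary.denominators[group],
                    "burden": summary.ratios[group],
                }
            )
    return pd.DataFrame(rows)


def rank_pathways(burden: pd.DataFrame, group: str) -> pd.DataFrame:
    """Pathways of one group ordered by descending burden, ties by pathway_id."""
    sub = burden.loc[burden["group"] == group]
    if sub.empty:
        raise ValidationError(f"unknown group {group!r}")
    ordered = sub.sort_values(
        ["burden", "pathway_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ordered["rank"] = range(1, len(ordered) + 1)
    return ordered


def compare_pathway_burdens(burden: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise group comparison of per-pathway burden vectors (Bonferroni)."""
    groups = {
        g: sub.sort_values("pathway_id")["burden"].to_numpy()
        for g, sub in burden.dropna(subset=["burden"]).groupby("group")
    }
    return compare_groups(groups, alpha=alpha)
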