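"""Approach 2: confidence-thresholded interactome, hubness and consensus selection.

The graph is built from a weighted edge list at an inclusive confidence
cutoff (default 0.9, the "highest confidence" convention) with zero node
addition: edges touching genes outside the allowed node set are dropped.
Degree is the raw, unnormalized edge count. The approach-2 essential set
contains nodes strictly above BOTH the network mean degree and the network
mean consensus score — the same above-average convention the alteration
approach uses; the exact rule behind published hub sets is not stated, so
the thresholds are reported alongside the selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import spearmanr

from .exceptions import ValidationError
from .types import GeneSet

logger = logging.getLogger(__name__)


def build_graph(
    edges: pd.DataFrame,
    cutoff: float = 0.9,
    allowed_nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Simple undirected graph from (gene_a, gene_b, confidence) rows.

    Edges with confidence >= cutoff are retained (inclusive). With
    ``allowed_nodes``, edges touching any other gene are dropped (zero node
    addition) and allowed genes left isolated are kept as nodes flagged
    ``isolated=True``. Self-loops and duplicate unordered pairs raise.
    """
    bad_conf = edges.loc[(edges["confidence"] < 0) | (edges["confidence"] > 1)]
    if len(bad_conf):
        raise ValidationError(f"confidences outside [0,1] at rows {list(bad_conf.index[:10])}")
    loops = edges.loc[edges["gene_a"] == edges["gene_b"]]
    if len(loops):
        raise ValidationError(
            f"self-loops on {sorted(set(loops['gene_a']))[:10]}"
        )
    pairs = edges.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    dup = pairs[pairs.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate edges: {sorted(set(dup))[:10]}")

    kept = edges.loc[edges["confidence"] >= cutoff]
    if allowed_nodes is not None:
        allowed = set(allowed_nodes)
        inside = kept["gene_a"].isin(allowed) & kept["gene_b"].isin(allowed)
        dropped = int((~inside).sum())
        if dropped:
            logger.info("dropped %d edges touching nodes outside the allowed set", dropped)
        kept = kept.loc[inside]

    graph = nx.Graph(confidence_cutoff=cutoff)
    for row in kept.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, confidence=float(row.confidence))
    if allowed_nodes is not None:
        for node in allowed:
            if node not in graph:
                graph.add_node(node, isolated=True)
    return graph


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Raw edge count per node (sum over nodes equals twice the edge count)."""
    return dict(graph.degree())


def subnetwork_stats(
    graph: nx.Graph,
    consensus: Mapping[str, float],
    subset: Iterable[str],
) -> tuple[float, float]:
    """(mean degree, mean consensus) over a node subset.

    Subset members without a consensus score are excluded from the
    consensus mean with a logged count; the consensus mean is NaN if none
    remain.
    """
    members = sorted(set(subset))
    if not members:
        raise ValidationError("subset is empty")
    stray = [g for g in members if g not in graph]
    if stray:
        raise ValidationError(f"subset members not in graph: {stray[:10]}")
    degs = dict(graph.degree(members))
    mean_degree = sum(degs.values()) / len(members)
    scored = [g for g in members if g in consensus]
    missing = len(members) - len(scored)
    if missing:
        logger.info("excluding %d subset members without consensus scores", missing)
    mean_consensus = (
        sum(consensus[g] for g in scored) / len(scored) if scored else float("nan")
    )
    return mean_degree, mean_consensus


def select_hub_consensus(
    graph: nx.Graph,
    consensus: Mapping[str, float],
) -> tuple[GeneSet, dict[str, float]]:
    """Approach-2 essential set: strictly above-mean degree AND consensus.

    The degree mean is over all graph nodes; the consensus mean is over
    graph nodes that have a score (a node without a score can never be
    selected). Returns the selection and the two thresholds used.
    """
    degrees = degree_centrality(graph)
    if not degrees:
        raise ValidationError("graph has no nodes")
    scored = {g: consensus[g] for g in graph.nodes if g in consensus}
    if not scored:
        raise ValidationError("no graph node has a consensus score")
    mean_degree = sum(degrees.values()) / len(degrees)
    mean_consensus = sum(scored.values()) / len(scored)
    selected = frozenset(
        g for g, s in scored.items() if degrees[g] > mean_degree and s > mean_consensus
    )
    thresholds = {"mean_degree": mean_degree, "mean_consensus": mean_consensus}
    return GeneSet("ppi_network", selected), thresholds


@dataclass
class ReferenceValidation:
    n_shared_nodes: int
    n_shared_edges: int
    spearman_rho: float
    p_value: float


def validate_against_reference(graph: nx.Graph, reference: nx.Graph) -> ReferenceValidation:
    """Overlap with an experimentally derived reference sub-network.

    Reports shared node and edge counts and the Spearman rank correlation
    of the two degree vectors on the shared nodes; the correlation is NaN
    when fewer than three nodes are shared.
    """
    shared = sorted(set(graph.nodes) & set(reference.nodes))
    shared_edges = sum(
        1 for a, b in reference.edges if graph.has_edge(a, b)
    )
    if len(shared) < 3:
        return ReferenceValidation(len(shared), shared_edges, float("nan"), float("nan"))
    deg_g = [graph.degree(n) for n in shared]
    deg_r = [reference.degree(n) for n in shared]
    rho, p = spearmanr(deg_g, deg_r)
    return ReferenceValidation(len(shared), shared_edges, float(rho), float(p))
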