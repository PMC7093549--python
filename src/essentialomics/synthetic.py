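"""Synthetic study generator.

Emulates the statistical structure of the pipeline's real inputs — a
subtyped and staged tumor cohort, per-sample gene alteration events, a
hub-structured confidence-weighted interaction network with per-gene
consensus priors, replicate protein Z-scores with tumor/normal IHC levels,
and loss-of-function dependency screens with xenograft expression — with a
configurable set of planted essential genes carrying elevated alteration
rates, network hubness, |Z| shifts and depleted dependency scores.

Every generator is a pure function of its :class:`~essentialomics.config.
SimulationConfig`; randomness comes from per-generator seed streams (see
``config.STREAMS``), so regenerating any one table never perturbs the
others and identical seeds give byte-identical TSV output.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import STREAMS, SimulationConfig
from .exceptions import ConfigurationError
from .types import CATEGORIES, IHC_LEVELS, MUTATION_SUBTYPES

logger = logging.getLogger(__name__)

# mutation consequence mix and driver assignment are generation-time
# annotations: the pipeline consumes driver flags, it never infers them
_MUTATION_SUBTYPE_P = (0.60, 0.20, 0.10, 0.10)
_IHC_LEVEL_P = (0.30, 0.35, 0.20, 0.15)
_EXPRESSED = ("high", "medium")
_NOT_EXPRESSED = ("low", "not_detected")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(STREAMS[stream],)))


# --------------------------------------------------------------------------
# cohort

def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Sample a cohort table (sample_id, subtype, stage).

    Each sample gets exactly one subtype and one stage, drawn independently
    from the configured proportions, so empirical compositions converge to
    the configured fractions as the cohort grows.
    """
    rng = _rng(config, "cohort")
    n = config.n_samples
    subtypes = sorted(config.subtype_proportions)
    stages = sorted(config.stage_proportions)
    sub_p = np.array([config.subtype_proportions[s] for s in subtypes])
    stage_p = np.array([config.stage_proportions[s] for s in stages])
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "subtype": rng.choice(subtypes, size=n, p=sub_p) if n else [],
            "stage": rng.choice(stages, size=n, p=stage_p) if n else [],
        }
    )


# --------------------------------------------------------------------------
# alteration events

def generate_alterations(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Bernoulli alteration events per (sample, gene, category).

    Events are independent across categories (co-occurrence is not
    modelled). Mutation rows additionally carry a consequence subtype and a
    driver/passenger flag drawn with probability ``driver_fraction``.
    """
    rng = _rng(config, "alterations")
    rates = config.alteration_rates
    subtype_by_sample = cohort["subtype"].to_numpy()
    sample_ids = cohort["sample_id"].to_numpy()
    n = len(cohort)

    rows: list[tuple[str, str, str]] = []
    for gene in config.gene_panel:
        cls = config.gene_class(gene)
        for cat in CATEGORIES:
            try:
                p = np.array([rates[(cls, s, cat)] for s in subtype_by_sample])
            except KeyError as err:
                raise ConfigurationError(f"no alteration rate for {err.args[0]!r}") from None
            hit = rng.random(n) < p
            rows.extend((sid, gene, cat) for sid in sample_ids[hit])

    events = pd.DataFrame(rows, columns=["sample_id", "gene", "category"])
    events["mutation_subtype"] = "NA"
    events["driver_flag"] = "NA"
    is_mut = events["category"] == "mutation"
    n_mut = int(is_mut.sum())
    if n_mut:
        events.loc[is_mut, "mutation_subtype"] = rng.choice(
            MUTATION_SUBTYPES, size=n_mut, p=_MUTATION_SUBTYPE_P
        )
        events.loc[is_mut, "driver_flag"] = np.where(
            rng.random(n_mut) < config.driver_fraction, "driver", "passenger"
        )
    events = events.sort_values(["sample_id", "gene", "category"], kind="stable")
    return events.reset_index(drop=True)


# --------------------------------------------------------------------------
# interaction network + consensus priors

def generate_network(config: SimulationConfig) -> tuple[nx.Graph, dict[str, float]]:
    """Hub-structured random graph and correlated consensus scores.

    Undirected simple graph over the gene panel. A pair's edge probability
    is the background ``edge_prob`` multiplied by ``hub_boost`` when either
    endpoint is a planted gene (capped at 1). Edge confidences are uniform
    on [conf_low, conf_high]. Consensus scores are Beta(8, 2) background
    draws (mean 0.8); planted hubs are pulled toward 0.95 with weight
    ``consensus_strength``.
    """
    if not config.gene_panel:
        raise ConfigurationError("gene_panel must be non-empty")
    params = config.network_params
    rng = _rng(config, "network")
    genes = list(config.gene_panel)
    hubs = set(config.planted_essential)
    n = len(genes)

    ii, jj = np.triu_indices(n, k=1)
    is_hub = np.array([g in hubs for g in genes])
    boosted = is_hub[ii] | is_hub[jj]
    p = np.where(boosted, np.minimum(1.0, params.edge_prob * params.hub_boost), params.edge_prob)
    hit = rng.random(len(ii)) < p
    conf = rng.uniform(params.conf_low, params.conf_high, size=int(hit.sum()))

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for (a, b), c in zip(zip(ii[hit], jj[hit]), conf):
        graph.add_edge(genes[a], genes[b], confidence=float(c))

    base = rng.beta(8, 2, size=n)
    s = params.consensus_strength
    scores = np.where(is_hub, (1 - s) * base + s * 0.95, base)
    consensus = {g: float(v) for g, v in zip(genes, scores)}
    return graph, consensus


# --------------------------------------------------------------------------
# protein expression (replicate Z-scores + IHC levels)

def generate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate protein Z-scores and tumor/normal IHC levels.

    Z-scores: ``n_expression_samples`` standard-normal replicates per
    protein; planted proteins are shifted by +/- ``expression_effect``
    (sign drawn once per protein). IHC: the normal-tissue level is
    categorical over (high, medium, low, not_detected); the tumor level is
    concordant unless the protein is in a planted discordant subset or hits
    the background ``ihc_discordance_rate``.
    """
    rng = _rng(config, "expression")
    genes = list(config.gene_panel)
    planted = set(config.planted_essential)
    m = config.n_expression_samples

    shift = np.zeros(len(genes))
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    for k, g in enumerate(genes):
        if g in planted:
            shift[k] = signs[k] * config.expression_effect
    z = rng.normal(0.0, 1.0, size=(len(genes), m)) + shift[:, None]
    rppa = pd.DataFrame(
        {
            "protein": np.repeat(genes, m),
            "z_score": z.ravel(),
            "source": "rppa",
        }
    )

    for name, subset in (
        ("ihc_discordant_low", config.ihc_discordant_low),
        ("ihc_discordant_high", config.ihc_discordant_high),
    ):
        stray = set(subset) - set(genes)
        if stray:
            raise ConfigurationError(f"{name} not in gene_panel: {sorted(stray)}")

    ihc_rng = _rng(config, "ihc")
    low_set, high_set = set(config.ihc_discordant_low), set(config.ihc_discordant_high)
    rows = []
    for g in genes:
        normal = ihc_rng.choice(IHC_LEVELS, p=_IHC_LEVEL_P)
        if g in low_set:  # expressed in normal tissue, lost in tumor
            normal = ihc_rng.choice(_EXPRESSED)
            tumor = ihc_rng.choice(_NOT_EXPRESSED)
        elif g in high_set:  # gained in tumor
            normal = ihc_rng.choice(_NOT_EXPRESSED)
            tumor = ihc_rng.choice(_EXPRESSED)
        elif ihc_rng.random() < config.ihc_discordance_rate:
            pool = _NOT_EXPRESSED if normal in _EXPRESSED else _EXPRESSED
            tumor = ihc_rng.choice(pool)
        else:
            tumor = normal
        rows.append((g, "normal", normal))
        rows.append((g, "tumor", tumor))
    ihc = pd.DataFrame(rows, columns=["protein", "tissue", "level"])
    return rppa, ihc


# --------------------------------------------------------------------------
# dependency screen + PDX expression

def generate_dependency_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene x cell-line dependency scores, line annotations and PDX Z-scores.

    Background scores are Normal(background_mean, background_sd). Planted
    common-essential genes receive ``planted_shift`` in every line (so at
    shift -1 their per-gene median sits at the common-essential calibration
    point); planted strongly selective genes receive it only in breast
    lines of ``selective_subtype``. PDX Z-scores are generated like the
    expression layer, with ``pdx_effect`` as the planted |Z| shift.
    """
    params = config.dependency_params
    rng = _rng(config, "dependency")
    genes = list(config.gene_panel)
    common = set(
        params.common_essential
        if params.common_essential is not None
        else config.planted_essential
    )
    selective = set(params.strongly_selective or [])
    for name, subset in (("common_essential", common), ("strongly_selective", selective)):
        stray = subset - set(genes)
        if stray:
            raise ConfigurationError(f"{name} not in gene_panel: {sorted(stray)}")

    lines, subtypes, is_breast = [], [], []
    for subtype in sorted(params.n_cell_lines):
        for i in range(params.n_cell_lines[subtype]):
            lines.append(f"BC_{subtype}_{i:02d}")
            subtypes.append(subtype)
            is_breast.append(True)
    for i in range(params.n_background_cell_lines):
        lines.append(f"PAN_{i:03d}")
        subtypes.append("unknown")
        is_breast.append(False)
    annotation = pd.DataFrame({"cell_line": lines, "subtype": subtypes, "is_breast": is_breast})

    scores = rng.normal(params.background_mean, params.background_sd, size=(len(genes), len(lines)))
    selective_cols = np.array(
        [st == params.selective_subtype and br for st, br in zip(subtypes, is_breast)]
    )
    for k, g in enumerate(genes):
        if g in common:
            scores[k, :] += params.planted_shift
        elif g in selective:
            scores[k, selective_cols] += params.planted_shift
    matrix = pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=lines)

    pdx_rng = _rng(config, "pdx")
    models = [f"TM{i:04d}" for i in range(params.pdx_n_models)]
    planted = set(config.planted_essential)
    pdx_signs = pdx_rng.choice([-1.0, 1.0], size=len(genes))
    pdx_shift = np.array(
        [pdx_signs[k] * params.pdx_effect if g in planted else 0.0 for k, g in enumerate(genes)]
    )
    pdx_z = pdx_rng.normal(0.0, 1.0, size=(len(genes), len(models))) + pdx_shift[:, None]
    pdx = pd.DataFrame(
        {
            "protein": np.repeat(genes, len(models)),
            "model_id": models * len(genes),
            "z_score": pdx_z.ravel(),
        }
    )
    return matrix, annotation, pdx


# --------------------------------------------------------------------------
# TSV round-trip IO

def _read(path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", keep_default_na=False, na_values=[],
        float_precision="round_trip", **kw,
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return _read(path, dtype=str)


def write_alterations(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_alterations(path) -> pd.DataFrame:
    return _read(path, dtype=str)


def write_network(graph: nx.Graph, path) -> None:
    rows = [(a, b, d["confidence"]) for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_network_edges(path) -> pd.DataFrame:
    return _read(path, dtype={"gene_a": str, "gene_b": str, "confidence": float})


def write_consensus(consensus: dict[str, float], path) -> None:
    pd.DataFrame(sorted(consensus.items()), columns=["gene", "consensus_score"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_consensus(path) -> dict[str, float]:
    df = _read(path, dtype={"gene": str, "consensus_score": float})
    return dict(zip(df["gene"], df["consensus_score"]))


def write_expression_rppa(rppa: pd.DataFrame, path) -> None:
    rppa.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_expression_rppa(path) -> pd.DataFrame:
    return _read(path, dtype={"protein": str, "z_score": float, "source": str})


def write_expression_ihc(ihc: pd.DataFrame, path) -> None:
    ihc.to_csv(path, sep="\t", index=False)


def read_expression_ihc(path) -> pd.DataFrame:
    return _read(path, dtype=str)


def write_dependency(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="gene", float_format="%.17g")


def read_dependency(path) -> pd.DataFrame:
    return _read(path).set_index("gene").astype(float)


def write_cell_lines(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_cell_lines(path) -> pd.DataFrame:
    df = _read(path, dtype={"cell_line": str, "subtype": str})
    df["is_breast"] = df["is_breast"].map({"True": True, "False": False, True: True, False: False})
    return df


def write_pdx(pdx: pd.DataFrame, path) -> None:
    pdx.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pdx(path) -> pd.DataFrame:
    return _read(path, dtype={"protein": str, "model_id": str, "z_score": float})


def simulate_study(config: SimulationConfig, out_dir=None) -> dict:
    """Generate every synthetic table; optionally write them all as TSV.

    Returns a dict with keys cohort, alterations, network, consensus,
    rppa, ihc, dependency, cell_lines, pdx.
    """
    cohort = generate_cohort(config)
    events = generate_alterations(cohort, config)
    graph, consensus = generate_network(config)
    rppa, ihc = generate_expression(config)
    matrix, annotation, pdx = generate_dependency_screen(config)
    study = {
        "cohort": cohort,
        "alterations": events,
        "network": graph,
        "consensus": consensus,
        "rppa": rppa,
        "ihc": ihc,
        "dependency": matrix,
        "cell_lines": annotation,
        "pdx": pdx,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort.tsv")
        write_alterations(events, out / "alterations.tsv")
        write_network(graph, out / "network_edges.tsv")
        write_consensus(consensus, out / "consensus.tsv")
        write_expression_rppa(rppa, out / "expression_rppa.tsv")
        write_expression_ihc(ihc, out / "expression_ihc.tsv")
        write_dependency(matrix, out / "dependency.tsv")
        write_cell_lines(annotation, out / "cell_lines.tsv")
        write_pdx(pdx, out / "pdx.tsv")
        logger.info("wrote synthetic study (seed=%d) to %s", config.seed, out)
    return study
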