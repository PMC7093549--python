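"""End-to-end orchestration: four evidence approaches, then integration.

``run_pipeline`` takes a :class:`SimulationConfig` and either simulates the
study or loads previously written TSV inputs, executes the four approach
selections with one shared set of thresholds, integrates them into the
essentiality ledger, and (optionally) writes ledger.tsv, tiers.json and a
manifest recording config hash, seed, thresholds and package version.
A validation failure in any stage aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, alterations, dependency, expression, integrate, network, synthetic
from .config import SimulationConfig
from .exceptions import PipelineError
from .types import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class PipelineThresholds:
    """Selection thresholds shared by the four approaches.

    Defaults follow the conventions the modules document: inclusive 0.9
    confidence cutoff, |Z| >= 2 expression and PDX significance, -1
    dependency cutoff, top-25% depletion rank in >= 90% of lines for common
    essentials, likelihood ratio >= 100 for strong selectivity.
    """

    confidence_cutoff: float = 0.9
    z_threshold: float = 2.0
    z_aggregation: str = "mean"
    dependency_cutoff: float = -1.0
    top_fraction: float = 0.25
    line_fraction: float = 0.90
    lr_threshold: float = 100.0
    pdx_threshold: float = 2.0


@dataclass
class PipelineResult:
    approach_sets: dict[str, GeneSet]
    ledger: pd.DataFrame
    tiers: dict
    thresholds: PipelineThresholds
    details: dict = field(default_factory=dict)


_INPUT_FILES = {
    "cohort": ("cohort.tsv", synthetic.read_cohort),
    "alterations": ("alterations.tsv", synthetic.read_alterations),
    "network_edges": ("network_edges.tsv", synthetic.read_network_edges),
    "consensus": ("consensus.tsv", synthetic.read_consensus),
    "rppa": ("expression_rppa.tsv", synthetic.read_expression_rppa),
    "ihc": ("expression_ihc.tsv", synthetic.read_expression_ihc),
    "dependency": ("dependency.tsv", synthetic.read_dependency),
    "cell_lines": ("cell_lines.tsv", synthetic.read_cell_lines),
    "pdx": ("pdx.tsv", synthetic.read_pdx),
}

_STAGE_OF_INPUT = {
    "cohort": "genomic_alterations",
    "alterations": "genomic_alterations",
    "network_edges": "ppi_network",
    "consensus": "ppi_network",
    "rppa": "protein_expression",
    "ihc": "protein_expression",
    "dependency": "dependency_pdx",
    "cell_lines": "dependency_pdx",
    "pdx": "dependency_pdx",
}


def load_study(input_dir) -> dict:
    """Read all stage inputs from a directory of TSVs written by the simulator."""
    input_dir = Path(input_dir)
    study: dict = {}
    for key, (fname, reader) in _INPUT_FILES.items():
        path = input_dir / fname
        if not path.exists():
            raise PipelineError(f"stage {_STAGE_OF_INPUT[key]}: missing input {fname}")
        study[key] = reader(path)
    study["network"] = None  # edges are re-thresholded by the network stage
    return study


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage {name}: {err}") from err

    return wrap


def run_pipeline(
    config: SimulationConfig,
    out_dir=None,
    input_dir=None,
    thresholds: PipelineThresholds | None = None,
) -> PipelineResult:
    """Execute approaches 1-4 and integration; idempotent given (config, inputs)."""
    th = thresholds or PipelineThresholds()
    if input_dir is not None:
        study = load_study(input_dir)
    else:
        study = synthetic.simulate_study(config)
    panel = list(config.gene_panel)
    details: dict = {}

    # approach 1 — genomic alterations
    run = _stage("genomic_alterations")
    run(alterations.validate_events, study["alterations"], study["cohort"])
    events = run(alterations.dedupe_events, study["alterations"])
    events = run(alterations.filter_driver_mutations, events)
    set1, threshold1 = run(alterations.oncoprint_select, events, panel)
    details["alteration_threshold"] = threshold1
    details["driver_filtered_events"] = len(events)

    # approach 2 — interactome hubness + consensus
    run = _stage("ppi_network")
    if study.get("network_edges") is not None:
        edges = study["network_edges"]
    else:
        graph_full = study["network"]
        edges = pd.DataFrame(
            [(a, b, d["confidence"]) for a, b, d in graph_full.edges(data=True)],
            columns=["gene_a", "gene_b", "confidence"],
        )
    graph = run(network.build_graph, edges, cutoff=th.confidence_cutoff, allowed_nodes=panel)
    set2, net_thresholds = run(network.select_hub_consensus, graph, study["consensus"])
    details["network_thresholds"] = net_thresholds
    details["network_nodes"] = graph.number_of_nodes()
    details["network_edges"] = graph.number_of_edges()

    # approach 3 — protein expression
    run = _stage("protein_expression")
    z = run(expression.aggregate_z, study["rppa"], method=th.z_aggregation)
    z_high, z_low = run(expression.zscore_select, z, threshold=th.z_threshold)
    ihc_low, ihc_high = run(expression.ihc_discordance, study["ihc"])
    set3, provenance3 = run(
        expression.approach3_set,
        z_high.members, z_low.members, ihc_low.members, ihc_high.members,
    )
    details["expression_provenance"] = provenance3

    # approach 4 — dependency screens + PDX confirmation
    run = _stage("dependency_pdx")
    if study.get("dependency") is None:
        raise PipelineError("stage dependency_pdx: missing dependency matrix")
    matrix, annotation = study["dependency"], study["cell_lines"]
    counts, qualifying, total_dep, frac = run(
        dependency.substantial_dependencies, matrix, cutoff=th.dependency_cutoff
    )
    ratios = run(
        dependency.subtype_dependency_ratio, matrix, annotation, cutoff=th.dependency_cutoff
    )
    common = run(
        dependency.classify_common_essential,
        matrix, top_fraction=th.top_fraction, line_fraction=th.line_fraction,
    )
    selective, ss_report = run(
        dependency.classify_strongly_selective, matrix, lr_threshold=th.lr_threshold
    )
    candidates = common.members | selective.members
    set4, pdx_report = run(
        dependency.pdx_filter, candidates, study["pdx"], threshold=th.pdx_threshold
    )
    details.update(
        dependency_counts=counts,
        dependency_total=total_dep,
        dependency_qualifying_fraction=frac,
        subtype_ratios=ratios,
        common_essential=common,
        strongly_selective=selective,
        selective_report=ss_report,
        pdx_report=pdx_report,
    )

    # integration
    run = _stage("integration")
    approach_sets = {
        "genomic_alterations": set1,
        "ppi_network": set2,
        "protein_expression": set3,
        "dependency_pdx": set4,
    }
    ledger = run(venn_from_sets, approach_sets)
    tiers = integrate.tier_summary(ledger)
    result = PipelineResult(
        approach_sets=approach_sets, ledger=ledger, tiers=tiers, thresholds=th, details=details
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def venn_from_sets(approach_sets: dict[str, GeneSet]) -> pd.DataFrame:
    return integrate.venn_classify({k: v.members for k, v in approach_sets.items()})


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_outputs(result: PipelineResult, config: SimulationConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.ledger.to_csv(out / "ledger.tsv", sep="\t", index=False)
    with open(out / "tiers.json", "w") as fh:
        json.dump(result.tiers, fh, indent=2, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "thresholds": asdict(result.thresholds),
        "approach_set_sizes": {k: len(v) for k, v in result.approach_sets.items()},
        "n_essential_genes": int(result.tiers["total"]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline outputs written to %s (seed=%d)", out, config.seed)
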