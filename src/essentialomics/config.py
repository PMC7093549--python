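"""Simulation configuration.

A single :class:`SimulationConfig` drives every synthetic generator. One
global integer seed governs all sub-generators through a documented
stream-splitting scheme: each generator draws from
``numpy.random.default_rng(SeedSequence(seed, spawn_key=(k,)))`` where
``k`` is the generator's fixed index in :data:`STREAMS`. Identical
configurations therefore produce byte-identical outputs, and changing one
generator never perturbs another's stream.

Default cohort composition follows the reference breast-cancer cohort:
subtype counts 499/197/171/78/36 (luminal A / luminal B / basal-like /
Her2-enriched / normal-like) and stage counts 255/586/113/103 (T1-T4),
each rescaled to proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

from .exceptions import ConfigurationError
from .types import CATEGORIES, STAGES, SUBTYPES

# fixed spawn-key index per generator stream
STREAMS = {
    "cohort": 0,
    "alterations": 1,
    "network": 2,
    "expression": 3,
    "dependency": 4,
    "pdx": 5,
    "ihc": 6,
}

GENE_CLASSES = ("background", "planted")

_SUBTYPE_COUNTS = {
    "luminal_A": 499,
    "luminal_B": 197,
    "basal_like": 171,
    "her2_enriched": 78,
    "normal_like": 36,
}
_STAGE_COUNTS = {"T1": 255, "T2": 586, "T3": 113, "T4": 103}


def _rescale(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def default_subtype_proportions() -> dict[str, float]:
    return _rescale(_SUBTYPE_COUNTS)


def default_stage_proportions() -> dict[str, float]:
    return _rescale(_STAGE_COUNTS)


def uniform_alteration_rates(
    background_rate: float,
    planted_rate: float,
    subtypes: Sequence[str] = tuple(s for s in SUBTYPES if s != "unknown"),
    categories: Sequence[str] = CATEGORIES,
) -> dict[tuple[str, str, str], float]:
    """Build a full (gene-class, subtype, category) -> probability map
    with one rate per gene class, constant across subtypes and categories."""
    rates: dict[tuple[str, str, str], float] = {}
    for subtype in subtypes:
        for cat in categories:
            rates[("background", subtype, cat)] = background_rate
            rates[("planted", subtype, cat)] = planted_rate
    return rates


@dataclass
class NetworkParams:
    """Hub-structured random interaction graph parameters.

    ``edge_prob`` is the background probability of an edge between two
    non-hub genes; edges incident to a planted hub are ``hub_boost`` times
    more probable (capped at 1). Confidences are Uniform(conf_low,
    conf_high); the downstream graph builder keeps edges at confidence
    >= 0.9, so roughly (conf_high - 0.9)/(conf_high - conf_low) of
    generated edges survive the default cutoff. ``consensus_strength`` in
    [0, 1] pulls planted hubs' consensus score toward 0.95 (0 = no
    correlation with hub status).
    """

    edge_prob: float = 0.2
    hub_boost: float = 5.0
    conf_low: float = 0.5
    conf_high: float = 1.0
    consensus_strength: float = 0.6

    def validate(self) -> None:
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ConfigurationError(f"edge_prob must be in [0,1], got {self.edge_prob}")
        if self.hub_boost < 0:
            raise ConfigurationError("hub_boost must be non-negative")
        if not 0.0 <= self.conf_low <= self.conf_high <= 1.0:
            raise ConfigurationError("confidence bounds must satisfy 0 <= low <= high <= 1")
        if not 0.0 <= self.consensus_strength <= 1.0:
            raise ConfigurationError("consensus_strength must be in [0,1]")


@dataclass
class DependencyParams:
    """Loss-of-function screen generator parameters.

    Scores are on the calibrated dependency scale: 0 = not essential, -1 =
    median of known common-essential genes. Background entries are
    Normal(background_mean, background_sd); planted common-essential genes
    are shifted by ``planted_shift`` in every line; planted strongly
    selective genes are shifted only in lines of ``selective_subtype``.
    ``common_essential``/``strongly_selective`` name the planted genes per
    class; when ``common_essential`` is None it defaults to the study's
    ``planted_essential`` set and ``strongly_selective`` to empty.
    """

    background_mean: float = 0.0
    background_sd: float = 0.2
    planted_shift: float = -1.0
    n_cell_lines: Mapping[str, int] = field(
        default_factory=lambda: {
            "luminal_A": 8,
            "luminal_B": 5,
            "her2_enriched": 8,
            "basal_like": 12,
        }
    )
    n_background_cell_lines: int = 40
    selective_subtype: str = "basal_like"
    common_essential: Sequence[str] | None = None
    strongly_selective: Sequence[str] | None = None
    pdx_n_models: int = 8
    pdx_effect: float = 4.0

    def validate(self) -> None:
        if self.background_sd <= 0:
            raise ConfigurationError("background_sd must be positive")
        if not self.n_cell_lines:
            raise ConfigurationError("at least one cell-line subtype is required")
        for subtype, n in self.n_cell_lines.items():
            if subtype not in SUBTYPES:
                raise ConfigurationError(f"unknown cell-line subtype {subtype!r}")
            if n < 1:
                raise ConfigurationError(f"n_cell_lines[{subtype!r}] must be >= 1, got {n}")
        if self.n_background_cell_lines < 0:
            raise ConfigurationError("n_background_cell_lines must be >= 0")
        if self.selective_subtype not in self.n_cell_lines:
            raise ConfigurationError(
                f"selective_subtype {self.selective_subtype!r} has no cell lines configured"
            )
        if self.pdx_n_models < 1:
            raise ConfigurationError("pdx_n_models must be >= 1")


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study.

    ``alteration_rates`` maps (gene-class, subtype, category) to a
    per-sample Bernoulli probability; gene classes are ``background`` and
    ``planted`` (membership set by ``planted_essential``). Defaults plant
    strong, recoverable effects: alteration rate ratio 6x, |Z| shift 4,
    dependency shift -1. A null study is the same configuration with
    ``null_config()``.
    """

    n_samples: int = 150
    subtype_proportions: Mapping[str, float] = field(default_factory=default_subtype_proportions)
    stage_proportions: Mapping[str, float] = field(default_factory=default_stage_proportions)
    gene_panel: Sequence[str] = field(default_factory=lambda: [f"G{i:03d}" for i in range(100)])
    planted_essential: Sequence[str] = field(
        default_factory=lambda: [f"G{i:03d}" for i in range(10)]
    )
    alteration_rates: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: uniform_alteration_rates(0.05, 0.30)
    )
    driver_fraction: float = 0.5
    network_params: NetworkParams = field(default_factory=NetworkParams)
    expression_effect: float = 4.0
    n_expression_samples: int = 20
    ihc_discordance_rate: float = 0.0
    ihc_discordant_low: Sequence[str] = field(default_factory=list)
    ihc_discordant_high: Sequence[str] = field(default_factory=list)
    dependency_params: DependencyParams = field(default_factory=DependencyParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_panel = list(self.gene_panel)
        self.planted_essential = list(self.planted_essential)
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be non-negative")
        for name, props in (
            ("subtype_proportions", self.subtype_proportions),
            ("stage_proportions", self.stage_proportions),
        ):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")
            if any(p < 0 for p in props.values()):
                raise ConfigurationError(f"{name} contains a negative proportion")
        unknown_sub = set(self.subtype_proportions) - set(SUBTYPES)
        if unknown_sub:
            raise ConfigurationError(f"unknown subtypes in proportions: {sorted(unknown_sub)}")
        unknown_stage = set(self.stage_proportions) - set(STAGES)
        if unknown_stage:
            raise ConfigurationError(f"unknown stages in proportions: {sorted(unknown_stage)}")
        if len(set(self.gene_panel)) != len(self.gene_panel):
            raise ConfigurationError("gene_panel contains duplicates")
        stray = set(self.planted_essential) - set(self.gene_panel)
        if stray:
            raise ConfigurationError(f"planted_essential not in gene_panel: {sorted(stray)}")
        for key, p in self.alteration_rates.items():
            if len(key) != 3 or key[0] not in GENE_CLASSES:
                raise ConfigurationError(f"bad alteration rate key {key!r}")
            if key[1] not in SUBTYPES or key[2] not in CATEGORIES:
                raise ConfigurationError(f"bad alteration rate key {key!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"rate for {key!r} outside [0,1]: {p}")
        if not 0.0 <= self.driver_fraction <= 1.0:
            raise ConfigurationError("driver_fraction must be in [0,1]")
        if self.expression_effect < 0:
            raise ConfigurationError("expression_effect must be >= 0")
        if self.n_expression_samples < 1:
            raise ConfigurationError("n_expression_samples must be >= 1")
        if not 0.0 <= self.ihc_discordance_rate <= 1.0:
            raise ConfigurationError("ihc_discordance_rate must be in [0,1]")
        self.network_params.validate()
        self.dependency_params.validate()

    def gene_class(self, gene: str) -> str:
        return "planted" if gene in set(self.planted_essential) else "background"

    def null_copy(self) -> "SimulationConfig":
        """The same study with every planted effect removed (null condition)."""
        bg = {
            key: self.alteration_rates[("background",) + key[1:]]
            for key in self.alteration_rates
        }
        cfg = SimulationConfig(
            n_samples=self.n_samples,
            subtype_proportions=dict(self.subtype_proportions),
            stage_proportions=dict(self.stage_proportions),
            gene_panel=list(self.gene_panel),
            planted_essential=list(self.planted_essential),
            alteration_rates=bg,
            driver_fraction=self.driver_fraction,
            network_params=NetworkParams(
                edge_prob=self.network_params.edge_prob,
                hub_boost=1.0,
                conf_low=self.network_params.conf_low,
                conf_high=self.network_params.conf_high,
                consensus_strength=0.0,
            ),
            expression_effect=0.0,
            n_expression_samples=self.n_expression_samples,
            ihc_discordance_rate=self.ihc_discordance_rate,
            ihc_discordant_low=[],
            ihc_discordant_high=[],
            dependency_params=DependencyParams(
                background_mean=self.dependency_params.background_mean,
                background_sd=self.dependency_params.background_sd,
                planted_shift=0.0,
                n_cell_lines=dict(self.dependency_params.n_cell_lines),
                n_background_cell_lines=self.dependency_params.n_background_cell_lines,
                selective_subtype=self.dependency_params.selective_subtype,
                common_essential=self.dependency_params.common_essential,
                strongly_selective=self.dependency_params.strongly_selective,
                pdx_n_models=self.dependency_params.pdx_n_models,
                pdx_effect=0.0,
            ),
            seed=self.seed,
        )
        return cfg

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alteration_rates"] = {
            "|".join(k): v for k, v in self.alteration_rates.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "alteration_rates" in d and d["alteration_rates"] is not None:
            raw = d["alteration_rates"]
            if raw and isinstance(next(iter(raw)), str):
                d["alteration_rates"] = {tuple(k.split("|")): v for k, v in raw.items()}
        if isinstance(d.get("network_params"), Mapping):
            d["network_params"] = NetworkParams(**d["network_params"])
        if isinstance(d.get("dependency_params"), Mapping):
            d["dependency_params"] = DependencyParams(**d["dependency_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
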