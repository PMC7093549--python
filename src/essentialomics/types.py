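"""Closed vocabularies and lightweight shared containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

SUBTYPES = ("luminal_A", "luminal_B", "her2_enriched", "basal_like", "normal_like", "unknown")
STAGES = ("T1", "T2", "T3", "T4", "unknown")
CATEGORIES = ("mrna_up", "mrna_down", "cnv_amp", "cnv_deepdel", "mutation", "fusion")
MUTATION_SUBTYPES = ("missense", "truncating", "inframe", "other")
IHC_LEVELS = ("high", "medium", "low", "not_detected")
ROLES = ("oncogene", "tumor_suppressor", "driver_other", "none")
FUNCTIONAL_CATEGORIES = ("immunotherapy", "kinome", "cell_cycle", "dna_repair", "rbp")

APPROACHES = ("genomic_alterations", "ppi_network", "protein_expression", "dependency_pdx")


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def sorted(self) -> list[str]:
        return sorted(self.members)


@dataclass
class FrequencySummary:
    """Per-key event counts, denominators, ratios and category percentages.

    ``undefined`` lists keys whose denominator was zero (ratio is reported
    as NaN, never as 0) or which had no events when percentages were
    requested.
    """

    unit: str
    counts: Mapping[str, float] = field(default_factory=dict)
    denominators: Mapping[str, float] = field(default_factory=dict)
    ratios: Mapping[str, float] = field(default_factory=dict)
    percentages: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)
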