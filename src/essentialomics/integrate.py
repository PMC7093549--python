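"""Cross-approach evidence integration: the essentiality ledger.

Each gene selected by at least one of the four approaches (genomic
alterations, interactome hubness, protein expression, dependency screens +
PDX) gets a ledger row recording which approaches it passed; its tier is
that count (1-4). Gene identity is the uppercased symbol string — no alias
resolution. Venn region counts (exactly 1/2/3/4 approaches) and cumulative
counts (>=1, >=2, >=3) summarize the ledger.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from . import stats
from .exceptions import ValidationError
from .types import APPROACHES, FUNCTIONAL_CATEGORIES, ROLES

logger = logging.getLogger(__name__)


def venn_classify(approach_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Build the essentiality ledger from exactly four named approach sets.

    Returns a DataFrame (gene, approaches_passed, n_approaches, tier)
    sorted by descending n_approaches then gene symbol. Gene symbols are
    uppercased; duplicates within one set are deduplicated with a warning.
    """
    if set(approach_sets) != set(APPROACHES):
        raise ValidationError(
            f"expected the four approach sets {list(APPROACHES)}, got {sorted(approach_sets)}"
        )
    normalized: dict[str, set[str]] = {}
    for name in APPROACHES:
        raw = [str(g).upper() for g in approach_sets[name]]
        members = set(raw)
        if len(members) != len(raw):
            logger.warning("deduplicated %d genes in approach %s", len(raw) - len(members), name)
        normalized[name] = members
    genes = sorted(set().union(*normalized.values()))
    rows = []
    for gene in genes:
        passed = [name for name in APPROACHES if gene in normalized[name]]
        rows.append(
            {
                "gene": gene,
                "approaches_passed": ",".join(passed),
                "n_approaches": len(passed),
                "tier": f"tier_{len(passed)}",
            }
        )
    ledger = pd.DataFrame(rows, columns=["gene", "approaches_passed", "n_approaches", "tier"])
    return ledger.sort_values(
        ["n_approaches", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def region_counts(ledger: pd.DataFrame) -> dict[int, int]:
    """Genes passing exactly k approaches, k = 1..4."""
    vc = ledger["n_approaches"].value_counts().to_dict()
    return {k: int(vc.get(k, 0)) for k in (1, 2, 3, 4)}


def tier_summary(ledger: pd.DataFrame) -> dict:
    """Exact tier counts, cumulative counts and the >=1 total."""
    exact = region_counts(ledger)
    cumulative = {k: sum(v for kk, v in exact.items() if kk >= k) for k in (1, 2, 3, 4)}
    return {"exact": exact, "cumulative": cumulative, "total": cumulative[1]}


def annotate_summary(ledger: pd.DataFrame, annotations: pd.DataFrame) -> dict:
    """Role, hallmark and functional-category report over the essential genes.

    ``annotations`` columns: gene, role, hallmarks (comma-joined tags, may
    be empty), categories (comma-joined from the closed vocabulary). Genes
    without an annotation row get role ``none``. Report percentages are
    integers rounded half away from zero; exact fractions are kept under
    ``exact``.
    """
    bad_roles = set(annotations["role"]) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
    genes = list(ledger["gene"])
    n = len(genes)
    ann = annotations.drop_duplicates("gene").set_index("gene")

    def _tags(gene: str, column: str) -> list[str]:
        if gene not in ann.index:
            return []
        raw = str(ann.loc[gene, column]) if column in ann.columns else ""
        return [t for t in raw.split(",") if t]

    roles = {g: (ann.loc[g, "role"] if g in ann.index else "none") for g in genes}
    role_counts = {r: sum(1 for g in genes if roles[g] == r) for r in ROLES}
    hallmark_genes = sorted(g for g in genes if _tags(g, "hallmarks"))
    category_genes = {
        c: sorted(g for g in genes if c in _tags(g, "categories"))
        for c in FUNCTIONAL_CATEGORIES
    }
    bad_cats = {
        t
        for g in genes
        for t in _tags(g, "categories")
        if t not in FUNCTIONAL_CATEGORIES
    }
    if bad_cats:
        raise ValidationError(f"unknown functional categories: {sorted(bad_cats)}")
    overlaps = {
        f"{a}&{b}": sorted(set(category_genes[a]) & set(category_genes[b]))
        for i, a in enumerate(FUNCTIONAL_CATEGORIES)
        for b in FUNCTIONAL_CATEGORIES[i + 1:]
    }
    report = {
        "n_genes": n,
        "role_pct": {
            r: (stats.percentage(c, n) if n else float("nan")) for r, c in role_counts.items()
        },
        "hallmark_count": len(hallmark_genes),
        "hallmark_pct": stats.percentage(len(hallmark_genes), n) if n else float("nan"),
        "hallmark_genes": hallmark_genes,
        "category_genes": category_genes,
        "category_overlaps": overlaps,
        "exact": {
            "role_fraction": {r: (c / n if n else float("nan")) for r, c in role_counts.items()},
            "hallmark_fraction": len(hallmark_genes) / n if n else float("nan"),
        },
    }
    return report
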