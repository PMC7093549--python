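import numpy as np
import pandas as pd
import pytest

from essentialomics import SimulationConfig
from essentialomics.config import uniform_alteration_rates


def make_events(rows):
    """Event table from (sample_id, gene, category[, mutation_subtype, driver_flag]) tuples."""
    full = []
    for row in rows:
        if len(row) == 3:
            row = (*row, "NA", "NA")
        full.append(row)
    return pd.DataFrame(
        full, columns=["sample_id", "gene", "category", "mutation_subtype", "driver_flag"]
    )


def make_cohort(n, subtype="luminal_A", stage="T2"):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "subtype": subtype if isinstance(subtype, str) else subtype,
            "stage": stage,
        }
    )


def random_events(rng, samples, genes, n_events):
    """Uniform random event table over the given samples and genes (no mutations)."""
    cats = ["mrna_up", "mrna_down", "cnv_amp", "cnv_deepdel", "fusion"]
    return make_events(
        [
            (rng.choice(samples), rng.choice(genes), rng.choice(cats))
            for _ in range(n_events)
        ]
    )


def dependency_matrix_with_counts(dep_per_subtype, n_genes=300):
    """Dependency matrix + annotation whose per-subtype counts of scores <= -1
    are exactly as requested: {subtype: (n_dependencies, n_lines)}."""
    frames, ann_frames = [], []
    genes = [f"G{i}" for i in range(n_genes)]
    for subtype, (n_dep, n_lines) in dep_per_subtype.items():
        lines = [f"{subtype}_{j}" for j in range(n_lines)]
        block = np.zeros((n_genes, n_lines))
        placed = set()
        i = 0
        while len(placed) < n_dep:
            placed.add((i % n_genes, (i // n_genes + i) % n_lines))
            i += 1
        for r, c in placed:
            block[r, c] = -1.5
        frames.append(pd.DataFrame(block, index=genes, columns=lines))
        ann_frames.append(
            pd.DataFrame({"cell_line": lines, "subtype": subtype, "is_breast": True})
        )
    matrix = pd.concat(frames, axis=1)
    matrix.index.name = "gene"
    return matrix, pd.concat(ann_frames, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A small but fully-featured study: 60 genes, 6 planted, 80 samples."""
    genes = [f"G{i:03d}" for i in range(60)]
    return SimulationConfig(
        n_samples=80,
        gene_panel=genes,
        planted_essential=genes[:6],
        alteration_rates=uniform_alteration_rates(0.05, 0.30),
        seed=11,
    )
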