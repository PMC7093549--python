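"""Synthetic study generator: determinism, planted structure, round-trip IO."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from essentialomics import ConfigurationError, SimulationConfig, synthetic
from essentialomics.config import uniform_alteration_rates


def binom_bounds_99(n, p):
    """Independent oracle: central 99% interval of Binomial(n, p)."""
    return binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)


def binom_bounds_999(n, p):
    """Central 99.9% interval, for tests making many simultaneous checks."""
    return binom.ppf(0.0005, n, p), binom.ppf(0.9995, n, p)


# ---------------------------------------------------------------------------
# configuration validation


@pytest.mark.parametrize(
    "kwargs",
    [
        {"subtype_proportions": {"luminal_A": 0.6, "luminal_B": 0.3}},
        {"stage_proportions": {"T1": 0.5, "T2": 0.6}},
        {"planted_essential": ["NOT_A_GENE"]},
        {"driver_fraction": 1.5},
        {"alteration_rates": {("background", "luminal_A", "cnv_amp"): 1.2}},
    ],
)
def test_invalid_configurations_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**kwargs)


def test_network_edge_prob_outside_unit_interval_rejected():
    from essentialomics import NetworkParams

    with pytest.raises(ConfigurationError):
        SimulationConfig(network_params=NetworkParams(edge_prob=1.5))


# ---------------------------------------------------------------------------
# cohort


def test_empty_cohort():
    cfg = SimulationConfig(n_samples=0)
    cohort = synthetic.generate_cohort(cfg)
    assert len(cohort) == 0
    assert list(cohort.columns) == ["sample_id", "subtype", "stage"]


def test_cohort_composition_within_binomial_bounds():
    # reference cohort: 1084 samples at the 499/197/171/78/36 subtype mix
    counts = {"luminal_A": 499, "luminal_B": 197, "basal_like": 171,
              "her2_enriched": 78, "normal_like": 36}
    total = sum(counts.values())
    props = {k: v / total for k, v in counts.items()}
    cfg = SimulationConfig(n_samples=1084, subtype_proportions=props, seed=5)
    cohort = synthetic.generate_cohort(cfg)
    observed = cohort["subtype"].value_counts()
    for subtype, p in props.items():
        lo, hi = binom_bounds_99(1084, p)
        assert lo <= observed.get(subtype, 0) <= hi, subtype


def test_cohort_determinism_byte_identical():
    cfg = SimulationConfig(n_samples=200, seed=42)
    a = synthetic.generate_cohort(cfg).to_csv(sep="\t")
    b = synthetic.generate_cohort(cfg).to_csv(sep="\t")
    assert a == b


def test_each_sample_has_one_subtype_and_stage(small_config):
    cohort = synthetic.generate_cohort(small_config)
    assert cohort["sample_id"].is_unique
    assert cohort["subtype"].isin(set(small_config.subtype_proportions)).all()
    assert cohort["stage"].isin(set(small_config.stage_proportions)).all()


# ---------------------------------------------------------------------------
# alteration events


def test_zero_rates_give_zero_events():
    cfg = SimulationConfig(
        n_samples=30, gene_panel=["A", "B"], planted_essential=[],
        alteration_rates=uniform_alteration_rates(0.0, 0.0),
    )
    events = synthetic.generate_alterations(synthetic.generate_cohort(cfg), cfg)
    assert len(events) == 0


def test_rate_one_forces_single_event():
    rates = uniform_alteration_rates(0.0, 0.0)
    for s in set(k[1] for k in rates):
        rates[("background", s, "cnv_amp")] = 1.0
    cfg = SimulationConfig(n_samples=1, gene_panel=["A"], planted_essential=[],
                           alteration_rates=rates)
    events = synthetic.generate_alterations(synthetic.generate_cohort(cfg), cfg)
    assert len(events) == 1
    assert events.iloc[0]["category"] == "cnv_amp"
    assert events.iloc[0]["driver_flag"] == "NA"


def test_event_frequencies_match_configured_rates():
    genes = [f"G{i}" for i in range(20)]
    cfg = SimulationConfig(
        n_samples=200, gene_panel=genes, planted_essential=genes[:5],
        alteration_rates=uniform_alteration_rates(0.05, 0.30), seed=7,
    )
    cohort = synthetic.generate_cohort(cfg)
    events = synthetic.generate_alterations(cohort, cfg)
    # per (gene, category) the event count is Binomial(n_samples, rate)
    counts = events.groupby(["gene", "category"]).size()
    for gene in genes:
        rate = 0.30 if gene in cfg.planted_essential[:5] else 0.05
        # 40 simultaneous checks: use the wider 99.9% per-check interval
        lo, hi = binom_bounds_999(200, rate)
        for cat in ["mrna_up", "cnv_amp"]:
            assert lo <= counts.get((gene, cat), 0) <= hi, (gene, cat)


def test_mutation_rows_carry_subtype_and_driver_flag(small_config):
    cohort = synthetic.generate_cohort(small_config)
    events = synthetic.generate_alterations(cohort, small_config)
    mut = events[events["category"] == "mutation"]
    non = events[events["category"] != "mutation"]
    assert (mut["mutation_subtype"] != "NA").all()
    assert mut["driver_flag"].isin(["driver", "passenger"]).all()
    assert (non["mutation_subtype"] == "NA").all() and (non["driver_flag"] == "NA").all()


def test_missing_rate_raises():
    rates = uniform_alteration_rates(0.1, 0.1)
    del rates[("background", "luminal_A", "fusion")]
    cfg = SimulationConfig(n_samples=20, gene_panel=["A"], planted_essential=[],
                           alteration_rates=rates, seed=1)
    cohort = synthetic.generate_cohort(cfg)
    if (cohort["subtype"] == "luminal_A").any():
        with pytest.raises(ConfigurationError):
            synthetic.generate_alterations(cohort, cfg)


# ---------------------------------------------------------------------------
# network


def test_edge_prob_zero_gives_no_edges():
    from essentialomics import NetworkParams

    cfg = SimulationConfig(gene_panel=["A", "B", "C"], planted_essential=[],
                           network_params=NetworkParams(edge_prob=0.0))
    graph, _ = synthetic.generate_network(cfg)
    assert graph.number_of_edges() == 0


def test_edge_prob_one_gives_complete_graph():
    from essentialomics import NetworkParams

    cfg = SimulationConfig(gene_panel=["A", "B", "C", "D"], planted_essential=[],
                           network_params=NetworkParams(edge_prob=1.0, hub_boost=1.0))
    graph, _ = synthetic.generate_network(cfg)
    assert all(d == 3 for _, d in graph.degree())


def test_hub_boost_raises_hub_degrees():
    from essentialomics import NetworkParams

    genes = [f"G{i:03d}" for i in range(200)]
    wins = 0
    for seed in range(100):
        cfg = SimulationConfig(
            gene_panel=genes, planted_essential=genes[:10],
            network_params=NetworkParams(edge_prob=0.03, hub_boost=5.0),
            seed=seed,
        )
        graph, _ = synthetic.generate_network(cfg)
        degs = dict(graph.degree())
        hub_mean = np.mean([degs[g] for g in genes[:10]])
        bg_mean = np.mean([degs[g] for g in genes[10:]])
        wins += hub_mean > bg_mean
    assert wins >= 95


def test_consensus_scores_bounded_and_hub_correlated(small_config):
    _, consensus = synthetic.generate_network(small_config)
    values = np.array(list(consensus.values()))
    assert ((0 <= values) & (values <= 1)).all()
    hubs = [consensus[g] for g in small_config.planted_essential]
    bg = [consensus[g] for g in small_config.gene_panel if g not in small_config.planted_essential]
    assert np.mean(hubs) > np.mean(bg)


# ---------------------------------------------------------------------------
# expression


def test_null_zscore_tail_fraction():
    # 500 proteins x 20 replicates = 10,000 standard-normal draws;
    # two-sided tail P(|Z| >= 2) = 0.0455, MC sd ~ 0.0021
    genes = [f"P{i:03d}" for i in range(500)]
    cfg = SimulationConfig(gene_panel=genes, planted_essential=[],
                           expression_effect=0.0, n_expression_samples=20, seed=3)
    rppa, _ = synthetic.generate_expression(cfg)
    frac = (rppa["z_score"].abs() >= 2).mean()
    assert abs(frac - 0.0455) < 0.008


def test_planted_effect_four_passes_threshold():
    genes = [f"P{i}" for i in range(30)]
    hits = 0
    for seed in range(50):
        cfg = SimulationConfig(gene_panel=genes, planted_essential=genes[:10],
                               expression_effect=4.0, n_expression_samples=20, seed=seed)
        rppa, _ = synthetic.generate_expression(cfg)
        agg = rppa.groupby("protein")["z_score"].mean()
        hits += sum(abs(agg[g]) >= 2 for g in genes[:10])
    assert hits / (50 * 10) >= 0.97


def test_ihc_concordant_without_planting():
    genes = [f"P{i}" for i in range(50)]
    cfg = SimulationConfig(gene_panel=genes, planted_essential=[], seed=9)
    _, ihc = synthetic.generate_expression(cfg)
    wide = ihc.pivot(index="protein", columns="tissue", values="level")
    assert (wide["normal"] == wide["tumor"]).all()  # default discordance rate is 0


def test_planted_ihc_discordance():
    genes = [f"P{i}" for i in range(20)]
    cfg = SimulationConfig(gene_panel=genes, planted_essential=[],
                           ihc_discordant_low=genes[:3], ihc_discordant_high=genes[3:5], seed=2)
    _, ihc = synthetic.generate_expression(cfg)
    wide = ihc.pivot(index="protein", columns="tissue", values="level")
    for g in genes[:3]:
        assert wide.loc[g, "normal"] in {"high", "medium"}
        assert wide.loc[g, "tumor"] in {"low", "not_detected"}
    for g in genes[3:5]:
        assert wide.loc[g, "normal"] in {"low", "not_detected"}
        assert wide.loc[g, "tumor"] in {"high", "medium"}


# ---------------------------------------------------------------------------
# dependency screen


def test_common_essential_median_near_minus_one():
    from essentialomics import DependencyParams

    genes = [f"G{i}" for i in range(20)]
    cfg = SimulationConfig(
        gene_panel=genes, planted_essential=genes[:5],
        dependency_params=DependencyParams(
            background_sd=0.1, planted_shift=-1.0,
            n_cell_lines={"basal_like": 60}, n_background_cell_lines=40,
            selective_subtype="basal_like",
        ),
        seed=13,
    )
    matrix, _, _ = synthetic.generate_dependency_screen(cfg)
    for g in genes[:5]:
        assert -1.05 <= matrix.loc[g].median() <= -0.95


def test_background_scores_never_cross_cutoff():
    # Phi(-5) ~ 3e-7: at desk scale no background score reaches -1
    from essentialomics import DependencyParams

    genes = [f"G{i}" for i in range(50)]
    cfg = SimulationConfig(
        gene_panel=genes, planted_essential=[],
        dependency_params=DependencyParams(background_sd=0.2,
                                           n_cell_lines={"luminal_A": 20},
                                           n_background_cell_lines=30,
                                           selective_subtype="luminal_A"),
        seed=4,
    )
    matrix, _, _ = synthetic.generate_dependency_screen(cfg)
    assert (matrix.to_numpy() > -1).all()


def test_selective_genes_depleted_only_in_configured_subtype():
    from essentialomics import DependencyParams

    genes = [f"G{i}" for i in range(10)]
    cfg = SimulationConfig(
        gene_panel=genes, planted_essential=[],
        dependency_params=DependencyParams(
            n_cell_lines={"basal_like": 15, "luminal_A": 15},
            n_background_cell_lines=10,
            common_essential=[], strongly_selective=genes[:2],
            selective_subtype="basal_like", planted_shift=-1.5,
        ),
        seed=6,
    )
    matrix, ann, _ = synthetic.generate_dependency_screen(cfg)
    basal = ann.loc[(ann["subtype"] == "basal_like"), "cell_line"]
    other = ann.loc[(ann["subtype"] != "basal_like"), "cell_line"]
    for g in genes[:2]:
        assert matrix.loc[g, basal].mean() < -1.0
        assert abs(matrix.loc[g, other].mean()) < 0.5


def test_dependency_determinism(small_config):
    m1, a1, p1 = synthetic.generate_dependency_screen(small_config)
    m2, a2, p2 = synthetic.generate_dependency_screen(small_config)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(p1, p2)


# ---------------------------------------------------------------------------
# TSV round-trip


def test_all_tables_round_trip_losslessly(small_config, tmp_path):
    study = synthetic.simulate_study(small_config, out_dir=tmp_path)
    pd.testing.assert_frame_equal(synthetic.read_cohort(tmp_path / "cohort.tsv"),
                                  study["cohort"])
    pd.testing.assert_frame_equal(synthetic.read_alterations(tmp_path / "alterations.tsv"),
                                  study["alterations"])
    edges = synthetic.read_network_edges(tmp_path / "network_edges.tsv")
    assert len(edges) == study["network"].number_of_edges()
    for row in edges.itertuples(index=False):
        assert study["network"][row.gene_a][row.gene_b]["confidence"] == row.confidence
    assert synthetic.read_consensus(tmp_path / "consensus.tsv") == study["consensus"]
    pd.testing.assert_frame_equal(
        synthetic.read_expression_rppa(tmp_path / "expression_rppa.tsv"), study["rppa"])
    pd.testing.assert_frame_equal(
        synthetic.read_expression_ihc(tmp_path / "expression_ihc.tsv"), study["ihc"])
    pd.testing.assert_frame_equal(
        synthetic.read_dependency(tmp_path / "dependency.tsv"), study["dependency"],
        check_names=False)
    pd.testing.assert_frame_equal(
        synthetic.read_cell_lines(tmp_path / "cell_lines.tsv"), study["cell_lines"])
    pd.testing.assert_frame_equal(synthetic.read_pdx(tmp_path / "pdx.tsv"), study["pdx"])


def test_generators_are_pure_functions_of_config(small_config, tmp_path):
    a = synthetic.simulate_study(small_config, out_dir=tmp_path / "a")
    b = synthetic.simulate_study(small_config, out_dir=tmp_path / "b")
    for name in ("cohort.tsv", "alterations.tsv", "network_edges.tsv", "dependency.tsv",
                 "expression_rppa.tsv", "pdx.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
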