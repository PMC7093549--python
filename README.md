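# essentialomics

Multi-evidence essentiality scoring for cancer genes. Four independently
computed evidence layers — genomic alteration burden, protein–protein
interactome hubness with consensus priors, protein-expression extremity
and tumor/normal discordance, and loss-of-function dependency screens
confirmed in patient-derived xenografts — are integrated by counting, per
gene, how many layers select it. The per-gene output is an evidence tier
in {0..4}; tier ≥ 3 genes are the high-confidence essential set.

The package is aimed at computational cancer-biology groups who work with
tabular exports of these modalities (alteration event tables, weighted
interaction edge lists with per-gene priors, protein Z-scores and IHC
levels, gene × cell-line dependency matrices, xenograft Z-scores) and want
a tested, deterministic implementation of the evidence-counting strategy —
plus a synthetic study generator with planted essential genes so the whole
pipeline can be exercised and validated without consortium downloads.

## The method in brief

For a gene panel *G* and per-sample event table *E*:

* **Approach 1 (alterations):** after discarding passenger mutations, gene
  *g* is selected iff its event total *n(g)* > mean over the panel.
  Group summaries are events per sample: ratio(group) = events among the
  group's samples / group size; group differences use pairwise two-sided
  Mann–Whitney U with Bonferroni adjustment (p_adj = min(1, m·p)).
* **Approach 2 (network):** edges with confidence ≥ 0.9 and both endpoints
  in the panel form graph *N*; gene *g* is selected iff deg(g) > mean
  degree of *N* **and** consensus(g) > mean consensus, with degree the raw
  edge count.
* **Approach 3 (expression):** selected iff aggregate Z ≥ 2 or Z ≤ −2
  (cohort-mean aggregation for replicate input), or iff IHC levels are
  discordant between tumor and normal tissue (expressed = high/medium vs
  not expressed = low/not-detected, either direction).
* **Approach 4 (dependencies):** on the calibrated dependency scale
  (0 = no effect, −1 = common-essential median), candidates are the union
  of *common-essential* genes (top 25% most-depleting rank in ≥ 90% of
  pan-cancer lines) and *strongly selective* genes (skew-normal vs normal
  maximum-likelihood ratio ≥ 100), kept iff at least one xenograft model
  shows |Z| ≥ 2.

Pathway-level summaries (hypergeometric enrichment with Benjamini–Hochberg
FDR < 0.01, per-group alteration burden) sit alongside approach 1.
`docs/methods.md` documents every rule, default, numerical choice and the
generator's scope.

## Worked example

```python
import json
from essentialomics import SimulationConfig, run_pipeline

cfg = SimulationConfig(seed=7)          # 100 genes, 10 planted essential
res = run_pipeline(cfg)
print("tiers:", json.dumps(res.tiers["exact"]), "total:", res.tiers["total"])
print("sets:", {k: len(v) for k, v in res.approach_sets.items()})
```

prints

```
tiers: {"1": 12, "2": 0, "3": 1, "4": 9} total: 22
sets: {'genomic_alterations': 10, 'ppi_network': 21, 'protein_expression': 10, 'dependency_pdx': 10}
```

Read: 22 genes were selected by at least one approach. The 10 planted
essential genes all reach tier ≥ 3 (9 pass all four approaches, 1 passes
three) — the planted alteration-rate ratio (6×), hub boost (5×), |Z| shift
(4) and dependency shift (−1) are all individually detectable, so the
evidence count concentrates on the planted set. The 12 tier-1 genes are
background genes that crossed a single approach's above-average or chance
threshold; no background gene assembles three approvals. The ledger itself
(`res.ledger`) lists each gene with the approaches it passed:

```
gene                                                 approaches_passed  n_approaches   tier
G000 genomic_alterations,ppi_network,protein_expression,dependency_pdx             4 tier_4
...
```

The same run from a shell, writing `ledger.tsv`, `tiers.json` and a
manifest (config hash, seed, thresholds):

```sh
essentialomics all --seed 7 --out out/
```

Individual stages are exposed as `essentialomics simulate | alterations |
pathways | network | expression | dependency | integrate` over TSV inputs.

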