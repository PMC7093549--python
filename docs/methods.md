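# Methods

## Overview

`essentialomics` scores cancer genes for essentiality by counting how many
of four independent evidence layers ("approaches") select them. Each
approach has its own selection rule over a different data modality; the
integration step is deliberately simple — a Venn classification — so the
per-gene output is an evidence tier in {0..4}. Genes in tier ≥ 3 are the
high-confidence essential set. The package also ships a synthetic study
generator so that every stage, and the composite behavior of the whole
pipeline, can be tested without consortium downloads.

## The four approaches

**1. Genomic alterations.** Input is a per-sample event table: one row per
(sample, gene, alteration category), categories being mRNA up/down
regulation, CNV amplification, CNV deep deletion, mutation and fusion.
Mutation rows carry a pre-annotated driver/passenger flag; passenger
mutations are discarded before summarizing (the pipeline consumes driver
status, it never infers it). The selection rule is above-average burden:
a gene is selected when its total event count strictly exceeds the panel
mean. Strict inequality means a flat count profile selects nothing.
Group summaries (per molecular subtype, per tumor stage) are events per
sample — event count among a group's samples divided by the group's sample
count. A group with zero samples is reported as undefined, never as 0.
Pairwise group differences are tested with two-sided Mann–Whitney U and
Bonferroni adjustment over the number of tested pairs; counts of genomic
events are skewed, so a rank test is the robust default.

Counting conventions: summarizers count event rows exactly as given
(linearity), and the pipeline applies an explicit dedupe step first so a
sample counts once per (gene, category). Samples with unknown subtype or
stage are excluded from grouped summaries but retained in cohort-wide
ones.

**2. Interactome hubness.** A confidence-weighted edge list is thresholded
at an inclusive cutoff (default 0.9, the "highest confidence" convention
of interaction databases) with zero node addition: edges touching genes
outside the allowed panel are dropped. Degree is the raw edge count, not
the normalized centrality, matching the magnitudes such analyses report.
Each gene also has an externally supplied consensus prior in [0, 1]
(consumed, never computed here). The selection rule mirrors approach 1:
strictly above the network mean degree AND strictly above the network mean
consensus. Published hub selections of this kind rarely state their exact
rule; the above-both-means convention is the package's documented choice
and both thresholds are returned with the selection. An overlap check
against an experimentally derived reference network reports shared
nodes/edges and the Spearman correlation of degree vectors on shared nodes
(undefined below three shared nodes).

**3. Protein expression.** Two rules, united: (a) Z-score extremity — one
aggregate Z per protein, selected when Z ≥ 2 (high) or Z ≤ −2 (low), both
boundaries inclusive; (b) immunohistochemistry discordance — expressed
(high/medium) in one tissue and not expressed (low/not-detected) in the
other, in either direction. When replicate per-sample Z-scores are
supplied, the per-protein aggregate is the cohort mean (median and
max-|z| are selectable). The mean is the package's default because it is
the least surprising aggregate and because a per-protein mean over even a
modest cohort makes chance selection at |Z| ≥ 2 essentially impossible —
which is what separates signal from noise in the integrated tier (see
"Composite behavior" below). Rule provenance (which of the four sub-rules
fired) is kept per protein.

**4. Dependency screens + xenograft confirmation.** Dependency scores are
on the calibrated scale where 0 means no effect of knocking the gene down
and −1 is the median effect over known common-essential genes. A
substantial dependency is a (gene, line) score ≤ −1 (inclusive). Two gene
classes are computed on the pan-cancer matrix:

* *common essential*: ranked within the top `top_fraction` (default 0.25)
  most-depleting genes in at least 90% of lines. The fraction is
  configurable because the upstream convention leaves it unstated.
* *strongly selective*: the gene's score vector is ≥ 100× more likely
  under a skew-normal than under a normal maximum-likelihood fit. This is
  a skew-normal simplification of the skew-t likelihood-ratio criterion
  used by dependency portals: nearly the same decision boundary at desk
  scale, with a far cheaper and more robust fit. The skew-normal
  log-likelihood is maximized with L-BFGS over (shape, location,
  log-scale) from a method-of-moments start, with the nested normal
  solution as a second start so the fitted likelihood can never fall below
  the normal one (LR ≥ 1 by construction). Constant vectors and failed
  fits are flagged `unclassified`, never silently dropped.

Candidates (union of the two classes) are confirmed by patient-derived
xenograft protein expression: kept only with |Z| ≥ 2 in at least one
model. Candidates never measured in the PDX resource are excluded —
evidence must be positive, not merely absent — and logged distinctly from
"measured but not significant".

**Pathway analysis** (not one of the four approaches, but part of the
alteration summaries): over-representation of the panel in each pathway by
the hypergeometric upper tail with Benjamini–Hochberg control at q < 0.01,
and per-(pathway, group) alteration burden defined as events in member
genes per sample. A gene in k pathways contributes to all k — pathway
burdens deliberately double-count, as pathway-level tallies of this kind
do. An EASE-style offset (subtract one from the overlap) is available but
off by default; the plain hypergeometric tail is the reproducible closed
form.

## Integration

Gene identity is the uppercased symbol string; no alias resolution. The
ledger records, per gene selected anywhere, which approaches passed; the
tier is the count. Ordering is (descending tier, gene symbol) so output is
deterministic. Region counts (exactly k approaches) and cumulative counts
(≥ k) are reported; percentages in human-readable reports are rounded half
away from zero (65/73 → 89%), with exact fractions kept in machine output.
Ratios per cell-line subtype are additionally reported at one decimal,
matching the presentation convention of the source analyses.

## The synthetic study generator

The generator emulates the statistical structure the pipeline assumes,
with planted essential genes carrying effects in all four layers:

* **Cohort**: each sample draws one molecular subtype and one tumor stage
  i.i.d. from configured proportions. Defaults are the reference cohort
  composition (subtype counts 499/197/171/78/36, stage counts
  255/586/113/103, rescaled).
* **Alterations**: Bernoulli per (sample, gene, category) with rates keyed
  by (gene class, subtype, category); independent across categories —
  co-occurrence is not modelled because the summarizers under test are
  linear in events. Defaults: background 0.05, planted 0.30 per category
  (a 6× burden ratio). Driver flags are assigned at generation time with
  probability 0.5.
* **Network**: pairwise edges with background probability 0.2, boosted 5×
  for pairs touching a planted hub (capped at 1); confidences uniform on
  [0.5, 1.0], so about a fifth of generated edges survive the 0.9 cutoff;
  consensus scores Beta(8, 2) (mean 0.8, near the reported whole-network
  average), with planted hubs pulled toward 0.95 at configurable strength
  (default 0.6).
* **Expression**: 20 standard-normal replicate Z-scores per protein;
  planted proteins shifted by ±4 (sign drawn once per protein). IHC levels
  are concordant between tissues unless discordance is planted explicitly;
  the background discordance rate defaults to 0 because in this design
  discordance is a planted signal, not an emergent one.
* **Dependency screen**: 33 breast lines (8/5/8/12 across four subtypes)
  plus 40 pan-cancer background lines; background scores Normal(0, 0.2);
  planted common-essential genes shifted by −1 in every line (median at
  the common-essential calibration point), planted strongly selective
  genes shifted only in one configured subtype. PDX Z-scores mirror the
  expression layer with a ±4 planted shift over 8 models.

One integer seed drives everything through named sub-streams
(`SeedSequence(seed, spawn_key=(k,))` with a fixed index per generator),
so every generator is a pure function of its configuration, regenerating
one table never perturbs another, and a rerun is byte-identical.

What the generator does **not** emulate: alteration co-occurrence and
mutual exclusivity, copy-number segment structure, network modularity or
degree-distribution heavy tails beyond the planted hubs, batch effects and
missingness in expression data, and screen-specific artifacts (seed
effects, copy-number confounding). Passing tests therefore demonstrate
that the summarization, selection and integration logic is correct and
that the pipeline separates planted signal from i.i.d. noise — not that
the thresholds are optimal for any real cohort.

## Composite behavior

With the default (strong-effect) configuration, planted genes pass all
four approaches with high probability, and the recovery experiment —
fraction of planted genes in tier ≥ 3, averaged over 20 seeds — sits at
or near 1. Under the matched null configuration (`null_copy()`: rate ratio
1, no hub boost, zero consensus correlation, zero Z and dependency shifts)
tier ≥ 3 is empty in ≥ 95% of seeds. The null behavior is driven by the
design of approach 3 and 4 null rates: a cohort-mean Z at |Z| ≥ 2 and a
rank-based common-essential rule are both vanishingly improbable under the
null, so no gene can assemble three approvals even though the above-mean
rules of approaches 1 and 2 select ~50%/~25% of genes by chance. Problem
sizes for this experiment are the generator defaults: 100 genes (10
planted), 150 samples, 73 cell lines, 20 replicate Z-scores, 8 PDX
models, 20 seeds per condition.

## Numerical choices and degenerate inputs

* Threshold boundaries are inclusive everywhere a published rule prints
  one (confidence ≥ 0.9, |Z| ≥ 2, score ≤ −1, LR ≥ 100).
* Rank ties in the common-essential rule use minimum rank; ranking ties in
  pathway ordering break lexicographically by identifier.
* `round_half_away` implements arithmetic rounding (ties away from zero)
  because report percentages use that convention; Python's built-in
  banker's rounding would print 15.668% as 16 but 12.5% as 12.
* Bonferroni m is the number of *tested* pairs; pairs with a group of
  fewer than two values appear as flagged skip rows and do not inflate m.
* Identical group vectors short-circuit to p = 1 (no location evidence).
* Zero-sample groups, zero-event groups, proteins missing a tissue,
  unmeasured PDX candidates and unclassifiable score vectors are all
  reported as flagged/undefined rather than silently dropped or zeroed.
* TSV IO writes floats at 17 significant digits and reads with
  round-trip float parsing, so all tables round-trip losslessly.

## Limitations

The evidence-counting integration treats approaches as exchangeable and
independent; it has no notion of effect size beyond each approach's own
threshold, and a gene narrowly missing two thresholds scores lower than a
gene barely passing one. The above-mean selection rules of approaches 1
and 2 adapt to the panel, so tier membership is panel-relative. The
skew-normal LR classifier can flag heavy-tailed symmetric score vectors at
small line counts; the ≥ 20-line precondition limits but does not remove
this. Real-data headline gene lists depend on specific consortium exports
and are not reproducible from this package; what is reproducible is every
arithmetic worked example those analyses print, and the statistical
behavior of the method under a known ground truth.
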