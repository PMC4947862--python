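# Methods and numerical conventions

This document records the exact definitions, default parameters, and
numerical conventions used throughout `sappred`, plus the scope of the
synthetic-data generator and the known limitations.

## GO.BP multifunctionality (`sappred.ontology`)

**Ontology model.** Terms form a DAG over `is_a` edges; only the
`biological_process` namespace enters the count. Obsolete terms and edges to
unknown terms are dropped at parse time (`parse_obo`, built on `obonet`).

**True-path propagation.** A gene annotated to term *t* is implicitly
annotated to every ancestor of *t*. `propagate_annotations` closes each
gene's direct term set under ancestry; evidence codes are ignored (IEA
included).

**Information content.** Over the propagated corpus with *N* annotated
genes, `IC(t) = −ln(n_t / N)` in nats, where `n_t` counts genes whose
propagated set contains *t*. Consequences verified by tests: the root has
IC exactly 0 (a `+0.0` guard avoids `−0.0`), and IC is anti-monotone along
`is_a` edges. Terms with `n_t = 0` get no IC entry.

**The count.** For a gene's *direct* BP annotations:

1. *IC filter*: keep terms with `IC ≥ ic_threshold` (default **2.0 nats**,
   boundary inclusive), i.e. terms annotating at most `N·e^−2 ≈ 13.5 %` of
   genes.
2. *Child collapse*: drop any surviving term that has a proper ancestor
   among the surviving terms.

The count is the number of remaining terms. The order is semantic, not
incidental: filtering first lets two specific siblings survive the removal
of their generic parent, whereas collapsing first would merge them into it
(`examples/01_multifunctionality.py` shows a corpus where the two orders
give 3 vs 2). `go_bp_delta(gene, old, new, …)` evaluates the count in each
release with that release's own IC table and returns the difference.

## Benchmark assembly (`sappred.datasets`)

* SAP identity is `gene:protein-position:ref>alt` at the amino-acid level;
  nucleotide records collapsing to one SAP are de-duplicated keeping the
  maximum allele frequency.
* **Pathogenic filter**: disease-flagged, missense (reference ≠ alternate
  residue, both canonical), autosomal (X/Y excluded), allele frequency
  `< 0.01` (missing AF allowed).
* **Benign filter**: population variants with AF `≥ 0.01`, not
  disease-flagged, missense, autosomal.
* **Circularity removal**: type 1 removes SAPs present in an external
  predictor's training variants; type 2 removes all SAPs of genes present in
  its training genes.
* **Gene-aware resampling**: `gene_aware_split` shuffles genes with a seeded
  `numpy` generator and accumulates whole genes until the SAP fraction
  reaches the target (default **0.9**); the achieved fraction is stored in
  `DataFrame.attrs["achieved_train_fraction"]`. `gene_aware_folds` deals
  whole genes to `k` folds greedily by current fold size. No gene ever
  straddles a boundary.

## Features (`sappred.features`)

A fixed registry of 28 features: variant-level predictor scores (PON-P2,
PROVEAN, SIFT, GERP, conservation/structure descriptors), substitution
properties (Grantham distance, five AAindex deltas, Kyte–Doolittle
hydropathy), and gene-level features broadcast to all of a gene's SAPs
(GO.BP, expression breadth above a data-derived threshold, protein-network
degree/betweenness/closeness from a confidence-filtered interaction graph
via `networkx`, paralog and ortholog counts, gene/protein length, protein
age). Each oriented feature records whether **higher** or **lower** values
indicate pathogenicity; raw scores are sign-flipped accordingly before
ranking-based evaluation. `complete_cases` drops SAPs with missing values
and reports per-feature missingness.

## Feature clustering (`sappred.clustering`)

Pairwise-complete Pearson correlations, distance `1 − |r|`, average-linkage
hierarchical clustering (`scipy.cluster.hierarchy`), and the mean silhouette
width computed on the precomputed distance matrix. `optimal_clustering`
scans `k = 2 … n−1` and keeps the maximising `k` (smallest `k` on ties).
Features with zero variance are rejected rather than silently dropped.

## Forward selection (`sappred.selection`)

Repeated gene-aware 5-fold cross-validation. Within each training fold a
ranker orders the candidate features:

* `logistic`: features enter greedily by the decrease in deviance of a
  logistic model (IRLS; an L2-ridged step is substituted automatically when
  quasi-separation makes the Hessian ill-conditioned);
* `random_forest`: permutation-style importance from
  `sklearn.ensemble.RandomForestClassifier` with subsampling
  (`n_estimators`, `max_samples` are runtime-scaling knobs).

Each prefix of the fold's ranking (up to `max_steps`) is refit on the
training fold and scored by misclassification on the held-out fold. The
trace aggregates over `iterations × k` evaluations: per-step selection
frequencies, mean and SD of test error. `choose_prefix` applies the
**one-standard-error rule**: the shortest prefix whose mean error is within
`sd_min / √n_eval` of the minimum, where `n_eval = iterations × k`.

The three predictive feature sets are nested logistic models:
PFS1 (gene-level only) ⊂ PFS2 (+ strongest predictor scores) ⊂ PFS3 (all
selected features).

## Evaluation (`sappred.evaluate`)

* **AUC** uses midranks (`scipy.stats.rankdata`), handling ties as ½; tests
  verify the identity with explicit pair counting and with the trapezoidal
  area under the empirical ROC to 1e-10.
* **Classification rule**: score ≥ cutoff ⇒ pathogenic.
* **MCC-optimal cutoff**: exhaustive scan over all distinct scores plus a
  sentinel above the maximum; ties broken toward the smallest cutoff.
  Degenerate confusion matrices give MCC = NaN by convention.
* **Sensitivity at fixed specificity** walks the empirical ROC and takes the
  last operating point with specificity ≥ the target (step convention, no
  interpolation); the default pipeline target is 0.86.
* **Paired bootstrap AUC test**: class-stratified resampling of the shared
  index for both score vectors, difference `d` of original AUCs scaled by
  the bootstrap SD `s` of the difference, two-sided
  `p = 2·(1 − Φ(|d|/s))`. Identical score vectors short-circuit to `p = 1`.
* `evaluation_report` ranks classifiers by AUC and tests each against the
  next best.

## Downstream analyses (`sappred.downstream`)

* **Difficult SAPs**: intersection of all compared methods' false-positive
  (respectively false-negative) sets at their MCC-optimal cutoffs; the full
  Venn partition over methods is reported alongside.
* **Rescue fractions**: for each method, the share of its errors that no
  other method gets right.
* **Gene FN excess**: genes flagged when their false-negative count exceeds
  the binomial upper tail at the expected FN rate (default 0.05).
* **Annotation bias**: genes grouped by first disease report (early / late
  / never); per-gene GO.BP growth between two releases compared between
  groups with a **one-sided pooled-variance Student t-test**
  (`group_a > group_b`).

## Synthetic-data generator (`sappred.simulate`)

No benchmark data ship with the package; the generator produces every input
with planted ground truth. Defaults
(`SimulationConfig`): 150 disease + 150 neutral genes, zero-truncated
Poisson(5) variants per gene, ontology of 200 terms / depth 5 with 10 %
extra edges, neutral genes averaging 2 specific annotations and disease
genes targeting a 3× GO.BP ratio, feature shifts sized to reproduce the
published single-score ordering (PON-P2 2.2 > PROVEAN 1.65 > SIFT 1.5
standardised units), a conservation block (ρ = 0.45) and a tight
polarity–hydropathy pair (ρ = 0.85), 2 % missingness, optional
filter-violating contaminants, and release growth rates of 2.2 / 2.0 / 0.5
new specific terms per gene for early-disease / late-disease /
never-implicated genes. `planted_matrix` builds the pure feature-selection
testbed (informative Gaussian shifts + noise features, gene-blocked).

**Scope**: the generator emulates the *statistical structure* the analysis
assumes (class-conditional shifts, correlation blocks, gene-level constancy,
annotation growth differentials) — it does not emulate protein biology,
sequence context, or real GO term semantics. Conclusions drawn from it
concern the correctness and power of the *methods*, not biology.

## Pipeline (`sappred.pipeline`)

Eight stages — simulate → gobp / split / cluster → select → evaluate →
difficult / bias — with declared dependencies checked at run time. Full
scale defaults: 5 folds, 300 logistic / 100 forest selection iterations,
500 trees, 5000 bootstrap replicates. `RunConfig.desk_scale` substitutes
laptop-friendly values (10/5 iterations, 30 trees at `max_samples` 0.5,
500 bootstrap replicates, 6 selection steps); these desk-scale sizes are
this package's own choice of a fast default, not a claim about the original
study's compute. Outputs are TSV/JSON with fixed float formatting; the
manifest lists each file's SHA-256 and a hash of the configuration
(excluding the output directory path), so reruns of the same configuration
are byte-identical, manifest included. The `sappred` CLI exposes `run-all`
and one command per stage.

## Limitations

* All quantitative results in this repository are on synthetic cohorts; the
  planted effect sizes make the combined classifiers stronger (AUC ≥ 0.98
  at desk scale) than the corresponding real-data figures.
* The GO.BP count depends on the direct-annotation sets; corpora that
  pre-propagate annotations will inflate counts unless collapsed first.
* The bootstrap AUC test uses a normal approximation to the bootstrap
  distribution of the difference; at very small validation sets
  (≲ 50 SAPs per class) its type-I error is only approximately calibrated.
* The pooled t-test for annotation bias assumes comparable within-group
  variances; groups with very different sizes and variances would warrant a
  Welch variant.
* `gene_aware_split` hits the target fraction only as closely as whole-gene
  granularity allows; with few genes the achieved fraction can deviate by
  several percentage points.
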