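# sappred

Gene-feature-aware pathogenicity analysis of single amino acid polymorphisms
(SAPs): Gene Ontology multifunctionality as a gene-level feature, leakage-free
benchmark assembly, gene-aware cross-validated forward feature selection, and
head-to-head classifier evaluation with difficult-variant and
annotation-bias downstream analyses.

## Scientific background

Most missense-variant pathogenicity predictors score the *variant*: how
conserved the position is, how different the substituted residue is, whether
the site is buried or disordered. `sappred` is built around the observation
that the *gene* carries signal too. Genes already implicated in disease tend
to be multifunctional — annotated to many distinct biological processes — and
a simple count of a gene's distinct GO biological-process annotations
(**GO.BP**) is a useful pathogenicity feature on its own and in combination
with variant-level scores.

The package implements that idea end to end:

1. **GO.BP multifunctionality** (`sappred.ontology`). Parse an OBO ontology,
   propagate annotations along the true-path rule, compute per-term
   information content `IC(t) = −ln(n_t / N)` in nats, then count a gene's
   distinct processes in two steps: drop terms with `IC < 2.0` (too generic),
   and drop terms that still have a surviving ancestor among the gene's own
   terms (so a term and its specialisation count once). The order matters —
   filtering by IC *before* collapsing lets specific terms survive the
   removal of a generic parent (see `examples/01_multifunctionality.py`).
   `go_bp_delta` computes the change in the count between two annotation
   releases, using each release's own IC table.
2. **Benchmark assembly** (`sappred.datasets`). Filter raw variant records
   into pathogenic (disease-flagged, allele frequency < 0.01, autosomal,
   missense) and benign (population variants with AF ≥ 0.01, not
   disease-flagged) SAP sets, de-duplicate nucleotide variants to amino-acid
   level, remove two kinds of circularity against external predictors'
   training data (shared variants, and shared genes), and build train/test
   splits and k-folds that always keep all SAPs of a gene on one side.
3. **Feature table** (`sappred.features`). A fixed registry of 28 features —
   variant-level predictor scores and substitution properties, plus
   gene-level features (GO.BP, expression breadth, protein-network degree /
   betweenness / closeness, homolog counts) broadcast to each gene's SAPs.
4. **Feature structure** (`sappred.clustering`). Hierarchical clustering of
   features under the `1 − |r|` distance with average linkage, cut at the
   silhouette-optimal number of clusters.
5. **Feature selection** (`sappred.selection`). Repeated gene-aware 5-fold
   cross-validated forward selection with a logistic or random-forest
   ranker, and a one-standard-error rule to choose the final prefix. Three
   nested predictive feature sets (PFS1 ⊂ PFS2 ⊂ PFS3) are fit as logistic
   models.
6. **Evaluation** (`sappred.evaluate`). Midrank (tie-aware) AUC, ROC,
   MCC-optimal cutoffs found exhaustively, sensitivity at fixed specificity,
   and a paired class-stratified bootstrap test for AUC differences.
7. **Downstream analyses** (`sappred.downstream`). Difficult SAPs
   (misclassified by *every* compared method) via error-set intersection with
   full Venn partitions; genes with excess false negatives; and an
   annotation-growth bias test comparing GO.BP gains between gene groups
   across two ontology releases with one-sided pooled t-tests.
8. **Synthetic data** (`sappred.simulate`). A fully seeded generator for
   ontologies, annotation corpora, release pairs, variant tables and feature
   matrices with planted class effects, correlation blocks, missingness and
   filter-violating contaminants — every analysis in the package can be
   exercised, and checked against ground truth, without any external data.
9. **Pipeline** (`sappred.pipeline`, `sappred.cli`). Eight stages (simulate,
   gobp, split, cluster, select, evaluate, difficult, bias) with explicit
   dependencies, deterministic per-stage seeds, and a SHA-256 manifest that
   is byte-identical across reruns of the same configuration.

## Worked example

`examples/07_full_pipeline.py` runs the whole analysis twice at desk scale on
simulated data and prints (actual output):

```
validation ranking:
classifier   auc   mcc
      PFS2 0.987 0.927
      PFS3 0.984 0.927
    PON-P2 0.906 0.791
   PROVEAN 0.862 0.647
      PFS1 0.836 0.660
      SIFT 0.814 0.605

selected feature sets (stage 'all'):
  logistic: ['PON-P2', 'GO.BP', 'SIFT', 'GERP']
  random_forest: ['PON-P2', 'GO.BP', 'PROVEAN', 'SIFT', 'AAindex.hydropathy']

manifests byte-identical across reruns: True
```

Both rankers put the strongest variant-level predictor first and the
gene-level GO.BP count second — the combination of variant and gene signal is
exactly what the combined feature sets (PFS2/PFS3) exploit to beat every
single predictor. The same run from the command line:

```sh
sappred run-all --out runs/demo --seed 42
sappred gobp --out runs/demo          # re-run a single stage
```

The other examples are self-contained narrative scripts:

| script | shows |
| --- | --- |
| `examples/01_multifunctionality.py` | the GO.BP count step by step, and why IC filtering precedes child collapse |
| `examples/02_benchmark_assembly.py` | variant filters, circularity removal, gene-aware splitting |
| `examples/03_feature_structure.py` | recovery of planted correlation blocks by clustering |
| `examples/04_forward_selection.py` | recovery of planted informative features and the 1-SE stop |
| `examples/05_evaluation.py` | AUC ranking with bootstrap comparisons and error-set rescue analysis |
| `examples/06_annotation_bias.py` | detection of differential annotation growth between gene groups |

For instance, `examples/04_forward_selection.py` prints:

```
per-step cross-validation error (mean over iterations x folds):
 step feature  selection_frequency  mean_test_error  sd_test_error
    1    inf1               1.0000           0.1856         0.0096
    2    inf2               0.9800           0.1537         0.0091
    3    inf3               0.9800           0.1330         0.0080
    4  noise8               0.2600           0.1338         0.0081
    5  noise8               0.2800           0.1341         0.0082
    6  noise3               0.2000           0.1343         0.0082

selected prefix (1-SE rule): ('inf1', 'inf2', 'inf3')
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds twelve property-based end-to-end checks
(oracle equivalence of the GO.BP count on random ontologies, IC laws,
leakage-free resampling, AUC identities, exhaustive-search equivalence of the
MCC cutoff, planted-structure recovery for clustering and forward selection,
agreement of a single-feature classifier with Gaussian theory, type-I error
calibration of both significance tests, power of the bias analysis,
brute-force equivalence of the difficult-SAP sets, and byte-identical
pipeline reruns). The rest of the suite covers each module with
hand-computed cases and independent brute-force oracles (`tests/oracles.py`).

## Reproduction

`scripts/acceptance.py` runs the full pipeline at desk scale on simulated
data and writes the headline quantities (dataset sizes, GO.BP group means,
achieved split fraction, clustering summary, per-classifier AUC / MCC /
sensitivity-at-specificity, difficult-SAP counts, bias-test statistics) to a
JSON file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Each entry is `{"name": {"value": <float>, "n": <sample size>}}`. The run is
fully determined by the seed; it takes about 90 seconds on one CPU core.

## Layout

```
src/sappred/        library (ontology, datasets, features, clustering,
                    selection, evaluate, downstream, simulate, pipeline, cli)
tests/              pytest suite + independent oracles
examples/           runnable narrative scripts (01–07)
scripts/            acceptance.py reproduction script
docs/methods.md     parameter reference and numerical conventions
```
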