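"""Synthetic data with the statistical structure the analysis assumes.

No benchmark dataset is distributed with this package (the real pathogenic
sets derive from licensed databases), so every pipeline input is generated
here: an ontology DAG with annotations for two releases, a variant table with
selection-filter contaminants, and a 28-feature matrix with class-conditional
shifts, correlated feature blocks, gene-level constancy, and missing values.

The generator's defaults emulate the structure reported for the real data:

* genes of pathogenic variants carry about three times the GO.BP
  multifunctionality of benign-variant genes;
* conservation-related scores form one correlated block, the polarity and
  hydropathy amino-acid indices another, tighter one;
* class-conditional Gaussian shifts are sized so that the single-score AUCs
  of the strong external predictors fall in the high-0.8s to mid-0.9s with
  the published ordering (PON-P2 > PROVEAN > SIFT);
* between two annotation releases, annotation growth differs by gene group
  (disease genes grow faster than never-implicated genes).

Everything is driven by one seed; identical configurations give identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (FEATURE_NAMES, GENE_LEVEL_FEATURES, HIGHER_PATHOGENIC,
                       LOWER_PATHOGENIC, ORIENTATION)
from .ontology import BP, AnnotationCorpus, OntologyDAG, OntologyTerm, compute_ic, go_bp_count, write_obo

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: class-conditional location shifts (standardised scales) in the pathogenic
#: direction of each feature's orientation; unoriented features get noise-only
#: defaults.  GO.BP is absent: it is generated mechanistically from the
#: ontology/annotation simulators.
DEFAULT_EFFECTS: dict[str, float] = {
    "PON-P2": 2.2,
    "PROVEAN": 1.65,
    "SIFT": 1.5,
    "GERP": 1.0,
    "evolutionary.rate": 1.1,
    "disordered.region": 0.6,
    "Grantham": 0.5,
    "accessibility": 0.4,
    "AAindex.polarity": 0.35,
    "AAindex.hydropathy": 0.3,
    "AAindex.volume": 0.25,
    "AAindex.composition": 0.2,
    "AAindex.net.charge": 0.2,
    "protein.age": 0.3,
    "degree": 0.3,
    "centrality": 0.2,
    "betweenness": 0.2,
    "paralog.id": 0.1,
    "paralog.nr": 0.1,
    "mouse.orth.id": 0.0,
    "mouse.orth.nr": 0.0,
    "expression": 0.0,
    "gene.length": 0.0,
    "protein.length": 0.0,
}

#: correlated feature blocks (shared latent factor) with within-block
#: correlation of the noise component
DEFAULT_BLOCKS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("SIFT", "PROVEAN", "GERP", "PON-P2", "evolutionary.rate",
      "disordered.region", "accessibility"), 0.45),
    (("AAindex.polarity", "AAindex.hydropathy"), 0.85),
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the seed fixes every draw."""

    seed: int = 0
    n_disease_genes: int = 150
    n_neutral_genes: int = 150
    variants_per_gene_mean: float = 5.0      # zero-truncated Poisson
    benign_in_disease_fraction: float = 0.1  # disease genes also hosting benign SAPs
    contaminant_rate: float = 0.0            # filter-violating records per clean record
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    blocks: tuple = DEFAULT_BLOCKS
    missing_rate: float = 0.02
    # ontology shape
    n_terms: int = 200
    depth: int = 5
    extra_edge_prob: float = 0.1
    # annotations
    neutral_terms_mean: float = 2.0
    gobp_ratio_target: float = 3.0
    ic_threshold: float = 2.0
    # release growth: mean newly added specific terms per gene and period
    growth_rates: dict[str, float] = field(default_factory=lambda: {
        "group1": 2.2, "group2": 2.0, "group3": 0.5})

    def validate(self) -> None:
        for name, val in (("benign_in_disease_fraction", self.benign_in_disease_fraction),
                          ("missing_rate", self.missing_rate),
                          ("extra_edge_prob", self.extra_edge_prob)):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_terms < self.depth:
            raise ValueError("n_terms must be >= depth")


def _zt_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (resample zeros)."""
    out = rng.poisson(mean, size)
    while np.any(out == 0):
        zeros = out == 0
        out[zeros] = rng.poisson(mean, int(zeros.sum()))
    return out


# ---------------------------------------------------------------------------
# Ontology and annotations
# ---------------------------------------------------------------------------

def simulate_ontology(config: SimulationConfig, rng: np.random.Generator | None = None) -> OntologyDAG:
    """Rooted random biological-process DAG.

    Terms are laid out in levels under a single root; each non-root term gets
    one parent in the previous level plus, with ``extra_edge_prob``, an extra
    is_a parent from any strictly shallower level (acyclic by construction).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, depth = config.n_terms, config.depth
    ids = [f"SGO:{i:07d}" for i in range(n)]
    levels = np.zeros(n, dtype=int)
    if depth >= 1 and n > 1:
        levels[1:] = rng.integers(1, depth + 1, n - 1)
        levels[1:] = np.sort(levels[1:])
    terms: dict[str, OntologyTerm] = {}
    for i, tid in enumerate(ids):
        if i == 0:
            terms[tid] = OntologyTerm(tid, "root process", BP)
            continue
        shallower = [j for j in range(i) if levels[j] < levels[i]]
        if not shallower:
            shallower = [0]
        parents = {ids[int(rng.choice(shallower))]}
        if rng.random() < config.extra_edge_prob and len(shallower) > 1:
            parents.add(ids[int(rng.choice(shallower))])
        terms[tid] = OntologyTerm(tid, f"process {i}", BP, frozenset(parents))
    return OntologyDAG(terms)


def _term_levels(dag: OntologyDAG) -> dict[str, int]:
    levels: dict[str, int] = {}

    def level(t: str) -> int:
        if t not in levels:
            parents = dag.terms[t].parent_ids
            levels[t] = 0 if not parents else 1 + max(level(p) for p in parents)
        return levels[t]

    for t in dag.terms:
        level(t)
    return levels


def simulate_annotations(
    dag: OntologyDAG,
    disease_genes: list[str],
    neutral_genes: list[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> AnnotationCorpus:
    """Direct annotations with a planted multifunctionality ratio.

    Genes draw direct terms preferentially from deep (specific) levels;
    disease genes draw more than neutral genes.  A short calibration loop
    adjusts the disease-gene intensity so the realised mean GO.BP ratio
    (disease / neutral) approximates ``gobp_ratio_target``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    levels = _term_levels(dag)
    max_level = max(levels.values()) if levels else 0
    term_ids = sorted(dag.terms)
    # sampling weights favour deep, specific terms
    weights = np.array([1.0 + 2.0 * levels[t] / max(max_level, 1) for t in term_ids])
    weights /= weights.sum()

    def draw_corpus(disease_mean: float, loop_rng: np.random.Generator) -> AnnotationCorpus:
        corpus = AnnotationCorpus(release_label="release-old")
        for genes, mean in ((neutral_genes, config.neutral_terms_mean),
                            (disease_genes, disease_mean)):
            for g in genes:
                k = int(loop_rng.poisson(mean))
                for t in loop_rng.choice(len(term_ids), size=min(k, len(term_ids)),
                                         replace=False, p=weights):
                    corpus.add(g, term_ids[int(t)], "IEA")
        return corpus

    disease_mean = config.gobp_ratio_target * config.neutral_terms_mean
    corpus = draw_corpus(disease_mean, np.random.default_rng(rng.integers(2**31)))
    for _ in range(3):
        try:
            ic = compute_ic(dag, corpus, BP)
        except Exception:
            break
        d = np.mean([go_bp_count(g, corpus, dag, ic, config.ic_threshold)
                     for g in disease_genes])
        n = np.mean([go_bp_count(g, corpus, dag, ic, config.ic_threshold)
                     for g in neutral_genes])
        if n <= 0 or d <= 0:
            break
        realised = d / n
        if abs(realised - config.gobp_ratio_target) < 0.2:
            break
        disease_mean *= config.gobp_ratio_target / realised
        disease_mean = float(np.clip(disease_mean, 0.5, 10 * config.neutral_terms_mean))
        corpus = draw_corpus(disease_mean, np.random.default_rng(rng.integers(2**31)))
    return corpus


def simulate_two_releases(
    dag: OntologyDAG,
    corpus: AnnotationCorpus,
    groups: dict[str, set[str]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AnnotationCorpus, AnnotationCorpus]:
    """Grow a corpus into a second release at group-specific rates.

    ``groups`` maps group name -> gene set; each gene gains
    Poisson(growth_rates[group]) new direct terms (never loses any).  Genes in
    no listed group keep their annotations unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    old = AnnotationCorpus("release-old",
                           {g: set(a) for g, a in corpus.direct_annotations.items()})
    new = AnnotationCorpus("release-new",
                           {g: set(a) for g, a in corpus.direct_annotations.items()})
    levels = _term_levels(dag)
    max_level = max(levels.values()) if levels else 0
    term_ids = sorted(dag.terms)
    weights = np.array([1.0 + 2.0 * levels[t] / max(max_level, 1) for t in term_ids])
    weights /= weights.sum()
    for group in sorted(groups):
        rate = config.growth_rates.get(group, 0.0)
        for g in sorted(groups[group]):
            k = int(rng.poisson(rate))
            if k == 0:
                continue
            for t in rng.choice(len(term_ids), size=min(k, len(term_ids)),
                                replace=False, p=weights):
                new.add(g, term_ids[int(t)], "IEA")
    return old, new


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------

def simulate_variant_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Variant records exercising the selection filters.

    Disease genes host pathogenic variants (disease-flagged, allele frequency
    absent or < 0.01); neutral genes host benign ones (population-observed,
    frequency > 0.01); a fraction of disease genes additionally carries benign
    variants.  With ``contaminant_rate`` > 0, filter-violating records
    (X-chromosome entries, common "pathogenic" records, rare unflagged
    records) are interleaved.  Bookkeeping columns ``planted_class`` and
    ``planted_valid`` record the generator's intent; the TSV writer drops
    them.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    disease_genes = [f"DG{i:04d}" for i in range(config.n_disease_genes)]
    neutral_genes = [f"NG{i:04d}" for i in range(config.n_neutral_genes)]
    rows: list[dict] = []

    def add_variant(gene, cls, valid=True, chrom=None, af=None, flags=None):
        ref_aa, alt_aa = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        if chrom is None:
            chrom = str(int(rng.integers(1, 23)))
        if flags is None:
            if cls == "pathogenic":
                flags = dict(disease_mutation=True,
                             clinically_pathogenic=bool(rng.random() < 0.3),
                             observed_in_population=af is not None)
            else:
                flags = dict(disease_mutation=False, clinically_pathogenic=False,
                             observed_in_population=True)
        ref_nt, alt_nt = rng.choice(list("ACGT"), size=2, replace=False)
        rows.append({
            "chrom": chrom,
            "pos": int(rng.integers(1, 10**6)),
            "ref": str(ref_nt),
            "alt": str(alt_nt),
            "gene_id": gene,
            "aa_ref": ref_aa,
            "aa_pos": int(rng.integers(1, 1000)),
            "aa_alt": alt_aa,
            "allele_freq": af,
            **flags,
            "planted_class": cls,
            "planted_valid": valid,
        })

    counts_d = _zt_poisson(rng, config.variants_per_gene_mean, len(disease_genes))
    counts_n = _zt_poisson(rng, config.variants_per_gene_mean, len(neutral_genes))
    for gene, k in zip(disease_genes, counts_d):
        for _ in range(int(k)):
            af = None if rng.random() < 0.5 else float(rng.uniform(0, 0.009))
            add_variant(gene, "pathogenic", af=af)
        if rng.random() < config.benign_in_disease_fraction:
            add_variant(gene, "benign", af=float(rng.uniform(0.02, 0.5)))
    for gene, k in zip(neutral_genes, counts_n):
        for _ in range(int(k)):
            add_variant(gene, "benign", af=float(rng.uniform(0.02, 0.5)))

    n_clean = len(rows)
    n_contam = int(round(config.contaminant_rate * n_clean))
    for i in range(n_contam):
        kind = i % 3
        if kind == 0:      # pathogenic-flagged but common -> dropped by AF bound
            add_variant(str(rng.choice(disease_genes)), "pathogenic", valid=False,
                        af=float(rng.uniform(0.02, 0.3)))
        elif kind == 1:    # X-chromosome record -> dropped by autosome filter
            cls = "pathogenic" if rng.random() < 0.5 else "benign"
            af = None if cls == "pathogenic" else float(rng.uniform(0.02, 0.5))
            add_variant(str(rng.choice(disease_genes if cls == "pathogenic"
                                       else neutral_genes)), cls, valid=False,
                        chrom="X", af=af)
        else:              # unflagged rare population record -> fails benign AF bound
            add_variant(str(rng.choice(neutral_genes)), "benign", valid=False,
                        af=float(rng.uniform(0.0, 0.009)))
    df = pd.DataFrame(rows)
    # distinct protein positions per (gene, class) keep planted SAP counts exact
    df["aa_pos"] = df.groupby("gene_id").cumcount() + 1
    return df


def write_variant_table(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "pos", "ref", "alt", "gene_id", "aa_ref", "aa_pos", "aa_alt",
            "allele_freq", "disease_mutation", "clinically_pathogenic",
            "observed_in_population"]
    out = df[cols].copy()
    for flag in cols[-3:]:
        out[flag] = out[flag].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def simulate_feature_matrix(
    saps: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gobp: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Class-conditional 28-feature matrix for labeled SAPs.

    Numeric features are unit-variance Gaussians shifted by the configured
    effect size in the pathogenic direction of each feature's orientation;
    block members share a latent factor producing the configured within-block
    correlation.  Gene-level features are drawn once per gene and broadcast.
    GO.BP comes from ``gobp`` (gene -> count) when given — the mechanistic
    ontology path — otherwise from a class-conditional Poisson fallback with
    the configured ratio.  Missingness is applied independently per cell.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    n = len(saps)
    labels = (saps["label"] == "pathogenic").to_numpy(dtype=float)
    genes = saps["gene_id"].to_numpy()
    uniq_genes = pd.unique(genes)
    gene_pos = {g: i for i, g in enumerate(uniq_genes)}
    gene_is_disease = pd.Series(labels).groupby(genes).max()

    in_block: dict[str, tuple[int, float]] = {}
    for bi, (members, rho) in enumerate(config.blocks):
        for m in members:
            in_block[m] = (bi, rho)
    block_latent = rng.standard_normal((len(config.blocks), n))

    out = pd.DataFrame(index=saps["sap_key"].values)
    out["gene_id"] = genes
    out["label"] = saps["label"].values

    for spec_name in FEATURE_NAMES:
        if spec_name == "GO.BP":
            continue
        d = config.effects.get(spec_name, 0.0)
        sign = -1.0 if ORIENTATION[spec_name] == LOWER_PATHOGENIC else 1.0
        gene_level = spec_name in GENE_LEVEL_FEATURES
        if gene_level:
            g_noise = rng.standard_normal(len(uniq_genes))
            base = g_noise[[gene_pos[g] for g in genes]]
            shift = d * gene_is_disease.reindex(genes).to_numpy()
        else:
            if spec_name in in_block:
                bi, rho = in_block[spec_name]
                base = (np.sqrt(rho) * block_latent[bi]
                        + np.sqrt(1 - rho) * rng.standard_normal(n))
            else:
                base = rng.standard_normal(n)
            shift = d * labels
        values = sign * shift + base
        if spec_name in ("secondary.structure.3", "PfamA"):
            values = (values > 0).astype(float)  # categorical encoded 0/1
        if spec_name == "secondary.structure.8":
            values = np.floor(np.clip(values + 4, 0, 7))
        out[spec_name] = values

    if gobp is not None:
        out["GO.BP"] = [float(gobp.get(g, 0)) for g in genes]
    else:
        lam_neutral = 2.0
        lam = np.where(gene_is_disease.reindex(uniq_genes).to_numpy() > 0,
                       lam_neutral * config.gobp_ratio_target, lam_neutral)
        per_gene = rng.poisson(lam).astype(float)
        out["GO.BP"] = per_gene[[gene_pos[g] for g in genes]]

    if config.missing_rate > 0:
        for spec_name in FEATURE_NAMES:
            mask = rng.random(n) < config.missing_rate
            col = out[spec_name].to_numpy(dtype=float)
            col[mask] = np.nan
            out[spec_name] = col
    out.index.name = "sap_key"
    return out.reset_index().set_index("sap_key")


# ---------------------------------------------------------------------------
# Planted matrices for selection experiments
# ---------------------------------------------------------------------------

def planted_matrix(
    n_saps: int,
    n_genes: int,
    effects: list[float],
    n_noise: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Generic labeled matrix: informative Gaussian features plus pure noise.

    Genes get a class (half disease, half neutral); SAPs are dealt to genes
    round-robin and inherit the gene's class; informative feature i is shifted
    by ``effects[i]`` in pathogenic SAPs.  Feature names are ``inf1..`` and
    ``noise1..``; useful for selection and clustering experiments.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    gene_class = np.array([i < n_genes // 2 for i in range(n_genes)])
    perm = rng.permutation(n_genes)
    gene_of = np.array([perm[i % n_genes] for i in range(n_saps)])
    y = gene_class[gene_of].astype(float)
    data = {
        "sap_key": [f"S{i:05d}" for i in range(n_saps)],
        "gene_id": [genes[g] for g in gene_of],
        "label": np.where(y > 0, "pathogenic", "benign"),
    }
    for i, d in enumerate(effects, start=1):
        data[f"inf{i}"] = d * y + rng.standard_normal(n_saps)
    for i in range(1, n_noise + 1):
        data[f"noise{i}"] = rng.standard_normal(n_saps)
    return pd.DataFrame(data).set_index("sap_key").reset_index()


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, generated from one config."""

    config: SimulationConfig
    dag: OntologyDAG
    corpus_old: AnnotationCorpus
    corpus_new: AnnotationCorpus
    bias_groups: dict[str, set[str]]
    variant_records: pd.DataFrame
    saps: pd.DataFrame            # labeled, deduplicated SAPs
    matrix: pd.DataFrame          # 28-feature matrix with labels
    gobp: dict[str, int]


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate the complete synthetic study from one seed.

    The annotation corpus provides the GO.BP counts used in the feature
    matrix, so the ontology path is exercised end to end.  Bias groups:
    group1 = half the disease genes ("known early"), group2 = the other half
    ("discovered later"), group3 = the neutral genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    disease_genes = [f"DG{i:04d}" for i in range(config.n_disease_genes)]
    neutral_genes = [f"NG{i:04d}" for i in range(config.n_neutral_genes)]

    dag = simulate_ontology(config, np.random.default_rng(rng.integers(2**31)))
    corpus = simulate_annotations(dag, disease_genes, neutral_genes, config,
                                  np.random.default_rng(rng.integers(2**31)))
    half = len(disease_genes) // 2
    groups = {"group1": set(disease_genes[:half]),
              "group2": set(disease_genes[half:]),
              "group3": set(neutral_genes)}
    corpus_old, corpus_new = simulate_two_releases(
        dag, corpus, groups, config, np.random.default_rng(rng.integers(2**31)))

    records = simulate_variant_table(config, np.random.default_rng(rng.integers(2**31)))
    from .datasets import select_benign, select_pathogenic
    saps = pd.concat([select_pathogenic(records), select_benign(records)],
                     ignore_index=True)

    ic = compute_ic(dag, corpus_old, BP)
    gobp = {g: go_bp_count(g, corpus_old, dag, ic, config.ic_threshold)
            for g in disease_genes + neutral_genes}
    matrix = simulate_feature_matrix(
        saps, config, np.random.default_rng(rng.integers(2**31)), gobp=gobp)
    return SyntheticBundle(config, dag, corpus_old, corpus_new, groups,
                           records, saps, matrix, gobp)


def write_run_directory(bundle: SyntheticBundle, path) -> None:
    """Write all standard pipeline inputs as plain-text files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "ontology.obo").write_text(write_obo(bundle.dag))
    (path / "annotations_old.tsv").write_text(bundle.corpus_old.to_table())
    (path / "annotations_new.tsv").write_text(bundle.corpus_new.to_table())
    write_variant_table(bundle.variant_records, path / "variants.tsv")
    bundle.matrix.to_csv(path / "feature_matrix.tsv", sep="\t")
    groups = pd.DataFrame(
        [(g, name) for name in sorted(bundle.bias_groups)
         for g in sorted(bundle.bias_groups[name])],
        columns=["gene_id", "group"])
    groups.to_csv(path / "bias_groups.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(bundle.config)
    cfg["blocks"] = [[list(m), r] for m, r in bundle.config.blocks]
    pd.Series(cfg, dtype=object).to_json(path / "config.json", indent=2)
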