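"""Labeled SAP benchmark construction: selection filters, circularity removal,
and gene-aware splits and CV folds.

A SAP (single amino acid polymorphism) is identified by its gene plus protein
substitution; several nucleotide changes collapsing to one substitution are one
SAP.  Pathogenic candidates come from disease-mutation / clinically-pathogenic
records that are rare or unobserved in the population (allele frequency below
0.01); benign candidates are common population variants (frequency above 0.01)
with no pathogenic record.  Both classes are restricted to the autosomes to
avoid sex-specific effects.

Because trained predictors are later compared on these sets, variants (type 1)
or whole genes (type 2) overlapping an external predictor's training data can
be removed, and every split or fold keeps all SAPs of a gene on one side of
the boundary so no gene-level information leaks across.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AUTOSOMES = {str(i) for i in range(1, 23)}

#: columns expected in a variant table
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene_id", "aa_ref", "aa_pos", "aa_alt",
    "allele_freq", "disease_mutation", "clinically_pathogenic",
    "observed_in_population",
]


def sap_key(gene_id: str, aa_ref: str, aa_pos: int, aa_alt: str) -> str:
    return f"{gene_id}:{aa_ref}{int(aa_pos)}{aa_alt}"


def _with_sap_key(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    records["sap_key"] = [
        sap_key(g, r, p, a)
        for g, r, p, a in zip(records["gene_id"], records["aa_ref"],
                              records["aa_pos"], records["aa_alt"])
    ]
    return records


def read_variant_table(path_or_buf) -> pd.DataFrame:
    """Read the headered variant TSV; empty allele_freq means 'not observed'."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns {missing}")
    for flag in ("disease_mutation", "clinically_pathogenic", "observed_in_population"):
        df[flag] = df[flag].astype(bool)
    return df


def _dedup_saps(records: pd.DataFrame, label: str) -> pd.DataFrame:
    """Collapse SNVs to SAPs, keeping the maximum allele frequency per SAP."""
    records = _with_sap_key(records)
    records = records.sort_values(
        ["sap_key", "allele_freq"], na_position="first", kind="mergesort"
    )
    out = records.groupby("sap_key", sort=True).last().reset_index()
    out["label"] = label
    cols = ["sap_key", "gene_id", "label", "allele_freq", "chrom", "pos",
            "ref", "alt", "aa_ref", "aa_pos", "aa_alt"]
    return out[cols]


def select_pathogenic(records: pd.DataFrame, af_max: float = 0.01) -> pd.DataFrame:
    """Pathogenic SAPs: disease-flagged, autosomal, unobserved or rare.

    Keeps records with a disease-mutation or clinically-pathogenic flag whose
    allele frequency is absent (never observed in the population panel) or
    below ``af_max``.
    """
    r = records
    flagged = r["disease_mutation"] | r["clinically_pathogenic"]
    rare = r["allele_freq"].isna() | (r["allele_freq"] < af_max)
    autosomal = r["chrom"].astype(str).isin(AUTOSOMES)
    missense = r["aa_ref"] != r["aa_alt"]
    return _dedup_saps(r[flagged & rare & autosomal & missense], "pathogenic")


def select_benign(records: pd.DataFrame, af_min: float = 0.01) -> pd.DataFrame:
    """Benign SAPs: common autosomal population variants with no pathogenic record."""
    r = records
    common = r["observed_in_population"] & (r["allele_freq"] > af_min)
    unflagged = ~(r["disease_mutation"] | r["clinically_pathogenic"])
    autosomal = r["chrom"].astype(str).isin(AUTOSOMES)
    missense = r["aa_ref"] != r["aa_alt"]
    return _dedup_saps(r[common & unflagged & autosomal & missense], "benign")


def remove_circular(
    saps: pd.DataFrame,
    external_sap_keys: set[str],
    external_gene_ids: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split SAPs into (kept, removed) by overlap with external training data.

    Type 1 circularity: the SAP itself appears in the external set.  Type 2:
    a different variant of the same gene does, so the whole gene is excluded.
    """
    hit = saps["sap_key"].isin(external_sap_keys) | saps["gene_id"].isin(external_gene_ids)
    return saps[~hit].copy(), saps[hit].copy()


def gene_aware_split(
    saps: pd.DataFrame, train_fraction: float = 0.9, seed: int = 0
) -> pd.DataFrame:
    """Assign whole genes to train/validation, targeting a SAP-count fraction.

    Genes are shuffled by ``seed`` and assigned to the training partition until
    the cumulative SAP count first reaches ``train_fraction`` of the total;
    the rest go to validation.  No gene straddles the boundary, so the exact
    fraction is generally unattainable; the achieved fraction is reported in
    the ``achieved_train_fraction`` DataFrame attribute.
    """
    genes = saps["gene_id"].unique()
    if len(genes) < 2:
        raise ValueError("gene-aware split requires at least 2 genes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.sort(genes))
    counts = saps["gene_id"].value_counts()
    total = len(saps)
    target = train_fraction * total
    train_genes: set[str] = set()
    cum = 0
    last_added = None
    for g in order:
        if cum >= target:
            break
        train_genes.add(g)
        last_added = g
        cum += counts[g]
    if len(train_genes) == len(genes):
        # every gene swept into train (last gene overshot): keep a nonempty
        # validation partition by releasing the last added gene
        train_genes.discard(last_added)
        cum -= counts[last_added]
    partition = saps["gene_id"].map(lambda g: "train" if g in train_genes else "validation")
    out = pd.DataFrame({"sap_key": saps["sap_key"], "gene_id": saps["gene_id"],
                        "partition": partition.values})
    out.attrs["achieved_train_fraction"] = cum / total
    out.attrs["seed"] = seed
    return out


def gene_aware_folds(saps: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.Series:
    """Deal whole genes into k folds, balancing SAP counts.

    Genes are shuffled by ``seed`` and assigned greedily to the currently
    smallest fold (by SAP count), so every SAP of a gene shares one fold.
    Returns a Series fold index (0..k-1) indexed by sap_key.
    """
    genes = saps["gene_id"].unique()
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.sort(genes))
    counts = saps["gene_id"].value_counts()
    fold_sizes = np.zeros(k, dtype=int)
    gene_fold: dict[str, int] = {}
    for g in order:
        f = int(np.argmin(fold_sizes))
        gene_fold[g] = f
        fold_sizes[f] += counts[g]
    return pd.Series(
        [gene_fold[g] for g in saps["gene_id"]],
        index=saps["sap_key"].values, name="fold",
    )
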