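"""Assembling a labeled SAP benchmark from raw variant records.

Simulates a variant table that deliberately contains records violating the
selection filters (common 'pathogenic' entries, X-chromosome records, rare
unflagged population variants), applies the pathogenic/benign filters,
removes circular variants, and builds a gene-aware train/validation split.
"""

import pandas as pd

from sappred.datasets import (
    gene_aware_folds, gene_aware_split, remove_circular, select_benign,
    select_pathogenic,
)
from sappred.simulate import SimulationConfig, simulate_variant_table

cfg = SimulationConfig(seed=7, n_disease_genes=60, n_neutral_genes=60,
                       contaminant_rate=0.15)
records = simulate_variant_table(cfg)
print(f"raw records: {len(records)} "
      f"({(~records['planted_valid']).sum()} filter-violating)")

pathogenic = select_pathogenic(records)
benign = select_benign(records)
saps = pd.concat([pathogenic, benign], ignore_index=True)
print(f"selected SAPs: {len(pathogenic)} pathogenic, {len(benign)} benign")

# circularity removal: pretend an external predictor was trained on a few of
# our SAPs (type 1) and on other variants of two of our genes (type 2)
external_saps = set(saps["sap_key"].iloc[:5])
external_genes = {"DG0000", "NG0001"}
kept, removed = remove_circular(saps, external_saps, external_genes)
print(f"after circularity removal: kept {len(kept)}, removed {len(removed)}")

split = gene_aware_split(kept, train_fraction=0.9, seed=0)
frac = split.attrs["achieved_train_fraction"]
print(f"gene-aware split: achieved train fraction {frac:.3f}")
straddling = (split.groupby("gene_id")["partition"].nunique() > 1).sum()
print(f"genes straddling the boundary: {straddling}")

folds = gene_aware_folds(kept, k=5, seed=0)
print("fold sizes:", folds.value_counts().sort_index().tolist())
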