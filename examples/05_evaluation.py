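"""Head-to-head evaluation and the difficult-SAP analysis.

Fits the three predictive feature sets on a synthetic training partition,
scores them and the raw predictor scores on held-out SAPs, ranks everything
by AUC with paired bootstrap comparisons, then intersects the error sets to
find SAPs that every method gets wrong.
"""

import numpy as np
import pandas as pd

from sappred.datasets import gene_aware_split, select_benign, select_pathogenic
from sappred.downstream import MethodPredictions, false_sets, rescue_fractions
from sappred.evaluate import best_mcc_cutoff, evaluation_report
from sappred.features import LOWER_PATHOGENIC, ORIENTATION
from sappred.selection import PFS_SETS, fit_logistic_pfs
from sappred.simulate import (
    SimulationConfig, simulate_feature_matrix, simulate_variant_table,
)

cfg = SimulationConfig(seed=11, n_disease_genes=120, n_neutral_genes=120)
records = simulate_variant_table(cfg)
saps = pd.concat([select_pathogenic(records), select_benign(records)],
                 ignore_index=True)
matrix = simulate_feature_matrix(saps, cfg).dropna()

split = gene_aware_split(matrix.reset_index(), 0.9, seed=1)
is_train = matrix.index.isin(split.loc[split["partition"] == "train", "sap_key"])
train, val = matrix[is_train], matrix[~is_train]
labels = (val["label"] == "pathogenic").astype(int).to_numpy()
print(f"train {len(train)} SAPs / validation {len(val)} SAPs")

scored = {}
for name, pfs in PFS_SETS.items():
    clf = fit_logistic_pfs(train, pfs)
    scored[name] = (clf.predict_proba(val).to_numpy(), labels)
for raw in ("PON-P2", "PROVEAN", "SIFT"):
    sign = -1.0 if ORIENTATION[raw] == LOWER_PATHOGENIC else 1.0
    scored[raw] = (sign * val[raw].to_numpy(), labels)

report = evaluation_report(scored, n_boot=1000, seed=0)
cols = ["classifier", "auc", "mcc", "sensitivity", "specificity", "p_vs_next"]
print("\nranked comparison (each row tested against the next best):")
print(report[cols].to_string(index=False,
                             float_format=lambda v: f"{v:.3f}"))

methods = []
for name in ("PFS3", "PON-P2", "PROVEAN"):
    s, y = scored[name]
    cutoff, _ = best_mcc_cutoff(s, y)
    methods.append(MethodPredictions.from_scores(
        name, val.index, s, np.where(y == 1, "pathogenic", "benign"), cutoff))
sets = false_sets(methods)
print("\nshare of each method's errors that no other method rescues:")
print(rescue_fractions(sets).to_string(index=False,
                                       float_format=lambda v: f"{v:.2f}"))
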