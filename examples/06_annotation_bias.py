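"""Annotation-growth bias between two ontology releases.

Genes are grouped by when their first disease variant was reported (early /
late / never).  Each group's GO.BP multifunctionality growth between two
annotation releases is compared with one-sided pooled t-tests: growth in
disease genes over never-implicated genes is the planted signal.
"""

import numpy as np

from sappred.downstream import BiasGroups, bias_analysis
from sappred.simulate import (
    SimulationConfig, simulate_annotations, simulate_ontology,
    simulate_two_releases,
)

cfg = SimulationConfig(seed=2, n_terms=150, depth=4,
                       n_disease_genes=120, n_neutral_genes=120)
rng = np.random.default_rng(cfg.seed)
dag = simulate_ontology(cfg, np.random.default_rng(rng.integers(2**31)))
disease = [f"DG{i:04d}" for i in range(120)]
neutral = [f"NG{i:04d}" for i in range(120)]
corpus = simulate_annotations(dag, disease, neutral, cfg,
                              np.random.default_rng(rng.integers(2**31)))

groups = {"group1": set(disease[:60]),    # first disease report: early period
          "group2": set(disease[60:]),    # first disease report: late period
          "group3": set(neutral)}         # never implicated
old, new = simulate_two_releases(dag, corpus, groups, cfg,
                                 np.random.default_rng(rng.integers(2**31)))

report = bias_analysis(old, new, dag, dag, BiasGroups(**groups))
cols = ["comparison", "n_a", "n_b", "mean_a", "mean_b", "t", "p"]
print("per-group GO.BP growth between releases:")
print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\ngroup2 > group3 is the planted effect (disease genes gain more");
print("annotations); group1 > group2 is flat by construction here.")
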