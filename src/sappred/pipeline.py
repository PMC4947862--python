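"""End-to-end orchestration of the analysis stages with reproducible manifests.

Stages communicate through plain-text files in a run directory, so any stage
can be rerun from its inputs; a manifest records the configuration hash, the
seeds, and a checksum for every file each stage wrote.  The manifest contains
no timestamps: two runs with the same configuration produce byte-identical
manifests.

Stage order: simulate -> gobp -> split -> cluster -> select -> evaluate ->
difficult -> bias (cluster and gobp/bias are side branches; select feeds
evaluate feeds difficult).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, downstream, evaluate, selection
from .datasets import gene_aware_split
from .features import FEATURE_NAMES, LOWER_PATHOGENIC, NUMERIC_FEATURES, ORIENTATION, complete_cases
from .ontology import BP, AnnotationCorpus, compute_ic, go_bp_count, parse_obo
from .simulate import SimulationConfig, simulate_bundle, write_run_directory

#: rule prediction scores (alignment/biochemistry-derived) and the trained
#: score admitted in the third selection stage
RPS = ("SIFT", "PROVEAN", "GERP", "Grantham")
TPS = ("PON-P2",)
RAW_FEATURES = tuple(f for f in FEATURE_NAMES if f not in RPS + TPS)

#: numeric-only candidate pools of the three-stage selection protocol
_NUMERIC = set(NUMERIC_FEATURES)
STAGE_POOLS: dict[str, tuple[str, ...]] = {
    "raw": tuple(f for f in RAW_FEATURES if f in _NUMERIC),
    "raw+rps": tuple(f for f in RAW_FEATURES + RPS if f in _NUMERIC),
    "all": tuple(f for f in FEATURE_NAMES if f in _NUMERIC),
}

#: the five methods compared in the misclassification analysis
COMPARED_METHODS = ("PFS1", "PFS2", "PFS3", "PON-P2", "PROVEAN")


@dataclass
class RunConfig:
    """All numeric constants of the analysis, with the published defaults.

    The CLI substitutes desk-scale iteration counts; the constants here are
    the full-scale ones.
    """

    out_dir: str = "sappred_run"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    ic_threshold: float = 2.0
    af_max_pathogenic: float = 0.01
    af_min_benign: float = 0.01
    train_fraction: float = 0.9
    cv_folds: int = 5
    iterations_logistic: int = 300
    iterations_forest: int = 100
    forest_trees: int = 500
    n_boot: int = 5000
    target_specificity: float = 0.86
    expected_fn_rate: float = 0.05
    selection_stages: tuple[str, ...] = ("raw", "raw+rps", "all")
    selection_max_steps: int = 10      # prefixes evaluated per fold
    forest_max_samples: float | None = None

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    @classmethod
    def desk_scale(cls, out_dir: str, seed: int = 0, **overrides) -> "RunConfig":
        """Reduced settings for interactive runs and tests."""
        defaults = dict(iterations_logistic=10, iterations_forest=5,
                        forest_trees=30, forest_max_samples=0.5, n_boot=500,
                        selection_max_steps=6)
        defaults.update(overrides)
        return cls(out_dir=out_dir, seed=seed, **defaults)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["sim"]["blocks"] = [[list(m), r] for m, r in self.sim.blocks]
        payload.pop("out_dir")  # location-independent hash
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, files: list[str], producer: str) -> None:
    for f in files:
        if not (out / f).exists():
            raise StageError(
                f"missing input {f!r}: run the {producer!r} stage first")


def _read_matrix(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "inputs" / "feature_matrix.tsv", sep="\t")


def _oriented(scores: pd.Series, feature: str) -> pd.Series:
    return -scores if ORIENTATION[feature] == LOWER_PATHOGENIC else scores


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(out: Path, cfg: RunConfig) -> list[str]:
    bundle = simulate_bundle(cfg.sim)
    write_run_directory(bundle, out / "inputs")
    return [f"inputs/{p.name}" for p in sorted((out / "inputs").iterdir())]


def _stage_gobp(out: Path, cfg: RunConfig) -> list[str]:
    _require(out, ["inputs/ontology.obo", "inputs/annotations_old.tsv",
                   "inputs/annotations_new.tsv"], "simulate")
    dag = parse_obo((out / "inputs" / "ontology.obo").read_text())
    old = AnnotationCorpus.from_table((out / "inputs" / "annotations_old.tsv").read_text(), "old")
    new = AnnotationCorpus.from_table((out / "inputs" / "annotations_new.tsv").read_text(), "new")
    genes = sorted(old.genes() | new.genes())
    ic_old = compute_ic(dag, old, BP)
    ic_new = compute_ic(dag, new, BP)
    rows = [{
        "gene_id": g,
        "gobp_old": go_bp_count(g, old, dag, ic_old, cfg.ic_threshold),
        "gobp_new": go_bp_count(g, new, dag, ic_new, cfg.ic_threshold),
    } for g in genes]
    df = pd.DataFrame(rows)
    df["delta"] = df["gobp_new"] - df["gobp_old"]
    df.to_csv(out / "gobp.tsv", sep="\t", index=False)
    return ["gobp.tsv"]


def _stage_split(out: Path, cfg: RunConfig) -> list[str]:
    _require(out, ["inputs/feature_matrix.tsv"], "simulate")
    matrix = _read_matrix(out)
    split = gene_aware_split(matrix, cfg.train_fraction, seed=cfg.seed)
    split.to_csv(out / "split.tsv", sep="\t", index=False)
    summary = {"achieved_train_fraction": split.attrs["achieved_train_fraction"],
               "seed": cfg.seed}
    (out / "split_summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return ["split.tsv", "split_summary.json"]


def _stage_cluster(out: Path, cfg: RunConfig) -> list[str]:
    _require(out, ["inputs/feature_matrix.tsv"], "simulate")
    matrix = _read_matrix(out)
    numeric = [f for f in NUMERIC_FEATURES if matrix[f].notna().sum() >= 3
               and matrix[f].dropna().nunique() > 1]
    corr = clustering.abs_corr(matrix, numeric)
    result = clustering.optimal_clustering(corr)
    report = pd.DataFrame({
        "feature": corr.index,
        "cluster": result.labels.values,
        "silhouette_width": result.silhouette_widths.values,
    })
    report.to_csv(out / "clusters.tsv", sep="\t", index=False)
    clustering.corr_long_format(corr).to_csv(out / "corr_long.tsv", sep="\t",
                                             index=False, float_format="%.6g")
    (out / "cluster_summary.json").write_text(json.dumps(
        {"k": result.k, "mean_silhouette": result.mean_width}, sort_keys=True))
    return ["clusters.tsv", "corr_long.tsv", "cluster_summary.json"]


def _stage_select(out: Path, cfg: RunConfig) -> list[str]:
    _require(out, ["inputs/feature_matrix.tsv", "split.tsv"], "split")
    matrix = _read_matrix(out)
    split = pd.read_csv(out / "split.tsv", sep="\t")
    train_keys = set(split.loc[split["partition"] == "train", "sap_key"])
    train = matrix[matrix["sap_key"].isin(train_keys)]
    outputs = []
    pfs: dict[str, dict[str, list[str]]] = {}
    for stage in cfg.selection_stages:
        pool = list(STAGE_POOLS[stage])
        pfs[stage] = {}
        for ranker, iters in (("logistic", cfg.iterations_logistic),
                              ("random_forest", cfg.iterations_forest)):
            trace = selection.forward_selection(
                train, pool, ranker=ranker, k=cfg.cv_folds, iterations=iters,
                seed=cfg.seed, n_estimators=cfg.forest_trees,
                max_steps=cfg.selection_max_steps,
                max_samples=cfg.forest_max_samples)
            chosen = selection.choose_prefix(trace)
            pfs[stage][ranker] = list(chosen)
            tag = stage.replace("+", "_")
            fn = f"trace_{tag}_{ranker}.tsv"
            trace.steps.to_csv(out / fn, sep="\t", index=False, float_format="%.6g")
            outputs.append(fn)
    (out / "pfs.json").write_text(json.dumps(pfs, sort_keys=True, indent=1))
    outputs.append("pfs.json")
    return outputs


def _stage_evaluate(out: Path, cfg: RunConfig) -> list[str]:
    _require(out, ["inputs/feature_matrix.tsv", "split.tsv"], "split")
    matrix = _read_matrix(out)
    split = pd.read_csv(out / "split.tsv", sep="\t")
    part = split.set_index("sap_key")["partition"]
    matrix = matrix.assign(partition=matrix["sap_key"].map(part))

    needed = sorted(set(selection.PFS1) | set(selection.PFS2) | set(selection.PFS3))
    usable = complete_cases(matrix, needed)
    train = usable[usable["partition"] == "train"]
    val = usable[usable["partition"] == "validation"]
    labels = (val["label"] == "pathogenic").astype(int).to_numpy()

    scored: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, pfs in selection.PFS_SETS.items():
        clf = selection.fit_logistic_pfs(train, pfs)
        scored[name] = (clf.predict_proba(val).to_numpy(), labels)
    for score in ("PON-P2", "PROVEAN", "SIFT"):
        scored[score] = (_oriented(val[score], score).to_numpy(), labels)

    report = evaluate.evaluation_report(scored, n_boot=cfg.n_boot, seed=cfg.seed)
    report["sens_at_target_spec"] = [
        evaluate.sensitivity_at_specificity(*scored[c], cfg.target_specificity)
        for c in report["classifier"]]
    report.to_csv(out / "eval_report.tsv", sep="\t", index=False, float_format="%.6g")

    pred = pd.DataFrame({"sap_key": val["sap_key"].values,
                         "gene_id": val["gene_id"].values,
                         "label": val["label"].values})
    cutoffs = report.set_index("classifier")["cutoff"]
    for name, (s, _) in scored.items():
        pred[f"score_{name}"] = s
        pred[f"pred_{name}"] = np.where(s >= cutoffs[name], "pathogenic", "benign")
    pred.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.6g")

    rocs, prs = [], []
    for name, (s, y) in scored.items():
        roc = evaluate.roc_curve(s, y)
        roc.insert(0, "classifier", name)
        rocs.append(roc)
        pr = evaluate.precision_recall_curve(s, y)
        pr.insert(0, "classifier", name)
        prs.append(pr)
    pd.concat(rocs).to_csv(out / "roc_curves.tsv", sep="\t", index=False,
                           float_format="%.6g")
    pd.concat(prs).to_csv(out / "pr_curves.tsv", sep="\t", index=False,
                          float_format="%.6g")
    return ["eval_report.tsv", "predictions.tsv", "roc_curves.tsv", "pr_curves.tsv"]


def _stage_difficult(out: Path, cfg: RunConfig) -> list[str]:
    _require(out, ["predictions.tsv"], "evaluate")
    pred = pd.read_csv(out / "predictions.tsv", sep="\t")
    methods = [downstream.MethodPredictions(
        m, pred.set_index("sap_key")[f"pred_{m}"], pred.set_index("sap_key")["label"])
        for m in COMPARED_METHODS]
    sets = downstream.false_sets(methods)
    diff_fp, diff_fn, venn_fp, venn_fn = downstream.difficult_saps(sets)
    rescue = downstream.rescue_fractions(sets)
    rescue.to_csv(out / "rescue.tsv", sep="\t", index=False, float_format="%.6g")

    rows = ([{"sap_key": s, "error_type": "FP"} for s in sorted(diff_fp)]
            + [{"sap_key": s, "error_type": "FN"} for s in sorted(diff_fn)])
    gene_of = pred.set_index("sap_key")["gene_id"]
    diff = pd.DataFrame(rows, columns=["sap_key", "error_type"])
    diff["gene_id"] = diff["sap_key"].map(gene_of) if len(diff) else ""
    diff.to_csv(out / "difficult_saps.tsv", sep="\t", index=False)

    venn_rows = [{"error_type": et, "methods": "&".join(sorted(region)), "count": c}
                 for et, venn in (("FP", venn_fp), ("FN", venn_fn))
                 for region, c in sorted(venn.items(), key=lambda kv: sorted(kv[0]))]
    pd.DataFrame(venn_rows, columns=["error_type", "methods", "count"]).to_csv(
        out / "venn.tsv", sep="\t", index=False)

    excess = downstream.gene_fn_excess(
        diff_fn, pred["gene_id"].value_counts(), gene_of,
        expected_rate=cfg.expected_fn_rate)
    excess.to_csv(out / "fn_excess.tsv", sep="\t", index=False, float_format="%.6g")
    return ["difficult_saps.tsv", "venn.tsv", "rescue.tsv", "fn_excess.tsv"]


def _stage_bias(out: Path, cfg: RunConfig) -> list[str]:
    _require(out, ["inputs/ontology.obo", "inputs/annotations_old.tsv",
                   "inputs/annotations_new.tsv", "inputs/bias_groups.tsv"], "simulate")
    dag = parse_obo((out / "inputs" / "ontology.obo").read_text())
    old = AnnotationCorpus.from_table((out / "inputs" / "annotations_old.tsv").read_text(), "old")
    new = AnnotationCorpus.from_table((out / "inputs" / "annotations_new.tsv").read_text(), "new")
    gtab = pd.read_csv(out / "inputs" / "bias_groups.tsv", sep="\t")
    groups = downstream.BiasGroups(
        set(gtab.loc[gtab["group"] == "group1", "gene_id"]),
        set(gtab.loc[gtab["group"] == "group2", "gene_id"]),
        set(gtab.loc[gtab["group"] == "group3", "gene_id"]),
    )
    report = downstream.bias_analysis(old, new, dag, dag, groups, cfg.ic_threshold)
    report.to_csv(out / "bias_report.tsv", sep="\t", index=False, float_format="%.6g")
    return ["bias_report.tsv"]


STAGES = {
    "simulate": _stage_simulate,
    "gobp": _stage_gobp,
    "split": _stage_split,
    "cluster": _stage_cluster,
    "select": _stage_select,
    "evaluate": _stage_evaluate,
    "difficult": _stage_difficult,
    "bias": _stage_bias,
}


def run_stage(name: str, config: RunConfig) -> dict:
    """Execute one stage and return its manifest entry."""
    if name not in STAGES:
        raise StageError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = STAGES[name](out, config)
    entry = {"outputs": {f: _sha256(out / f) for f in sorted(files)}}
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else
                {"config_hash": config.config_hash(), "seed": config.seed,
                 "stages": {}})
    manifest["stages"][name] = entry
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return entry


def run_all(config: RunConfig) -> Path:
    """Run every stage in order; returns the manifest path."""
    out = Path(config.out_dir)
    manifest = out / "manifest.json"
    if manifest.exists():
        manifest.unlink()
    for name in STAGES:
        run_stage(name, config)
    return manifest
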