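"""K-fold evaluation, classification reports, correlation reporting and the
end-to-end pipeline runner.

Every classifier (the two boosting-style families plus SVM, random forest
and naive Bayes comparison models) is invoked through one contract: build a
seeded estimator, fit on the training side of a fold, predict the held-out
side.  Per-fold sensitivity/specificity/accuracy and the closed-form AUC are
summarized as mean ± std over folds; both AUC aggregations (mean of per-fold
AUCs, and the formula applied to mean rates) are reported because they can
differ at small fold sizes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .datagen import SimulationSpec, generate_dataset
from .io_preprocess import (ExpressionMatrix, FoldSpec, make_folds,
                            read_matrix, scale_minmax)
from .metrics import (accuracy, auc_from_rates, class_report, confusion,
                      round_half_away, sensitivity, specificity)
from .mrmr import GeneSet
from .selector import (GradientBoostingProvider, SelectorConfig, select_genes)
from .tuner import builtin_space, tune

__all__ = [
    "make_classifier",
    "bind_boosting_params",
    "MetricSummary",
    "cross_validate",
    "make_cv_objective",
    "correlation_report",
    "run_pipeline",
]

CLASSIFIERS = ("catboost-style", "xgboost-style", "svm", "random-forest",
               "naive-bayes")

# Native boosting parameter -> sklearn GradientBoostingClassifier argument.
_CATBOOST_BINDING = {"iterations": "n_estimators", "depth": "max_depth",
                     "subsample": "subsample", "rsm": "max_features",
                     "learning_rate": "learning_rate"}
_XGBOOST_BINDING = {"n_estimators": "n_estimators", "max_depth": "max_depth",
                    "subsample": "subsample", "colsample_bytree": "max_features",
                    "learning_rate": "learning_rate",
                    "min_child_weight": "min_samples_leaf"}


def bind_boosting_params(family: str, params: dict) -> dict:
    """Translate a native-vocabulary config to sklearn arguments; parameters
    without an sklearn analogue are silently dropped."""
    binding = _CATBOOST_BINDING if family == "catboost-style" else _XGBOOST_BINDING
    return {binding[k]: v for k, v in params.items() if k in binding}


def make_classifier(name: str, params: dict | None = None, seed: int = 0):
    """Seeded estimator for any supported classifier name."""
    params = dict(params or {})
    if name in ("catboost-style", "xgboost-style"):
        kwargs = bind_boosting_params(name, params)
        kwargs.setdefault("n_estimators", 100)
        return GradientBoostingClassifier(random_state=seed, **kwargs)
    if name == "svm":
        return SVC(kernel=params.get("kernel", "linear"),
                   C=params.get("C", 1.0), random_state=seed)
    if name == "random-forest":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 200)), random_state=seed)
    if name == "naive-bayes":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass
class MetricSummary:
    """metric name -> (mean, std) over folds, plus the per-fold records."""

    metrics: dict[str, tuple[float, float]]
    k: int
    per_fold: list[dict] = field(default_factory=list)
    auc_on_mean_rates: float | None = None

    def formatted(self, name: str) -> str:
        m, s = self.metrics[name]
        return f"{round_half_away(m):.2f} ± {round_half_away(s):.2f}"

    def to_dict(self) -> dict:
        out = {
            "k": self.k,
            "summary": {n: {"mean": m, "std": s} for n, (m, s) in self.metrics.items()},
            "per_fold": self.per_fold,
        }
        if self.auc_on_mean_rates is not None:
            out["auc_on_mean_rates"] = self.auc_on_mean_rates
        return out


def cross_validate(
    matrix: ExpressionMatrix,
    genes: GeneSet | None,
    folds: FoldSpec,
    classifier: str = "catboost-style",
    params: dict | None = None,
    seed: int = 0,
    scale_mode: str = "per-fold",
    gene_selector=None,
) -> MetricSummary:
    """Train-on-rest/test-on-fold evaluation on the given gene subset.

    ``gene_selector``, when given, is a callable(train_matrix) -> GeneSet
    re-run inside every fold (leak-free nested evaluation); it overrides
    ``genes``.
    """
    per_fold = []
    pooled_true, pooled_pred = [], []
    for f in range(folds.k):
        train = matrix.subset_samples(folds.train_indices(f))
        test = matrix.subset_samples(folds.test_indices(f))
        if gene_selector is not None:
            fold_genes = gene_selector(train)
        else:
            fold_genes = genes
        if fold_genes is not None and len(fold_genes) > 0:
            train = train.subset_genes(fold_genes.gene_ids)
            test = test.subset_genes(fold_genes.gene_ids)
        if scale_mode == "per-fold":
            test = scale_minmax(train, test)
            train = scale_minmax(train)
        clf = make_classifier(classifier, params, seed=seed)
        clf.fit(train.values, train.labels)
        pred = clf.predict(test.values)
        cc = confusion(test.labels, pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny folds can hit 0/0 rates
            sen, spec = sensitivity(cc), specificity(cc)
        per_fold.append({
            "fold": f, "accuracy": accuracy(cc), "sensitivity": sen,
            "specificity": spec, "auc": auc_from_rates(sen, 1 - spec),
            "tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn,
        })
        pooled_true.extend(test.labels.tolist())
        pooled_pred.extend(np.asarray(pred).tolist())
    names = ("accuracy", "sensitivity", "specificity", "auc")
    metrics = {
        n: (float(np.mean([r[n] for r in per_fold])),
            float(np.std([r[n] for r in per_fold])))
        for n in names
    }
    mean_sen = metrics["sensitivity"][0]
    mean_spec = metrics["specificity"][0]
    summary = MetricSummary(
        metrics=metrics, k=folds.k, per_fold=per_fold,
        auc_on_mean_rates=auc_from_rates(mean_sen, 1 - mean_spec),
    )
    summary.pooled = (pooled_true, pooled_pred)  # for classification reports
    return summary


def make_cv_objective(
    matrix: ExpressionMatrix,
    classifier: str,
    k: int,
    seed: int,
    genes: GeneSet | None = None,
):
    """Objective for the tuner: 1 - mean stratified k-fold accuracy."""
    folds = make_folds(matrix.labels, k, seed)

    def objective(config: dict) -> float:
        summary = cross_validate(matrix, genes, folds, classifier=classifier,
                                 params=config, seed=seed)
        return 1.0 - summary.metrics["accuracy"][0]

    return objective


def correlation_report(
    matrix: ExpressionMatrix, genes: GeneSet, out_prefix
) -> dict[str, Path]:
    """Pearson matrix of the selected genes (TSV), heat map and
    average-linkage dendrogram on correlation distance 1 - r (PNG)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sub = matrix.subset_genes(genes.gene_ids)
    frame = pd.DataFrame(sub.values, columns=sub.gene_ids)
    corr = frame.corr().fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    corr = (corr + corr.T) / 2  # enforce exact symmetry
    paths = {"correlation": out_prefix.with_suffix(".tsv")}
    corr.to_csv(paths["correlation"], sep="\t", float_format="%.12g")

    fig, ax = plt.subplots(figsize=(8, 7))
    sns.heatmap(corr, vmin=-1, vmax=1, cmap="vlag", ax=ax,
                xticklabels=False, yticklabels=False, cbar_kws={"label": "Pearson r"})
    ax.set_title("Correlation among selected genes")
    paths["heatmap"] = out_prefix.parent / (out_prefix.name + "_heatmap.png")
    fig.savefig(paths["heatmap"], dpi=100)
    plt.close(fig)

    if len(genes) > 1:
        dist = squareform(np.clip(1.0 - corr.values, 0.0, 2.0), checks=False)
        link = hierarchy.linkage(dist, method="average")
        fig, ax = plt.subplots(figsize=(10, 5))
        hierarchy.dendrogram(link, labels=list(corr.columns), ax=ax,
                             leaf_font_size=6)
        ax.set_ylabel("correlation distance (1 - r)")
        paths["dendrogram"] = out_prefix.parent / (out_prefix.name + "_dendrogram.png")
        fig.savefig(paths["dendrogram"], dpi=100, bbox_inches="tight")
        plt.close(fig)
    return paths


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_geneset(genes: GeneSet, path: Path) -> None:
    pd.DataFrame({
        "rank": np.arange(1, len(genes) + 1),
        "gene_id": genes.gene_ids,
        "score": genes.scores,
    }).to_csv(path, sep="\t", index=False, float_format="%.12g")


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    text = Path(config).read_text()
    return yaml.safe_load(text)


def run_pipeline(config) -> Path:
    """Execute the full workflow from a config mapping or YAML file.

    scale -> folds -> selection (fixed threshold or sweep) -> optional
    hyperparameter tuning -> k-fold evaluation per requested classifier ->
    reports.  Artifacts: selected.tsv, pruned.tsv, metrics.json, report.tsv,
    stage-counts.json, correlation files and figures, run.log.  Any stage
    error aborts with the stage name; earlier artifacts are preserved.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("out_dir", "genevote_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    k = int(cfg.get("k", 8))
    log_lines = [f"seed={seed} k={k}"]

    stage = "load"
    try:
        if cfg.get("matrix"):
            matrix = read_matrix(cfg["matrix"], dialect=cfg.get("dialect", "tsv"),
                                 orientation=cfg.get("orientation", "samples-as-rows"),
                                 label_column=cfg.get("label_column", "label"))
        elif cfg.get("simulate"):
            spec = SimulationSpec(**{**cfg["simulate"], "seed": seed})
            matrix, truth = generate_dataset(spec)
            _json_dump({"informative": truth.informative_gene_ids,
                        "redundant": truth.redundant_gene_ids}, out_dir / "truth.json")
        else:
            raise ValueError("config needs either 'matrix' (a path) or 'simulate'")
        log_lines.append(f"matrix: {matrix.n_samples} x {matrix.n_genes}")

        stage = "select"
        sel_cfg = SelectorConfig(
            k=k,
            threshold=cfg.get("threshold", 0.84),
            n_final=int(cfg.get("n_final", 50)),
            r_max=float(cfg.get("r_max", 0.5)),
            min_votes=cfg.get("min_votes"),
            use_embedded_svm=bool(cfg.get("use_embedded_svm", False)),
            use_mrmr_union=bool(cfg.get("use_mrmr_union", False)),
            scale_mode=cfg.get("scale_mode", "per-fold"),
            second_pass=bool(cfg.get("second_pass", False)),
            seed=seed,
        )
        provider = GradientBoostingProvider(
            seed=seed, n_estimators=int(cfg.get("provider_trees", 100)))
        folds = make_folds(matrix.labels, k, seed)
        result = select_genes(matrix, sel_cfg, provider=provider, folds=folds)
        _write_geneset(result.selected, out_dir / "selected.tsv")
        _write_geneset(result.pruned, out_dir / "pruned.tsv")
        _json_dump(result.stages, out_dir / "stage-counts.json")
        log_lines.append(f"threshold={result.threshold} "
                         f"selected={len(result.selected)} pruned={len(result.pruned)}")

        stage = "tune"
        tuned_params: dict[str, dict] = {}
        tune_cfg = cfg.get("tune") or {}
        if tune_cfg.get("enabled"):
            sub = matrix.subset_genes(result.selected.gene_ids)
            for family in tune_cfg.get("classifiers", ["catboost-style"]):
                objective = make_cv_objective(sub, family, k, seed)
                best, history = tune(objective, builtin_space(family),
                                     n_trials=int(tune_cfg.get("trials", 30)),
                                     seed=seed,
                                     backend=tune_cfg.get("backend", "adaptive-sequential"))
                tuned_params[family] = best.config
                pd.DataFrame([{"index": t.index, "loss": t.loss, **t.config}
                              for t in history]).to_csv(
                    out_dir / f"trials_{family}.tsv", sep="\t", index=False,
                    float_format="%.12g")
                log_lines.append(f"tuned {family}: loss={best.loss:.4f}")

        stage = "evaluate"
        metrics_obj: dict = {}
        report_frames = []
        for name in cfg.get("classifiers", ["catboost-style"]):
            summary = cross_validate(matrix, result.selected, folds,
                                     classifier=name,
                                     params=tuned_params.get(name),
                                     seed=seed,
                                     scale_mode=sel_cfg.scale_mode)
            metrics_obj[name] = summary.to_dict()
            y_true, y_pred = summary.pooled
            rep = class_report(y_true, y_pred)
            frame = pd.DataFrame(rep.to_dict()).T
            frame.insert(0, "classifier", name)
            report_frames.append(frame)
            log_lines.append(f"{name}: acc {summary.formatted('accuracy')}, "
                             f"auc {summary.formatted('auc')}")
        _json_dump(metrics_obj, out_dir / "metrics.json")
        pd.concat(report_frames).to_csv(out_dir / "report.tsv", sep="\t",
                                        float_format="%.12g")

        stage = "report"
        correlation_report(matrix, result.selected, out_dir / "correlation")
    except Exception as exc:
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out_dir
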