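"""Cross-fold importance voting, embedded-SVM ranking and redundancy pruning.

The selection pipeline: fit a tree-ensemble importance provider on the
training side of each of k stratified folds, max-normalize each fold's
importance row, keep the genes whose normalized importance exceeds a
threshold (strictly), count per gene the number of folds it survived
(*voting*), rank by (votes, mean importance, id) and truncate to the target
size.  Optional parallel stages — an embedded linear-SVM weight ranking and
an mRMR union — feed the same final set, which can then be pruned so that no
two kept genes have |Pearson r| at or above a cutoff.

The importance provider is a contract: any object with
``importances(X, y) -> non-negative vector`` and ``make_classifier()``.
The default binding is a seeded gradient-boosted-tree classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.svm import SVC

from .io_preprocess import ExpressionMatrix, FoldSpec, make_folds, scale_minmax
from .mrmr import GeneSet, MrmrConfig, _abs_corr, mrmr_rank

__all__ = [
    "ImportanceProvider",
    "GradientBoostingProvider",
    "ImportanceTable",
    "VoteTally",
    "SelectorConfig",
    "SelectionResult",
    "fold_importances",
    "normalize_importances",
    "threshold_filter",
    "vote",
    "select_by_votes",
    "sweep_threshold",
    "embedded_svm_rank",
    "merge_unique",
    "correlation_prune",
    "select_genes",
]


@runtime_checkable
class ImportanceProvider(Protocol):
    def importances(self, X: np.ndarray, y: np.ndarray) -> np.ndarray: ...

    def make_classifier(self): ...


class GradientBoostingProvider:
    """Default provider: seeded gradient-boosted trees.

    ``feature_importances_`` of the fitted ensemble is the per-gene score;
    ``make_classifier`` hands out an identically-configured fresh estimator
    for accuracy evaluation during threshold sweeps.
    """

    def __init__(self, seed: int = 0, n_estimators: int = 200,
                 max_depth: int = 1, learning_rate: float = 0.1,
                 max_features: float | None = 0.1):
        # shallow trees + random feature subspaces (the "rsm" idea) spread
        # importance across correlated genes instead of letting one gene
        # shadow its partners — essential for stable cross-fold voting
        self.seed = seed
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.max_features = max_features

    def make_classifier(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            max_features=self.max_features,
            random_state=self.seed,
        )

    def importances(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        imp = self.make_classifier().fit(X, y).feature_importances_
        # an ensemble with no effective splits yields 0/0 = NaN; tiny
        # negative values can appear from floating-point cancellation
        return np.clip(np.nan_to_num(imp, nan=0.0), 0.0, None)


@dataclass
class ImportanceTable:
    """k x n_genes non-negative importances, one row per fold."""

    fold_importances: np.ndarray
    gene_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.fold_importances = np.asarray(self.fold_importances, dtype=float)
        if self.fold_importances.ndim != 2:
            raise ValueError("fold_importances must be 2-D (k x n_genes)")
        if self.fold_importances.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids must match the number of columns")
        if np.any(self.fold_importances < 0):
            raise ValueError("importances must be non-negative")

    @property
    def k(self) -> int:
        return self.fold_importances.shape[0]

    @property
    def fold_means(self) -> np.ndarray:
        return self.fold_importances.mean(axis=1)

    @property
    def gene_means(self) -> np.ndarray:
        return self.fold_importances.mean(axis=0)


@dataclass
class VoteTally:
    """gene id -> number of folds in which the gene survived the filter."""

    votes: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        for g, v in self.votes.items():
            if not 0 <= v <= self.k:
                raise ValueError(f"vote count {v} for {g!r} outside [0, {self.k}]")


@dataclass(frozen=True)
class SelectorConfig:
    """Knobs of the selection pipeline.

    threshold: normalized-importance cutoff in [0, 1], or "sweep" to pick
    the accuracy-maximizing grid point.  n_final: target size of the voted
    set (50 in the reference workflow).  r_max: correlation-prune cutoff
    (genes with |r| >= r_max to a kept gene are dropped); second_pass adds
    an extra prune at r_max + 0.01.
    """

    k: int = 8
    threshold: float | str = 0.84
    sweep_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    min_votes: int | str | None = None  # hard floor; "auto" means k
    n_final: int = 50
    r_max: float = 0.5
    second_pass: bool = False
    use_embedded_svm: bool = False
    use_mrmr_union: bool = False
    scale_mode: str = "per-fold"  # or "global"
    prune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_final < 1:
            raise ValueError("n_final must be >= 1")
        if not 0 < self.r_max <= 1:
            raise ValueError("r_max must be in (0, 1]")
        if list(self.sweep_grid) != sorted(self.sweep_grid):
            raise ValueError("sweep_grid must be sorted ascending")
        if self.scale_mode not in ("per-fold", "global"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")


def fold_importances(
    matrix: ExpressionMatrix,
    folds: FoldSpec,
    provider: ImportanceProvider,
    scale_mode: str = "per-fold",
) -> ImportanceTable:
    """Row f = provider importances fitted on all samples outside fold f."""
    if scale_mode == "global":
        matrix = scale_minmax(matrix)
    rows = []
    for f in range(folds.k):
        train = matrix.subset_samples(folds.train_indices(f))
        if scale_mode == "per-fold":
            train = scale_minmax(train)
        try:
            imp = np.asarray(provider.importances(train.values, train.labels), float)
        except Exception as exc:
            raise RuntimeError(f"importance provider failed on fold {f}: {exc}") from exc
        if imp.shape != (matrix.n_genes,) or np.any(imp < 0) or not np.all(np.isfinite(imp)):
            raise RuntimeError(f"importance provider returned an invalid vector on fold {f}")
        rows.append(imp)
    return ImportanceTable(np.vstack(rows), list(matrix.gene_ids), normalized=False)


def normalize_importances(table: ImportanceTable) -> ImportanceTable:
    """Divide each fold row by its max; all-zero rows pass through."""
    rows = table.fold_importances.copy()
    mx = rows.max(axis=1, keepdims=True)
    nz = mx[:, 0] > 0
    rows[nz] = rows[nz] / mx[nz]
    return ImportanceTable(rows, list(table.gene_ids), normalized=True)


def threshold_filter(table: ImportanceTable, t: float) -> list[GeneSet]:
    """Per fold, the genes with normalized importance strictly above ``t``,
    ordered by descending importance (ties to the lower column index)."""
    if not 0 <= t <= 1:
        raise ValueError(f"threshold {t} outside [0, 1]")
    if not table.normalized:
        raise ValueError("threshold_filter expects a normalized table")
    sets = []
    for row in table.fold_importances:
        idx = np.flatnonzero(row > t)
        idx = idx[np.argsort(-row[idx], kind="stable")]
        sets.append(GeneSet([table.gene_ids[i] for i in idx],
                            [float(row[i]) for i in idx]))
    return sets


def vote(fold_sets: list[GeneSet]) -> VoteTally:
    """votes[g] = number of fold sets containing gene g."""
    if not fold_sets:
        raise ValueError("vote requires at least one fold set")
    votes: dict[str, int] = {}
    for gs in fold_sets:
        for g in gs.gene_ids:
            votes[g] = votes.get(g, 0) + 1
    return VoteTally(votes, k=len(fold_sets))


def select_by_votes(
    tally: VoteTally, table: ImportanceTable, config: SelectorConfig
) -> GeneSet:
    """Rank by (votes desc, mean importance desc, id asc), truncate.

    Only genes with at least one vote (or ``min_votes`` when set) are
    eligible; nothing is fabricated when fewer than ``n_final`` qualify.
    """
    means = dict(zip(table.gene_ids, table.gene_means))
    min_votes = tally.k if config.min_votes == "auto" else config.min_votes
    floor = max(min_votes or 1, 1)
    eligible = [(g, v) for g, v in tally.votes.items() if v >= floor]
    eligible.sort(key=lambda gv: (-gv[1], -means.get(gv[0], 0.0), gv[0]))
    chosen = eligible[: config.n_final]
    return GeneSet([g for g, _ in chosen], [float(v) for _, v in chosen])


def _cv_accuracy(
    matrix: ExpressionMatrix, genes: GeneSet, folds: FoldSpec, provider, scale_mode
) -> float:
    """Mean k-fold accuracy of the provider's classifier on the given genes;
    an empty gene set scores as majority-class prediction."""
    if len(genes) == 0:
        counts = np.bincount(matrix.labels.astype(int))
        return float(counts.max() / counts.sum())
    sub = matrix.subset_genes(genes.gene_ids)
    if scale_mode == "global":
        sub = scale_minmax(sub)
    accs = []
    for f in range(folds.k):
        train = sub.subset_samples(folds.train_indices(f))
        test = sub.subset_samples(folds.test_indices(f))
        if scale_mode == "per-fold":
            test = scale_minmax(train, test)
            train = scale_minmax(train)
        clf = provider.make_classifier()
        clf.fit(train.values, train.labels)
        accs.append(float(np.mean(clf.predict(test.values) == test.labels)))
    return float(np.mean(accs))


def sweep_threshold(
    matrix: ExpressionMatrix,
    folds: FoldSpec,
    provider: ImportanceProvider,
    grid,
    config: SelectorConfig = SelectorConfig(),
    table: ImportanceTable | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Pick the grid threshold maximizing mean CV accuracy of the voted set.

    Ties go to the smallest threshold.  Returns (best_t, accuracy curve).
    """
    grid = [float(t) for t in grid]
    if any(t < 0 or t > 1 for t in grid):
        raise ValueError("sweep grid must lie in [0, 1]")
    if table is None:
        table = normalize_importances(
            fold_importances(matrix, folds, provider, config.scale_mode)
        )
    curve = []
    for t in grid:
        selected = select_by_votes(vote(threshold_filter(table, t)), table, config)
        curve.append((t, _cv_accuracy(matrix, selected, folds, provider,
                                      config.scale_mode)))
    best_t = max(curve, key=lambda ta: (ta[1], -ta[0]))[0]
    return best_t, curve


def embedded_svm_rank(matrix: ExpressionMatrix, top_m: int) -> GeneSet:
    """Rank genes by |weight| of a linear maximum-margin classifier.

    The matrix is min-max scaled before fitting; exact weight ties (e.g.
    duplicated genes) are broken by gene id.
    """
    if len(np.unique(matrix.labels)) < 2:
        raise ValueError("embedded SVM requires both classes")
    if not 1 <= top_m <= matrix.n_genes:
        raise ValueError(f"top_m={top_m} outside [1, {matrix.n_genes}]")
    scaled = scale_minmax(matrix)
    try:
        svm = SVC(kernel="linear", C=1.0).fit(scaled.values, scaled.labels)
    except Exception as exc:
        raise RuntimeError(f"embedded SVM fit failed: {exc}") from exc
    w = np.abs(np.asarray(svm.coef_).ravel())
    order = sorted(range(matrix.n_genes), key=lambda i: (-w[i], matrix.gene_ids[i]))
    order = order[:top_m]
    return GeneSet([matrix.gene_ids[i] for i in order], [float(w[i]) for i in order])


def merge_unique(sets: list[GeneSet], seed: int = 0) -> GeneSet:
    """Seeded shuffle of the concatenation, then first-occurrence unique."""
    ids = [g for gs in sets for g in gs.gene_ids]
    scores = [s for gs in sets for s in gs.scores]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    seen: dict[str, float] = {}
    for i in order:
        if ids[i] not in seen:
            seen[ids[i]] = float(scores[i])
    return GeneSet(list(seen.keys()), list(seen.values()))


def correlation_prune(
    matrix: ExpressionMatrix, genes: GeneSet, r_max: float
) -> GeneSet:
    """Greedy scan in GeneSet order, dropping any gene with |Pearson r| >=
    ``r_max`` to an already-kept gene.

    Constant genes correlate 0 with everything, except that two identical
    constant genes count as duplicates (r = 1), so only the first survives.
    """
    if not 0 < r_max <= 1:
        raise ValueError("r_max must be in (0, 1]")
    idx = matrix.gene_index(genes.gene_ids)
    cols = matrix.values[:, idx]
    constant = cols.std(axis=0) == 0
    kept: list[int] = []
    for j in range(len(idx)):
        ok = True
        for i in kept:
            if constant[i] or constant[j]:
                r = 1.0 if (constant[i] and constant[j]
                            and np.array_equal(cols[:, i], cols[:, j])) else 0.0
            else:
                r = float(_abs_corr(cols[:, [i]], cols[:, j])[0])
            if r >= r_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return GeneSet([genes.gene_ids[j] for j in kept],
                   [genes.scores[j] for j in kept])


@dataclass
class SelectionResult:
    """Everything the pipeline produced, including per-stage gene counts."""

    selected: GeneSet          # post-voting set (the workflow's final genes)
    pruned: GeneSet            # after correlation pruning
    table: ImportanceTable     # normalized importances
    tally: VoteTally
    threshold: float
    sweep_curve: list[tuple[float, float]] | None
    stages: dict = field(default_factory=dict)


def select_genes(
    matrix: ExpressionMatrix,
    config: SelectorConfig = SelectorConfig(),
    provider: ImportanceProvider | None = None,
    folds: FoldSpec | None = None,
) -> SelectionResult:
    """Run the full selection pipeline on one expression matrix.

    Stages: stratified folds -> per-fold importances (scaled per fold by
    default) -> max-normalization -> threshold filter (fixed or sweep) ->
    voting -> rank-and-truncate; optional embedded-SVM and mRMR union
    stages; correlation pruning last.
    """
    provider = provider or GradientBoostingProvider(seed=config.seed)
    folds = folds or make_folds(matrix.labels, config.k, config.seed)
    table = normalize_importances(
        fold_importances(matrix, folds, provider, config.scale_mode)
    )
    stages: dict = {
        "nonzero_per_fold": [int((row > 0).sum()) for row in table.fold_importances]
    }
    curve = None
    if config.threshold == "sweep":
        t, curve = sweep_threshold(matrix, folds, provider, config.sweep_grid,
                                   config, table=table)
    else:
        t = float(config.threshold)
    fold_sets = threshold_filter(table, t)
    tally = vote(fold_sets)
    selected = select_by_votes(tally, table, config)
    stages["post_vote"] = len(selected)

    final = selected
    if config.use_embedded_svm:
        per_fold = [
            embedded_svm_rank(matrix.subset_samples(folds.train_indices(f)),
                              top_m=matrix.n_genes)
            for f in range(folds.k)
        ]
        stages["svm_redundant"] = sum(len(s) for s in per_fold)
        svm_unique = merge_unique(per_fold, seed=config.seed)
        stages["svm_unique"] = len(svm_unique)
        extra = [g for g in svm_unique.gene_ids[: config.n_final]
                 if g not in final.gene_ids]
        final = GeneSet(final.gene_ids + extra,
                        final.scores + [0.0] * len(extra))
    if config.use_mrmr_union:
        ranked = mrmr_rank(matrix, MrmrConfig(m=min(config.n_final, matrix.n_genes)))
        extra = [g for g in ranked.gene_ids if g not in final.gene_ids]
        final = GeneSet(final.gene_ids + extra, final.scores + [0.0] * len(extra))
        stages["mrmr_union"] = len(final)

    if config.prune:
        pruned = correlation_prune(matrix, final, config.r_max)
        if config.second_pass:
            pruned = correlation_prune(matrix, pruned, min(config.r_max + 0.01, 1.0))
    else:
        pruned = final
    stages["post_prune"] = len(pruned)
    return SelectionResult(selected=final, pruned=pruned, table=table,
                           tally=tally, threshold=t, sweep_curve=curve,
                           stages=stages)
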