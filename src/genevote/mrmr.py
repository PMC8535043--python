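"""Greedy minimum-redundancy maximum-relevance (mRMR) gene ranking.

Classic mRMR picks, at each step, the gene maximizing a trade-off between
relevance to the class label and mean redundancy to the genes already
selected.  Two scoring schemes are provided — quotient (relevance divided by
redundancy) and difference (relevance minus redundancy) — plus the two
ensemble variants: *exhaustive* (k parallel runs seeded at the k most
relevant genes, so the first pick of each run is guaranteed distinct) and
*bootstrap* (classic mRMR on k class-stratified resamples of the samples).

Relevance defaults to |Pearson r(gene, label)|; redundancy is the mean
|Pearson r| between a candidate and the selected set.  Constant genes have
zero correlation to everything by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import f_classif

from .io_preprocess import ExpressionMatrix

__all__ = ["GeneSet", "MrmrConfig", "relevance", "mrmr_rank",
           "mrmr_exhaustive", "mrmr_bootstrap"]


@dataclass
class GeneSet:
    """An ordered list of selected genes with their selection-time scores."""

    gene_ids: list[str]
    scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scores:
            self.scores = [float("nan")] * len(self.gene_ids)
        if len(self.scores) != len(self.gene_ids):
            raise ValueError("scores must parallel gene_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in GeneSet")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


@dataclass(frozen=True)
class MrmrConfig:
    scheme: str = "quotient"  # or "difference"
    relevance_metric: str = "abs-pearson-with-label"  # or "f-statistic"
    redundancy_metric: str = "mean-abs-pearson"
    m: int = 50
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.scheme not in ("quotient", "difference"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.relevance_metric not in ("abs-pearson-with-label", "f-statistic"):
            raise ValueError(f"unknown relevance metric {self.relevance_metric!r}")
        if self.redundancy_metric != "mean-abs-pearson":
            raise ValueError(f"unknown redundancy metric {self.redundancy_metric!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _abs_corr(columns: np.ndarray, target: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column with target; 0 where either is constant."""
    x = columns - columns.mean(axis=0)
    t = target - target.mean()
    xn = np.sqrt((x**2).sum(axis=0))
    tn = np.sqrt((t**2).sum())
    denom = xn * tn
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(x.T @ t) / np.where(denom == 0, 1.0, denom)
    r[denom == 0] = 0.0
    return r


def relevance(matrix: ExpressionMatrix, config: MrmrConfig = MrmrConfig()) -> np.ndarray:
    """Per-gene relevance to the binary label (finite, non-negative)."""
    if len(np.unique(matrix.labels)) < 2:
        raise ValueError("relevance requires both classes to be present")
    if config.relevance_metric == "abs-pearson-with-label":
        return _abs_corr(matrix.values, matrix.labels.astype(float))
    f, _ = f_classif(matrix.values, matrix.labels)
    return np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max)


def _greedy(
    matrix: ExpressionMatrix, config: MrmrConfig, first: int | None = None
) -> GeneSet:
    rel = relevance(matrix, config)
    p = matrix.n_genes
    m = config.m
    if m > p:
        raise ValueError(f"m={m} exceeds the number of genes ({p})")
    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for step in range(m):
        if step == 0:
            idx = int(np.argmax(rel)) if first is None else int(first)
            score = float(rel[idx])
        else:
            red = red_sum / len(selected)
            if config.scheme == "quotient":
                crit = rel / np.maximum(red, config.epsilon)
            else:
                crit = rel - red
            crit = np.where(remaining, crit, -np.inf)
            idx = int(np.argmax(crit))  # argmax keeps the lowest index on ties
            score = float(crit[idx])
        selected.append(idx)
        scores.append(score)
        remaining[idx] = False
        red_sum += _abs_corr(matrix.values, matrix.values[:, idx])
    return GeneSet([matrix.gene_ids[i] for i in selected], scores)


def mrmr_rank(matrix: ExpressionMatrix, config: MrmrConfig = MrmrConfig()) -> GeneSet:
    """Classic greedy mRMR: first pick is the relevance argmax, then the
    scheme criterion over remaining candidates, ties to the lower index."""
    return _greedy(matrix, config)


def mrmr_exhaustive(
    matrix: ExpressionMatrix, config: MrmrConfig, k_starts: int
) -> list[GeneSet]:
    """k parallel greedy runs seeded at the k most relevant genes."""
    if k_starts > matrix.n_genes:
        raise ValueError(
            f"k_starts={k_starts} exceeds the number of genes ({matrix.n_genes})"
        )
    rel = relevance(matrix, config)
    heads = np.argsort(-rel, kind="stable")[:k_starts]
    return [_greedy(matrix, config, first=int(h)) for h in heads]


def mrmr_bootstrap(
    matrix: ExpressionMatrix, config: MrmrConfig, k_boot: int, seed: int
) -> list[GeneSet]:
    """Classic mRMR on ``k_boot`` class-stratified bootstrap resamples.

    Resampling with replacement is done within each class so that no
    resample collapses to a single class at small n.
    """
    if k_boot < 1:
        raise ValueError("k_boot must be >= 1")
    rng = np.random.default_rng(seed)
    classes = [np.flatnonzero(matrix.labels == c) for c in np.unique(matrix.labels)]
    out: list[GeneSet] = []
    for _ in range(k_boot):
        rows = np.concatenate([rng.choice(c, size=len(c), replace=True) for c in classes])
        resampled = ExpressionMatrix(
            matrix.values[rows],
            list(matrix.gene_ids),
            [f"b{i}" for i in range(len(rows))],
            matrix.labels[rows],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicated rows can trip f_classif
            out.append(mrmr_rank(resampled, config))
    return out
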