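"""Seed-deterministic hyperparameter search over gradient-boosting spaces.

Two built-in search spaces mirror the two boosting libraries' parameter
vocabularies (the "catboost-style" space: iterations, depth, subsample, rsm,
log10 learning-rate exponent, l2_leaf_reg, random_strength,
bagging_temperature, scale_pos_weight; the "xgboost-style" space:
n_estimators, max_depth, min_child_weight, gamma, subsample, natural-log
learning-rate exponent, colsample_bytree).  Learning-rate bounds are
exponents on the stated scale and are materialized to actual rates when a
configuration is sampled.

Backends: plain random search, and a lightweight adaptive-sequential search
(seeded random warm-up, then candidates scored by a nearest-neighbour
surrogate over past trials, exploiting the neighbourhood of the incumbent).
Both are exactly reproducible from (seed, backend).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ParamSpec", "SearchSpace", "TrialResult", "builtin_space", "tune"]


@dataclass(frozen=True)
class ParamSpec:
    """One search dimension: bounds live on ``scale``; sampled values are
    mapped back (log10 -> 10**u, ln -> exp(u))."""

    name: str
    low: float
    high: float
    scale: str = "linear"  # {"linear", "log10", "ln"}
    kind: str = "real"     # {"real", "integer"}

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.scale not in ("linear", "log10", "ln"):
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}")
        if self.kind not in ("real", "integer"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "integer" and not (
            float(self.low).is_integer() and float(self.high).is_integer()
        ):
            raise ValueError(f"{self.name}: integer parameter needs integer bounds")

    def transform(self, u: float):
        if self.scale == "log10":
            v = 10.0**u
        elif self.scale == "ln":
            v = math.exp(u)
        else:
            v = u
        return int(round(v)) if self.kind == "integer" else float(v)

    def sample_unit(self, rng: np.random.Generator) -> float:
        """Draw the raw (on-scale) coordinate."""
        if self.kind == "integer":
            return float(rng.integers(int(self.low), int(self.high) + 1))
        return float(rng.uniform(self.low, self.high))

    def clip_unit(self, u: float) -> float:
        u = min(max(u, self.low), self.high)
        return float(round(u)) if self.kind == "integer" else u


@dataclass(frozen=True)
class SearchSpace:
    params: tuple[ParamSpec, ...]

    def sample(self, rng: np.random.Generator) -> tuple[dict, np.ndarray]:
        units = np.array([p.sample_unit(rng) for p in self.params])
        return self._materialize(units), units

    def _materialize(self, units: np.ndarray) -> dict:
        return {p.name: p.transform(u) for p, u in zip(self.params, units)}

    def contains(self, config: dict) -> bool:
        for p in self.params:
            v = config[p.name]
            lo, hi = p.transform(p.low), p.transform(p.high)
            if not min(lo, hi) <= v <= max(lo, hi):
                return False
        return True


_CATBOOST_SPACE = (
    ParamSpec("iterations", 1, 500, kind="integer"),
    ParamSpec("depth", 1, 16, kind="integer"),
    ParamSpec("subsample", 0.5, 1.0),
    ParamSpec("rsm", 0.75, 1.0),
    ParamSpec("learning_rate", -3.0, -0.7, scale="log10"),
    ParamSpec("l2_leaf_reg", 1.0, 10.0),
    ParamSpec("random_strength", 1e-9, 10.0),
    ParamSpec("bagging_temperature", 0.0, 1.0),
    ParamSpec("scale_pos_weight", 0.01, 1.0),
)

_XGBOOST_SPACE = (
    ParamSpec("n_estimators", 50, 900, kind="integer"),
    ParamSpec("max_depth", 1, 12, kind="integer"),
    ParamSpec("min_child_weight", 1, 6, kind="integer"),
    ParamSpec("gamma", 0.5, 1.0),
    ParamSpec("subsample", 0.5, 1.0),
    ParamSpec("learning_rate", math.log(0.001), math.log(0.3), scale="ln"),
    ParamSpec("colsample_bytree", 0.5, 1.0),
)


def builtin_space(classifier: str) -> SearchSpace:
    """The published bounds, assigned by parameter-name vocabulary."""
    if classifier == "catboost-style":
        return SearchSpace(_CATBOOST_SPACE)
    if classifier == "xgboost-style":
        return SearchSpace(_XGBOOST_SPACE)
    raise ValueError(f"unknown classifier family {classifier!r}")


@dataclass
class TrialResult:
    config: dict
    loss: float
    index: int


def _evaluate(objective, config: dict, index: int) -> TrialResult:
    try:
        loss = float(objective(config))
    except Exception as exc:  # a failing config scores worst, loudly
        warnings.warn(f"trial {index} raised {exc!r}; recording loss 1.0",
                      stacklevel=3)
        loss = 1.0
    return TrialResult(config=config, loss=loss, index=index)


def tune(
    objective,
    space: SearchSpace,
    n_trials: int,
    seed: int,
    backend: str = "random",
) -> tuple[TrialResult, list[TrialResult]]:
    """Minimize ``objective`` over ``space``; returns (best, history).

    random: independent draws.  adaptive-sequential: after a random warm-up,
    each step scores a candidate pool (half Gaussian perturbations of the
    incumbent, half fresh draws) with a 3-nearest-neighbour surrogate on the
    normalized coordinates of past trials and evaluates the most promising
    candidate.  Identical (seed, backend) reproduce the history exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if backend not in ("random", "adaptive-sequential"):
        raise ValueError(f"unknown backend {backend!r}")
    rng = np.random.default_rng(seed)
    history: list[TrialResult] = []
    units_hist: list[np.ndarray] = []
    widths = np.array([p.high - p.low for p in space.params])

    n_warmup = n_trials if backend == "random" else max(min(10, n_trials), n_trials // 3)
    for i in range(n_trials):
        if i < n_warmup:
            config, units = space.sample(rng)
        else:
            best_i = int(np.argmin([t.loss for t in history]))
            pool_units = []
            for c in range(16):
                if c % 2 == 0:  # local move around the incumbent
                    u = units_hist[best_i] + rng.normal(0, 0.15, len(widths)) * widths
                    u = np.array([p.clip_unit(v) for p, v in zip(space.params, u)])
                else:
                    _, u = space.sample(rng)
                pool_units.append(u)
            # k-NN surrogate on normalized coordinates
            H = (np.array(units_hist) - [p.low for p in space.params]) / widths
            scores = []
            for u in pool_units:
                un = (u - np.array([p.low for p in space.params])) / widths
                d = np.linalg.norm(H - un, axis=1)
                nn = np.argsort(d)[:3]
                scores.append(np.mean([history[j].loss for j in nn]))
            units = pool_units[int(np.argmin(scores))]
            config = space._materialize(units)
        history.append(_evaluate(objective, config, i))
        units_hist.append(units)
    best = min(history, key=lambda t: (t.loss, t.index))
    return best, history
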