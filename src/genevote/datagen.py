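"""Synthetic two-class expression matrices with planted structure.

Emulates the small-n/large-p microarray regime (tens of samples, ~1000
probe sets) that the selection pipeline targets: a handful of informative
genes carrying an additive class-mean shift, blocks of redundant genes that
are noisy linear copies of an informative parent, and the remainder pure
label-independent Gaussian noise.  Ground truth identifies every planted
gene so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import ExpressionMatrix

__all__ = ["SimulationSpec", "GroundTruth", "generate_dataset"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the planted-signal generator.

    effect_size is the class-mean shift of informative genes in units of the
    within-class standard deviation (``noise_sd``).  redundancy_rho is the
    target Pearson correlation between a redundant gene and its parent.
    """

    n_samples: int = 28
    n_genes: int = 1070
    n_informative: int = 10
    effect_size: float = 2.0
    n_redundant_per_informative: int = 2
    redundancy_rho: float = 0.8
    class_balance: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 samples and 1 gene")
        if self.n_informative < 0 or self.n_redundant_per_informative < 0:
            raise ValueError("planted gene counts must be non-negative")
        if self.n_planted > self.n_genes:
            raise ValueError(
                f"{self.n_planted} planted genes exceed n_genes={self.n_genes}"
            )
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if not 0 <= self.redundancy_rho <= 1:
            raise ValueError("redundancy_rho must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_planted(self) -> int:
        return self.n_informative * (1 + self.n_redundant_per_informative)


@dataclass(frozen=True)
class GroundTruth:
    """Which gene ids were planted, and which parent each copy tracks."""

    informative_gene_ids: list[str]
    redundant_gene_ids: list[str]
    parent_map: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.informative_gene_ids) & set(self.redundant_gene_ids):
            raise ValueError("informative and redundant id sets must be disjoint")
        if set(self.parent_map) != set(self.redundant_gene_ids):
            raise ValueError("parent_map keys must equal redundant_gene_ids")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}_at" for i in range(n)]


def generate_dataset(spec: SimulationSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one dataset; bit-identical for identical ``spec``.

    Labels: ``round(n_samples * class_balance)`` samples of class 1, the
    rest class 0.  Informative genes get ``effect_size * noise_sd`` added
    for class-1 samples.  A redundant copy of parent z is
    ``rho * z + eps`` with eps scaled so the population correlation with z
    equals ``redundancy_rho`` exactly.  Planted genes are scattered over
    random column positions.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_genes
    n_pos = int(round(n * spec.class_balance))
    if n_pos in (0, n):
        raise ValueError("class_balance leaves a class empty at this n_samples")
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1

    values = rng.normal(0.0, spec.noise_sd, size=(n, p))

    positions = rng.permutation(p)
    info_pos = positions[: spec.n_informative]
    red_pos = positions[
        spec.n_informative : spec.n_informative
        + spec.n_informative * spec.n_redundant_per_informative
    ]

    shift = spec.effect_size * spec.noise_sd
    if spec.n_informative:
        values[np.ix_(labels == 1, info_pos)] += shift

    # population variance of an informative gene (balance-weighted shift)
    b = n_pos / n
    parent_var = spec.noise_sd**2 + b * (1 - b) * shift**2
    rho = spec.redundancy_rho
    eps_sd = float(np.sqrt(parent_var * (1 - rho**2)))

    parent_map_pos: dict[int, int] = {}
    for j, rp in enumerate(red_pos):
        parent = info_pos[j % max(spec.n_informative, 1)]
        values[:, rp] = rho * values[:, parent] + rng.normal(0.0, eps_sd, size=n)
        parent_map_pos[rp] = parent

    ids = _gene_ids(p)
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    matrix = ExpressionMatrix(values, ids, sample_ids, labels)
    truth = GroundTruth(
        informative_gene_ids=[ids[i] for i in info_pos],
        redundant_gene_ids=[ids[i] for i in red_pos],
        parent_map={ids[r]: ids[pa] for r, pa in parent_map_pos.items()},
    )
    return matrix, truth
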