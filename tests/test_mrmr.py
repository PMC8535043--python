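import numpy as np
import pytest

from genevote import (ExpressionMatrix, MrmrConfig, SimulationSpec,
                      generate_dataset, mrmr_bootstrap, mrmr_exhaustive,
                      mrmr_rank, relevance)


def brute_force_trace(values, labels, m, scheme, first=None, eps=1e-6):
    """Independent step-by-step evaluation of the greedy mRMR criterion."""
    def absr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return abs(np.corrcoef(a, b)[0, 1])

    p = values.shape[1]
    rel = [absr(values[:, i], labels.astype(float)) for i in range(p)]
    selected = []
    for step in range(m):
        if step == 0 and first is not None:
            selected.append(int(first))
            continue
        best, best_score = None, -np.inf
        for i in range(p):
            if i in selected:
                continue
            if step == 0:
                score = rel[i]
            else:
                red = np.mean([absr(values[:, i], values[:, j]) for j in selected])
                score = rel[i] / max(red, eps) if scheme == "quotient" else rel[i] - red
            if score > best_score:  # strict ">" keeps the lowest index on ties
                best, best_score = i, score
        selected.append(best)
    return selected


def random_instance(rng, n=30, p=8):
    values = rng.normal(size=(n, p))
    labels = rng.integers(0, 2, size=n)
    while len(set(labels)) < 2:
        labels = rng.integers(0, 2, size=n)
    values[:, 0] += labels  # some signal so relevance is not pure noise
    return ExpressionMatrix(values, [f"g{i:02d}" for i in range(p)],
                            [f"s{i}" for i in range(n)], labels)


def test_relevance_examples():
    rng = np.random.default_rng(0)
    n = 1000
    labels = rng.integers(0, 2, n)
    values = np.column_stack([
        labels.astype(float),        # identical to the label: maximal
        rng.normal(size=n),          # label-independent: near zero
        labels.astype(float),        # duplicate of gene 0
    ])
    m = ExpressionMatrix(values, ["gL", "gN", "gL2"], [f"s{i}" for i in range(n)],
                         labels)
    rel = relevance(m)
    assert rel[0] == max(rel) and rel[0] == pytest.approx(1.0)
    assert rel[1] < 0.1
    assert rel[2] == pytest.approx(rel[0])


def test_relevance_single_class_errors():
    m = ExpressionMatrix(np.ones((4, 2)), ["a", "b"], list("wxyz"), [1, 1, 1, 1])
    with pytest.raises(ValueError, match="class"):
        relevance(m)


def test_m1_reduces_to_relevance_argmax():
    rng = np.random.default_rng(5)
    m = random_instance(rng)
    gs = mrmr_rank(m, MrmrConfig(m=1))
    assert gs.gene_ids == [m.gene_ids[int(np.argmax(relevance(m)))]]


def test_redundant_twin_deferred_to_weak_independent_gene():
    # A and its exact copy A' are highly relevant; C is weakly relevant but
    # carries new information — quotient mRMR picks (A, C)
    rng = np.random.default_rng(2)
    n = 400
    labels = np.array([0, 1] * (n // 2))
    a = labels + 0.3 * rng.normal(size=n)
    c = 0.3 * labels + np.sqrt(1 - 0.09) * rng.normal(size=n) * 0.5
    m = ExpressionMatrix(np.column_stack([a, a.copy(), c]), ["gA", "gA2", "gC"],
                         [f"s{i}" for i in range(n)], labels)
    gs = mrmr_rank(m, MrmrConfig(m=2, scheme="quotient"))
    assert gs.gene_ids == ["gA", "gC"]


@pytest.mark.parametrize("scheme", ["quotient", "difference"])
def test_greedy_trace_matches_brute_force(scheme):
    rng = np.random.default_rng(7)
    for _ in range(10):
        m = random_instance(rng, n=25, p=6)
        got = mrmr_rank(m, MrmrConfig(m=4, scheme=scheme))
        expected = brute_force_trace(m.values, m.labels, 4, scheme)
        assert [m.gene_ids[i] for i in expected] == got.gene_ids


def test_exhaustive_heads_distinct_and_match_oracle():
    rng = np.random.default_rng(9)
    m = random_instance(rng, n=30, p=6)
    config = MrmrConfig(m=3)
    sols = mrmr_exhaustive(m, config, k_starts=3)
    heads = [s.gene_ids[0] for s in sols]
    assert len(set(heads)) == 3
    assert sols[0].gene_ids == mrmr_rank(m, config).gene_ids
    rel = relevance(m)
    order = np.argsort(-rel, kind="stable")
    for i, sol in enumerate(sols):
        expected = brute_force_trace(m.values, m.labels, 3, "quotient",
                                     first=int(order[i]))
        assert sol.gene_ids == [m.gene_ids[j] for j in expected]
    assert mrmr_exhaustive(m, config, 1)[0].gene_ids == sols[0].gene_ids
    with pytest.raises(ValueError):
        mrmr_exhaustive(m, config, k_starts=99)


def test_bootstrap_deterministic_and_stable_on_planted_signal():
    # a dominant signature gene (plus correlated copies) keeps being found:
    # it should sit in the top-5 of nearly every bootstrap solution
    matrix, truth = generate_dataset(SimulationSpec(
        n_samples=100, n_genes=50, n_informative=1, effect_size=2.0,
        n_redundant_per_informative=3, redundancy_rho=0.8, seed=4))
    config = MrmrConfig(m=5)
    sols1 = mrmr_bootstrap(matrix, config, k_boot=10, seed=21)
    sols2 = mrmr_bootstrap(matrix, config, k_boot=10, seed=21)
    assert [s.gene_ids for s in sols1] == [s.gene_ids for s in sols2]
    top_planted = truth.informative_gene_ids[0]
    hits = sum(top_planted in s.gene_ids for s in sols1)
    assert hits >= 8


def test_gene_permutation_does_not_change_selection():
    rng = np.random.default_rng(13)
    m = random_instance(rng, n=40, p=8)
    perm = rng.permutation(m.n_genes)
    permuted = ExpressionMatrix(m.values[:, perm], [m.gene_ids[i] for i in perm],
                                m.sample_ids, m.labels)
    a = mrmr_rank(m, MrmrConfig(m=5))
    b = mrmr_rank(permuted, MrmrConfig(m=5))
    assert a.gene_ids == b.gene_ids


def test_schemes_agree_on_first_gene():
    rng = np.random.default_rng(17)
    for _ in range(5):
        m = random_instance(rng)
        q = mrmr_rank(m, MrmrConfig(m=2, scheme="quotient"))
        d = mrmr_rank(m, MrmrConfig(m=2, scheme="difference"))
        assert q.gene_ids[0] == d.gene_ids[0]


def test_m_exceeding_gene_count_errors():
    rng = np.random.default_rng(1)
    m = random_instance(rng, p=4)
    with pytest.raises(ValueError):
        mrmr_rank(m, MrmrConfig(m=5))
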