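import numpy as np
import pytest

from genevote import (ExpressionMatrix, GeneSet, ImportanceTable,
                      SelectorConfig, correlation_prune, embedded_svm_rank,
                      fold_importances, make_folds, merge_unique,
                      normalize_importances, select_by_votes, select_genes,
                      sweep_threshold, threshold_filter, vote)
from genevote.selector import VoteTally


def table_from(rows, ids, normalized=True):
    return ImportanceTable(np.asarray(rows, float), ids, normalized=normalized)


def test_fold_importances_shape_and_determinism(small_matrix, variance_provider):
    folds = make_folds(small_matrix.labels, 3, seed=0)
    t1 = fold_importances(small_matrix, folds, variance_provider)
    t2 = fold_importances(small_matrix, folds, variance_provider)
    assert t1.fold_importances.shape == (3, 4)
    assert np.array_equal(t1.fold_importances, t2.fold_importances)


def test_fold_importances_error_names_fold(small_matrix):
    class Broken:
        def importances(self, X, y):
            raise RuntimeError("boom")

        def make_classifier(self):
            raise NotImplementedError

    folds = make_folds(small_matrix.labels, 3, seed=0)
    with pytest.raises(RuntimeError, match="fold 0"):
        fold_importances(small_matrix, folds, Broken())


def test_equal_importances_survive_any_threshold(small_matrix, equal_provider):
    folds = make_folds(small_matrix.labels, 3, seed=0)
    table = normalize_importances(fold_importances(small_matrix, folds,
                                                   equal_provider))
    for t in (0.0, 0.5, 0.99):
        sets = threshold_filter(table, t)
        assert all(len(s) == small_matrix.n_genes for s in sets)


def test_normalize_rows():
    table = table_from([[2, 4, 8], [0, 0, 0]], ["a", "b", "c"], normalized=False)
    normed = normalize_importances(table)
    assert np.allclose(normed.fold_importances[0], [0.25, 0.5, 1.0])
    assert np.all(normed.fold_importances[1] == 0)
    again = normalize_importances(normed)
    assert np.allclose(again.fold_importances, normed.fold_importances)


def test_threshold_filter_is_strict_at_the_boundary():
    table = table_from([[0.9, 0.5, 0.84]], ["g1", "g2", "g3"])
    sets = threshold_filter(table, 0.84)
    assert sets[0].gene_ids == ["g1"]
    assert all(len(s) == 0 for s in threshold_filter(table, 1.0))
    with pytest.raises(ValueError):
        threshold_filter(table, 1.5)


def test_vote_enumeration():
    sets = [GeneSet(["A", "B"]), GeneSet(["A"]), GeneSet(["A", "C"])]
    tally = vote(sets)
    assert tally.votes == {"A": 3, "B": 1, "C": 1}


def test_select_by_votes_truncates_by_mean_importance():
    # 60 genes, all in every fold: keep the 50 with highest mean importance
    ids = [f"g{i:02d}" for i in range(60)]
    imp = np.tile(np.linspace(1.0, 0.1, 60), (4, 1))
    table = table_from(imp, ids)
    tally = vote([GeneSet(ids)] * 4)
    got = select_by_votes(tally, table, SelectorConfig(n_final=50))
    assert len(got) == 50
    assert got.gene_ids == ids[:50]


def test_select_by_votes_never_fabricates_and_breaks_ties_by_id():
    table = table_from([[0.5, 0.5, 0.5]], ["gC", "gA", "gB"])
    tally = VoteTally({"gC": 1, "gA": 1}, k=1)
    got = select_by_votes(tally, table, SelectorConfig(n_final=50))
    assert got.gene_ids == ["gA", "gC"]  # equal votes, equal means -> id order


def test_select_by_votes_min_votes_floor():
    table = table_from([[1.0, 0.9]] * 4, ["g1", "g2"])
    tally = VoteTally({"g1": 4, "g2": 2}, k=4)
    got = select_by_votes(tally, table, SelectorConfig(min_votes="auto", k=4))
    assert got.gene_ids == ["g1"]


def test_sweep_threshold_perfectly_separable_signal(variance_provider):
    # one gene separates the classes; wherever it survives, CV accuracy is 1,
    # so the sweep returns the smallest grid point
    rng = np.random.default_rng(0)
    n = 24
    labels = np.array([0, 1] * (n // 2))
    values = np.column_stack([
        labels * 10.0 + rng.normal(0, 0.1, n),  # huge variance + separates
        rng.normal(0, 0.5, n),
    ])
    m = ExpressionMatrix(values, ["gSig", "gNoise"],
                         [f"s{i}" for i in range(n)], labels)
    folds = make_folds(m.labels, 4, seed=1)
    best_t, curve = sweep_threshold(m, folds, variance_provider,
                                    grid=[0.0, 0.2, 0.5],
                                    config=SelectorConfig(k=4, n_final=5))
    assert best_t == 0.0
    assert all(acc == 1.0 for _, acc in curve)
    single, _ = sweep_threshold(m, folds, variance_provider, grid=[0.3],
                                config=SelectorConfig(k=4, n_final=5))
    assert single == 0.3


def test_embedded_svm_ranks_informative_gene_first():
    rng = np.random.default_rng(3)
    n = 40
    labels = np.array([0, 1] * (n // 2))
    values = np.column_stack([rng.normal(size=n),
                              labels + 0.2 * rng.normal(size=n)])
    m = ExpressionMatrix(values, ["gNoise", "gSig"],
                         [f"s{i}" for i in range(n)], labels)
    assert embedded_svm_rank(m, top_m=2).gene_ids[0] == "gSig"
    # duplicated genes tie on |weight| and fall back to id order
    dup = ExpressionMatrix(np.column_stack([values[:, 1], values[:, 1]]),
                           ["gZ", "gA"], [f"s{i}" for i in range(n)], labels)
    assert embedded_svm_rank(dup, top_m=2).gene_ids == ["gA", "gZ"]
    assert sorted(embedded_svm_rank(m, top_m=2).gene_ids) == sorted(m.gene_ids)


def test_merge_unique():
    a, b = GeneSet(["A", "B"]), GeneSet(["B", "C"])
    merged = merge_unique([a, b], seed=0)
    assert sorted(merged.gene_ids) == ["A", "B", "C"]
    disjoint = merge_unique([GeneSet(["A"]), GeneSet(["B"])], seed=0)
    assert sorted(disjoint.gene_ids) == ["A", "B"]
    assert sorted(merge_unique([a], seed=5).gene_ids) == sorted(a.gene_ids)


def exact_corr_columns(rho_ab, rho_bc, rho_ac, n=400, seed=0):
    """Three columns with the requested *exact* sample correlations."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 3))
    # orthonormalize, then mix with the Cholesky factor of the target matrix
    q, _ = np.linalg.qr(base - base.mean(axis=0))
    target = np.array([[1, rho_ab, rho_ac], [rho_ab, 1, rho_bc],
                       [rho_ac, rho_bc, 1]])
    return q @ np.linalg.cholesky(target).T


def test_correlation_prune_chain():
    cols = exact_corr_columns(0.6, 0.6, 0.1)
    m = ExpressionMatrix(cols, ["A", "B", "C"], [f"s{i}" for i in range(len(cols))],
                         [0, 1] * (len(cols) // 2))
    kept = correlation_prune(m, GeneSet(["A", "B", "C"]), r_max=0.5)
    assert kept.gene_ids == ["A", "C"]


def test_correlation_prune_duplicates_and_independents():
    rng = np.random.default_rng(8)
    x = rng.normal(size=100)
    m = ExpressionMatrix(np.column_stack([x, x, rng.normal(size=100)]),
                         ["g1", "g2", "g3"], [f"s{i}" for i in range(100)],
                         [0, 1] * 50)
    kept = correlation_prune(m, GeneSet(["g1", "g2", "g3"]), r_max=0.5)
    assert kept.gene_ids == ["g1", "g3"]
    loose = correlation_prune(m, GeneSet(["g1", "g3"]), r_max=0.5)
    assert loose.gene_ids == ["g1", "g3"]


def test_correlation_prune_constant_gene_kept_unless_duplicated():
    m = ExpressionMatrix(
        np.column_stack([np.ones(10), np.ones(10), np.arange(10.0)]),
        ["c1", "c2", "g"], [f"s{i}" for i in range(10)], [0, 1] * 5)
    kept = correlation_prune(m, GeneSet(["c1", "c2", "g"]), r_max=0.5)
    assert kept.gene_ids == ["c1", "g"]


def test_pipeline_outputs_subset_of_inputs_and_deterministic(planted,
                                                             variance_provider):
    matrix, _ = planted
    cfg = SelectorConfig(k=4, threshold=0.0, n_final=20, seed=5)
    r1 = select_genes(matrix, cfg, provider=variance_provider)
    r2 = select_genes(matrix, cfg, provider=variance_provider)
    assert set(r1.selected.gene_ids) <= set(matrix.gene_ids)
    assert set(r1.pruned.gene_ids) <= set(r1.selected.gene_ids)
    assert r1.selected.gene_ids == r2.selected.gene_ids
    assert r1.pruned.gene_ids == r2.pruned.gene_ids
    # prune postcondition: no kept pair at or above the cutoff
    sub = matrix.subset_genes(r1.pruned.gene_ids)
    corr = np.corrcoef(sub.values.T)
    np.fill_diagonal(corr, 0.0)
    assert np.abs(corr).max() < cfg.r_max


def test_pipeline_optional_stages_extend_the_panel(planted):
    matrix, _ = planted
    base = SelectorConfig(k=4, threshold=0.0, n_final=10, seed=5)
    both = SelectorConfig(k=4, threshold=0.0, n_final=10, seed=5,
                          use_embedded_svm=True, use_mrmr_union=True)
    from genevote import GradientBoostingProvider
    provider = GradientBoostingProvider(seed=5, n_estimators=50)
    r_base = select_genes(matrix, base, provider=provider)
    r_both = select_genes(matrix, both, provider=provider)
    assert set(r_base.selected.gene_ids) <= set(r_both.selected.gene_ids)
    assert "svm_unique" in r_both.stages and "mrmr_union" in r_both.stages
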