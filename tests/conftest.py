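import numpy as np
import pytest

from genevote import ExpressionMatrix, SimulationSpec, generate_dataset


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """6 samples x 4 genes with hand-set values and balanced labels."""
    values = np.array([
        [2.0, 1.0, 0.0, 5.0],
        [4.0, 1.5, 1.0, 5.0],
        [6.0, 0.5, 2.0, 5.0],
        [8.0, 9.0, 3.0, 5.0],
        [10.0, 9.5, 4.0, 5.0],
        [12.0, 8.5, 5.0, 5.0],
    ])
    return ExpressionMatrix(values, ["gA", "gB", "gC", "gD"],
                            [f"s{i}" for i in range(6)],
                            np.array([0, 0, 0, 1, 1, 1]))


@pytest.fixture
def planted():
    """A moderately sized planted-signal dataset with known ground truth."""
    spec = SimulationSpec(n_samples=60, n_genes=120, n_informative=5,
                          effect_size=2.0, n_redundant_per_informative=1,
                          redundancy_rho=0.8, seed=11)
    return generate_dataset(spec)


class EqualImportanceProvider:
    """Deterministic stub: every gene equally important."""

    def importances(self, X, y):
        return np.ones(X.shape[1])

    def make_classifier(self):
        from sklearn.dummy import DummyClassifier
        return DummyClassifier(strategy="most_frequent")


class VarianceImportanceProvider:
    """Deterministic stub: importance = per-gene variance of the training data."""

    def importances(self, X, y):
        return X.var(axis=0)

    def make_classifier(self):
        from sklearn.naive_bayes import GaussianNB
        return GaussianNB()


@pytest.fixture
def equal_provider():
    return EqualImportanceProvider()


@pytest.fixture
def variance_provider():
    return VarianceImportanceProvider()
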