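import numpy as np
import pandas as pd
import pytest

from oice.graph import CausalGraph
from oice.scm import LinearMechanism, StructuralCausalModel


class LogisticStub:
    """Hand-set logistic classifier over one feature, sklearn-flavored.

    p(target) = sigmoid(weight * (x[feature] - threshold)); classes_
    is (source, target) so predict_proba column 1 is the target class.
    """

    def __init__(self, feature, threshold, weight=2.0, classes=("control", "AD")):
        self.feature = feature
        self.threshold = threshold
        self.weight = weight
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        x = X[self.feature].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.atleast_2d(X)[:, self.feature]
        p = 1.0 / (1.0 + np.exp(-self.weight * (x - self.threshold)))
        return np.column_stack([1.0 - p, p])


@pytest.fixture
def toy_scm():
    """X2 = 2*X1 + u2, X1 = u1 (identity standardization)."""
    graph = CausalGraph(["X1", "X2"], [("X1", "X2")])
    return StructuralCausalModel.from_mechanisms(graph, {
        "X1": LinearMechanism("X1", [], [], 0.0, 1.0),
        "X2": LinearMechanism("X2", ["X1"], [2.0], 0.0, 1.0),
    })


@pytest.fixture
def abc_scm():
    """Three count features: A -> B, C isolated, in count space.

    B = 5 + 0.8*(A - 5) + u_B; A = 5 + u_A; C = 5 + u_C (standardization
    mean 5, scale 1, so counts live near 5).
    """
    graph = CausalGraph(["A", "B", "C"], [("A", "B")])
    mechs = {
        "A": LinearMechanism("A", [], [], 0.0, 1.0),
        "B": LinearMechanism("B", ["A"], [0.8], 0.0, 1.0),
        "C": LinearMechanism("C", [], [], 0.0, 1.0),
    }
    return StructuralCausalModel.from_mechanisms(
        graph, mechs, means=[5.0, 5.0, 5.0], scales=[1.0, 1.0, 1.0])


@pytest.fixture
def abc_cohort(abc_scm):
    rng = np.random.default_rng(7)
    u = rng.standard_normal((40, 3))
    counts = np.clip(np.rint(abc_scm.destandardize(abc_scm.generate(u))), 0, None)
    return pd.DataFrame(counts.astype(int), columns=["A", "B", "C"])
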