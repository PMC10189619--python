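"""Structural causal model with generative neural-network mechanisms.

The model is the triplet (X, F, U): endogenous variables X (the
feature columns), one causal mechanism F_i per node, and independent
standard-normal exogenous noise U_i.  Mechanisms are *additive* in
their noise,

    X_i = f_i(PA_i) + sigma_i * U_i,

with f_i either a one-hidden-layer tanh network (trained) or a linear
map (hand-set, used for ground-truth worlds and tests).  Additivity
makes abduction closed-form: given an observed sample, the noise that
produced it is recovered exactly as U_i = (X_i - f_i(PA_i)) / sigma_i,
so counterfactuals keep the individual's "background conditions" while
a do-intervention pins one variable and lets its descendants respond.

Training minimizes the joint maximum mean discrepancy (multi-bandwidth
Gaussian kernel) between observed samples and samples generated by
ancestral sampling, in the spirit of causal generative neural networks.
All numerics run on standardized (zero-mean, unit-variance) columns;
the model stores the standardization constants so callers can move
between count space and model space.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._autodiff import Adam, SGD, Tensor, concat
from .graph import CausalGraph

__all__ = ["LinearMechanism", "MLPMechanism", "StructuralCausalModel", "mmd"]

# CGNN-style multi-bandwidth kernel: widths applied to the median
# pairwise squared distance of the data.
DEFAULT_BANDWIDTH_WIDTHS = (0.005, 0.05, 0.25, 0.5, 1.0, 5.0, 50.0)


class LinearMechanism:
    """x = w . parents + b + sigma * u, for hand-specified models."""

    def __init__(self, node: str, parents: Sequence[str], weights, intercept: float, sigma: float):
        if sigma <= 0:
            raise ValueError(f"sigma must be positive for node {node}")
        self.node = node
        self.parents = list(parents)
        self.weights = np.asarray(weights, dtype=float).reshape(len(self.parents))
        self.intercept = float(intercept)
        self.sigma = float(sigma)

    def f(self, parent_values: np.ndarray) -> np.ndarray:
        if not self.parents:
            return np.full(parent_values.shape[0], self.intercept)
        return parent_values @ self.weights + self.intercept


class MLPMechanism:
    """One-hidden-layer tanh network f plus a positive noise scale.

    Root nodes (no parents) collapse to a learned constant mean, so a
    root is mu + sigma * u.
    """

    def __init__(self, node: str, parents: Sequence[str], hidden: int, rng: np.random.Generator):
        self.node = node
        self.parents = list(parents)
        p = len(self.parents)
        self.hidden = hidden
        scale = 1.0 / np.sqrt(max(p, 1))
        self.W1 = rng.normal(0.0, scale, size=(p, hidden))
        self.b1 = rng.normal(0.0, 0.1, size=hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
        self.b2 = 0.0
        self.log_sigma = 0.0  # sigma = 1 at init

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    def f(self, parent_values: np.ndarray) -> np.ndarray:
        if not self.parents:
            return np.full(parent_values.shape[0], self.b2)
        h = np.tanh(parent_values @ self.W1 + self.b1)
        return h @ self.W2 + self.b2


def _median_sq_distance(x: np.ndarray) -> float:
    n = min(len(x), 500)
    sub = x[:n]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    med = float(np.median(d2[np.triu_indices(n, k=1)]))
    return med if med > 0 else 1.0


def _gammas(base: float, widths=DEFAULT_BANDWIDTH_WIDTHS) -> np.ndarray:
    return 1.0 / (np.asarray(widths) * base)


def mmd(sample_a, sample_b, bandwidths: Sequence[float] | None = None, biased: bool = True) -> float:
    """Multi-bandwidth Gaussian-kernel MMD^2 between two sample sets.

    The biased (V-statistic) estimator is the default: it is symmetric,
    nonnegative, and exactly zero when the two sample sets coincide.
    ``bandwidths`` are kernel variances; by default they are the
    standard width multiples of the pooled median pairwise squared
    distance.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    if bandwidths is None:
        base = _median_sq_distance(np.vstack([a, b]))
        gammas = _gammas(base)
    else:
        gammas = 1.0 / np.asarray(bandwidths, dtype=float)

    def kmat(x, y):
        d2 = ((x[:, None, :] - y[None, :, :]) ** 2).sum(-1)
        return sum(np.exp(-g * d2) for g in gammas)

    kaa, kbb, kab = kmat(a, a), kmat(b, b), kmat(a, b)
    if biased:
        return float(kaa.mean() + kbb.mean() - 2 * kab.mean())
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("unbiased estimator needs at least 2 samples per set")
    np.fill_diagonal(kaa, 0.0)
    np.fill_diagonal(kbb, 0.0)
    return float(kaa.sum() / (na * (na - 1)) + kbb.sum() / (nb * (nb - 1)) - 2 * kab.mean())


def _mmd2_tensor(gen: Tensor, data: Tensor, gammas: np.ndarray) -> Tensor:
    """Biased MMD^2 as an autodiff graph (gradient flows through ``gen``)."""

    def sqdist(x: Tensor, y: Tensor) -> Tensor:
        xx = (x * x).sum(axis=1, keepdims=True)           # (n,1)
        yy = (y * y).sum(axis=1, keepdims=True)           # (m,1)
        return xx + yy.transpose(1, 0) - 2.0 * (x @ y.transpose(1, 0))

    daa, dbb, dab = sqdist(gen, gen), sqdist(data, data), sqdist(gen, data)
    loss = None
    for g in gammas:
        term = ((daa * -g).exp().mean() + (dbb * -g).exp().mean()
                - 2.0 * (dab * -g).exp().mean())
        loss = term if loss is None else loss + term
    return loss


class StructuralCausalModel:
    """SCM estimator: fit mechanisms by MMD, then generate/abduct/intervene.

    Parameters follow scikit-learn conventions; fitted state carries a
    trailing underscore.  ``fit`` expects a DataFrame whose columns are
    exactly the graph's nodes.

    Parameters
    ----------
    graph : CausalGraph
        Fixed causal structure; one mechanism is learned per node.
    hidden_units : int
        Width of each mechanism's hidden layer.
    epochs, learning_rate, batch_size : training loop controls.
    optimizer : "adam" or "sgd" (momentum 0.9).
    seed : int
        Controls initialization and the noise draws during training.
    """

    def __init__(self, graph: CausalGraph, hidden_units: int = 20, epochs: int = 500,
                 learning_rate: float = 1e-2, batch_size: int = 128,
                 optimizer: str = "adam", seed: int = 0):
        self.graph = graph
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.seed = seed

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("graph", "hidden_units", "epochs", "learning_rate",
                 "batch_size", "optimizer", "seed")}

    def set_params(self, **params) -> "StructuralCausalModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- construction from explicit mechanisms ------------------------------
    @classmethod
    def from_mechanisms(cls, graph: CausalGraph, mechanisms: Mapping[str, object],
                        means=None, scales=None) -> "StructuralCausalModel":
        """Build a ready-to-use model from hand-specified mechanisms.

        ``means``/``scales`` are the count-space standardization
        constants (default identity).
        """
        model = cls(graph)
        model.nodes_ = list(graph.nodes)
        if set(mechanisms) != set(model.nodes_):
            raise ValueError("need exactly one mechanism per node")
        for node in model.nodes_:
            mech = mechanisms[node]
            if list(mech.parents) != graph.parents(node):
                raise ValueError(
                    f"mechanism parents {mech.parents} do not match graph "
                    f"parents {graph.parents(node)} for node {node}")
            if mech.sigma <= 0:
                raise ValueError(f"sigma must be positive for node {node}")
        model.mechanisms_ = dict(mechanisms)
        d = len(model.nodes_)
        model.means_ = np.zeros(d) if means is None else np.asarray(means, dtype=float)
        model.scales_ = np.ones(d) if scales is None else np.asarray(scales, dtype=float)
        model.loss_trace_ = []
        return model

    # -- standardization ----------------------------------------------------
    def standardize(self, x) -> np.ndarray:
        arr = self._as_array(x)
        return (arr - self.means_) / self.scales_

    def destandardize(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) * self.scales_ + self.means_

    def _as_array(self, x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            return x[self.nodes_].to_numpy(dtype=float)
        if isinstance(x, pd.Series):
            return x[self.nodes_].to_numpy(dtype=float)
        return np.asarray(x, dtype=float)

    # -- core SCM operations (standardized space) ---------------------------
    def generate(self, u, interventions: Mapping[str, float | np.ndarray] | None = None) -> np.ndarray:
        """Ancestral generation x = G(u, I; F) in standardized space.

        Nodes are evaluated in topological order; intervened nodes are
        pinned to their value (mechanism and noise severed), all others
        follow x_i = f_i(PA_i) + sigma_i * u_i.  ``u`` may be (d,) or
        (B, d); intervention values broadcast over the batch.
        """
        u_arr = np.atleast_2d(np.asarray(u, dtype=float))
        if u_arr.shape[1] != len(self.nodes_):
            raise ValueError("exogenous vector has wrong dimension")
        interventions = interventions or {}
        for node in interventions:
            if node not in self.nodes_:
                raise KeyError(f"unknown intervention node {node}")
        idx = {n: i for i, n in enumerate(self.nodes_)}
        x = np.empty_like(u_arr)
        for node in self.graph.topological_order():
            i = idx[node]
            if node in interventions:
                x[:, i] = np.broadcast_to(np.asarray(interventions[node], dtype=float),
                                          (u_arr.shape[0],))
            else:
                mech = self.mechanisms_[node]
                pa = x[:, [idx[p] for p in mech.parents]]
                x[:, i] = mech.f(pa) + mech.sigma * u_arr[:, i]
        return x if np.ndim(u) == 2 else x[0]

    def abduct(self, x) -> np.ndarray:
        """Recover the exogenous noise u such that generate(u) == x exactly."""
        x_arr = np.atleast_2d(self._as_array(x))
        idx = {n: i for i, n in enumerate(self.nodes_)}
        u = np.empty_like(x_arr)
        for node in self.graph.topological_order():
            i = idx[node]
            mech = self.mechanisms_[node]
            if mech.sigma <= 0:
                raise ValueError(f"non-positive sigma for node {node}")
            pa = x_arr[:, [idx[p] for p in mech.parents]]
            u[:, i] = (x_arr[:, i] - mech.f(pa)) / mech.sigma
        return u if np.ndim(x) == 2 or isinstance(x, pd.DataFrame) else u[0]

    def sample(self, n: int, seed: int | None = None,
               interventions: Mapping[str, float] | None = None) -> np.ndarray:
        """Draw n samples (standardized space), optionally under do()."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        u = rng.standard_normal((n, len(self.nodes_)))
        return self.generate(u, interventions)

    # -- MMD training --------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "StructuralCausalModel":
        """Train all mechanism parameters jointly against the joint MMD."""
        if isinstance(X, pd.DataFrame):
            if set(X.columns) != set(self.graph.nodes):
                raise ValueError("data columns must match graph nodes")
            data_raw = X[list(self.graph.nodes)].to_numpy(dtype=float)
        else:
            data_raw = np.asarray(X, dtype=float)
        self.nodes_ = list(self.graph.nodes)
        d = len(self.nodes_)
        if data_raw.shape[1] != d:
            raise ValueError("data has wrong number of columns")
        self.means_ = data_raw.mean(axis=0)
        scales = data_raw.std(axis=0)
        self.scales_ = np.where(scales > 0, scales, 1.0)
        data = (data_raw - self.means_) / self.scales_

        rng = np.random.default_rng(self.seed)
        mechs = {n: MLPMechanism(n, self.graph.parents(n), self.hidden_units, rng)
                 for n in self.nodes_}
        params: dict[str, dict[str, Tensor]] = {}
        flat: list[Tensor] = []
        for n, m in mechs.items():
            group = {
                "W1": Tensor(m.W1, requires_grad=True),
                "b1": Tensor(m.b1, requires_grad=True),
                "W2": Tensor(m.W2.reshape(-1, 1), requires_grad=True),
                "b2": Tensor(np.array(m.b2), requires_grad=True),
                "log_sigma": Tensor(np.array(m.log_sigma), requires_grad=True),
            }
            params[n] = group
            flat.extend(group.values())
        if self.optimizer == "adam":
            opt = Adam(flat, lr=self.learning_rate)
        elif self.optimizer == "sgd":
            opt = SGD(flat, lr=self.learning_rate, momentum=0.9)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        gammas = _gammas(_median_sq_distance(data))
        idx = {n: i for i, n in enumerate(self.nodes_)}
        topo = self.graph.topological_order()
        batch = min(self.batch_size, len(data))
        self.loss_trace_ = []
        for epoch in range(self.epochs):
            take = rng.choice(len(data), size=batch, replace=False)
            target = Tensor(data[take])
            u = rng.standard_normal((batch, d))
            cols: dict[str, Tensor] = {}
            for node in topo:
                g = params[node]
                pars = self.graph.parents(node)
                sigma = g["log_sigma"].exp()
                noise = Tensor(u[:, [idx[node]]])
                if pars:
                    pa = concat([cols[p] for p in pars], axis=1)
                    h = (pa @ g["W1"] + g["b1"]).tanh()
                    cols[node] = h @ g["W2"] + g["b2"] + sigma * noise
                else:
                    cols[node] = g["b2"] + sigma * noise
            gen = concat([cols[n] for n in self.nodes_], axis=1)
            loss = _mmd2_tensor(gen, target, gammas)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite MMD loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            self.loss_trace_.append(loss.item())

        for n, m in mechs.items():
            g = params[n]
            m.W1 = g["W1"].data
            m.b1 = g["b1"].data
            m.W2 = g["W2"].data.reshape(-1)
            m.b2 = float(g["b2"].data)
            m.log_sigma = float(g["log_sigma"].data)
        self.mechanisms_ = mechs
        return self

    # -- checkpointing --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize graph, mechanisms and standardization to a JSON archive."""
        mechs = {}
        for n, m in self.mechanisms_.items():
            if isinstance(m, LinearMechanism):
                mechs[n] = {"type": "linear", "parents": m.parents,
                            "weights": m.weights.tolist(),
                            "intercept": m.intercept, "sigma": m.sigma}
            else:
                mechs[n] = {"type": "mlp", "parents": m.parents,
                            "W1": m.W1.tolist(), "b1": m.b1.tolist(),
                            "W2": m.W2.tolist(), "b2": m.b2,
                            "log_sigma": m.log_sigma, "hidden": m.hidden}
        payload = {
            "schema_version": 1,
            "nodes": self.nodes_,
            "edges": sorted(self.graph.edges),
            "means": self.means_.tolist(),
            "scales": self.scales_.tolist(),
            "mechanisms": mechs,
        }
        Path(path).write_text(json.dumps(payload), "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "StructuralCausalModel":
        payload = json.loads(Path(path).read_text("utf-8"))
        if payload.get("schema_version") != 1:
            raise ValueError("unsupported checkpoint schema version")
        graph = CausalGraph(payload["nodes"], [tuple(e) for e in payload["edges"]])
        mechs: dict[str, object] = {}
        for n, spec in payload["mechanisms"].items():
            if spec["type"] == "linear":
                mechs[n] = LinearMechanism(n, spec["parents"], spec["weights"],
                                           spec["intercept"], spec["sigma"])
            else:
                m = MLPMechanism(n, spec["parents"], spec["hidden"],
                                 np.random.default_rng(0))
                m.W1 = np.asarray(spec["W1"], dtype=float).reshape(len(spec["parents"]), spec["hidden"])
                m.b1 = np.asarray(spec["b1"], dtype=float)
                m.W2 = np.asarray(spec["W2"], dtype=float)
                m.b2 = float(spec["b2"])
                m.log_sigma = float(spec["log_sigma"])
                mechs[n] = m
        return cls.from_mechanisms(graph, mechs, payload["means"], payload["scales"])
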