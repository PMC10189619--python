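"""Ground-truth synthetic worlds for end-to-end testing.

Real dementia-transcript corpora are access-restricted, so the package
ships a generator of fully specified worlds: a causal DAG over tag
features, linear-Gaussian mechanisms with known coefficients, a count
mapping (scale, offset, round, clip at zero), and a logistic label
rule over a named feature subset.  Every downstream stage — discovery,
SCM fitting, classification, counterfactual search, importance
metrics — can then be validated against known ground truth.

``fixture_pos_world`` is the repo's standard 27-tag world.  Its edge
set is the subset of tag-to-tag causal relations attested in the
accompanying analysis of dementia speech (e.g. NN causing CD/DT/JJ, RB
having no descendants); relations that could not be included without
breaking acyclicity were dropped.  Offsets keep count means well above
zero so clipping is rare and abduction round-trips stay meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .graph import CausalGraph
from .scm import LinearMechanism, StructuralCausalModel
from .tags import CANONICAL_TAGS

__all__ = ["WorldSpec", "make_world", "fixture_pos_world", "FIXTURE_EDGES"]

# Tag-to-tag causal relations attested in the dementia-speech analysis
# this package accompanies.  The prose also implies PRP->VBD and
# VBD->{PRP, TO} readings that cannot both be direct edges in a DAG;
# no VBD edge is included (see docs/methods.md).
FIXTURE_EDGES: tuple[tuple[str, str], ...] = (
    ("NN", "CD"), ("NN", "DT"), ("NN", "JJ"),
    ("VBG", "DT"), ("VBG", "VBZ"),
    ("PDT", "VBG"), ("PDT", "DT"), ("PDT", "RP"),
    ("NNP", "DT"),
    ("VB", "RB"), ("VB", "WP"), ("VB", "TO"),
    ("JJ", "NNP"), ("JJ", "UH"), ("JJ", "RB"),
    ("WP", "RB"), ("WP", "VBP"),
    ("RP", "VBG"), ("RP", "VBZ"), ("RP", "NNP"),
    ("IN", "CD"), ("IN", "DT"), ("IN", "EX"), ("IN", "PRP"),
    ("IN", "VBG"), ("IN", "VBN"),
)


@dataclass
class WorldSpec:
    """Complete recipe for a synthetic labeled count dataset.

    Mechanisms are linear in the latent (standardized) space:
    z_i = sum_p w_ip z_p + sigma_i * u_i.  Counts are
    clip(round(scale_i * z_i + offset_i), 0).  Labels are Bernoulli
    with P(positive) = logistic(intercept + sum_k coef_k * z_k).
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    weights: Mapping[tuple[str, str], float]          # (parent, child) -> w
    noise_scales: Mapping[str, float]
    count_scale: Mapping[str, float]
    count_offset: Mapping[str, float]
    label_coefs: Mapping[str, float]
    label_intercept: float = 0.0
    positive_label: str = "AD"
    negative_label: str = "control"
    n: int = 1000
    seed: int = 0

    def validate(self) -> CausalGraph:
        graph = CausalGraph(self.nodes, self.edges)  # raises on cycles
        for k in self.label_coefs:
            if k not in self.nodes:
                raise ValueError(f"label-rule feature {k} is not a node")
        for (a, b) in self.weights:
            if (a, b) not in graph.edges:
                raise ValueError(f"weight given for non-edge ({a}, {b})")
        for node in self.nodes:
            if self.noise_scales.get(node, 1.0) <= 0:
                raise ValueError(f"noise scale must be positive for {node}")
        return graph

    def to_yaml(self, path) -> None:
        payload = {
            "nodes": self.nodes,
            "edges": [list(e) for e in self.edges],
            "weights": {f"{a}->{b}": w for (a, b), w in self.weights.items()},
            "noise_scales": dict(self.noise_scales),
            "count_scale": dict(self.count_scale),
            "count_offset": dict(self.count_offset),
            "label_coefs": dict(self.label_coefs),
            "label_intercept": self.label_intercept,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "n": self.n,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "WorldSpec":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        payload["edges"] = [tuple(e) for e in payload["edges"]]
        payload["weights"] = {tuple(k.split("->")): v
                              for k, v in payload["weights"].items()}
        return cls(**payload)


def ground_truth_scm(spec: WorldSpec) -> StructuralCausalModel:
    """The spec's own SCM, with count-space standardization attached."""
    graph = spec.validate()
    mechs = {}
    for node in spec.nodes:
        parents = graph.parents(node)
        mechs[node] = LinearMechanism(
            node, parents,
            [spec.weights.get((p, node), 0.0) for p in parents],
            intercept=0.0,
            sigma=spec.noise_scales.get(node, 1.0),
        )
    means = [spec.count_offset.get(n, 0.0) for n in spec.nodes]
    scales = [spec.count_scale.get(n, 1.0) for n in spec.nodes]
    return StructuralCausalModel.from_mechanisms(graph, mechs, means, scales)


def make_world(spec: WorldSpec) -> tuple[pd.DataFrame, pd.Series, StructuralCausalModel]:
    """Sample a labeled count table from the spec's ground-truth SCM.

    Returns (counts, labels, ground-truth SCM).  Fully deterministic
    given the spec's seed.
    """
    scm = ground_truth_scm(spec)
    rng = np.random.default_rng(spec.seed)
    u = rng.standard_normal((spec.n, len(spec.nodes)))
    z = scm.generate(u)
    counts_arr = np.maximum(np.rint(scm.destandardize(z)), 0.0).astype(int)
    index = pd.Index([f"r{i:05d}" for i in range(spec.n)], name="record_id")
    counts = pd.DataFrame(counts_arr, columns=spec.nodes, index=index)

    logits = np.full(spec.n, spec.label_intercept, dtype=float)
    node_idx = {n: i for i, n in enumerate(spec.nodes)}
    for k, coef in spec.label_coefs.items():
        logits += coef * z[:, node_idx[k]]
    p = 1.0 / (1.0 + np.exp(-logits))
    draws = rng.random(spec.n)
    labels = pd.Series(
        np.where(draws < p, spec.positive_label, spec.negative_label),
        index=index, name="label",
    )
    return counts, labels, scm


def fixture_pos_world(n: int = 1000, seed: int = 0) -> WorldSpec:
    """The standard 27-tag end-to-end fixture world.

    Linear mechanisms over the attested edge set with moderate edge
    weights; the label rule weights PRP, IN and RB — features a
    dementia classifier plausibly keys on — strongly enough that a
    simple classifier separates the classes well and counterfactual
    flips are reachable within observed ranges.
    """
    nodes = list(CANONICAL_TAGS)
    edges = list(FIXTURE_EDGES)
    weights = {e: 0.4 for e in edges}
    graph = CausalGraph(nodes, edges)
    # keep total variance near one regardless of in-degree
    noise = {node: float(np.sqrt(max(1.0 - 0.16 * len(graph.parents(node)), 0.2)))
             for node in nodes}
    count_scale = {node: 3.0 for node in nodes}
    count_offset = {node: 12.0 for node in nodes}
    return WorldSpec(
        nodes=nodes,
        edges=edges,
        weights=weights,
        noise_scales=noise,
        count_scale=count_scale,
        count_offset=count_offset,
        label_coefs={"PRP": 3.0, "IN": 3.0, "RB": 3.0},
        label_intercept=0.0,
        n=n,
        seed=seed,
    )
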