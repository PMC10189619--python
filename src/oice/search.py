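"""One-intervention counterfactual search.

For a factual count vector x^F classified as the source class, find —
separately for every feature k — the single do-intervention
do(X_k = a) whose counterfactual

    x^CF = round( G(u^F, do(X_k = a); F) )

is assigned to the target class with the required certainty.  The
individual's exogenous noise u^F is first recovered by abduction, so
the counterfactual answers "what would *this* record have looked like
had feature k been a"; descendants of k respond through the causal
mechanisms while non-descendants keep their factual values.

Because the features are nonnegative integers with narrow observed
ranges, the search enumerates every candidate value exhaustively.
Acceptance uses the squared-distance certainty rule (p - 1)^2 < alpha
on the scalar target-class probability, so alpha = 0.04 corresponds to
80% certainty.  Among accepted candidates per feature, the one with
minimal MAD-weighted L1 distance to the factual is kept (ties: smaller
|a - x^F_k|, then smaller a).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pos_features import FeatureStats
from .scm import StructuralCausalModel

logger = logging.getLogger(__name__)

__all__ = ["SearchConfig", "CounterfactualExample", "OICEExplainer",
           "candidate_values", "mad_distance", "certainty_threshold",
           "solve_oice", "explain_cohort"]


def certainty_threshold(alpha: float) -> float:
    """Scalar-probability certainty implied by the squared rule (p-1)^2 < alpha."""
    return 1.0 - float(np.sqrt(alpha))


@dataclass
class SearchConfig:
    """Knobs of the exhaustive one-intervention solver.

    alpha : acceptance threshold on (p - 1)^2; 0.04 means the
        counterfactual must be at least 80% certain to be the target.
    grid : "observed" enumerates integers in each feature's observed
        [min, max]; currently the only policy.
    mad_floor : value substituted for zero MADs inside the distance
        (reported statistics are never floored).
    target_class : label the counterfactual must reach.
    """

    alpha: float = 0.04
    grid: str = "observed"
    mad_floor: float = 1.0
    target_class: object = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.grid != "observed":
            raise ValueError(f"unknown candidate grid policy {self.grid!r}")


@dataclass
class CounterfactualExample:
    """One accepted single-intervention counterfactual."""

    record_id: object
    feature: str
    value: int
    counterfactual: pd.Series
    probability: float
    distance: float
    deltas: pd.Series = field(repr=False)

    def to_json(self) -> str:
        return json.dumps({
            "record_id": str(self.record_id),
            "feature": self.feature,
            "value": int(self.value),
            "probability": round(self.probability, 6),
            "distance": round(self.distance, 6),
            "deltas": {k: int(v) for k, v in self.deltas.items() if v != 0},
        })


def candidate_values(feature: str, stats: FeatureStats, exclude: int | None = None) -> list[int]:
    """All integers in the feature's observed [min, max], minus ``exclude``."""
    lo = int(np.floor(stats.min_[feature]))
    hi = int(np.ceil(stats.max_[feature]))
    return [v for v in range(lo, hi + 1) if v != exclude]


def mad_distance(x, x_other, stats: FeatureStats, floor: float = 1.0) -> float:
    """L1 distance with coordinates down-weighted by the feature MADs.

    Zero MADs are floored (default one count) so the distance stays
    finite for near-constant features.
    """
    xs = pd.Series(x) if not isinstance(x, pd.Series) else x
    ys = pd.Series(x_other) if not isinstance(x_other, pd.Series) else x_other
    mads = stats.mad.reindex(xs.index)
    w = np.maximum(mads.to_numpy(dtype=float), floor)
    return float((np.abs(xs.to_numpy(dtype=float) - ys.reindex(xs.index).to_numpy(dtype=float)) / w).sum())


class OICEExplainer:
    """Explains a classifier's decisions by one-intervention counterfactuals.

    Parameters
    ----------
    scm : fitted StructuralCausalModel over the feature columns.
    classifier : any object with sklearn's ``predict_proba`` returning
        (n, 2) probabilities and a ``classes_`` attribute; the reference
        attention model, a logistic regression, trees — anything.
    config : SearchConfig.

    ``fit(X)`` records the cohort feature statistics (ranges for the
    candidate grids, MADs for the distance); ``explain`` then solves
    the search for individual records or a whole cohort.
    """

    def __init__(self, scm: StructuralCausalModel, classifier, config: SearchConfig | None = None):
        self.scm = scm
        self.classifier = classifier
        self.config = config or SearchConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"scm": self.scm, "classifier": self.classifier, "config": self.config}

    def set_params(self, **params) -> "OICEExplainer":
        for k, v in params.items():
            if k not in ("scm", "classifier", "config"):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "OICEExplainer":
        from .pos_features import compute_feature_stats

        self.features_ = list(X.columns)
        self.stats_ = compute_feature_stats(X)
        return self

    def _proba_target(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.classifier.predict_proba(X)
        classes = list(self.classifier.classes_)
        return np.asarray(proba)[:, classes.index(self.config.target_class)]

    def explain(self, x: pd.Series, record_id=None) -> list[CounterfactualExample]:
        """Solve the one-intervention search for a single factual record.

        The factual must currently be classified as the source class
        (target probability <= 0.5); otherwise a ValueError is raised —
        cohort-level code skips such records instead.
        """
        cfg = self.config
        record_id = x.name if record_id is None else record_id
        x = x.reindex(self.features_).astype(float)
        x_frame = pd.DataFrame([x.values], columns=self.features_)
        p_fact = float(self._proba_target(x_frame)[0])
        if p_fact > 0.5:
            raise ValueError(
                f"record {record_id} is already classified as the target class")

        scm = self.scm
        u = scm.abduct(scm.standardize(x))  # Series path reorders to scm node order
        results: list[CounterfactualExample] = []
        means, scales = scm.means_, scm.scales_
        node_idx = {n: i for i, n in enumerate(scm.nodes_)}
        for k in self.features_:
            cands = candidate_values(k, self.stats_, exclude=int(x[k]))
            if not cands:
                logger.warning("feature %s has an empty candidate grid", k)
                continue
            a_std = (np.asarray(cands, dtype=float) - means[node_idx[k]]) / scales[node_idx[k]]
            u_batch = np.tile(u, (len(cands), 1))
            gen = scm.generate(u_batch, {k: a_std})
            counts = np.rint(scm.destandardize(gen))
            counts = np.maximum(counts, 0.0)
            # re-pin the intervened coordinate: rounding must not move it
            counts[:, node_idx[k]] = cands
            cf_frame = pd.DataFrame(counts, columns=scm.nodes_)[self.features_]
            p = self._proba_target(cf_frame)
            accepted = np.flatnonzero((p - 1.0) ** 2 < cfg.alpha)
            if accepted.size == 0:
                continue
            best = None
            for i in accepted:
                cf = cf_frame.iloc[i]
                dist = mad_distance(x, cf, self.stats_, cfg.mad_floor)
                key = (dist, abs(cands[i] - x[k]), cands[i])
                if best is None or key < best[0]:
                    best = (key, i, cf, dist)
            _, i, cf, dist = best
            cf_int = cf.round().astype(int)
            results.append(CounterfactualExample(
                record_id=record_id,
                feature=k,
                value=int(cands[i]),
                counterfactual=cf_int,
                probability=float(p[i]),
                distance=dist,
                deltas=(cf_int - x.astype(int)),
            ))
        return results

    def explain_cohort(self, X: pd.DataFrame, y: Sequence) -> dict[object, list[CounterfactualExample]]:
        """Explain every correctly classified source-class record.

        Records whose label is the target class, and source-class
        records the classifier misclassifies, are excluded — only
        records the model gets right are worth explaining.
        """
        y = pd.Series(list(y), index=X.index)
        p = self._proba_target(X)
        out: dict[object, list[CounterfactualExample]] = {}
        for pos, rid in enumerate(X.index):
            if y.iloc[pos] == self.config.target_class:
                continue
            if p[pos] > 0.5:  # misclassified source-class record
                continue
            out[rid] = self.explain(X.iloc[pos], record_id=rid)
        logger.info("explained %d of %d records", len(out), len(X))
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def solve_oice(x_factual: pd.Series, target_class, scm: StructuralCausalModel,
               classifier, config: SearchConfig | None = None,
               stats: FeatureStats | None = None,
               cohort: pd.DataFrame | None = None) -> list[CounterfactualExample]:
    """Functional form of :meth:`OICEExplainer.explain`.

    Feature statistics come either from ``stats`` or are computed from
    ``cohort``.
    """
    config = config or SearchConfig()
    config.target_class = target_class
    expl = OICEExplainer(scm, classifier, config)
    if stats is not None:
        expl.stats_ = stats
        expl.features_ = list(stats.features)
    elif cohort is not None:
        expl.fit(cohort)
    else:
        raise ValueError("provide either stats or a cohort to derive them from")
    return expl.explain(x_factual)


def explain_cohort(X: pd.DataFrame, y, target_class, scm, classifier,
                   config: SearchConfig | None = None):
    config = config or SearchConfig()
    config.target_class = target_class
    expl = OICEExplainer(scm, classifier, config).fit(X)
    return expl.explain_cohort(X, y)


def write_cfe_jsonl(cfes: Mapping[object, list[CounterfactualExample]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid in cfes:
            for cfe in cfes[rid]:
                fh.write(cfe.to_json() + "\n")
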