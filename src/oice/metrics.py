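"""Global feature-importance metrics aggregated from counterfactuals.

Given the cohort of one-intervention counterfactual explanations, each
feature k is scored by:

* **impact score** ``IS_k = |I_k| / n`` — the fraction of explained
  samples whose outcome flips by intervening on k (I_k is the set of
  samples with an accepted counterfactual via k);
* **cost of impact** ``CI_k`` — the mean absolute change of the
  intervened coordinate, as a fraction of the feature's observed range
  R_k (reportable as a percentage), with a direction summary
  (increase, decrease, or both);
* **weighted impact score** ``wIS_k = IS_k / CI_k`` — impact per unit
  of normalized change, split into signed variants wIS+ / wIS- when
  both directions occur (each signed slot uses the sign-partitioned IS
  and CI; the overall wIS is then their average);
* **pure impact score** — a decomposition of IS_k into the intervened
  feature's own contribution and contributions routed through its
  causal children, satisfying ``PIS_k^k + sum_m PIS_k^m = IS_k``
  exactly and normalized over IS_k into percentages;
* a **behavior class** (cooperative / dominant / idling / inverse)
  summarizing each decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import CausalGraph
from .pos_features import FeatureStats
from .search import CounterfactualExample

__all__ = [
    "impact_score", "cost_of_impact", "weighted_impact_score",
    "pure_impact_scores", "classify_behavior", "select_important",
    "FeatureImportanceReport", "summarize_cohort",
]

UP, DOWN, BOTH = "up", "down", "both"


def impact_score(n_flipped: int, n: int) -> float:
    """IS = |I_k| / n, the fraction of explained samples flipped via k."""
    if n <= 0:
        raise ValueError("number of explained samples must be positive")
    return n_flipped / n


def cost_of_impact(deltas: Sequence[float], feature_range: float):
    """Mean |delta| / R_k over the flip set, with per-direction variants.

    Returns (ci, direction, ci_up, ci_down) where the per-direction
    costs are means over the sign-partitioned subsets (NaN when a
    direction does not occur).  ``ci`` is NaN when the flip set is
    empty, and undefined (ValueError) for a zero range.
    """
    deltas = np.asarray(list(deltas), dtype=float)
    if feature_range <= 0:
        raise ValueError("cost of impact undefined for zero feature range")
    if deltas.size == 0:
        return math.nan, None, math.nan, math.nan
    ci = float(np.abs(deltas).mean() / feature_range)
    pos, neg = deltas[deltas > 0], deltas[deltas < 0]
    ci_up = float(pos.mean() / feature_range) if pos.size else math.nan
    ci_down = float(-neg.mean() / feature_range) if neg.size else math.nan
    if pos.size and neg.size:
        direction = BOTH
    else:
        direction = UP if pos.size else DOWN
    return ci, direction, ci_up, ci_down


def weighted_impact_score(is_k: float, ci_k: float, direction: str | None = UP,
                          is_up: float | None = None, ci_up: float | None = None,
                          is_down: float | None = None, ci_down: float | None = None):
    """wIS with its signed variants.

    Uniform direction: wIS = IS / CI lands in the matching signed slot,
    the other slot is 0.  Mixed directions: each slot is the
    sign-partitioned IS over the sign-partitioned CI, and the overall
    wIS is the average of the two slots.

    Returns (wis, wis_up, wis_down).
    """
    if is_k == 0:
        return 0.0, 0.0, 0.0
    if direction == BOTH:
        if any(v is None for v in (is_up, ci_up, is_down, ci_down)):
            raise ValueError("mixed-direction wIS needs sign-partitioned IS and CI")
        wis_up = is_up / ci_up
        wis_down = is_down / ci_down
        return (wis_up + wis_down) / 2.0, wis_up, wis_down
    if ci_k is None or not np.isfinite(ci_k) or ci_k == 0:
        raise ValueError("a nonzero impact score requires a nonzero cost of impact")
    wis = is_k / ci_k
    if direction == DOWN:
        return wis, 0.0, wis
    return wis, wis, 0.0


@dataclass
class PISDecomposition:
    """Pure-impact decomposition for one intervened feature."""

    feature: str
    is_k: float
    own: float                       # PIS_k^k
    children: dict[str, float]       # PIS_k^m for m in CH_k
    own_pct: float = field(init=False)
    children_pct: dict[str, float] = field(init=False)

    def __post_init__(self):
        if self.is_k > 0:
            self.own_pct = 100.0 * self.own / self.is_k
            self.children_pct = {m: 100.0 * v / self.is_k for m, v in self.children.items()}
        else:
            self.own_pct = 0.0
            self.children_pct = {m: 0.0 for m in self.children}


def pure_impact_scores(
    feature: str,
    cfes: Sequence[CounterfactualExample],
    graph: CausalGraph,
    wis_signed: Mapping[str, tuple[float, float]],
    stats: FeatureStats,
    n: int,
) -> PISDecomposition:
    """Decompose IS_k into the intervened feature's own share and its children's.

    For each child m of k, the routed impact is the mean normalized
    change of m across k's flip set times m's own signed wIS:

        PIS_k^m = s_m * wIS_m^{delta_m} * mean_i |C_m - S_m| / R_m

    where delta_m is the realized mean direction of m's change.  The
    sign s_m is +1 when that direction is one m itself uses to flip
    outcomes (its matching signed wIS slot is nonzero) and -1 when m's
    own flips only ever move the other way — in which case the
    opposite slot supplies the magnitude.  The intervened feature's own
    share is then PIS_k^k = IS_k - sum_m PIS_k^m, so the decomposition
    sums to IS_k identically.
    """
    if not cfes:
        raise ValueError(f"no counterfactuals flip via feature {feature}")
    is_k = impact_score(len(cfes), n)
    children = graph.children(feature)
    contributions: dict[str, float] = {}
    for m in children:
        deltas = np.array([float(c.deltas[m]) for c in cfes])
        mean_abs = float(np.abs(deltas).mean())
        if mean_abs == 0:
            contributions[m] = 0.0
            continue
        r_m = float(stats.range_[m])
        if r_m <= 0:
            raise ValueError(f"child {m} changes but has zero range")
        if m not in wis_signed:
            raise ValueError(f"child {m} changes but its wIS is unavailable")
        wis_up, wis_down = wis_signed[m]
        delta_dir = UP if deltas.mean() >= 0 else DOWN
        matching = wis_up if delta_dir == UP else wis_down
        opposite = wis_down if delta_dir == UP else wis_up
        if matching > 0:
            contributions[m] = matching * mean_abs / r_m
        elif opposite > 0:
            contributions[m] = -opposite * mean_abs / r_m
        else:
            contributions[m] = 0.0
    own = is_k - sum(contributions.values())
    return PISDecomposition(feature, is_k, own, contributions)


@dataclass(frozen=True)
class BehaviorClass:
    label: str                      # cooperative | dominant | idling | inverse
    low_pct: float
    high_pct: float


def classify_behavior(decomp: PISDecomposition, low: float = 10.0, high: float = 50.0) -> BehaviorClass:
    """Assign the feature-behavior taxonomy label to a decomposition.

    Working on normalized percentages: *inverse* when the intervened
    feature's own share is negative while its children push toward the
    flip; *dominant* when the own share is high and children contribute
    little or oppose; *idling* when the own share is small and children
    do the work; *cooperative* when both shares are material.  Any
    remaining case falls to dominant/idling by whichever share is
    larger.  Thresholds are reported with the label.
    """
    own = decomp.own_pct
    kids = sum(decomp.children_pct.values())
    if own < 0 and kids > 0:
        label = "inverse"
    elif own >= high and kids <= low:
        label = "dominant"
    elif own <= low and kids >= high:
        label = "idling"
    elif own > low and kids > low:
        label = "cooperative"
    else:
        label = "dominant" if own >= kids else "idling"
    return BehaviorClass(label, low, high)


def select_important(report: pd.DataFrame, t: int = 12) -> list[str]:
    """Features in the top-t of both the IS and wIS rankings, by rank sum.

    Features strong on only one ranking are excluded: a high wIS with a
    low IS is backed by too few samples to be reliable.
    """
    if t <= 0:
        return []
    is_rank = report["IS"].rank(ascending=False, method="min")
    wis_rank = report["wIS"].rank(ascending=False, method="min")
    eligible = report.index[(is_rank <= t) & (wis_rank <= t)]
    rank_sum = (is_rank + wis_rank).loc[eligible]
    return list(rank_sum.sort_values(kind="stable").index)


@dataclass
class FeatureImportanceReport:
    """Cohort-level importance summary across all features."""

    table: pd.DataFrame                         # IS, CI, direction, wIS, ranks
    decompositions: dict[str, PISDecomposition]
    behaviors: dict[str, BehaviorClass]
    n_explained: int

    def important(self, t: int = 12) -> list[str]:
        return select_important(self.table, t)

    def pis_matrix(self) -> pd.DataFrame:
        """Normalized PIS percentages: rows = intervened feature, cols = contributors."""
        feats = list(self.table.index)
        mat = pd.DataFrame(0.0, index=feats, columns=feats)
        for k, dec in self.decompositions.items():
            mat.loc[k, k] = dec.own_pct
            for m, v in dec.children_pct.items():
                mat.loc[k, m] = v
        return mat


def summarize_cohort(
    cfes: Mapping[object, Sequence[CounterfactualExample]],
    stats: FeatureStats,
    graph: CausalGraph,
    behavior_low: float = 10.0,
    behavior_high: float = 50.0,
    n_explained: int | None = None,
) -> FeatureImportanceReport:
    """Aggregate per-sample counterfactuals into the full importance report.

    ``n_explained`` overrides the IS denominator when the mapping holds
    only samples with at least one solution.
    """
    n = len(cfes) if n_explained is None else n_explained
    if n == 0:
        raise ValueError("no explained samples")
    features = list(stats.features)
    by_feature: dict[str, list[CounterfactualExample]] = {k: [] for k in features}
    for sols in cfes.values():
        for cfe in sols:
            by_feature[cfe.feature].append(cfe)

    rows = {}
    wis_signed: dict[str, tuple[float, float]] = {}
    for k in features:
        sols = by_feature[k]
        is_k = impact_score(len(sols), n)
        deltas = [float(c.deltas[k]) for c in sols]
        r_k = float(stats.range_[k])
        if r_k > 0:
            ci, direction, ci_up, ci_down = cost_of_impact(deltas, r_k)
        else:
            ci, direction, ci_up, ci_down = math.nan, None, math.nan, math.nan
        if is_k == 0 or not np.isfinite(ci):
            wis, wis_up, wis_down = (0.0, 0.0, 0.0)
        elif direction == BOTH:
            d_arr = np.asarray(deltas)
            is_up = (d_arr > 0).sum() / n
            is_down = (d_arr < 0).sum() / n
            wis, wis_up, wis_down = weighted_impact_score(
                is_k, ci, BOTH, is_up=is_up, ci_up=ci_up,
                is_down=is_down, ci_down=ci_down)
        else:
            wis, wis_up, wis_down = weighted_impact_score(is_k, ci, direction)
        wis_signed[k] = (wis_up, wis_down)
        rows[k] = {"IS": is_k, "CI": ci, "CI_pct": 100.0 * ci if np.isfinite(ci) else math.nan,
                   "direction": {UP: "↑", DOWN: "↓", BOTH: "↑↓", None: ""}[direction],
                   "wIS": wis, "wIS_up": wis_up, "wIS_down": wis_down,
                   "n_flipped": len(sols)}

    table = pd.DataFrame.from_dict(rows, orient="index").reindex(features)
    table["rank_IS"] = table["IS"].rank(ascending=False, method="min").astype(int)
    table["rank_wIS"] = table["wIS"].rank(ascending=False, method="min").astype(int)

    decomps: dict[str, PISDecomposition] = {}
    behaviors: dict[str, BehaviorClass] = {}
    for k in features:
        if not by_feature[k]:
            continue
        dec = pure_impact_scores(k, by_feature[k], graph, wis_signed, stats, n)
        decomps[k] = dec
        behaviors[k] = classify_behavior(dec, behavior_low, behavior_high)
    return FeatureImportanceReport(table, decomps, behaviors, n)


def spider_plot_data(
    factuals: pd.DataFrame,
    counterfactuals: pd.DataFrame | None,
    labels: Sequence,
    positive_label,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group-mean feature profiles normalized to [0, 1] per feature.

    Rows: positive-class mean, negative-class mean, and (optionally)
    the counterfactual-cohort mean — the data behind a spider plot
    comparing cases, controls and counterfactual controls.
    """
    labels = pd.Series(list(labels), index=factuals.index)
    cols = list(features) if features is not None else list(factuals.columns)
    lo = factuals[cols].min(axis=0)
    span = (factuals[cols].max(axis=0) - lo).replace(0, 1)
    norm = (factuals[cols] - lo) / span
    out = {
        "positive_mean": norm[labels == positive_label].mean(axis=0),
        "negative_mean": norm[labels != positive_label].mean(axis=0),
    }
    if counterfactuals is not None and len(counterfactuals):
        out["counterfactual_mean"] = ((counterfactuals[cols] - lo) / span).mean(axis=0)
    return pd.DataFrame(out)
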