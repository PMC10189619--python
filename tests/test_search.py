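import numpy as np
import pandas as pd
import pytest

from oice.pos_features import compute_feature_stats
from oice.search import (OICEExplainer, SearchConfig, candidate_values,
                         certainty_threshold, mad_distance)

from conftest import LogisticStub


class TestCandidateValues:
    def test_full_observed_range(self):
        stats = compute_feature_stats(pd.DataFrame({"k": [0, 3, 1]}))
        assert candidate_values("k", stats) == [0, 1, 2, 3]

    def test_constant_feature(self):
        stats = compute_feature_stats(pd.DataFrame({"k": [2, 2]}))
        assert candidate_values("k", stats) == [2]

    def test_factual_excluded(self):
        stats = compute_feature_stats(pd.DataFrame({"k": [0, 5]}))
        assert candidate_values("k", stats, exclude=2) == [0, 1, 3, 4, 5]


class TestMadDistance:
    def test_zero_for_identical(self):
        stats = compute_feature_stats(pd.DataFrame({"a": [0, 4], "b": [1, 3]}))
        x = pd.Series({"a": 2, "b": 2})
        assert mad_distance(x, x, stats) == 0.0

    def test_hand_sum(self):
        from oice.pos_features import FeatureStats
        stats = FeatureStats(["a", "b", "c"],
                             pd.Series({"a": 0.0, "b": 0.0, "c": 0.0}),
                             pd.Series({"a": 9.0, "b": 9.0, "c": 9.0}),
                             pd.Series({"a": 1.0, "b": 1.0, "c": 3.0}))
        x = pd.Series({"a": 0, "b": 0, "c": 0})
        x2 = pd.Series({"a": 2, "b": 0, "c": 3})
        assert mad_distance(x, x2, stats) == pytest.approx(2 + 0 + 1)

    def test_floor_replaces_zero_mad(self):
        from oice.pos_features import FeatureStats
        stats = FeatureStats(["a"], pd.Series({"a": 0.0}), pd.Series({"a": 9.0}),
                             pd.Series({"a": 0.0}))
        assert mad_distance(pd.Series({"a": 0}), pd.Series({"a": 4}),
                            stats, floor=1.0) == pytest.approx(4.0)


def test_certainty_threshold_identity():
    assert certainty_threshold(0.04) == pytest.approx(0.8)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_oice(x, scm, clf, stats, alpha, target_class, mad_floor=1.0):
    """Literal enumeration of every (feature, value) pair, applying the
    abduct / pin / generate / round / accept / deduplicate steps one at
    a time, with no shortcuts shared with the implementation."""
    features = list(stats.features)
    u = scm.abduct(scm.standardize(x))
    target_col = list(clf.classes_).index(target_class)
    best = {}
    node_idx = {n: i for i, n in enumerate(scm.nodes_)}
    for k in features:
        lo, hi = int(stats.min_[k]), int(stats.max_[k])
        for a in range(lo, hi + 1):
            if a == int(x[k]):
                continue
            a_std = (a - scm.means_[node_idx[k]]) / scm.scales_[node_idx[k]]
            gen = scm.generate(u, {k: a_std})
            cf = np.maximum(np.rint(scm.destandardize(gen)), 0)
            cf[node_idx[k]] = a
            cf_s = pd.Series(cf, index=scm.nodes_)[features]
            p = clf.predict_proba(pd.DataFrame([cf_s]))[0, target_col]
            if (p - 1.0) ** 2 >= alpha:
                continue
            dist = mad_distance(x, cf_s, stats, mad_floor)
            key = (dist, abs(a - x[k]), a)
            if k not in best or key < best[k][0]:
                best[k] = (key, a, cf_s, p, dist)
    return {k: (v[1], tuple(v[2]), round(v[3], 12), round(v[4], 12))
            for k, v in best.items()}


@pytest.fixture
def abc_setup(abc_scm, abc_cohort):
    clf = LogisticStub("B", threshold=7.0, weight=2.0)
    config = SearchConfig(alpha=0.04, target_class="AD")
    expl = OICEExplainer(abc_scm, clf, config).fit(abc_cohort)
    stats = compute_feature_stats(abc_cohort)
    return expl, clf, stats


class TestSolveOICE:
    def test_matches_brute_force_oracle(self, abc_setup, abc_scm, abc_cohort):
        expl, clf, stats = abc_setup
        checked = 0
        for _, x in abc_cohort.head(15).iterrows():
            x = x.astype(float)
            p = clf.predict_proba(pd.DataFrame([x]))[0, 1]
            if p > 0.5:
                continue
            got = {c.feature: (c.value, tuple(c.counterfactual.astype(float)),
                               round(c.probability, 12), round(c.distance, 12))
                   for c in expl.explain(x)}
            expected = brute_force_oice(x, abc_scm, clf, stats, 0.04, "AD")
            assert got == expected
            checked += 1
        assert checked >= 5

    def test_isolated_unused_feature_never_solves(self, abc_setup, abc_cohort):
        # classifier reads B; C is isolated, so no intervention on C can flip
        expl, clf, _ = abc_setup
        for _, x in abc_cohort.head(15).iterrows():
            if clf.predict_proba(pd.DataFrame([x.astype(float)]))[0, 1] > 0.5:
                continue
            assert all(c.feature != "C" for c in expl.explain(x.astype(float)))

    def test_solution_count_monotone_in_alpha(self, abc_scm, abc_cohort):
        clf = LogisticStub("B", threshold=7.0, weight=2.0)
        x = abc_cohort.iloc[0].astype(float)
        counts = []
        for alpha in (0.04, 0.25, 0.99):
            cfg = SearchConfig(alpha=alpha, target_class="AD")
            expl = OICEExplainer(abc_scm, clf, cfg).fit(abc_cohort)
            counts.append(len(expl.explain(x)))
        assert counts == sorted(counts)

    def test_every_solution_satisfies_invariants(self, abc_setup, abc_scm, abc_cohort):
        expl, clf, _ = abc_setup
        desc = {k: abc_scm.graph.descendants(k) for k in abc_cohort.columns}
        for _, x in abc_cohort.head(10).iterrows():
            x = x.astype(float)
            if clf.predict_proba(pd.DataFrame([x]))[0, 1] > 0.5:
                continue
            for c in expl.explain(x):
                assert (c.probability - 1.0) ** 2 < 0.04
                changed = set(c.deltas[c.deltas != 0].index)
                assert changed <= ({c.feature} | desc[c.feature])
                assert (c.counterfactual >= 0).all()

    def test_target_class_factual_rejected(self, abc_setup, abc_cohort):
        expl, clf, _ = abc_setup
        high_b = pd.Series({"A": 5.0, "B": 12.0, "C": 5.0})
        assert clf.predict_proba(pd.DataFrame([high_b]))[0, 1] > 0.5
        with pytest.raises(ValueError, match="already classified"):
            expl.explain(high_b)


class TestExplainCohort:
    def test_misclassified_records_excluded(self, abc_scm, abc_cohort):
        # 5 control-labeled records; 2 sit above the boundary (misclassified)
        clf = LogisticStub("B", threshold=7.0, weight=2.0)
        X = pd.DataFrame({
            "A": [5, 5, 5, 5, 5],
            "B": [4, 5, 9, 3, 10],
            "C": [5, 5, 5, 5, 5],
        }, index=[f"s{i}" for i in range(5)], dtype=float)
        cfg = SearchConfig(target_class="AD")
        expl = OICEExplainer(abc_scm, clf, cfg).fit(abc_cohort)
        cfes = expl.explain_cohort(X, ["control"] * 5)
        assert set(cfes) == {"s0", "s1", "s3"}

    def test_empty_cohort(self, abc_setup, abc_cohort):
        expl, _, _ = abc_setup
        assert expl.explain_cohort(abc_cohort.iloc[:0], []) == {}

    def test_order_invariance(self, abc_setup, abc_cohort):
        expl, _, _ = abc_setup
        labels = ["control"] * len(abc_cohort)
        a = expl.explain_cohort(abc_cohort, labels)
        perm = abc_cohort.sample(frac=1, random_state=9)
        b = expl.explain_cohort(perm, ["control"] * len(perm))
        assert set(a) == set(b)
        for rid in a:
            assert [(c.feature, c.value) for c in a[rid]] == \
                   [(c.feature, c.value) for c in b[rid]]
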