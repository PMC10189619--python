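# oice — one-intervention causal counterfactual explanations

`oice` explains what drives a binary classifier over **nonnegative
integer count features** — here, the counts of 27 Penn-Treebank
part-of-speech (PoS) tags extracted from speech transcripts, as used to
separate Alzheimer-disease (AD) patients from healthy controls.  Unlike
attribution methods that perturb features independently, `oice` asks a
causal question: *which single do-intervention on one feature would flip
this record's classification, once the feature's causal descendants are
allowed to respond?*

## The method

A structural causal model (SCM) `M = (X, F, U)` is placed over the
feature variables: a DAG (discovered by the PC algorithm and oriented by
domain knowledge), one generative mechanism per node,

    X_i = f_i(PA_i) + σ_i · U_i,     U_i ~ N(0, 1),

with `f_i` a one-hidden-layer network trained so that ancestrally
generated samples match the data under the maximum mean discrepancy
(MMD).  Additive noise makes *abduction* exact: for a factual record
`x^F` the individual noise is `u^F_i = (x^F_i − f_i(PA_i)) / σ_i`.

For each feature `k`, the solver enumerates every integer candidate `a`
in the feature's observed range and generates the counterfactual
`x^CF = G(u^F, do(X_k = a); F)` — `k` is pinned, descendants respond,
non-descendants keep their factual values.  A candidate is accepted when
the classifier h's target-class probability satisfies
`(h(x^CF) − 1)² < α`; the default `α = 0.04` corresponds to 80%
certainty.  Per feature, the accepted counterfactual with the smallest
median-absolute-deviation-weighted L1 distance to `x^F` is kept.

Cohort-level counterfactuals are aggregated into global importance
metrics over the n explained records:

| metric | definition | meaning |
|---|---|---|
| `IS_k = |I_k| / n` | impact score | fraction of records flippable via k |
| `CI_k = mean |Δx_k| / R_k` | cost of impact | average change needed, as a fraction of k's range |
| `wIS_k = IS_k / CI_k` | weighted impact | impact per unit of normalized change (signed variants for ↑/↓) |
| `PIS_k^k = IS_k − Σ_m PIS_k^m` | pure impact | k's own share after subtracting what its children contribute |

The PIS decomposition classifies each feature's behavior as
*cooperative*, *dominant*, *idling* or *inverse*, depending on whether
the intervened feature or its descendants do the work of crossing the
decision boundary.

## Worked example

Real dementia corpora are access-restricted, so the package ships a
synthetic 27-tag world whose causal graph uses relations attested for
dementia speech and whose label rule depends on PRP, IN and RB:

```python
import pandas as pd
from sklearn.linear_model import LogisticRegression
from oice import (StructuralCausalModel, OICEExplainer, SearchConfig,
                  fixture_pos_world, make_world, summarize_cohort,
                  compute_feature_stats)

counts, labels, truth = make_world(fixture_pos_world(n=600, seed=1))
clf = LogisticRegression(max_iter=1000).fit(counts, labels)
scm = StructuralCausalModel(truth.graph, epochs=250, seed=1).fit(counts)
expl = OICEExplainer(scm, clf, SearchConfig(target_class="AD")).fit(counts)
cfes = expl.explain_cohort(counts, labels)          # correctly classified controls
report = summarize_cohort(cfes, compute_feature_stats(counts), scm.graph)
print(report.table.sort_values("rank_IS")[["IS", "CI_pct", "direction", "wIS"]].head(5))
print("important:", report.important(12)[:3])
```

Output:

```
           IS     CI_pct direction       wIS
IN   0.989286  29.843562         ↑  3.314905
PRP  0.842857  37.170433         ↑  2.267547
RB   0.775000  36.149514         ↑  2.143874
JJ   0.217857  32.182916         ↑  0.676934
WP   0.150000  41.931217         ↑  0.357729
important: ['IN', 'PRP', 'RB']
```

Reading the first row: intervening on IN alone (increasing it by about
30% of its range on average) flips the classifier for 98.9% of the
explained controls — and the three features the importance ranking
recovers are exactly the three the synthetic label rule uses.

The same pipeline is scriptable from the shell:

```bash
oice simulate --out run --n 600 --seed 1
oice discover-graph --workdir run --canonical-precedence
oice fit-scm --workdir run
oice train-classifier --workdir run
oice explain --workdir run --alpha 0.04 --target-class AD
oice summarize --workdir run
```

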