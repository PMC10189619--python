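# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind the package, and what the synthetic test
worlds do and do not establish about real data.

## Feature space

Each record is a 27-vector of Penn-Treebank PoS tag counts in a fixed
canonical order (`oice.tags.CANONICAL_TAGS`).  Tokenization is
whitespace/punctuation splitting with case preserved (proper-noun
tagging is case-sensitive).  The tagger is an injected `token -> tag`
callable: taggers drift across versions, and the method is
tagger-agnostic, so all tests use deterministic stub taggers and the
built-in default is a deliberately small rule/lexicon tagger.  Tags
outside the 27-tag schema (punctuation tags, WDT, WRB, ...) are dropped
with a warning, keeping the vector fixed-width.  Repeated-word
disfluencies are tagged as given; no collapsing is attempted.

Per-feature dataset statistics feed two places: the observed range
`R_k` normalizes the cost-of-impact metric, and the median absolute
deviation weights the counterfactual distance.  A zero MAD is floored
(default 1 count) **only inside the distance function**; reported
statistics are never floored.

## Causal graph

Skeleton discovery is the PC algorithm with Fisher-z
partial-correlation tests (default significance 0.05), v-structure
orientation from separating sets, and the Meek closure rules,
implemented in `oice.discovery`.  Node and edge iteration follows the
canonical column order, so results are deterministic given data and
level; the `seed` argument exists only for interface symmetry.  Two
conventions handle inevitable messiness of finite-sample discovery:
conflicting v-structures (an edge oriented both ways) fall back to
undirected, and constant columns are excluded with a warning.

Remaining undirected edges are resolved by machine-readable domain
knowledge (`OrientationRules`): explicit `(cause, effect)` pairs first,
then an optional precedence order (earlier tag causes later tag).  An
orientation that would close a cycle, or an uncovered edge with no
precedence order, is an error — the graph handed to the SCM is always a
DAG.

The fixture graph ships the tag-to-tag relations attested in the
dementia-speech analysis this package accompanies (NN→{CD,DT,JJ},
VBG→{DT,VBZ}, PDT→{VBG,DT,RP}, NNP→DT, VB→{RB,WP,TO}, JJ→{NNP,UH,RB},
WP→{RB,VBP}, RP→{VBG,VBZ,NNP}, IN→{CD,DT,EX,PRP,VBG,VBN}, RB
childless).  The narrative also implies both a PRP⇝VBD influence and
VBD having children {PRP, TO}; these readings cannot both be direct
edges of one DAG, so no VBD edge is included rather than guessing.

## Structural causal model

Mechanisms are **additive in their noise**: `X_i = f_i(PA_i) + σ_i·U_i`
with `U_i ~ N(0,1)` and `f_i` a one-hidden-layer tanh network (a
learned constant for roots).  Generic generative mechanisms that take
noise as a network input are not invertible in general, yet the
counterfactual procedure requires exact abduction `U = G⁻¹(x)`;
additivity is this package's resolution — abduction becomes the
closed form `u_i = (x_i − f_i(PA_i)) / σ_i`, and the
generate-after-abduct round trip is exact to numerical precision
(asserted at 1e-8 in tests).  A consequence worth remembering: the
model cannot represent heteroscedastic or multimodal conditionals.

Training minimizes the biased multi-bandwidth Gaussian-kernel MMD²
between observed samples and ancestrally generated samples, jointly
over all nodes (the whole generative model is matched to the joint
distribution, not node by node).  Kernel bandwidths are
{0.005, 0.05, 0.25, 0.5, 1, 5, 50} × the median pairwise squared
distance of the standardized data.  Defaults: hidden width 20, 500
epochs, Adam at 1e-2, batch 128, σ parameterized on the log scale.  All
numerics run on standardized columns; the standardization constants are
stored with the model.  Seeded runs are bit-reproducible.

Counts vs reals: the SCM operates on standardized reals.  Counterfactual
vectors are de-standardized, rounded to nearest integers and clipped at
zero only at the search boundary, after full ancestral generation —
never per node — and the intervened coordinate is re-pinned to its
integer candidate so rounding cannot move it.

## Classifier

The reference model treats each of the d features as a token: a learned
per-tag embedding scaled by the standardized count plus a per-tag bias,
a stack of multi-head self-attention layers (default 6) with residual
connections so attention ranges over the features *within* one record,
then a 1-D convolution along the token axis, mean pooling and a 2-way
softmax.  Training is SGD with momentum 0.9, class-weight correction
7:3 (minority:majority), an 81/9/10 train/validation/test split in the
`train_classifier` wrapper, and early stopping on validation loss with
patience 20.  The estimator accepts any feature count d, which keeps
small oracle tests cheap.

The explainer does not privilege this model: anything satisfying the
scikit-learn `predict_proba`/`classes_` contract can be explained, and
the end-to-end recovery suite deliberately plugs in a plain logistic
regression — the synthetic worlds are built so a simple classifier
separates them well, and a lighter h keeps repeated full-stack runs
cheap.

## Counterfactual search

Acceptance uses a scalar target-class probability with the rule
`(p − 1)² < α`, so `α = 0.04 ⇔ p > 0.8`: the stated 80% certainty is
exact under the scalar reading, whereas a 2-vector output would imply a
threshold near 0.859.  Candidate grids are all integers in each
feature's **observed** range (extrapolating beyond observed counts is
not attempted), the factual value excluded.  Per feature the accepted
candidate with minimal MAD-weighted L1 distance wins; ties break by
smaller |a − x_k|, then smaller a.  Cohort explanation covers only
correctly classified source-class records — a counterfactual of a
record the model already gets wrong explains nothing.  The solver is
exhaustive by design (integer features, narrow ranges); no Lagrangian
or gradient search is involved, and on ≤4-feature toys it is asserted
equal to literal brute-force enumeration.

## Importance metrics

`IS`, `CI` and `wIS` follow the definitions in the README.  Two
ambiguities required a convention:

* **CI's coordinate.**  CI is computed over the intervened coordinate
  only.  This reading makes the identity `wIS = IS / CI` hold exactly
  on uniform-direction features, which the published per-tag worked
  examples confirm to 2 d.p. (e.g. an impact score of 1 with a 29.5%
  cost gives 3.39).
* **PIS sign and magnitude.**  The routed impact of child m is
  `PIS_k^m = s_m · wIS_m^{δ_m} · mean|Δx_m| / R_m` where δ_m is m's
  realized mean direction under k's interventions.  When m's own flips
  move in that same direction, the matching signed wIS slot supplies
  the magnitude and `s_m = +1`.  When m's own flips only ever move the
  *other* way, the matching slot is zero by construction; the opposite
  slot supplies the magnitude with `s_m = −1` (the child is dragging
  the record away from the boundary).  Without this convention every
  direction-mismatched child would contribute exactly zero and the
  "inverse" behavior class could never occur.  `PIS_k^k` is defined by
  subtraction, so own + children ≡ IS_k identically, and the
  normalized decomposition sums to 100%.

Mixed-direction features split IS by sign (`IS^± = |I_k^±| / n`) and
use sign-partitioned CIs for the signed slots; the overall wIS is the
arithmetic mean of the two slots.

The behavior taxonomy uses thresholds low = 10%, high = 50% on the
normalized shares (invented defaults, always reported alongside the
label): *inverse* when the own share is negative and children positive;
*dominant* when own ≥ high and children ≤ low; *idling* when own ≤ low
and children ≥ high; *cooperative* when both exceed low; any remaining
case falls to dominant or idling by the larger share.

`select_important(t)` keeps features ranked in the top-t of **both**
the IS and wIS rankings, ordered by rank sum (default t = 12): a high
wIS backed by few flipped samples lacks majority agreement and is
excluded.

## Synthetic worlds

`make_world` samples a linear-Gaussian SCM in latent space, maps to
counts by `clip(round(scale·z + offset), 0)`, and draws labels from a
logistic rule in a named feature subset.  The fixture world uses the
attested 27-tag graph, edge weights 0.4 with noise scales chosen to
keep node variances near one, count scale 3 and offset 12 (so clipping
at zero affects < 1% of values and abduction round trips stay
meaningful), and a label rule weighting PRP, IN and RB at 3.0 each —
sized so a plain logistic regression reaches ≈ 0.92 accuracy and the
80% certainty threshold is attainable within observed feature ranges.

What passing tests on these worlds shows: the whole stack — MMD
training, abduction, do-interventions, exhaustive search, metric
aggregation — recovers known ground-truth important features (top-3 in
≥ 9 of 10 seeded runs at n = 600).  What it does not show: robustness
to non-Gaussian or heteroscedastic mechanisms, latent confounding,
misspecified graphs, or the marginal distributions of real transcript
counts.  The fixture is a correctness instrument, not a corpus
emulator.

## Problem sizes and numerical choices

Test and demonstration runs use n = 600–1000 records, 200–300 MMD
epochs and a logistic or reduced-depth attention classifier; these
sizes were chosen as the smallest at which the stochastic checks are
stable across seeds.  Degenerate inputs are handled explicitly:
constant features yield a single-value candidate grid and an undefined
(NA) cost of impact; empty flip sets give IS = 0 and wIS = 0; an empty
candidate grid logs a warning and contributes no solution.  A zero MAD
never reaches the distance (floored), and a zero range never reaches a
division (CI refuses, PIS raises if such a child nonetheless moves).

## Known limitations

* Additive-noise mechanisms only; no latent confounders, cycles, or
  non-Gaussian exogenous noise.
* The candidate grid does not extend beyond observed per-feature
  ranges, so counterfactuals never propose unseen extremes.
* One intervention per explanation by construction; interaction effects
  requiring simultaneous interventions are invisible to the metrics.
* PC discovery at 27 nodes with finite samples leaves many edges to
  the knowledge-based orientation step; a wrong precedence order
  propagates into the SCM unchecked.
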