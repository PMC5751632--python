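# Methods

## Network structure

The recognizer is a rooted tree of 88 binary nodes oriented generatively
from the query node (`eating`) to the sensor-driven leaves. The intermediate
layer mirrors a Five-W's / activity-theory context model: four top-level
context classes — subject, object, spatial and temporal property — each the
root of a tree submodule, with the subject class further split into
activity/wrist, body and operation contexts, and 15 low-level context
properties at the bottom of the inference layer (movement of hand,
dinnerware, posture, move/stop, indoor/outdoor, eating time, ...). Two
contexts named *posture* and two named *move/stop* occur in different
classes; node ids disambiguate them by owner (`posture_body` /
`posture_operation`, `move_stop_body` / `move_stop_spatial`). Counts are
fixed at 1 query + 23 inference + 64 evidence nodes.

The published figure of the full network is not machine-readable, so the
wiring of the 64 evidence leaves onto the 15 properties is this package's
own design (`structure.DEFAULT_EVIDENCE_WIRING`): wrist-motion contexts
observe wrist-accelerometer features, body contexts the phone accelerometer,
environmental contexts the wrist lux/temperature/humidity means. Distinct
evidence nodes may observe the same feature under different contexts; only
the counts and the class hierarchy are treated as binding. The single
temporal context (*eating time*) observes daylight proxies (`h_lux_mean`,
`h_temp_mean`) rather than clock time, keeping every feature a pure function
of the window's samples.

Modules exchange information only through shared nodes: each submodule root
is simultaneously a leaf of the main module. Formally the literal definition
of a modular network requires disjoint member sets; we enforce disjointness
on non-shared members and implement the shared-node semantics, which is what
message passing requires. The maximum parent count is capped at 2, but the
default structure is a tree (every node has exactly one parent).

## Windowing and features

Streams are segmented into non-overlapping, left-closed right-open windows
of 1 s — the smallest window covering the 1 Hz environmental channels, giving
20 accelerometer samples per window. A window is emitted only when every
required channel contributed at least one sample; for training the
requirement is all nine channels, while recognition requires only the
channels actually present in the stream (a dead sensor then surfaces as
absent evidence rather than lost windows). The window label is the majority
record label, ties broken toward the smaller activity index; activities 4
and 5 (eating with dinnerware / other eating) count as eating.

Features are deliberately minimal: mean, standard deviation (population) and
range per accelerometer axis, mean per environmental channel — 21 features.
Frequency-domain features are out of scope.

Attribute screening implements the four classical filter scores (Pearson
correlation against the 0/1 class, information gain, gain ratio, symmetric
uncertainty) with entropies in bits. Attributes are discretized by equal
frequency (default 10 bins) with the rule that equal values always share the
bin of their first-ranked occurrence — without it a constant attribute would
straddle bins and acquire spurious information.

## Evidence stumps

Each evidence node trains a depth-1 threshold classifier on its wired
feature against the truth state of its parent context. Depth 1 (rather than
a deeper tree) keeps the 64-classifier bank cheap and interpretable; the
split maximizes training accuracy over midpoints between consecutive
distinct values plus the two constant predictors, at both polarities
(`>= t` or `<= t` maps to state *true*). Ties go to the smallest threshold,
then to the `>=` polarity; a value exactly at the threshold always maps to
*true*. Single-class training targets yield a flagged degenerate stump
predicting the majority class. Stumps output hard states; soft/virtual
evidence is a non-goal.

## CPT learning

Every node's CPT is the smoothed relative co-occurrence frequency of
(parent state, child state) over fully annotated windows. The published
counting rule is stated for contexts directly under the query
(`P(I_i|Q) = num(I_i ∩ Q)/num(Q)`); we apply the identical rule to every
parent–child edge, which degenerates to the original for depth-1 links and
is required for a multi-level tree. Smoothing is Laplace with `alpha = 1`
by default (each row becomes `(count + alpha)/(total + alpha·2)`), keeping
every probability positive so posteriors stay defined under any evidence;
`alpha = 0` reproduces the raw quotients and raises on empty rows.

Training uses annotated truth states for the query and context nodes and
the stumps' *outputs* for the evidence nodes, so evidence CPT rows capture
the stumps' actual error rates rather than an idealized sensor. Cost is one
increment per node per window — linear in the data, as the counting
formulation promises. Banks accumulated on disjoint data merge exactly into
the bank of the concatenation.

## Inference

Exact inference uses upward likelihood messages on the tree: each submodule
reduces its evidence to a likelihood message at its shared root,
independently of the other submodules; the main module combines the four
root messages with the query prior. Messages are renormalized at every node
— the tree analogue of log-space stabilization — so products over 64 leaves
cannot underflow; the reported posterior is the standard normalized one (an
un-normalized chain-rule product is not a probability). Unobserved evidence
contributes a uniform message, i.e. is marginalized out. Shared-node
posteriors combine the node's bottom-up likelihood with the top-down message
from the query (prior × the other submodules' messages) and are exact
marginals, verified against enumeration.

A brute-force oracle enumerates the full joint (vectorized over bit
patterns for all-binary networks, refusing state spaces above 2^20) and
certifies the message-passing posterior to 1e-10 over seeded random trees.
The decision rule is `posterior >= threshold → eating` (tie inclusive, the
convention also used by the ROC sweep); the default threshold is 0.6.

## Synthetic data

The simulator emulates the study conditions rather than any deposited data:
defaults of 10 activities with an expected eating share of 47.27% of
collection time (eating bouts split 11:6 between dinnerware and other
eating, mirroring the study's subject counts), one-minute activity bouts,
nine channels at native rates, and per-sample dropout (default 1%).
Emissions are Gaussian-plus-sinusoid per channel — the minimal family that
reproduces the qualitative contrasts reported for real streams: periodic
hand motion while eating with dinnerware, low-variance wrist signal while
holding food, stride periodicity while walking, vehicle vibration, outdoor
illuminance. Per-activity parameters live in a shipped config
(`eatbn/data/default_profiles.yaml`) so tests and docs share fixtures.

Subject heterogeneity: per-channel multiplicative gain (log-normal, σ=0.08)
and small additive offsets on the environmental channels; children attenuate
wrist-y motion (food positioned higher); left-handed subjects (p=0.12) show
a strongly attenuated, steadier wrist x-axis and noisier y/z — the
heterogeneous case the network must absorb through its remaining contexts.

Context truth per activity is declared for the 15 low-level properties in
the profile config; higher nodes derive by majority vote of their children
and the query truth follows the activity label. This gives CPT learning the
full annotations its counting rule assumes.

What the simulator does *not* model: realistic biomechanics, activity
transition dynamics, phone placement variation, drift, or the long-tailed
label noise of field annotation. Synthetic streams are therefore much more
separable than real recordings — held-out accuracy near 98% on defaults —
so passing tests demonstrate correctness of the pipeline and its contracts
(robustness to missing sensors, calibration of the counting estimator), not
expected field accuracy.

## Evaluation

Metrics are the standard window-level percentages (accuracy, precision,
sensitivity, specificity); ratios with zero denominators are reported as
not-applicable, never 0. Values are rounded to two decimals for reporting
and kept unrounded internally; the four percentages recompute exactly from
the published pooled confusion matrix. The ROC sweep classifies at a
descending threshold grid with the same tie rule as recognition and reports
a trapezoidal AUC anchored at (0,0) and (1,1). Cross-validation stratifies
window-level folds by class after canonically ordering windows by start
time, so fold assignment depends only on the seed and the data, not input
order; window-level (rather than subject-level) folding matches the pooled
study-style confusion matrix. Per-activity error analysis reports each
activity's error rate and its share of all errors.

## Problem sizes

Default test and reproduction runs use 4 simulated subjects × 6 min
(≈ 1,400 one-second windows), 100 random oracle models of 3–20 nodes, and
50,000 ancestral samples for parameter recovery (binomial standard error
≈ 0.002–0.005, comfortably inside the 0.02 recovery tolerance). These sizes
were chosen so a full run completes in well under a minute on one CPU while
keeping every statistical check far from its noise floor.
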