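# eatbn — eating-activity recognition with a modular Bayesian network

`eatbn` recognizes **eating vs. non-eating activity** from nine low-power
wearable sensor channels: a wrist accelerometer (`h_acc_x/y/z`, 20 Hz), wrist
illuminance, temperature and humidity (`h_lux`, `h_temp`, `h_hum`, 1 Hz), and
a phone accelerometer (`acc_x/y/z`). It is aimed at digital-health uses —
automatic meal logging for diabetes management or elder care — where eating is
a *complex* activity: its motion signature varies wildly with utensil, food,
age and handedness, so a single accelerometer classifier generalizes poorly.

## The model

The recognizer is a **modular, tree-structured Bayesian network** with 88
binary nodes:

* 1 **query node** `Q` — eating vs. non-eating;
* 23 **inference nodes** `I` — hidden context variables organized by the
  Five-W's / activity-theory decomposition into four top-level context
  classes (*subject*, *object*, *spatial*, *temporal* property) and their
  low-level contexts (movement of hand, posture, indoor/outdoor, eating
  time, ...);
* 64 **evidence nodes** `V` — leaves set by per-window sensor features.

Edges run generatively `Q → I → V`, every node has one parent, and the
network is partitioned into a *main module* (`Q` plus the four context-class
roots) and four tree *submodules* that communicate with the main module only
through their shared roots. This keeps inference exact and cheap, and makes
the result explainable: the posterior of each shared node reports how
strongly each context class supports the decision.

Each evidence node owns a depth-1 decision tree (a stump) thresholding one
window feature. CPTs are learned by counting: for each parent–child link,
`P(child = s | parent = g)` is the smoothed relative frequency of the
co-occurrence — for a context `I_i` directly under the query this is exactly
`P(I_i | Q) = num(I_i ∩ Q) / num(Q)` — so training is a single linear pass
over the windows. The posterior `P(Q | e)` is computed by exact likelihood
message passing on the tree; unobserved evidence (a removed or dead sensor)
is marginalized out rather than breaking the decision. A window is called
*eating* when the posterior reaches the decision threshold (default 0.6).

Because the original 25-subject recordings are not public, the package ships
a **synthetic sensor-stream simulator** reproducing the study conditions:
the nine channels at their native rates, the 10-activity vocabulary, a
47.27% eating share of collection time, per-subject heterogeneity
(handedness, age, gain/offset) and sensor dropout — with full per-window
context annotations so every stage of the stack is testable end to end.

## Worked example

```python
import numpy as np
from eatbn import (build_default_structure, generate_dataset, segment_windows,
                   train_model, ConfusionMatrix, compute_metrics)

structure = build_default_structure()          # the 88-node network
records, annotations = generate_dataset(n_subjects=4, minutes_per_subject=6.0,
                                        seed=42)
windows = segment_windows(records)             # 1-s windows, 21 features each

rng = np.random.default_rng(0)
order = rng.permutation(len(windows))
train = [windows[i] for i in order[::2]]
test = [windows[i] for i in order[1::2]]
model = train_model(train, annotations, structure, alpha=1.0, threshold=0.6)

cm = ConfusionMatrix()
for w in test:
    rep = model.posterior(w.features)
    cm.add(rep.decision == "eating", w.is_eating)
print(compute_metrics(cm).rounded())
```

prints

```
{'accuracy': 97.26, 'precision': 96.89, 'sensitivity': 97.2, 'specificity': 97.32}
```

on a held-out half of 1388 synthetic windows (46.2% eating): the recognizer
is far above the 53.8% majority-class baseline. Synthetic streams are much
cleaner than real recordings, so these numbers characterize the pipeline,
not field performance. A single window's report is fully explainable:

```python
rep = model.posterior(test[0].features)
print(rep.query_posterior, rep.decision)       # e.g. 0.9997 eating
print(rep.shared_node_posteriors)              # per context class, e.g.
# {'subject_property': 1.0000, 'object_property': 0.9997,
#  'spatial_property': 1.0000, 'temporal_property': 0.9998}
```

The same pipeline is available from the shell:

```sh
eatbn simulate  --out-sensors s.csv --out-annotations a.csv --seed 11
eatbn train     --sensors s.csv --annotations a.csv --out-model model.json
eatbn recognize --model model.json --sensors s.csv --out decisions.csv
eatbn evaluate  --model model.json --sensors s.csv --out-metrics m.json --out-roc roc.csv
eatbn crossval  --sensors s.csv --annotations a.csv --out cv.json --k 10 --seed 1
```

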