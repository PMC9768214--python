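"""Subjective-scale labeling and before/after score comparison.

The six-indicator, five-grade subjective scale maps to mental-state
labels through a fixed rule table; behavioral game scores before and
after cognitive training are compared with the same t-test machinery as
the network metrics.
"""

import numpy as np

import neurostates as ns

ratings = [
    dict(effort="high", temporal_demand="medium", performance="medium",
         fatigue_degree="low", arousal="high", valence="medium"),
    dict(effort="low", temporal_demand="low", performance="medium",
         fatigue_degree="medium", arousal="low", valence="low"),
    dict(effort="medium", temporal_demand="high", performance="medium",
         fatigue_degree="high", arousal="low", valence="medium"),
    dict(effort="high", temporal_demand="high", performance="high",
         fatigue_degree="low", arousal="very_high", valence="high"),
]
for r in ratings:
    label = ns.label_state(ns.SubjectiveScaleVector(**r))
    print(f"arousal={r['arousal']:<9} valence={r['valence']:<7} -> {label}")

rng = np.random.default_rng(5)
before = rng.normal(40.0, 8.0, 13)           # game scores, 13 subjects
after = before + rng.normal(10.0, 5.0, 13)   # training gain
r = ns.compare_scores(before, after)
print(f"\ngame scores: before {r.group_means[1]:.1f}, after "
      f"{r.group_means[0]:.1f}; t = {r.t:.3f}, p = {r.p:.4f}, d = {r.d:.3f}")
print("positive t and large d: training improved performance")
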