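"""Accuracy recovery as clipping weakens (the tau sweep, at demo scale).

Generates a small cohort, then evaluates RF on RMS+WL features under each
clipping threshold with paired split plans.  Expect near-chance accuracy at
tau = 1e-6 (only sign structure survives) recovering toward the clean value
at tau = 1e-1.
"""

import numpy as np

from emgstress.degrade import DegradationSpec
from emgstress.evaluate import ClassifierSpec, prepare_windows, run_condition, summarize
from emgstress.features import FeatureSpec
from emgstress.synth import generate_cohort, micro_config

cfg = micro_config(n_subjects=2, n_sessions=2, seed=0)
prep = prepare_windows(generate_cohort(cfg), dtype=np.float32)
features = FeatureSpec(names=("RMS", "WL"))
rf = ClassifierSpec("rf", grid={"n_estimators": [50]})

print(f"chance level for {len(cfg.gesture_labels)} gestures: "
      f"{1 / len(cfg.gesture_labels):.3f}")
print(f"{'tau':>8} {'mean acc':>9} {'min':>7} {'max':>7}   (subject-wise)")
for tau in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1):
    res = run_condition(
        prep, features, rf, DegradationSpec(kind="clip", tau=tau),
        n_repeats=2, seed=42,
    )
    row = summarize(res).iloc[0]
    print(f"{tau:8.0e} {row.mean_accuracy:9.3f} {row.min_accuracy:7.3f} "
          f"{row.max_accuracy:7.3f}")
print("\nAccuracy rises monotonically with tau: weaker clipping leaves feature")
print("statistics closer to their clean values, so class separability returns.")
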