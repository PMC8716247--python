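"""Decode imagery conditions with CSP features and an RBF SVM.

Simulates a subject with a strong ERD contrast between the two classes,
fits common-spatial-pattern filters inside each outer cross-validation fold
(8-30 Hz band, 1-4 s window), selects the SVM cost C on the training folds
only, and reports the tenfold recognition rate. A label permutation shows
the chance level of the same pipeline.
"""

from dataclasses import replace

import numpy as np

import erdkit

config = erdkit.GeneratorConfig(
    sampling_rate=250.0, n_channels=8, n_trials_per_condition=60,
    alpha_peak=10.0, beta_peak=19.0, seed=3,
    erd_depth_db={"deep": {"alpha": -6.0, "beta": -6.0},
                  "none": {"alpha": 0.0, "beta": 0.0}},
    erd_depth_jitter_shared_db=0.0, erd_depth_jitter_cond_db=0.0,
)
trials = erdkit.generate_subject(config)

result = erdkit.recognition_rate(trials)
print(f"separable contrast: mean recognition rate {result.mean_accuracy:.3f}")
print(f"  per-fold: {np.round(result.fold_accuracies, 2).tolist()}")
print(f"  chosen C per fold: {result.chosen_c_per_fold}")

rng = np.random.default_rng(0)
shuffled = replace(trials,
                   condition_labels=rng.permutation(trials.condition_labels))
chance = erdkit.recognition_rate(shuffled)
print(f"permuted labels:    mean recognition rate {chance.mean_accuracy:.3f}")
print("a separable contrast decodes near 1.0; permuted labels near 0.5")
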