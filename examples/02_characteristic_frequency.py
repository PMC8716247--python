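"""Locate each subject's characteristic frequency from the energy curve.

Simulates a 10-subject cohort whose alpha peaks are drawn from 8-11 Hz,
collapses each subject's ERSP over the imagery window into a frequency-
domain energy curve, and reports the curve minimum inside the alpha search
range (the characteristic frequency) next to the injected ground truth.
"""

import erdkit
from erdkit.synth import cohort_configs

template = erdkit.GeneratorConfig(
    sampling_rate=250.0, n_channels=4, n_trials_per_condition=40
)
configs = cohort_configs(10, template, seed=11)
cohort = erdkit.generate_cohort(10, template, seed=11)

print("subject  injected_alpha_Hz  recovered_Hz  characteristic_band_Hz")
for cfg, trials in zip(configs, cohort):
    tf_map = erdkit.ersp(erdkit.bandpass(trials), "Cz")
    curve = erdkit.energy_curve(tf_map, window=(0.0, 4.0))
    res = erdkit.characteristic_frequency(curve, erdkit.ALPHA_BAND)
    lo, hi = res.characteristic_band
    print(f"{trials.subject_id:>7}  {cfg.alpha_peak:>17.0f}  "
          f"{res.characteristic_frequency:>12.0f}  [{lo:g}, {hi:g}]")
print("recovered frequencies should sit within 1 Hz of the injected peaks;")
print("the band is the contiguous below-baseline run around the minimum")
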