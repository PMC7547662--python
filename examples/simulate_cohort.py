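"""Simulate the contrast-discrimination task and its MEG-like power tensors.

Generates one staircase-titrated subject: ten contrast samples per trial
drawn around the adaptive 75%-accuracy offset, choices from a noisy
primacy-weighted accumulator, and an ROI x hemisphere x frequency x time
power tensor whose gamma band encodes contrast and whose low-frequency
band carries the choice-signed feedback signal.
"""

import numpy as np

from decidecode._rng import substream
from decidecode.neural import NeuralGenParams, default_frequency_grid, generate_power_tensor
from decidecode.trials import generate_trial_table

trials = generate_trial_table(n_subjects=1, n_trials=600, seed=0)
analyzed = trials.iloc[100:]  # first block calibrates the staircase

print(f"trials simulated:        {len(trials)} (analyzing last {len(analyzed)})")
print(f"accuracy:                {analyzed['correct'].mean():.3f}  (staircase target 0.75)")
print(f"stronger-category rate:  {(analyzed['stimulus_category'] == 'stronger').mean():.3f}")
print(f"median reaction time:    {analyzed['rt'].median():.2f} s")

params = NeuralGenParams(frequency_grid=default_frequency_grid(coarse=True))
tensor = generate_power_tensor(analyzed.reset_index(drop=True), params,
                               rng=substream(0, "neural"))
print(f"power tensor dims:       {dict(tensor.sizes)}")
baseline = tensor.sel(time=slice(-0.25, -1e-9)).mean().item()
print(f"baseline-window power:   {baseline:.2f}  (configured level {params.baseline_level})")
# The accuracy sits near the 75% staircase target, categories are balanced,
# and the pre-stimulus window contains only baseline power plus noise.
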