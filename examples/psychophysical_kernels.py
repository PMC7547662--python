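"""Psychophysical reverse correlation: which samples drive the choice?

For each of the ten sample positions the kernel is the ROC area comparing
contrast fluctuations between choices within each stimulus category
(hits vs misses, false alarms vs correct rejects, averaged).  A primacy
observer weights early evidence more, so the kernel starts above chance
and declines — the negative slope mirrors the behavioral finding the
statistic was designed to expose.
"""

import numpy as np
from scipy.stats import ttest_1samp

from decidecode.behavior import exclude_fast_rts, fit_choice_logreg, kernel_slope, psychophysical_kernel
from decidecode.group_stats import fdr_correct
from decidecode.trials import generate_trial_table

kernels, slopes, accs = [], [], []
for s in range(15):
    t = generate_trial_table(n_subjects=1, n_trials=700, seed=100 + s)
    t = exclude_fast_rts(t.iloc[100:].reset_index(drop=True))
    k = psychophysical_kernel(t)
    kernels.append(k)
    slopes.append(kernel_slope(k))
    accs.append(fit_choice_logreg(t).cv_accuracy)

group = np.mean(kernels, axis=0)
print("group psychophysical kernel (AUC per sample position):")
print("  " + "  ".join(f"{v:.3f}" for v in group))
print(f"group kernel slope:      {np.mean(slopes):+.4f} AUC/position (primacy => negative)")
print(f"choice-model CV accuracy:{np.mean(accs):.3f} (bounded near the 75% staircase target)")
p = ttest_1samp(np.array(kernels), 0.5, axis=0).pvalue
print(f"positions above chance (FDR-corrected): {np.flatnonzero(fdr_correct(p)) + 1}")
# All early positions carry significant choice information; the declining
# profile reflects the observer's primacy weighting of the evidence stream.
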