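"""Strict per-gait-cycle ROC for the five step counters.

Counts steps in a simulated 120-cycle walking bout. Under the strict
definition, a cycle with n > 0 detected events yields one true positive
and n - 1 false positives; empty cycles are misses; events outside every
cycle are false positives. Sweeping each counter's score threshold
traces an ROC whose FPR can exceed 1 for heavy over-counters.
"""

from stridekit import benchmark as bm

SEED = 3

print("counter   events  loose_err   TPR@FPR<=5%   TPR@FPR<=1%")
for algo in ("fsm", "ptm", "stft", "dwt", "dwt2"):
    curve, det, truth = bm.sc_roc(algo, SEED, noise_sd=0.05, n_cycles=120)
    loose = (len(det) - truth.cgt) / truth.cgt * 100
    print(f"{algo:8s}  {len(det):5d}   {loose:+7.1f}%   "
          f"{curve.best_tpr_at_fpr(0.05):10.3f}   {curve.best_tpr_at_fpr(0.01):10.3f}")
# The loose (count-difference) error hides false positives that cancel
# misses; the strict TPR/FPR pair does not. dwt2 typically over-counts
# heavily at the full-event end of its curve but is usable once
# thresholded, which only the ROC view reveals.
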