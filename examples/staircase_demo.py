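"""Threshold estimation with the 4-2-1 staircase.

Runs one simulated staircase per true threshold and prints the estimate
next to the truth: with a realistic observer (psychometric spread 0.5 dB,
3% response errors) the estimates track the truth to about 1 dB inside
the 0-34 dB dynamic range and saturate at its ends.
"""

import numpy as np

from mpsf.staircase import ObserverModel, staircase_421

rng = np.random.default_rng(7)
print("true threshold -> staircase estimate (presentations)")
for truth in (-5.0, 3.0, 12.0, 17.0, 25.5, 31.0, 40.0):
    obs = ObserverModel(true_threshold_db=truth, slope_sd_db=0.5,
                        false_pos_rate=0.03, false_neg_rate=0.03)
    res = staircase_421(obs, rng)
    print(f"  {truth:6.1f} dB -> {res.estimate_db:4.1f} dB "
          f"({len(res.presentation_log)} presentations, "
          f"{res.n_reversals} reversals)")
print("\nEstimates are clipped to the device's 0-34 dB range; a threshold")
print("below 0 reads 0 (never seen) and above 34 reads 34 (always seen).")
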