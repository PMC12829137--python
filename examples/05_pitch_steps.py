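"""Detecting abrupt pitch steps and testing their contingency on WN.

A step is flagged when the mean of the 20 renditions before an index and
the mean of the 20 from it differ by more than 5% of the local mean.
Steps are removed iteratively (largest first); the Z test asks whether
steps follow recent WN more often than chance.
"""

import numpy as np

from latentrl import detect_steps, remove_steps_iterative, step_rate_ztest

rng = np.random.default_rng(3)
T = 400
pitch = 200.0 + rng.normal(0, 2.0, T)
pitch[150:] += 18.0   # +9% step
pitch[300:] -= 14.0   # -7% step
wn = (rng.random(T) < 0.005).astype(float)
wn[145:150] = 1.0     # WN burst just before the first step

events = detect_steps(pitch, n_s=20, theta=0.05)
print(f"{len(events)} super-threshold indices at theta=5%")

corrected, removed = remove_steps_iterative(pitch, n_s=20, theta=0.05)
for e in removed:
    print(f"  removed step at i={e.index}: {e.left_mean:.1f} -> "
          f"{e.right_mean:.1f} Hz ({100 * e.size / e.local_mean:.1f}% of local mean)")
print(f"corrected series: {len(detect_steps(corrected, 20, 0.05))} steps remain")

res = step_rate_ztest(removed, wn, lookback=20)
print(f"\nWN contingency: {res.n_d_wn}/{res.n_d} steps WN-preceded "
      f"(chance {100 * res.r_c:.0f}%), Z = {res.z:.2f} "
      f"({'significant' if res.significant else 'not significant'} at |Z|>1.96)")
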