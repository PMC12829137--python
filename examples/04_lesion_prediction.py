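"""Predicting the effect of silencing the exploration source.

If a brain lesion removes the latent learner's exploration channel (and
nothing else), post-lesion pitch variance should equal the pre-lesion
variance minus the fitted exploration variance. The lesion_pair preset
generates a pre/post pair where the post trajectory deletes exploration;
the prediction is made from the pre-lesion fit alone.
"""

import numpy as np

from latentrl import fit_baseline, generate_synthetic_bird, predict_lesion_effect

pair = generate_synthetic_bird("lesion_pair", seed=5)
bl = fit_baseline(pair.traj)
table = predict_lesion_effect(bl.decomposition)

pre = np.var(pair.traj.pitch)
post = np.var(pair.post_traj.pitch)
print(f"pre-lesion pitch variance:        {pre:8.1f} Hz^2")
print(f"fitted exploration variance:      {bl.sigma_bl_expl**2:8.1f} Hz^2")
print(f"predicted post-lesion variance:   {table['predicted_post']:8.1f} Hz^2")
print(f"realized post-lesion variance:    {post:8.1f} Hz^2")
print("\ncomponent variances (pre-lesion fit):")
for k in ("exploration", "colored_noise", "circadian", "history"):
    print(f"  {k:14s} {table[k]:8.1f} Hz^2")
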