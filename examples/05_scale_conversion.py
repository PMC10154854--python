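"""Convert latent-scale heritability to the observed binary scale.

Shows the exact probit conversion, its agreement with the Dempster-Lerner
closed form, and how the conversion factor depends on trait prevalence.
"""

import numpy as np

from broodsex.scale import LatentParams, dempster_lerner, latent_to_observed

# a population with latent h2 = 0.25 and half the offspring male
sa = 0.25 / 0.75  # sigma2_a with residual 1 and no maternal variance
obs = latent_to_observed(LatentParams(mu_values=0.0, sigma2_a=sa, sigma2_re=sa))
print(f"latent h2 = 0.250, prevalence = {obs.p:.2f}")
print(f"observed-scale h2 = {obs.h2_obs:.5f} "
      f"(= 0.25 x 2/pi = {0.25 * 2 / np.pi:.5f})")

print("\nDempster-Lerner factor h2_obs / h2_lat by proportion male:")
for p in (0.1, 0.3, 0.5, 0.64, 0.9):
    print(f"  p = {p:.2f}: {dempster_lerner(1.0, p):.4f}")
# The factor peaks at 2/pi ~ 0.64 for an unbiased sex ratio and shrinks as
# the ratio becomes extreme: the same liability variation flips fewer sexes.
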