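"""Evaluate the training objectives at instructive points.

The mixed perceptual loss is alpha*(1-SSIM) + beta*MSE (alpha=300, beta=1),
weighted by lambda=100 inside the generator objective.  The discriminator
uses smoothed targets 0.9/0.1, which moves its optimum away from full
confidence: scanning the loss over (d_real, d_fake) shows the minimum at
exactly those labels.
"""

import math

import numpy as np

from attnfnet.losses import (LossConfig, discriminator_loss, generator_loss,
                             ssim, ssiml2_loss)

cfg = LossConfig()
rng = np.random.default_rng(0)
y = rng.random((27, 64))

print(f"ssim(y, y)            = {ssim(y, y).item():.6f}")
print(f"ssiml2(y, y)          = {ssiml2_loss(y, y, cfg).item():.6f}")
print(f"D loss at (0.5, 0.5)  = {discriminator_loss(0.5, 0.5, cfg).item():.6f}"
      f"  (2 ln 2 = {2 * math.log(2):.6f})")
print(f"G loss at d=0.5, g=y  = {generator_loss(0.5, y, y, cfg).item():.6f}"
      f"  (ln 2 = {math.log(2):.6f})")

grid = np.linspace(1e-4, 1 - 1e-4, 200)
losses = np.array([[discriminator_loss(dr, df, cfg).item() for df in grid]
                   for dr in grid])
i, j = np.unravel_index(losses.argmin(), losses.shape)
print(f"\nD-loss minimum on a 200x200 grid: d_real={grid[i]:.3f}, "
      f"d_fake={grid[j]:.3f} (labels are 0.9 / 0.1)")
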