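"""Run the two preprocessing paths on one raw sample.

Depth: no-return pixels (value 0) are repaired by an iterated 3x3 median,
the frame is clipped and shaped for the model.  Pressure: the ground truth
is area-average resampled to 27x64 and smoothed with a Gaussian (sigma 1.4).
Normalization statistics always come from the training split.
"""

import numpy as np

from attnfnet.preprocessing import PreprocessConfig, clean_depth
from attnfnet.synthetic import generate_dataset
from attnfnet.training import prepare_data

dataset = generate_dataset(6, 3, seed=7, grid_shape=(64, 56),
                           depth_dropout_prob=0.05)
cfg = PreprocessConfig(pad_to=(64, 56))

raw = dataset.samples[0].depth
print(f"raw depth: {int((raw == 0).sum())} no-return pixels")
clean = clean_depth(raw, cfg)
print(f"cleaned depth: {int((clean == 0).sum())} remaining, "
      f"shape {clean.shape}")

prepared = prepare_data(dataset, cfg)
print(f"depth stats (train split): [{prepared.depth_stats.vmin:.3f}, "
      f"{prepared.depth_stats.vmax:.3f}] m -> model range {cfg.depth_range}")
print(f"pressure stats (train split): [{prepared.pressure_stats.vmin:.3f}, "
      f"{prepared.pressure_stats.vmax:.3f}] raw -> {cfg.pressure_range}")
x, y, _ = prepared.splits["train"][0]
print(f"model inputs: depth {x.shape} in [{x.min():.2f}, {x.max():.2f}], "
      f"pressure {y.shape} in [{y.min():.2f}, {y.max():.2f}]")
# Pressure targets deliberately stay inside (0, 1): the generator's sigmoid
# never needs to saturate to reproduce the zero background.
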