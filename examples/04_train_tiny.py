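"""Train the desk-scale preset end to end and compare against a baseline.

Uses the "tiny" preset (8 subjects, 64-d embedding, 6 transformer blocks,
5 epochs) — the same architecture as the full model, scaled to run in a few
minutes on one CPU.  The success criterion is honest: held-out validation
MSE must beat a constant predictor that always outputs the train-split mean
pressure map.
"""

from attnfnet.config import tiny_experiment_config
from attnfnet.synthetic import generate_dataset
from attnfnet.training import (constant_predictor_baseline, fit,
                               prepare_data)

cfg = tiny_experiment_config(seed=0)
dataset = generate_dataset(cfg.data.n_subjects, cfg.data.poses_per_subject,
                           cfg.data.split_fractions, seed=cfg.seed,
                           grid_shape=cfg.data.grid_shape)
prepared = prepare_data(dataset, cfg.preprocess)
baseline = constant_predictor_baseline(prepared)

G, D, history = fit(dataset, cfg.train, cfg.loss, cfg.model, cfg.disc,
                    prepared=prepared)

print(f"{'epoch':>5} {'L_G':>10} {'L_D':>8} {'val MSE':>10} {'val SSIM':>9}")
for r in history.records:
    print(f"{r['epoch']:>5} {r['loss_g']:>10.1f} {r['loss_d']:>8.3f} "
          f"{r['val_mse']:>10.5f} {r['val_ssim']:>9.4f}")
best = min(r["val_mse"] for r in history.records)
print(f"\nconstant-mean-predictor val MSE:   {baseline:.5f}")
print(f"model val MSE (best checkpoint):   {best:.5f}")
print(f"model val MSE (final epoch):       "
      f"{history.records[-1]['val_mse']:.5f}")
# Validation MSE below the baseline means the generator actually uses the
# depth image, not just the average pressure pattern of the cohort.  The
# best-validation checkpoint is the retained model; the per-epoch value
# oscillates, which is normal for adversarial training at this scale.
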