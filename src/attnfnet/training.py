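"""Alternating conditional-GAN optimization: data preparation, the D/G step,
the epoch loop with per-epoch validation, checkpointing and history logging.

Defaults follow the training recipe the models were designed for: Adam with
beta1 = 0.5, beta2 = 0.999, learning rate 1e-4 for the transformer generator
(2e-4 for the U-Net baseline), batch size 1, 90 epochs, one discriminator
update then one generator update per sample.  Validation loss is recorded
every epoch (no early stopping by default) so that a diverging validation
MSE — the usual mode-collapse signature of this recipe — stays visible in
the history.

Everything is driven by explicit seeds through named substreams (model
init, discriminator init, per-epoch shuffling), so a rerun with the same
config and data is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import LossConfig, discriminator_loss, generator_loss, ssim
from .model import (AttnFnetGenerator, DiscriminatorSpec, GeneratorSpec,
                    PatchGANDiscriminator, UNetGenerator, build_unet_baseline)
from .nn import Adam, Module, Tensor
from .preprocessing import (NormStats, PreprocessConfig, clean_depth,
                            compute_norm_stats, denormalize, normalize,
                            preprocess_pressure)
from .synthetic import PairedSample, SyntheticDataset

__all__ = [
    "TrainConfig", "TrainHistory", "PreparedData", "prepare_data",
    "build_generator", "train_step", "fit", "predict",
    "constant_predictor_baseline", "save_checkpoint", "load_checkpoint",
]

VARIANTS = ("attnfnet", "vit_mlp", "unet")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4          # 2e-4 is the U-Net baseline default
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    epochs: int = 90
    batch_size: int = 1
    seed: int = 0
    checkpoint_every: int = 10
    variant: str = "attnfnet"
    max_grad_norm: float = 10.0   # global-norm clip; <= 0 disables

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not (0 <= self.adam_beta1 < 1 and 0 <= self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class PreparedData:
    """Model-ready normalized arrays per split, plus the train-split stats."""

    splits: dict[str, list[tuple[np.ndarray, np.ndarray, PairedSample]]]
    depth_stats: NormStats
    pressure_stats: NormStats
    pre_cfg: PreprocessConfig

    def manifest(self) -> dict:
        return {
            "depth_stats": self.depth_stats.to_dict(),
            "pressure_stats": self.pressure_stats.to_dict(),
            "gaussian_sigma": self.pre_cfg.gaussian_sigma,
            "depth_clip": list(self.pre_cfg.depth_clip),
            "pad_to": list(self.pre_cfg.pad_to),
            "split_sizes": {k: len(v) for k, v in self.splits.items()},
        }


def prepare_data(dataset: SyntheticDataset,
                 pre_cfg: PreprocessConfig | None = None) -> PreparedData:
    """Clean/smooth every sample and normalize with train-split statistics."""
    pre_cfg = pre_cfg or PreprocessConfig()
    cleaned: dict[str, list] = {}
    for split in ("train", "val", "test"):
        cleaned[split] = [
            (clean_depth(s.depth, pre_cfg),
             preprocess_pressure(s.pressure, pre_cfg), s)
            for s in dataset.subset(split)
        ]
    if not cleaned["train"]:
        raise ValueError("train split is empty")
    depth_stats = compute_norm_stats([d for d, _, _ in cleaned["train"]])
    pressure_stats = compute_norm_stats([p for _, p, _ in cleaned["train"]])
    splits = {
        split: [(normalize(d, depth_stats, pre_cfg.depth_range),
                 np.clip(normalize(p, pressure_stats, pre_cfg.pressure_range),
                         *pre_cfg.pressure_range), s)
                for d, p, s in items]
        for split, items in cleaned.items()
    }
    return PreparedData(splits=splits, depth_stats=depth_stats,
                        pressure_stats=pressure_stats, pre_cfg=pre_cfg)


def build_generator(spec: GeneratorSpec, variant: str, seed: int) -> Module:
    if variant == "attnfnet":
        return AttnFnetGenerator(
            GeneratorSpec(**{**spec.to_dict(), "ff_variant": "conv"}), seed)
    if variant == "vit_mlp":
        return AttnFnetGenerator(
            GeneratorSpec(**{**spec.to_dict(), "ff_variant": "mlp"}), seed)
    if variant == "unet":
        return build_unet_baseline(spec.input_shape, spec.output_shape,
                                   seed=seed)
    raise ValueError(f"unknown variant {variant!r}")


def _finite_or_abort(value: float, name: str, epoch: int, step: int) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite {name} ({value}) at epoch {epoch}, "
                           f"step {step}; aborting")
    return value


def _clip_global_norm(params, max_norm: float) -> None:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``.

    The perceptual term's lambda * alpha weighting makes raw generator
    gradients very large early in training; unclipped they overshoot the
    bounded output activation into saturation and inflate Adam's
    second-moment state so far that recovery stalls.
    """
    if max_norm <= 0:
        return
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def train_step(x: np.ndarray, y: np.ndarray, G: Module,
               D: PatchGANDiscriminator, opt_g: Adam, opt_d: Adam,
               loss_cfg: LossConfig, epoch: int = 0, step: int = 0,
               max_grad_norm: float = 10.0) -> dict[str, float]:
    """One discriminator update then one generator update on a single pair.

    The discriminator update sees the generator output detached; the
    generator update runs a fresh discriminator evaluation (post-D-update),
    so each player optimizes against the other's current parameters.
    """
    fake = G(x)

    # -- discriminator update (G frozen via detach) -------------------------
    opt_d.zero_grad()
    d_real = D.probability_map(x, Tensor(y))
    d_fake = D.probability_map(x, fake.detach())
    loss_d = discriminator_loss(d_real, d_fake, loss_cfg)
    loss_d.backward()
    _clip_global_norm(opt_d.params, max_grad_norm)
    opt_d.step()

    # -- generator update (fresh D evaluation) ------------------------------
    opt_g.zero_grad()
    D.zero_grad()
    d_fake2 = D.probability_map(x, fake)
    loss_g = generator_loss(d_fake2, Tensor(y), fake, loss_cfg)
    loss_g.backward()
    _clip_global_norm(opt_g.params, max_grad_norm)
    opt_g.step()
    D.zero_grad()   # discard D grads that flowed through the fresh evaluation
    G.zero_grad()

    return {
        "loss_d": _finite_or_abort(loss_d.item(), "discriminator loss",
                                   epoch, step),
        "loss_g": _finite_or_abort(loss_g.item(), "generator loss",
                                   epoch, step),
    }


def _validate(G: Module, items, loss_cfg: LossConfig) -> tuple[float, float]:
    mses, ssims = [], []
    for x, y, _ in items:
        pred = G(x).data
        mses.append(float(np.mean((pred - y) ** 2)))
        ssims.append(ssim(y, pred, loss_cfg.ssim).item())
    return float(np.mean(mses)), float(np.mean(ssims))


def fit(dataset: SyntheticDataset, cfg: TrainConfig,
        loss_cfg: LossConfig | None = None,
        gen_spec: GeneratorSpec | None = None,
        disc_spec: DiscriminatorSpec | None = None,
        pre_cfg: PreprocessConfig | None = None,
        out_dir: str | Path | None = None,
        prepared: PreparedData | None = None
        ) -> tuple[Module, PatchGANDiscriminator, TrainHistory]:
    """Train generator and discriminator on the dataset's train split.

    Validation MSE/SSIM (model units) are computed each epoch on the val
    split without touching parameters.  If ``out_dir`` is given, checkpoints
    are written every ``cfg.checkpoint_every`` epochs plus a separate
    best-validation-MSE checkpoint, and the history CSV at the end.
    """
    loss_cfg = loss_cfg or LossConfig()
    gen_spec = gen_spec or GeneratorSpec()
    prepared = prepared or prepare_data(dataset, pre_cfg)
    train_items = prepared.splits["train"]
    val_items = prepared.splits["val"]
    if not train_items or not val_items:
        raise ValueError("train and val splits must both be nonempty")

    root = np.random.SeedSequence(cfg.seed)
    ss_ginit, ss_dinit, ss_shuffle = root.spawn(3)
    G = build_generator(gen_spec, cfg.variant,
                        int(ss_ginit.generate_state(1)[0] % (2 ** 31)))
    D = PatchGANDiscriminator(disc_spec,
                              int(ss_dinit.generate_state(1)[0] % (2 ** 31)))
    opt_g = Adam(G.parameters(), cfg.learning_rate, cfg.adam_beta1,
                 cfg.adam_beta2)
    opt_d = Adam(D.parameters(), cfg.learning_rate, cfg.adam_beta1,
                 cfg.adam_beta2)
    shuffle_rng = np.random.default_rng(ss_shuffle)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    history = TrainHistory()
    best_val = np.inf
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(len(train_items))
        g_losses, d_losses = [], []
        for step, idx in enumerate(order):
            x, y, _ = train_items[idx]
            m = train_step(x, y, G, D, opt_g, opt_d, loss_cfg, epoch, step,
                           max_grad_norm=cfg.max_grad_norm)
            g_losses.append(m["loss_g"])
            d_losses.append(m["loss_d"])
        val_mse, val_ssim = _validate(G, val_items, loss_cfg)
        history.append(epoch=epoch, loss_g=float(np.mean(g_losses)),
                       loss_d=float(np.mean(d_losses)),
                       val_mse=val_mse, val_ssim=val_ssim)
        if out_dir is not None:
            if epoch % cfg.checkpoint_every == 0 or epoch == cfg.epochs:
                save_checkpoint(G, gen_spec, cfg,
                                out_dir / f"checkpoint_epoch{epoch:03d}")
            if val_mse < best_val:
                save_checkpoint(G, gen_spec, cfg, out_dir / "checkpoint_best")
        best_val = min(best_val, val_mse)
    if out_dir is not None:
        history.to_csv(out_dir / "history.csv")
    return G, D, history


def predict(G: Module, depth_raw: np.ndarray, prepared: PreparedData
            ) -> np.ndarray:
    """Full inference path: clean, normalize, forward, denormalize.

    Returns the predicted pressure map in raw sensor units (nonnegative,
    shape (27, 64)); multiply by the subject's calibration scalar for kPa.
    """
    cfg = prepared.pre_cfg
    x = normalize(clean_depth(depth_raw, cfg), prepared.depth_stats,
                  cfg.depth_range)
    out = G(x).data
    raw = denormalize(out, prepared.pressure_stats, cfg.pressure_range)
    return np.maximum(raw, 0.0)


def constant_predictor_baseline(prepared: PreparedData,
                                eval_split: str = "val") -> float:
    """MSE (model units) of always predicting the train-split mean map."""
    train_maps = np.stack([y for _, y, _ in prepared.splits["train"]])
    mean_map = train_maps.mean(axis=0)
    errs = [float(np.mean((mean_map - y) ** 2))
            for _, y, _ in prepared.splits[eval_split]]
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(G: Module, spec: GeneratorSpec, cfg: TrainConfig,
                    path_prefix: str | Path) -> None:
    """Write ``<prefix>.npz`` (parameters) and ``<prefix>.json`` (spec)."""
    path_prefix = Path(path_prefix)
    arrays = {f"param_{i:04d}": a for i, a in enumerate(G.state_arrays())}
    np.savez_compressed(path_prefix.with_suffix(".npz"), **arrays)
    meta = {
        "generator_spec": spec.to_dict(),
        "train_config": {k: getattr(cfg, k) for k in (
            "learning_rate", "adam_beta1", "adam_beta2", "epochs",
            "batch_size", "seed", "checkpoint_every", "variant")},
        "n_parameters": G.n_parameters(),
    }
    path_prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path_prefix: str | Path) -> tuple[Module, dict]:
    """Rebuild the generator from a checkpoint pair written by save_checkpoint."""
    path_prefix = Path(path_prefix)
    meta = json.loads(path_prefix.with_suffix(".json").read_text())
    spec_d = dict(meta["generator_spec"])
    for key in ("input_shape", "skip_block_indices", "decoder_channels",
                "output_shape"):
        spec_d[key] = tuple(spec_d[key])
    spec = GeneratorSpec(**spec_d)
    variant = meta["train_config"]["variant"]
    G = build_generator(spec, variant, seed=0)
    with np.load(path_prefix.with_suffix(".npz")) as data:
        arrays = [data[k] for k in sorted(data.files)]
    G.load_state_arrays(arrays)
    return G, meta
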