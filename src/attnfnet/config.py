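"""Experiment configuration: one serializable object binding data generation,
preprocessing, architecture, loss and training settings, plus the desk-scale
"tiny" preset used throughout the tests and examples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossConfig, SSIMParams
from .model import DiscriminatorSpec, GeneratorSpec
from .preprocessing import PreprocessConfig
from .training import TrainConfig

__all__ = ["DataConfig", "EvalConfig", "ExperimentConfig",
           "tiny_experiment_config", "default_experiment_config"]


@dataclass
class DataConfig:
    n_subjects: int = 40
    poses_per_subject: int = 3
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    grid_shape: tuple[int, int] = (128, 56)
    depth_noise_sd: float = 0.003
    depth_dropout_prob: float = 0.0
    pressure_noise_sd_frac: float = 0.02
    sensor_area_m2: float = (0.84 / 27) * (1.92 / 64)


@dataclass
class EvalConfig:
    ppa_tol_frac: float = 0.05
    iou_threshold_kpa: float = 1.0
    fid_features: int = 32
    fid_seed: int = 0


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


_TUPLE_FIELDS = {
    "split_fractions", "grid_shape", "input_shape", "skip_block_indices",
    "decoder_channels", "output_shape", "target_pressure_shape",
    "depth_clip", "depth_range", "pressure_range", "pad_to",
}


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name == "ssim":
            v = SSIMParams(**v)
        elif f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class ExperimentConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: GeneratorSpec = field(default_factory=GeneratorSpec)
    disc: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        return _to_plain(self)

    def config_hash(self) -> str:
        """Short content hash used to tag every output artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            seed=d.get("seed", 0),
            data=_from_dict(DataConfig, d.get("data", {})),
            preprocess=_from_dict(PreprocessConfig, d.get("preprocess", {})),
            model=_from_dict(GeneratorSpec, d.get("model", {})),
            disc=_from_dict(DiscriminatorSpec, d.get("disc", {})),
            loss=_from_dict(LossConfig, d.get("loss", {})),
            train=_from_dict(TrainConfig, d.get("train", {})),
            eval=_from_dict(EvalConfig, d.get("eval", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_experiment_config(seed: int = 0) -> ExperimentConfig:
    """Full-size architecture (712-d embedding, 12 blocks) configuration."""
    cfg = ExperimentConfig(seed=seed)
    cfg.train.seed = seed
    return cfg


def tiny_experiment_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale preset: minutes on one CPU, structure identical to default.

    8 subjects with 21 poses each (the real cohort offers 45 per subject),
    64x56 depth frames (8x7 patch grid), 64-d embedding with 4 heads, 6
    transformer blocks with skips from blocks 3/4/5, 5 epochs at learning
    rate 2e-4 with gradient-norm clipping at 10.
    """
    return ExperimentConfig(
        seed=seed,
        data=DataConfig(n_subjects=8, poses_per_subject=21,
                        grid_shape=(64, 56)),
        preprocess=PreprocessConfig(pad_to=(64, 56)),
        model=GeneratorSpec(input_shape=(64, 56), patch_size=8, embed_dim=64,
                            n_blocks=6, n_heads=4, skip_block_indices=(3, 4, 5),
                            decoder_channels=(64, 32, 16)),
        disc=DiscriminatorSpec(base_channels=32),
        train=TrainConfig(learning_rate=2e-4, epochs=5, seed=seed,
                          checkpoint_every=5),
    )
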