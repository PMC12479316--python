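"""Depth cleaning, pressure smoothing, normalization and kPa calibration.

Two data paths feed the models:

* depth: raw frames may contain no-return (sentinel) pixels; these are
  repaired by an iterated 3x3 valid-neighborhood median, then the frame is
  clipped and center-cropped / edge-padded to the model input size so the
  patch grid divides evenly.
* pressure: the ground-truth map is area-average resampled to the 27x64
  sensor grid and smoothed with a Gaussian filter (sigma 1.4, truncated at
  4 sigma, reflect boundary), then clamped nonnegative.

Min-max normalization statistics are computed on the training split only and
carry a provenance tag so a leak from val/test is detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import DEPTH_SENTINEL, PRESSURE_SHAPE

__all__ = [
    "PreprocessConfig", "NormStats", "clean_depth", "preprocess_pressure",
    "normalize", "denormalize", "compute_norm_stats", "calibrate_to_kpa",
    "crop_or_pad",
]


@dataclass
class PreprocessConfig:
    target_pressure_shape: tuple[int, int] = PRESSURE_SHAPE
    gaussian_sigma: float = 1.4
    gaussian_truncate: float = 4.0
    depth_clip: tuple[float, float] = (1.0, 2.2)     # meters
    depth_range: tuple[float, float] = (-1.0, 1.0)   # model units for depth
    # pressure targets sit strictly inside the sigmoid's output range so
    # neither the (dominant) zero background nor the peaks require the
    # activation to saturate
    pressure_range: tuple[float, float] = (0.05, 0.95)
    pad_to: tuple[int, int] = (128, 56)
    sentinel: float = DEPTH_SENTINEL

    def __post_init__(self):
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


@dataclass
class NormStats:
    """Min/max statistics with provenance; must come from the train split."""

    vmin: float
    vmax: float
    source: str = "train"

    def __post_init__(self):
        if self.vmax <= self.vmin:
            raise ValueError("vmax must exceed vmin (constant data cannot "
                             "be min-max normalized)")
        if self.source != "train":
            raise ValueError("normalization statistics must be computed on "
                             f"the train split, got source={self.source!r}")

    def to_dict(self) -> dict:
        return {"vmin": self.vmin, "vmax": self.vmax, "source": self.source}


def crop_or_pad(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Center-crop axes that are too large, edge-pad those too small."""
    out = img
    for ax, t in enumerate(target):
        n = out.shape[ax]
        if n > t:
            lo = (n - t) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(lo, lo + t)
            out = out[tuple(sl)]
        elif n < t:
            lo = (t - n) // 2
            spec = [(0, 0)] * out.ndim
            spec[ax] = (lo, t - n - lo)
            out = np.pad(out, spec, mode="edge")
    return out


def clean_depth(raw: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Repair no-return pixels, clip, and shape the frame for the model.

    Sentinel pixels are replaced by the median of their valid 3x3 neighbors,
    iterating until none remain (an all-sentinel frame is rejected).
    """
    raw = np.asarray(raw, dtype=np.float64)
    invalid = (raw == config.sentinel) | ~np.isfinite(raw)
    if invalid.all():
        raise ValueError("depth frame is entirely sentinel/no-return")
    img = raw.copy()
    while invalid.any():
        work = np.where(invalid, np.nan, img)
        padded = np.pad(work, 1, mode="constant", constant_values=np.nan)
        windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
        with np.errstate(all="ignore"):
            med = np.nanmedian(windows.reshape(*img.shape, 9), axis=-1)
        fillable = invalid & np.isfinite(med)
        if not fillable.any():  # isolated region fully surrounded by sentinels
            raise ValueError("sentinel region could not be repaired")
        img[fillable] = med[fillable]
        invalid = invalid & ~fillable
    img = np.clip(img, *config.depth_clip)
    return crop_or_pad(img, config.pad_to)


def _area_average_resample(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    from .synthetic import _area_average_matrix

    m0 = _area_average_matrix(img.shape[0], target[0])
    m1 = _area_average_matrix(img.shape[1], target[1])
    return m0 @ img @ m1.T


def preprocess_pressure(pressure: np.ndarray, config: PreprocessConfig
                        ) -> np.ndarray:
    """Smooth the pressure ground truth: resample to 27x64, Gaussian blur.

    Area-average resampling preserves the image mean exactly; the blur uses
    reflect boundary handling so a constant image passes through unchanged.
    """
    pressure = np.asarray(pressure, dtype=np.float64)
    if (pressure < 0).any():
        raise ValueError("pressure values must be nonnegative")
    out = _area_average_resample(pressure, config.target_pressure_shape)
    out = ndimage.gaussian_filter(out, sigma=config.gaussian_sigma,
                                  mode="reflect",
                                  truncate=config.gaussian_truncate)
    return np.maximum(out, 0.0)


def compute_norm_stats(images, source: str = "train") -> NormStats:
    """Min/max over a collection of arrays (train split only)."""
    vmin = min(float(np.min(im)) for im in images)
    vmax = max(float(np.max(im)) for im in images)
    return NormStats(vmin=vmin, vmax=vmax, source=source)


def normalize(img: np.ndarray, stats: NormStats,
              out_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    lo, hi = out_range
    return lo + (np.asarray(img, dtype=np.float64) - stats.vmin) \
        * (hi - lo) / (stats.vmax - stats.vmin)


def denormalize(img: np.ndarray, stats: NormStats,
                out_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    lo, hi = out_range
    return stats.vmin + (np.asarray(img, dtype=np.float64) - lo) \
        * (stats.vmax - stats.vmin) / (hi - lo)


def calibrate_to_kpa(pressure_raw: np.ndarray, calibration_kpa: float
                     ) -> np.ndarray:
    """Convert raw sensor counts to kPa with the per-subject scalar."""
    if calibration_kpa <= 0:
        raise ValueError("calibration_kpa must be positive")
    return np.asarray(pressure_raw, dtype=np.float64) * calibration_kpa
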