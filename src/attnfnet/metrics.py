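"""Evaluation metrics for predicted pressure maps.

Per-sample metrics: pixel prediction accuracy (PPA), SSIM, MSE (raw and
kPa^2), PSNR, posture IOU of the dominant high-pressure region, and body
weight estimated from the calibrated map.  Set-level: Frechet distance
between embedded real and generated map distributions, with a pluggable
embedding function (the default is a fixed seeded random projection, so the
metric runs offline; values are then internally consistent but not
comparable across embedders).  ``evaluate`` aggregates everything into a
:class:`MetricReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, ndimage

from .losses import SSIMParams, ssim
from .synthetic import GRAVITY, PairedSample

__all__ = [
    "ppa", "mse", "psnr", "posture_iou", "frechet_distance",
    "estimate_weight", "deviation_maps", "evaluate", "MetricReport",
    "random_projection_embedder",
]


def _check_shapes(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g.shape}")
    return y, g


def ppa(y, g, tol: float) -> float:
    """Fraction of pixels with ``|y - g| <= tol`` (pixel prediction accuracy)."""
    y, g = _check_shapes(y, g)
    if tol <= 0:
        raise ValueError("tol must be positive")
    return float(np.mean(np.abs(y - g) <= tol))


def mse(y, g) -> float:
    """Mean squared difference over all pixels."""
    y, g = _check_shapes(y, g)
    return float(np.mean((y - g) ** 2))


def psnr(y, g, max_val: float) -> float:
    """``10 log10(max_val^2 / MSE)`` in dB; +inf for identical images."""
    err = mse(y, g)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val ** 2 / err))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 4-connected component of a boolean mask (empty stays empty)."""
    if not mask.any():
        return mask
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def posture_iou(y, g, threshold: float) -> float:
    """IOU of the largest super-threshold pressure regions of y and g.

    Both maps are binarized at ``threshold`` and reduced to their largest
    4-connected component.  Both empty -> 1.0 (nothing to disagree about);
    exactly one empty -> 0.0.
    """
    y, g = _check_shapes(y, g)
    ay = _largest_component(y > threshold)
    ag = _largest_component(g > threshold)
    if not ay.any() and not ag.any():
        return 1.0
    union = np.logical_or(ay, ag).sum()
    inter = np.logical_and(ay, ag).sum()
    return float(inter / union)


def frechet_distance(real_set, gen_set, embed_fn) -> float:
    """Frechet distance between Gaussian fits of embedded image sets.

    ``||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})`` with a symmetrized
    matrix square root; requires at least two samples per set.
    """
    f1 = np.stack([np.asarray(embed_fn(x), dtype=np.float64) for x in real_set])
    f2 = np.stack([np.asarray(embed_fn(x), dtype=np.float64) for x in gen_set])
    if f1.shape[0] < 2 or f2.shape[0] < 2:
        raise ValueError("each set needs at least 2 samples")
    mu1, mu2 = f1.mean(axis=0), f2.mean(axis=0)
    s1 = np.atleast_2d(np.cov(f1, rowvar=False))
    s2 = np.atleast_2d(np.cov(f2, rowvar=False))
    covmean = linalg.sqrtm(s1 @ s2)
    if np.iscomplexobj(covmean):
        if np.abs(covmean.imag).max() > 1e-6:
            raise ValueError("matrix square root has a non-negligible "
                             "imaginary part; covariance product is too "
                             "far from PSD")
        covmean = covmean.real
    covmean = (covmean + covmean.T) / 2.0
    diff = mu1 - mu2
    fd = float(diff @ diff + np.trace(s1 + s2 - 2.0 * covmean))
    return max(fd, 0.0)


def random_projection_embedder(input_shape: tuple[int, int],
                               n_features: int = 32, seed: int = 0):
    """Fixed seeded Gaussian random-projection embedding (weight-free).

    A deterministic stand-in feature extractor for the Frechet distance;
    any pretrained embedder with the same ``image -> vector`` signature can
    be injected instead.
    """
    rng = np.random.default_rng(seed)
    dim = int(np.prod(input_shape))
    proj = rng.standard_normal((dim, n_features)) / np.sqrt(dim)

    def embed(img: np.ndarray) -> np.ndarray:
        flat = np.asarray(img, dtype=np.float64).reshape(-1)
        if flat.size != dim:
            raise ValueError(f"embedder expects shape {input_shape}")
        return flat @ proj

    return embed


def estimate_weight(pressure_kpa: np.ndarray, sensor_area_m2: float,
                    g: float = GRAVITY) -> float:
    """Body mass (kg) implied by a calibrated pressure map.

    Each sensel of area ``sensor_area_m2`` carries a normal force
    ``p_kPa * 1000 * area``; the total force divided by g is the mass.
    """
    p = np.asarray(pressure_kpa, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("pressure must be nonnegative")
    if sensor_area_m2 <= 0:
        raise ValueError("sensor_area_m2 must be positive")
    return float(p.sum() * 1000.0 * sensor_area_m2 / g)


def deviation_maps(pairs_by_posture: dict[str, list[tuple[np.ndarray, np.ndarray]]]
                   ) -> dict[str, np.ndarray]:
    """Pixelwise mean absolute deviation |y - g| per posture (kPa).

    Empty posture groups are omitted.  (Rendering convention: clip the
    displayed range to [0, 1.5] kPa; the returned arrays are unclipped.)
    """
    import warnings

    out = {}
    for posture, pairs in pairs_by_posture.items():
        if not pairs:
            warnings.warn(f"no samples for posture {posture!r}; omitted")
            continue
        devs = [np.abs(_check_shapes(y, g)[0] - np.asarray(g, dtype=np.float64))
                for y, g in pairs]
        out[posture] = np.mean(devs, axis=0)
    return out


@dataclass
class MetricReport:
    """Per-sample metric table plus test-set aggregates."""

    per_sample: pd.DataFrame
    aggregates: dict[str, float]
    notes: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"aggregates": self.aggregates, "notes": self.notes}


def evaluate(predict_fn, samples: list[PairedSample], sensor_area_m2: float,
             ppa_tol_frac: float = 0.05, iou_threshold_kpa: float = 1.0,
             fid_embedder=None, ssim_params: SSIMParams | None = None
             ) -> MetricReport:
    """Run ``predict_fn`` over test samples and compute the full metric suite.

    ``predict_fn`` maps a :class:`PairedSample` to a predicted pressure map
    in raw sensor units (same convention as the stored ground truth).  PPA
    uses an absolute tolerance of ``ppa_tol_frac`` times the per-sample
    ground-truth maximum; IOU thresholds calibrated maps at
    ``iou_threshold_kpa``.  PSNR uses the dynamic range of the calibrated
    ground-truth test set; infinite PSNR values (identical images) are
    excluded from the mean and counted in ``notes``.
    """
    if not samples:
        raise ValueError("no samples to evaluate")
    preds = [np.asarray(predict_fn(s), dtype=np.float64) for s in samples]
    y_kpa = [s.pressure_kpa for s in samples]
    g_kpa = [p * s.calibration_kpa for p, s in zip(preds, samples)]
    max_val = max(float(y.max()) for y in y_kpa)
    sp = ssim_params or SSIMParams(L=max_val)

    rows = []
    pairs_by_posture: dict[str, list] = {p: [] for p in set(s.posture for s in samples)}
    for i, s in enumerate(samples):
        y, g = y_kpa[i], g_kpa[i]
        tol = ppa_tol_frac * float(y.max())
        w_true = estimate_weight(y, sensor_area_m2)
        w_pred = estimate_weight(np.maximum(g, 0.0), sensor_area_m2)
        rows.append({
            "sample": i,
            "subject_id": s.subject_id,
            "posture": s.posture,
            "ppa": ppa(y, g, tol),
            "ssim": ssim(y, g, sp).item(),
            "mse_raw": mse(s.pressure, preds[i]),
            "mse_kpa2": mse(y, g),
            "psnr_db": psnr(y, g, max_val),
            "iou": posture_iou(y, g, iou_threshold_kpa),
            "weight_true_kg": w_true,
            "weight_pred_kg": w_pred,
            "weight_abs_err_kg": abs(w_pred - w_true),
        })
        pairs_by_posture[s.posture].append((y, g))
    table = pd.DataFrame(rows)

    embed = fid_embedder or random_projection_embedder(y_kpa[0].shape)
    if len(samples) >= 2:
        mfid = frechet_distance(y_kpa, g_kpa, embed)
    else:
        mfid = float("nan")

    finite_psnr = table["psnr_db"][np.isfinite(table["psnr_db"])]
    aggregates = {
        "MPPA": float(table["ppa"].mean()),
        "MSSIM": float(table["ssim"].mean()),
        "MFID": mfid,
        "MSE_raw": float(table["mse_raw"].mean()),
        "MSE_kpa2": float(table["mse_kpa2"].mean()),
        "MPSNR_db": float(finite_psnr.mean()) if len(finite_psnr) else float("inf"),
        "MIOU": float(table["iou"].mean()),
        "mean_abs_weight_diff_kg": float(table["weight_abs_err_kg"].mean()),
    }
    notes = {
        "n_samples": len(samples),
        "n_infinite_psnr_excluded": int(len(table) - len(finite_psnr)),
        "ppa_tol_frac": ppa_tol_frac,
        "iou_threshold_kpa": iou_threshold_kpa,
        "psnr_max_val_kpa": max_val,
    }
    return MetricReport(per_sample=table, aggregates=aggregates, notes=notes)
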