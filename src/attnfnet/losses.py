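"""Training objectives: SSIM, the mixed SSIM+L2 perceptual loss, and the
label-smoothed conditional-GAN discriminator/generator losses.

All functions accept plain ndarrays or autodiff Tensors and return a Tensor
(call ``.item()`` for the float), so the same code path serves both metric
evaluation and backpropagation.

The structural similarity index between images ``a`` and ``b`` is::

    SSIM(a, b) = (2 mu_a mu_b + C1)(2 sigma_ab + C2)
                 / ((mu_a^2 + mu_b^2 + C1)(sigma_a^2 + sigma_b^2 + C2))

with local moments taken under a Gaussian window (default 11x11, sigma 1.5,
reflect boundary) and C1 = (0.01 L)^2, C2 = (0.03 L)^2 for dynamic range L.

The generator is trained with ``-log D(x|G(x)) + lambda * L_SSIML2`` where
``L_SSIML2 = alpha (1 - SSIM(y, G(x))) + beta MSE(y, G(x))``; the pixel term
is the mean squared error so that the stated alpha=300 / beta=1 balance is
meaningful independently of image size.  The discriminator sees smoothed
targets (0.9 for real, 0.1 for generated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, as_tensor, conv2d

__all__ = ["SSIMParams", "LossConfig", "ssim", "ssiml2_loss",
           "discriminator_loss", "generator_loss", "gaussian_window"]

_EPS = 1e-7  # probability clamp for log stability


@dataclass
class SSIMParams:
    window_size: int = 11
    window_sigma: float = 1.5
    L: float = 1.0                       # dynamic range of the images
    C1: float | None = None              # default (0.01 L)^2
    C2: float | None = None              # default (0.03 L)^2

    def __post_init__(self):
        if self.window_size % 2 == 0 or self.window_size < 1:
            raise ValueError("window_size must be a positive odd integer")
        if self.window_sigma <= 0:
            raise ValueError("window_sigma must be positive")
        if self.C1 is None:
            self.C1 = (0.01 * self.L) ** 2
        if self.C2 is None:
            self.C2 = (0.03 * self.L) ** 2
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")


@dataclass
class LossConfig:
    lambda_adv: float = 100.0
    alpha: float = 300.0
    beta: float = 1.0
    y_real: float = 0.9
    y_gen: float = 0.1
    ssim: SSIMParams = field(default_factory=SSIMParams)

    def __post_init__(self):
        if min(self.lambda_adv, self.alpha, self.beta) < 0:
            raise ValueError("lambda, alpha, beta must be nonnegative")
        if not (0.0 <= self.y_gen < self.y_real <= 1.0):
            raise ValueError("labels must satisfy 0 <= y_gen < y_real <= 1")


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel."""
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k2 = np.outer(k1, k1)
    return k2 / k2.sum()


def _reflect_pad(x: Tensor, p: int) -> Tensor:
    """Reflect (mirror, no edge repeat) padding of the trailing two axes."""
    h, w = x.shape[-2], x.shape[-1]
    ih = np.concatenate([np.arange(p, 0, -1), np.arange(h),
                         np.arange(h - 2, h - 2 - p, -1)])
    iw = np.concatenate([np.arange(p, 0, -1), np.arange(w),
                         np.arange(w - 2, w - 2 - p, -1)])
    lead = (slice(None),) * (x.ndim - 2)
    return x[lead + (ih,)][lead + (slice(None), iw)]


def _as_nchw(img) -> Tensor:
    t = as_tensor(img)
    if t.ndim == 2:
        return t.reshape(1, 1, *t.shape)
    if t.ndim == 4:
        return t
    raise ValueError(f"expected 2-D or 4-D image, got shape {t.shape}")


def ssim(a, b, params: SSIMParams | None = None) -> Tensor:
    """Mean structural similarity over the image (differentiable).

    Local means, variances and the covariance are Gaussian-window averages
    (population form) with reflect boundary handling, so ``ssim(a, a) == 1``
    and constant image pairs reproduce the closed form
    ``(2pq + C1) / (p^2 + q^2 + C1)``.
    """
    params = params or SSIMParams()
    ta, tb = _as_nchw(a), _as_nchw(b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
    r = params.window_size // 2
    kern = Tensor(gaussian_window(params.window_size, params.window_sigma)
                  .reshape(1, 1, params.window_size, params.window_size))

    def wmean(t: Tensor) -> Tensor:
        return conv2d(_reflect_pad(t, r), kern)

    mu_a, mu_b = wmean(ta), wmean(tb)
    s_aa = wmean(ta * ta) - mu_a * mu_a
    s_bb = wmean(tb * tb) - mu_b * mu_b
    s_ab = wmean(ta * tb) - mu_a * mu_b
    c1, c2 = params.C1, params.C2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * s_ab + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (s_aa + s_bb + c2)
    return (num / den).mean()


def mse_term(y, g) -> Tensor:
    ty, tg = as_tensor(y), as_tensor(g)
    if ty.shape != tg.shape:
        raise ValueError(f"shape mismatch: {ty.shape} vs {tg.shape}")
    d = ty - tg
    return (d * d).mean()


def ssiml2_loss(y, g, cfg: LossConfig | None = None) -> Tensor:
    """alpha * (1 - SSIM(y, g)) + beta * MSE(y, g)."""
    cfg = cfg or LossConfig()
    return cfg.alpha * (1.0 - ssim(y, g, cfg.ssim)) + cfg.beta * mse_term(y, g)


def _check_prob(t: Tensor, name: str) -> Tensor:
    if np.isnan(t.data).any():
        raise ValueError(f"{name} contains NaN")
    if (t.data < 0).any() or (t.data > 1).any():
        raise ValueError(f"{name} must lie in [0, 1] before clamping")
    return t.clamp(_EPS, 1.0 - _EPS)


def discriminator_loss(d_real, d_fake, cfg: LossConfig | None = None) -> Tensor:
    """Label-smoothed binary cross-entropy over real and generated pairs.

    ``d_real``/``d_fake`` are discriminator probabilities (scalars or patch
    maps); terms are averaged over batch and patch positions.  Minimized at
    ``d_real = y_real``, ``d_fake = y_gen``.
    """
    cfg = cfg or LossConfig()
    dr = _check_prob(as_tensor(d_real), "d_real")
    df = _check_prob(as_tensor(d_fake), "d_fake")
    yr, yg = cfg.y_real, cfg.y_gen
    term_real = yr * dr.log() + (1.0 - yr) * (1.0 - dr).log()
    term_fake = yg * df.log() + (1.0 - yg) * (1.0 - df).log()
    return -(term_real.mean() + term_fake.mean())


def generator_loss(d_fake, y, g, cfg: LossConfig | None = None) -> Tensor:
    """Adversarial term plus lambda-weighted perceptual SSIM+L2 term."""
    cfg = cfg or LossConfig()
    df = _check_prob(as_tensor(d_fake), "d_fake")
    adv = -(df.log().mean())
    return adv + cfg.lambda_adv * ssiml2_loss(y, g, cfg)
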