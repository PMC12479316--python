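"""Generator and discriminator architectures.

The primary generator is a hybrid transformer/convolutional encoder-decoder
that translates a single-channel depth image into a 27x64 contact-pressure
map:

* **encoder** — the padded depth image is cut into patches by a strided
  convolution projecting each patch to a 712-dimensional embedding, fixed
  sinusoidal positional encodings are added, and the token grid passes
  through 12 transformer blocks.  Each block applies multi-head
  self-attention (single residual added after head concatenation and output
  projection) followed by a feed-forward stage in one of two variants: a
  token-wise MLP, or two 3x3 convolutions over the token grid laid out
  spatially (the convolutional variant, which preserves spatial hierarchy
  inside the block).
* **decoder** — the block-12 token grid is reshaped to its spatial layout
  and upsampled through transposed convolutions; the outputs of blocks 6, 8
  and 10 are carried across as skip connections (deepest block to the
  coarsest decoder stage), each resized to the stage resolution, projected
  by a 1x1 convolution and concatenated before the stage's deconvolution.
  A 1x1 head, bilinear resize and sigmoid produce the (27, 64) pressure map
  in [0, 1] model units.

The discriminator is a PatchGAN: the depth image is resized into the
pressure frame, concatenated with the (real or generated) pressure map, and
reduced by strided convolutions with leaky rectification to a grid of
per-patch real/fake logits.  A standard convolutional U-Net generator with
mirror skip connections is provided as a baseline under the same
input/output contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Adam, Conv2d, ConvTranspose2d, LayerNorm, Linear, Module,
                 Tensor, as_tensor, concat, resize_bilinear)

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "sinusoidal_positions",
    "MultiHeadSelfAttention", "TransformerBlock", "AttnFnetGenerator",
    "PatchGANDiscriminator", "build_discriminator", "UNetGenerator",
    "build_unet_baseline", "tokens_to_grid", "grid_to_tokens",
]


@dataclass
class GeneratorSpec:
    """Architecture hyperparameters of the transformer generator."""

    input_shape: tuple[int, int] = (128, 56)   # (length, width) after padding
    patch_size: int = 8
    embed_dim: int = 712
    n_blocks: int = 12
    n_heads: int = 8
    ff_variant: str = "conv"                   # "conv" or "mlp"
    skip_block_indices: tuple[int, ...] = (6, 8, 10)
    decoder_channels: tuple[int, ...] = (128, 64, 32)
    output_shape: tuple[int, int] = (27, 64)   # (width, length) sensor grid
    output_activation: str = "sigmoid"
    mlp_ratio: int = 2

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.input_shape[0] % self.patch_size or \
           self.input_shape[1] % self.patch_size:
            raise ValueError("input_shape must be divisible by patch_size "
                             "(pad the depth image first)")
        if self.ff_variant not in ("conv", "mlp"):
            raise ValueError(f"unknown ff_variant {self.ff_variant!r}")
        if not all(1 <= i <= self.n_blocks for i in self.skip_block_indices):
            raise ValueError("skip_block_indices must lie in [1, n_blocks]")
        if len(self.decoder_channels) != len(self.skip_block_indices):
            raise ValueError("need one decoder stage per skip connection")
        if self.output_activation != "sigmoid":
            raise ValueError("only sigmoid output activation is supported")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.input_shape[0] // self.patch_size,
                self.input_shape[1] // self.patch_size)

    @property
    def n_tokens(self) -> int:
        h, w = self.grid_shape
        return h * w

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class DiscriminatorSpec:
    n_layers: int = 3
    base_channels: int = 64
    kernel: int = 4
    input_shape: tuple[int, int] = (27, 64)

    @property
    def receptive_field(self) -> int:
        """Analytic receptive field of one output logit (square side)."""
        rf = 1
        rf = (rf - 1) * 1 + 3  # final stride-1 3x3 conv
        for _ in range(self.n_layers):
            rf = (rf - 1) * 2 + self.kernel
        return rf


def sinusoidal_positions(grid_shape: tuple[int, int], d: int) -> np.ndarray:
    """Fixed sin/cos positional encoding of the flattened token index.

    Channel 2i carries ``sin(pos / 10000^(2i/d))`` and channel 2i+1 the
    matching cosine, so position 0 maps to (0, 1, 0, 1, ...).
    """
    if d % 2:
        raise ValueError("embedding dimension must be even")
    n = grid_shape[0] * grid_shape[1]
    pos = np.arange(n)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.zeros((n, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def tokens_to_grid(tokens: Tensor, grid_shape: tuple[int, int]) -> Tensor:
    """(n, d) token array -> (1, d, h_p, w_p) spatial layout (row-major)."""
    n, d = tokens.shape
    h, w = grid_shape
    if n != h * w:
        raise ValueError(f"token count {n} does not match grid {grid_shape}")
    return tokens.reshape(h, w, d).transpose(2, 0, 1).reshape(1, d, h, w)


def grid_to_tokens(grid: Tensor) -> Tensor:
    """(1, d, h_p, w_p) -> (n, d)."""
    _, d, h, w = grid.shape
    return grid.reshape(d, h * w).transpose(1, 0)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over a token grid.

    Per head ``softmax(Q K^T / sqrt(d_k)) V``; heads are concatenated and
    linearly projected, and a single residual of the input is added to that
    projected output.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("d must be divisible by n_heads")
        self.d = d
        self.n_heads = n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def core(self, x: Tensor) -> Tensor:
        """Attention output before the residual addition."""
        if np.isnan(x.data).any():
            raise ValueError("attention input contains NaN")
        n, d = x.shape
        h, dk = self.n_heads, self.d // self.n_heads

        def split(t: Tensor) -> Tensor:  # (n, d) -> (h, n, dk)
            return t.reshape(n, h, dk).transpose(1, 0, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dk))
        attn = scores.softmax(axis=-1)
        heads = attn @ v                                   # (h, n, dk)
        merged = heads.transpose(1, 0, 2).reshape(n, d)    # concat heads
        return self.wo(merged)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.core(x)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """(h, n, n) softmax attention maps (no gradient), for inspection."""
        n, d = x.shape
        h, dk = self.n_heads, self.d // self.n_heads
        q = self.wq(x).data.reshape(n, h, dk).transpose(1, 0, 2)
        k = self.wk(x).data.reshape(n, h, dk).transpose(1, 0, 2)
        s = q @ k.transpose(0, 2, 1) / np.sqrt(dk)
        s = s - s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=-1, keepdims=True)


class _ConvFF(Module):
    """Feed-forward as two 3x3 convolutions over the spatial token grid."""

    def __init__(self, d: int, grid_shape: tuple[int, int],
                 rng: np.random.Generator):
        self.grid_shape = grid_shape
        self.c1 = Conv2d(d, d, 3, rng, padding=1)
        self.c2 = Conv2d(d, d, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        g = tokens_to_grid(x, self.grid_shape)
        g = self.c2(self.c1(g).gelu())
        return grid_to_tokens(g)


class _MlpFF(Module):
    """Token-wise two-layer perceptron feed-forward."""

    def __init__(self, d: int, ratio: int, rng: np.random.Generator):
        self.f1 = Linear(d, d * ratio, rng)
        self.f2 = Linear(d * ratio, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.f2(self.f1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm block: attention with residual, then feed-forward with residual.

    ``variant='mlp'`` uses the token-wise perceptron; ``variant='conv'``
    reshapes tokens to their spatial grid and applies two 3x3 convolutions,
    so the feed-forward stage itself has a local receptive field.  Output
    shape always equals input shape.
    """

    def __init__(self, d: int, n_heads: int, grid_shape: tuple[int, int],
                 variant: str, rng: np.random.Generator, mlp_ratio: int = 2):
        if variant not in ("conv", "mlp"):
            raise ValueError(f"unknown ff variant {variant!r}")
        self.grid_shape = grid_shape
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.ff = (_ConvFF(d, grid_shape, rng) if variant == "conv"
                   else _MlpFF(d, mlp_ratio, rng))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[0] != self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError(f"token count {x.shape[0]} inconsistent with "
                             f"grid {self.grid_shape}")
        h = x + self.attn.core(self.ln1(x))
        return h + self.ff(self.ln2(h))


class AttnFnetGenerator(Module):
    """Transformer encoder + skip-fed deconvolution decoder generator."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        d = spec.embed_dim
        hp, wp = spec.grid_shape
        self.patch_proj = Conv2d(1, d, spec.patch_size, rng,
                                 stride=spec.patch_size)
        self.pos = sinusoidal_positions(spec.grid_shape, d)
        self.blocks = [TransformerBlock(d, spec.n_heads, spec.grid_shape,
                                        spec.ff_variant, rng, spec.mlp_ratio)
                       for _ in range(spec.n_blocks)]
        # decoder: deepest skip feeds the coarsest stage
        self.skip_order = tuple(sorted(spec.skip_block_indices, reverse=True))
        chans = spec.decoder_channels
        self.skip_projs = [Conv2d(d, max(ch // 2, 4), 1, rng) for ch in chans]
        self.stages = []
        c_in = d
        self.stage_strides = tuple(2 if i < len(chans) - 1 else 1
                                   for i in range(len(chans)))
        for i, c_out in enumerate(chans):
            c_cat = c_in + max(c_out // 2, 4)
            if self.stage_strides[i] == 2:
                self.stages.append(ConvTranspose2d(c_cat, c_out, 4, rng,
                                                   stride=2, padding=1))
            else:
                self.stages.append(ConvTranspose2d(c_cat, c_out, 3, rng,
                                                   stride=1, padding=1))
            c_in = c_out
        self.head = Conv2d(c_in, 1, 1, rng)
        # pressure maps are mostly background: start the sigmoid near the
        # background level (prior init) instead of 0.5 so early training
        # does not have to drive every pixel down through saturation
        self.head.b.data = np.full(1, -3.0)

    # -- encoder -----------------------------------------------------------
    def patch_embed(self, image: Tensor) -> Tensor:
        """Strided-convolution patch projection -> (n_tokens, d) tokens."""
        image = as_tensor(image)
        if image.ndim == 2:
            image = image.reshape(1, 1, *image.shape)
        if image.shape[-2:] != tuple(self.spec.input_shape):
            raise ValueError(f"input shape {image.shape[-2:]} does not match "
                             f"spec {self.spec.input_shape}")
        return grid_to_tokens(self.patch_proj(image))

    def encode(self, image) -> tuple[Tensor, dict[int, Tensor]]:
        """Run the encoder; return the final latent and the skip token grids."""
        x = self.patch_embed(image) + Tensor(self.pos)
        skips: dict[int, Tensor] = {}
        for i, block in enumerate(self.blocks, start=1):
            x = block(x)
            if i in self.spec.skip_block_indices:
                skips[i] = x
        return x, skips

    # -- decoder -----------------------------------------------------------
    def decode(self, latent: Tensor, skips: dict[int, Tensor]) -> Tensor:
        """Upsample the latent grid, concatenating projected skips per stage."""
        if set(skips) != set(self.spec.skip_block_indices):
            raise ValueError(f"expected skips {self.spec.skip_block_indices}, "
                             f"got {tuple(skips)}")
        hp, wp = self.spec.grid_shape
        x = tokens_to_grid(latent, (hp, wp))
        for stage_i, (block_i, proj, deconv) in enumerate(
                zip(self.skip_order, self.skip_projs, self.stages)):
            skip = tokens_to_grid(skips[block_i], (hp, wp))
            skip = proj(skip)
            if skip.shape[-2:] != x.shape[-2:]:
                skip = resize_bilinear(skip, x.shape[-2:])
            if x.shape[-2:] != skip.shape[-2:]:
                raise ValueError(f"decoder stage {stage_i}: resolution "
                                 f"mismatch {x.shape} vs {skip.shape}")
            x = deconv(concat([x, skip], axis=1)).relu()
        x = self.head(x)
        # depth frame (length, width) -> sensor frame (width, length)
        w_out, l_out = self.spec.output_shape
        x = resize_bilinear(x, (l_out, w_out))
        return x.reshape(l_out, w_out).transpose(1, 0).sigmoid()

    def forward(self, image) -> Tensor:
        latent, skips = self.encode(image)
        return self.decode(latent, skips)


class PatchGANDiscriminator(Module):
    """Patch-level conditional real/fake classifier.

    The depth image is mapped into the pressure frame (transpose + bilinear
    resize) and concatenated channel-wise with the pressure map; a stack of
    stride-2 convolutions with leaky rectification emits a 2-D grid of
    patch logits.  The scalar ``D(x|y)`` used in the losses is the mean
    sigmoid of this map.
    """

    def __init__(self, spec: DiscriminatorSpec | None = None, seed: int = 0):
        self.spec = spec or DiscriminatorSpec()
        rng = np.random.default_rng(seed)
        layers = []
        c_in = 2
        ch = self.spec.base_channels
        for _ in range(self.spec.n_layers):
            layers.append(Conv2d(c_in, ch, self.spec.kernel, rng,
                                 stride=2, padding=1))
            c_in, ch = ch, min(ch * 2, 512)
        self.convs = layers
        self.final = Conv2d(c_in, 1, 3, rng, padding=1)

    def _align(self, depth, pressure) -> Tensor:
        d = as_tensor(depth)
        p = as_tensor(pressure)
        if d.ndim == 4:
            d = d.reshape(d.shape[-2], d.shape[-1])
        if d.ndim != 2 or p.ndim != 2:
            raise ValueError("depth and pressure must be 2-D images")
        if p.shape != tuple(self.spec.input_shape):
            raise ValueError(f"pressure shape {p.shape} does not match "
                             f"discriminator input {self.spec.input_shape}")
        d = d.transpose(1, 0)  # depth (length,width) -> (width,length)
        d = resize_bilinear(d.reshape(1, 1, *d.shape), p.shape)
        p = p.reshape(1, 1, *p.shape)
        return concat([d, p], axis=1)

    def forward(self, depth, pressure) -> Tensor:
        """Return the (1, 1, N, M) patch logit map for a (depth, pressure) pair."""
        x = self._align(depth, pressure)
        for conv in self.convs:
            x = conv(x).leaky_relu(0.2)
        return self.final(x)

    def probability_map(self, depth, pressure) -> Tensor:
        return self.forward(depth, pressure).sigmoid()

    def scalar_probability(self, depth, pressure) -> Tensor:
        """Mean per-patch sigmoid probability (the scalar D(x|y))."""
        return self.probability_map(depth, pressure).mean()


def build_discriminator(spec: DiscriminatorSpec | None = None,
                        seed: int = 0) -> PatchGANDiscriminator:
    return PatchGANDiscriminator(spec, seed)


class UNetGenerator(Module):
    """Convolutional encoder-decoder baseline with mirror skip connections.

    Same contract as the transformer generator: depth image in the padded
    input frame -> (27, 64) pressure map in [0, 1] model units.
    """

    def __init__(self, input_shape: tuple[int, int] = (128, 56),
                 output_shape: tuple[int, int] = (27, 64),
                 base_channels: int = 32, depth: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        if input_shape[0] % (2 ** depth) or input_shape[1] % (2 ** depth):
            raise ValueError("input_shape must be divisible by 2**depth")
        self.input_shape = tuple(input_shape)
        self.output_shape = tuple(output_shape)
        self.downs = []
        c_in, ch = 1, base_channels
        for _ in range(depth):
            self.downs.append(Conv2d(c_in, ch, 4, rng, stride=2, padding=1))
            c_in, ch = ch, ch * 2
        self.ups = []
        enc_channels = [base_channels * 2 ** i for i in range(depth)]
        c = enc_channels[-1]
        for i in reversed(range(depth)):
            c_skip = enc_channels[i]
            c_out = max(c_skip // 2, base_channels // 2)
            cat = c + (c_skip if i < depth - 1 else 0)
            self.ups.append(ConvTranspose2d(cat, c_out, 4, rng,
                                            stride=2, padding=1))
            c = c_out
        self.head = Conv2d(c, 1, 1, rng)
        self.head.b.data = np.full(1, -3.0)   # background-prior init

    def forward(self, image) -> Tensor:
        x = as_tensor(image)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        if x.shape[-2:] != self.input_shape:
            raise ValueError(f"input shape {x.shape[-2:]} != {self.input_shape}")
        feats = []
        for down in self.downs:
            x = down(x).leaky_relu(0.2)
            feats.append(x)
        for i, up in enumerate(self.ups):
            if i > 0:
                x = concat([x, feats[len(self.downs) - 1 - i]], axis=1)
            x = up(x).relu()
        x = self.head(x)
        w_out, l_out = self.output_shape
        x = resize_bilinear(x, (l_out, w_out))
        return x.reshape(l_out, w_out).transpose(1, 0).sigmoid()


def build_unet_baseline(input_shape: tuple[int, int] = (128, 56),
                        output_shape: tuple[int, int] = (27, 64),
                        base_channels: int = 32, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(input_shape, output_shape, base_channels, seed=seed)
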