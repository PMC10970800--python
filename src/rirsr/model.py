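"""The residual-in-residual super-resolution network.

Architecture
------------
A single 3x3 convolution extracts shallow features (1 -> f channels)
from the LR image.  The trunk is a residual-in-residual stack: ``n_groups``
residual groups, each a chain of ``n_blocks_per_group`` residual blocks
whose outputs — together with the group input — are concatenated and
fused by a 1x1 convolution (dense feature fusion).  The group outputs
are themselves concatenated and fused by a final 1x1 convolution, and a
long skip connection adds the shallow features so the deep path only has
to model high-frequency residuals.  A sub-pixel upscaler (3x3 conv to
``scale**2 * f`` channels, pixel shuffle, final 3x3 conv to 1 channel)
produces the HR image.

Each residual block processes its input with three parallel same-padded
convolutions (1x1, 3x3, 5x5, inception style), each followed by a
LeakyReLU.  The branches are either concatenated and fused by a 1x1
convolution (default) or summed (the "no concatenation" ablation); an
optional squeeze-excitation channel-attention gate and an optional
additive skip from the block input follow, then a final LeakyReLU.

There is no batch normalization anywhere: the network is trained and
evaluated with identical arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import ChannelAttention, Conv2d, LeakyReLU, Parameter, pixel_shuffle

__all__ = [
    "ModelConfig",
    "ResidualBlock",
    "ResidualGroup",
    "RIRNetwork",
    "count_parameters",
]

_VALID_SCALES = (2, 4, 8)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters, including the ablation flags.

    The reference configuration is 4 residual groups of 4 residual
    blocks with 64 filters; the proposed variant keeps concatenation
    fusion and block skip connections but disables channel attention.
    """

    n_groups: int = 4
    n_blocks_per_group: int = 4
    n_filters: int = 64
    scale: int = 4
    leaky_slope: float = 0.2
    use_channel_attention: bool = False
    use_concat_fusion: bool = True
    use_skip: bool = True
    ca_reduction: int = 16
    upsampler: str = "single"  # "single": one f -> scale^2*f stage; "cascade": x2 stages
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"scale={self.scale}: must be one of {_VALID_SCALES}")
        if self.n_groups < 1 or self.n_blocks_per_group < 1 or self.n_filters < 1:
            raise ValueError("n_groups, n_blocks_per_group, n_filters must be >= 1")
        if self.use_channel_attention and self.n_filters % self.ca_reduction:
            raise ValueError(
                f"n_filters={self.n_filters} not divisible by "
                f"ca_reduction={self.ca_reduction}"
            )
        if self.upsampler not in ("single", "cascade"):
            raise ValueError("upsampler must be 'single' or 'cascade'")


class ResidualBlock:
    """Inception-style residual block: parallel 1x1/3x3/5x5 branches."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 name: str = "rb", dtype=np.float32):
        f, s = cfg.n_filters, cfg.leaky_slope
        self.cfg = cfg
        self.conv1 = Conv2d(f, f, 1, rng, f"{name}.conv1", s, dtype)
        self.conv3 = Conv2d(f, f, 3, rng, f"{name}.conv3", s, dtype)
        self.conv5 = Conv2d(f, f, 5, rng, f"{name}.conv5", s, dtype)
        self.act1 = LeakyReLU(s)
        self.act3 = LeakyReLU(s)
        self.act5 = LeakyReLU(s)
        self.fuse = (
            Conv2d(3 * f, f, 1, rng, f"{name}.fuse", s, dtype,
                   activation="linear")
            if cfg.use_concat_fusion
            else None
        )
        self.ca = (
            ChannelAttention(f, cfg.ca_reduction, rng, f"{name}.ca", s, dtype)
            if cfg.use_channel_attention
            else None
        )
        self.act_out = LeakyReLU(s)

    def params(self) -> list[Parameter]:
        out = self.conv1.params() + self.conv3.params() + self.conv5.params()
        if self.fuse is not None:
            out += self.fuse.params()
        if self.ca is not None:
            out += self.ca.params()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.cfg.n_filters:
            raise ValueError(
                f"residual block expects {self.cfg.n_filters} channels, "
                f"got {x.shape[-1]}"
            )
        t1 = self.act1.forward(self.conv1.forward(x, train), train)
        t3 = self.act3.forward(self.conv3.forward(x, train), train)
        t5 = self.act5.forward(self.conv5.forward(x, train), train)
        if self.fuse is not None:
            merged = self.fuse.forward(np.concatenate([t1, t3, t5], axis=-1), train)
        else:
            merged = t1 + t3 + t5
        if self.ca is not None:
            merged = self.ca.forward(merged, train)
        pre = merged + x if self.cfg.use_skip else merged
        return self.act_out.forward(pre, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.act_out.backward(g)
        gx_skip = g if self.cfg.use_skip else 0.0
        if self.ca is not None:
            g = self.ca.backward(g)
        f = self.cfg.n_filters
        if self.fuse is not None:
            gcat = self.fuse.backward(g)
            g1, g3, g5 = gcat[..., :f], gcat[..., f : 2 * f], gcat[..., 2 * f :]
        else:
            g1 = g3 = g5 = g
        gx = self.conv1.backward(self.act1.backward(g1))
        gx = gx + self.conv3.backward(self.act3.backward(g3))
        gx = gx + self.conv5.backward(self.act5.backward(g5))
        return gx + gx_skip


class ResidualGroup:
    """Chain of residual blocks with dense feature fusion.

    The outputs of every block plus the group input are concatenated
    (``(n_blocks + 1) * f`` channels) and fused to ``f`` channels by a
    1x1 convolution.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 name: str = "rg", dtype=np.float32):
        f = cfg.n_filters
        self.cfg = cfg
        self.blocks = [
            ResidualBlock(cfg, rng, f"{name}.rb{i}", dtype)
            for i in range(cfg.n_blocks_per_group)
        ]
        self.fuse = Conv2d(
            (cfg.n_blocks_per_group + 1) * f, f, 1, rng, f"{name}.fuse",
            cfg.leaky_slope, dtype, activation="linear",
        )

    def params(self) -> list[Parameter]:
        out = []
        for b in self.blocks:
            out += b.params()
        return out + self.fuse.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = []
        h = x
        for b in self.blocks:
            h = b.forward(h, train)
            outs.append(h)
        return self.fuse.forward(np.concatenate(outs + [x], axis=-1), train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        f = self.cfg.n_filters
        gcat = self.fuse.backward(g)
        nb = len(self.blocks)
        gouts = [gcat[..., i * f : (i + 1) * f] for i in range(nb)]
        gx_direct = gcat[..., nb * f :]
        # Walk the chain in reverse, accumulating the gradient flowing
        # into each block's output from both the fusion concat and the
        # next block's input.
        gflow = gouts[-1]
        for i in range(nb - 1, 0, -1):
            gflow = self.blocks[i].backward(gflow) + gouts[i - 1]
        return self.blocks[0].backward(gflow) + gx_direct


class RIRNetwork:
    """Full super-resolution network: shallow conv, RIR trunk, upscaler."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        rng = np.random.default_rng(cfg.seed)
        f, s = cfg.n_filters, cfg.leaky_slope
        self.cfg = cfg
        self.dtype = dtype
        self.shallow = Conv2d(1, f, 3, rng, "shallow", s, dtype,
                              activation="linear")
        self.groups = [
            ResidualGroup(cfg, rng, f"rg{i}", dtype) for i in range(cfg.n_groups)
        ]
        self.trunk_fuse = Conv2d(cfg.n_groups * f, f, 1, rng, "trunk_fuse", s,
                                 dtype, activation="linear")
        # Zero-init the trunk fusion: the deep residual branch starts as
        # a no-op, so at initialization the network is exactly the
        # linear shallow -> long-skip -> upscaler path and the trunk is
        # grown in by training (residual-branch zero initialization).
        self.trunk_fuse.W.value[...] = 0.0
        if cfg.upsampler == "single":
            self.up_convs = [
                Conv2d(f, cfg.scale**2 * f, 3, rng, "up0", s, dtype,
                       activation="linear")
            ]
            self.up_factors = [cfg.scale]
        else:
            n_stages = int(math.log2(cfg.scale))
            self.up_convs = [
                Conv2d(f, 4 * f, 3, rng, f"up{i}", s, dtype,
                       activation="linear")
                for i in range(n_stages)
            ]
            self.up_factors = [2] * n_stages
        # ICNR: initialize each pre-shuffle convolution so all scale^2
        # sub-pixel positions share one filter, i.e. the upscaler starts
        # as nearest-neighbour upsampling of the feature maps (the
        # standard sub-pixel initialization; avoids checkerboard
        # artifacts and the slow learn-to-upsample transient).
        for conv, r in zip(self.up_convs, self.up_factors):
            w = conv.W.value  # (k, k, f, r*r*f)
            base = w[:, :, :, : w.shape[3] // (r * r)]
            conv.W.value = np.tile(base, (1, 1, 1, r * r)).copy()
        self.final = Conv2d(f, 1, 3, rng, "final", s, dtype,
                            activation="linear")

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Parameter]:
        out = self.shallow.params()
        for g in self.groups:
            out += g.params()
        out += self.trunk_fuse.params()
        for c in self.up_convs:
            out += c.params()
        return out + self.final.params()

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"checkpoint missing parameter {p.name!r}")
            arr = np.asarray(state[p.name], dtype=p.value.dtype)
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"parameter {p.name!r} shape {arr.shape} does not match "
                    f"model shape {p.value.shape}"
                )
            p.value = arr
            p.grad = np.zeros_like(arr)

    def cast(self, dtype) -> "RIRNetwork":
        """Return self with every parameter converted to ``dtype``."""
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        self.dtype = dtype
        return self

    # -- forward / backward -------------------------------------------------

    def shallow_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[-1] != 1:
            raise ValueError("expected a single-channel (N, H, W, 1) input")
        return self.shallow.forward(x, train)

    def trunk(self, sf: np.ndarray, train: bool = False) -> np.ndarray:
        """Deep-feature trunk: groups, dense fusion, long skip add."""
        outs = []
        h = sf
        for grp in self.groups:
            h = grp.forward(h, train)
            outs.append(h)
        fused = self.trunk_fuse.forward(np.concatenate(outs, axis=-1), train)
        return fused + sf  # long skip connection

    def upscale(self, feat: np.ndarray, train: bool = False) -> np.ndarray:
        h = feat
        for conv, r in zip(self.up_convs, self.up_factors):
            h = pixel_shuffle(conv.forward(h, train), r)
        return self.final.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map an ``(N, H, W, 1)`` LR batch to ``(N, sH, sW, 1)``.

        Operates on whatever intensity scale the caller provides; no
        clipping is applied here (see :meth:`predict_image` for the
        8-bit inference path).
        """
        sf = self.shallow_features(x, train)
        feat = self.trunk(sf, train)
        return self.upscale(feat, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.final.backward(g)
        for conv, r in zip(reversed(self.up_convs), reversed(self.up_factors)):
            g = conv.backward(_unshuffle_grad(g, r))
        gsf_lsc = g  # long skip: gradient into shallow features
        f = self.cfg.n_filters
        gcat = self.trunk_fuse.backward(g)
        gouts = [gcat[..., i * f : (i + 1) * f] for i in range(len(self.groups))]
        gflow = gouts[-1]
        for i in range(len(self.groups) - 1, 0, -1):
            gflow = self.groups[i].backward(gflow) + gouts[i - 1]
        gsf = self.groups[0].backward(gflow) + gsf_lsc
        return self.shallow.backward(gsf)

    # -- inference convenience ----------------------------------------------

    def predict_image(self, lr: np.ndarray) -> np.ndarray:
        """Super-resolve one [0, 255] grayscale image.

        The image is scaled to [0, 1] for the network and the output is
        rescaled and clipped back to the 8-bit range.
        """
        lr = np.asarray(lr, dtype=np.float64)
        x = (lr / 255.0).astype(self.dtype)[None, :, :, None]
        out = self.forward(x, train=False)[0, :, :, 0]
        return np.clip(out.astype(np.float64) * 255.0, 0.0, 255.0)


def _unshuffle_grad(g: np.ndarray, r: int) -> np.ndarray:
    """Gradient of pixel_shuffle: inverse rearrangement of ``g``."""
    n, hr, wr, c = g.shape
    h, w = hr // r, wr // r
    g = g.reshape(n, h, r, w, r, c)
    g = g.transpose(0, 1, 3, 2, 4, 5)
    return g.reshape(n, h, w, r * r * c)


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form parameter count for a configuration.

    Enumerates every weight/bias tensor shape implied by the
    architecture; equals ``RIRNetwork(cfg).n_parameters``.
    """
    f = cfg.n_filters
    nb, ng = cfg.n_blocks_per_group, cfg.n_groups

    def conv(c_in: int, c_out: int, k: int) -> int:
        return (k * k * c_in + 1) * c_out

    block = conv(f, f, 1) + conv(f, f, 3) + conv(f, f, 5)
    if cfg.use_concat_fusion:
        block += conv(3 * f, f, 1)
    if cfg.use_channel_attention:
        mid = f // cfg.ca_reduction
        block += f * mid + mid + mid * f + f  # two dense layers with biases
    group = nb * block + conv((nb + 1) * f, f, 1)
    total = conv(1, f, 3)  # shallow
    total += ng * group
    total += conv(ng * f, f, 1)  # trunk fusion
    if cfg.upsampler == "single":
        total += conv(f, cfg.scale**2 * f, 3)
    else:
        total += int(math.log2(cfg.scale)) * conv(f, 4 * f, 3)
    total += conv(f, 1, 3)  # final reconstruction conv
    return total
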