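"""HR -> LR forward model: bicubic downsampling and impulse noise.

The degradation pipeline mirrors the convention of the classical
``imresize`` routine: separable resampling with the Keys cubic kernel
(a = -0.5), and — when shrinking with antialiasing enabled — kernel
support widened by the inverse scale so the cubic acts as a low-pass
filter.  Salt-and-pepper corruption is applied after downsampling, to
the LR image only; HR ground truth always stays clean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DegradationSpec",
    "PatchPair",
    "bicubic_resize",
    "add_salt_pepper",
    "make_lr",
    "extract_patch_pairs",
]

_VALID_SCALES = (2, 4, 8)

#: Default cap on extracted patch pairs (seeded uniform subsample of the
#: stride-1 enumeration when the candidate count exceeds it).
DEFAULT_MAX_PAIRS = 102_400


@dataclass(frozen=True)
class DegradationSpec:
    """Forward-model parameters: scale factor, noise density, seed.

    ``scale`` is the integer super-resolution factor alpha in {2, 4, 8}
    (powers of two); ``noise_density`` is the fraction of pixels hit by
    salt-and-pepper corruption (0, 0.005, 0.01 and 0.02 are the studied
    levels); ``antialias`` widens the cubic kernel on shrink.
    """

    scale: int
    noise_density: float = 0.0
    seed: int = 0
    antialias: bool = True

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValueError(
                f"scale={self.scale}: must be one of {_VALID_SCALES} (powers of two)"
            )
        if not 0.0 <= self.noise_density <= 1.0:
            raise ValueError(
                f"noise_density={self.noise_density}: must lie in [0, 1]"
            )


@dataclass(frozen=True)
class PatchPair:
    """An aligned LR/HR training patch pair.

    ``origin`` is the (row, col) of the HR patch's top-left corner in the
    HR image; the LR patch starts at ``origin / scale`` exactly.
    """

    lr_patch: np.ndarray
    hr_patch: np.ndarray
    origin: tuple[int, int]

    @property
    def scale(self) -> int:
        return self.hr_patch.shape[0] // self.lr_patch.shape[0]


def _cubic(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic interpolation kernel with parameter ``a``."""
    ax = np.abs(x)
    ax2 = ax * ax
    ax3 = ax2 * ax
    out = np.where(
        ax <= 1,
        (a + 2) * ax3 - (a + 3) * ax2 + 1,
        np.where(ax < 2, a * ax3 - 5 * a * ax2 + 8 * a * ax - 4 * a, 0.0),
    )
    return out


def _reflect_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Map out-of-range sample indices into [0, n) by symmetric reflection."""
    period = 2 * n
    m = np.mod(idx, period)
    return np.where(m >= n, period - 1 - m, m)


def _resize_matrix(in_len: int, out_len: int, scale: float, antialias: bool) -> np.ndarray:
    """Dense (out_len, in_len) row-resampling operator for one axis.

    Output sample ``i`` is centred at ``(i + 0.5)/scale - 0.5`` in input
    coordinates; weights come from the cubic kernel, widened by
    ``1/scale`` when shrinking with antialias, and are normalized to sum
    to one.  Out-of-range taps are reflected symmetrically.
    """
    kscale = scale if (antialias and scale < 1.0) else 1.0
    kwidth = 4.0 / kscale
    u = (np.arange(out_len) + 0.5) / scale - 0.5
    left = np.floor(u - kwidth / 2).astype(int)
    n_taps = int(np.ceil(kwidth)) + 2
    taps = left[:, None] + np.arange(n_taps)[None, :]
    w = kscale * _cubic(kscale * (u[:, None] - taps))
    w /= w.sum(axis=1, keepdims=True)
    taps = _reflect_indices(taps, in_len)
    mat = np.zeros((out_len, in_len))
    np.add.at(mat, (np.repeat(np.arange(out_len), n_taps), taps.ravel()), w.ravel())
    return mat


def bicubic_resize(
    img: np.ndarray, scale_factor: float, antialias: bool = True
) -> np.ndarray:
    """Separable cubic resampling of a [0, 255] grayscale image.

    Matches the behavior of the classical ``imresize`` bicubic mode:
    Keys kernel a = -0.5, antialiased (widened) kernel on shrink, output
    size ``round(input * scale_factor)``, result clipped to [0, 255].
    ``scale_factor`` of exactly 1 is the identity.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("bicubic_resize expects a 2-D grayscale image")
    if scale_factor <= 0:
        raise ValueError(f"scale_factor={scale_factor}: must be positive")
    h, w = img.shape
    out_h = max(int(round(h * scale_factor)), 1)
    out_w = max(int(round(w * scale_factor)), 1)
    if out_h == h and out_w == w and scale_factor == 1.0:
        return img.copy()
    mr = _resize_matrix(h, out_h, scale_factor, antialias)
    mc = _resize_matrix(w, out_w, scale_factor, antialias)
    out = mr @ img @ mc.T
    return np.clip(out, 0.0, 255.0)


def add_salt_pepper(img: np.ndarray, density: float, seed: int) -> np.ndarray:
    """Corrupt each pixel independently with probability ``density``.

    A corrupted pixel becomes 0 (pepper) or 255 (salt) with equal
    probability.  Deterministic given ``seed``.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density={density}: must lie in [0, 1]")
    img = np.asarray(img, dtype=np.float64)
    rng = np.random.default_rng(seed)
    corrupt = rng.random(img.shape) < density
    salt = rng.random(img.shape) < 0.5
    out = img.copy()
    out[corrupt & salt] = 255.0
    out[corrupt & ~salt] = 0.0
    return out


def make_lr(hr: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply the full forward model: bicubic shrink by 1/scale, then noise.

    The HR image must be divisible by the scale so the LR grid is exact.
    Noise (if any) is applied after downsampling, never to the HR image.
    """
    hr = np.asarray(hr, dtype=np.float64)
    h, w = hr.shape
    if h % spec.scale or w % spec.scale:
        raise ValueError(
            f"HR size {h}x{w} not divisible by scale {spec.scale}"
        )
    lr = bicubic_resize(hr, 1.0 / spec.scale, antialias=spec.antialias)
    if spec.noise_density > 0:
        lr = add_salt_pepper(lr, spec.noise_density, spec.seed)
    return lr


def extract_patch_pairs(
    hr: np.ndarray,
    spec: DegradationSpec,
    lr_patch: int = 16,
    stride: int = 1,
    max_pairs: int | None = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> list[PatchPair]:
    """Enumerate aligned LR/HR patch pairs from one HR image.

    The LR image is computed once with :func:`make_lr`; LR origins are
    enumerated on a ``stride`` grid and each pair carries the
    corresponding ``scale * lr_patch`` HR patch.  When the enumeration
    exceeds ``max_pairs``, a seeded uniform subsample of exactly
    ``max_pairs`` pairs is returned.
    """
    if lr_patch < 1:
        raise ValueError("lr_patch must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    hr = np.asarray(hr, dtype=np.float64)
    lr = make_lr(hr, spec)
    lh, lw = lr.shape
    if lr_patch > lh or lr_patch > lw:
        raise ValueError(
            f"lr_patch={lr_patch} larger than LR image {lh}x{lw}"
        )
    rows = range(0, lh - lr_patch + 1, stride)
    cols = range(0, lw - lr_patch + 1, stride)
    origins = [(r, c) for r in rows for c in cols]
    if max_pairs is not None and len(origins) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(origins), size=max_pairs, replace=False)
        origins = [origins[i] for i in np.sort(keep)]
    alpha = spec.scale
    p = lr_patch
    pairs = []
    for r, c in origins:
        hr_r, hr_c = alpha * r, alpha * c
        pairs.append(
            PatchPair(
                lr_patch=lr[r : r + p, c : c + p].copy(),
                hr_patch=hr[hr_r : hr_r + alpha * p, hr_c : hr_c + alpha * p].copy(),
                origin=(hr_r, hr_c),
            )
        )
    return pairs


def write_manifest(
    rows: list[tuple[str, str, int, float, int]], path: str | Path
) -> Path:
    """Write a degradation manifest: one CSV line per image.

    Columns: hr_path, lr_path, scale, noise, seed.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("hr_path,lr_path,scale,noise,seed\n")
        for hr_path, lr_path, scale, noise, seed in rows:
            fh.write(f"{hr_path},{lr_path},{scale},{noise},{seed}\n")
    return path


def read_manifest(path: str | Path) -> list[dict]:
    """Read a manifest written by :func:`write_manifest`."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split(",")
    out = []
    for line in lines[1:]:
        vals = line.split(",")
        row = dict(zip(header, vals))
        row["scale"] = int(row["scale"])
        row["noise"] = float(row["noise"])
        row["seed"] = int(row["seed"])
        out.append(row)
    return out
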