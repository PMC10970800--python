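"""Synthetic radiograph-like phantom images.

Real chest radiographs are dominated by smooth low-frequency attenuation
gradients, overlaid with quasi-periodic rib shadows, occasional compact
bright opacities and fine-grained stochastic texture.  The phantoms built
here reproduce those four statistical ingredients — a broad smooth field,
warped sinusoidal bands, sparse Gaussian blobs and white texture noise —
so that the degradation, training and evaluation stages of this package
can be exercised end to end on seeded, locally generated data.

Phantoms make no claim of anatomical realism; they exist to provide
images whose spectral energy is concentrated at low frequencies, which is
the property the super-resolution network exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_components",
    "generate_set",
    "child_seed",
    "save_png",
    "load_png",
]

# Additive constant used to derive per-image child seeds; any odd constant
# well-mixed over 31 bits works, this is the golden-ratio multiplier.
_SEED_STRIDE = 0x9E3779B1
_SEED_MOD = 2**31


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic radiograph-like image.

    Attributes
    ----------
    height, width : int
        Image size in pixels.  Both must be >= 64 and divisible by 8 so
        that x2 / x4 / x8 downsampling produces integer-sized images.
    seed : int
        Seed controlling every random draw; identical specs produce
        bit-identical images.
    n_bands : int
        Number of rib-like periodic bands across the image height.
    n_blobs : int
        Number of sparse bright lesion-like spots.
    texture_sigma : float
        Standard deviation (intensity units) of the zero-mean fine
        texture added on top of the structured content.
    """

    height: int = 256
    width: int = 256
    seed: int = 0
    n_bands: int = 12
    n_blobs: int = 5
    texture_sigma: float = 2.0

    def __post_init__(self) -> None:
        for name, value in (("height", self.height), ("width", self.width)):
            if value < 64 or value % 8 != 0:
                raise ValueError(
                    f"{name}={value} invalid: phantom dimensions must be "
                    ">= 64 and divisible by 8 (so x2/x4/x8 degradation is exact)"
                )
        if self.n_bands < 0 or self.n_blobs < 0:
            raise ValueError("n_bands and n_blobs must be non-negative")
        if self.texture_sigma < 0:
            raise ValueError("texture_sigma must be >= 0")


def child_seed(seed: int, index: int) -> int:
    """Derive the seed of the ``index``-th image of a phantom set."""
    return (seed + _SEED_STRIDE * (index + 1)) % _SEED_MOD


def generate_components(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Return the four additive layers of a phantom, before clipping.

    Keys: ``smooth`` (broad low-frequency field), ``bands`` (warped
    sinusoidal rib-like structure), ``blobs`` (sparse bright Gaussians,
    peak amplitude around 40 intensity units) and ``texture`` (zero-mean
    white noise).  ``generate_phantom`` is the clipped sum of these.

    Random draws are consumed in a fixed order (smooth, bands, blobs,
    texture), and a layer whose count/sigma is zero consumes no draws for
    its shape randomness only when the layer is structurally absent.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.meshgrid(
        np.linspace(0.0, 1.0, h), np.linspace(0.0, 1.0, w), indexing="ij"
    )

    # Broad smooth field: a few large-sigma Gaussian bumps, rescaled to
    # span most of the 8-bit range.
    bump = np.zeros((h, w))
    for _ in range(3):
        cy, cx = rng.uniform(0.2, 0.8, size=2)
        sig = rng.uniform(0.25, 0.45)
        amp = rng.uniform(0.5, 1.0)
        bump += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    bump -= bump.min()
    peak = bump.max()
    if peak > 0:
        bump /= peak
    smooth = 30.0 + 170.0 * bump

    # Rib-like bands: a sinusoid of period height/n_bands, slightly
    # warped horizontally.
    if spec.n_bands > 0:
        phase = rng.uniform(0.0, 2 * np.pi)
        warp = rng.uniform(0.03, 0.10)
        bands = 28.0 * np.sin(
            2 * np.pi * spec.n_bands * (yy + warp * np.sin(2 * np.pi * xx)) + phase
        )
    else:
        bands = np.zeros((h, w))

    # Sparse bright blobs: small Gaussians, peak ~40 intensity units.
    blobs = np.zeros((h, w))
    for _ in range(spec.n_blobs):
        cy, cx = rng.uniform(0.1, 0.9, size=2)
        sig = rng.uniform(1.0 / 64.0, 1.0 / 32.0)
        peak_amp = rng.uniform(30.0, 50.0)
        blobs += peak_amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)
        )

    if spec.texture_sigma > 0:
        texture = rng.normal(0.0, spec.texture_sigma, size=(h, w))
    else:
        texture = np.zeros((h, w))

    return {"smooth": smooth, "bands": bands, "blobs": blobs, "texture": texture}


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate one phantom as a float64 array in [0, 255].

    The image is the clipped sum of the layers of
    :func:`generate_components`; it is kept at floating precision and
    only quantized to 8 bits when written to file, so downstream
    degradation tests are free of double-quantization bias.
    """
    parts = generate_components(spec)
    img = parts["smooth"] + parts["bands"] + parts["blobs"] + parts["texture"]
    return np.clip(img, 0.0, 255.0)


def generate_set(n: int, spec_template: PhantomSpec, seed: int) -> list[np.ndarray]:
    """Generate ``n`` phantoms with per-image seeds derived from ``seed``.

    Image ``i`` uses ``child_seed(seed, i)`` in place of the template's
    own seed; the call is fully deterministic given ``(n, template, seed)``.
    """
    if n < 1:
        raise ValueError(f"n={n}: must generate at least one phantom")
    return [
        generate_phantom(replace(spec_template, seed=child_seed(seed, i)))
        for i in range(n)
    ]


def save_png(img: np.ndarray, path: str | Path) -> Path:
    """Write a [0, 255] float image as an 8-bit grayscale PNG."""
    path = Path(path)
    arr = np.clip(np.rint(np.asarray(img, dtype=float)), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def load_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a float64 array in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)
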