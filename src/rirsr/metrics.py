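"""Image-quality metrics: PSNR, windowed SSIM, multi-scale MSIM.

PSNR is ``10 * log10(MAX^2 / MSE)`` on the 8-bit scale (MAX = 255);
identical images get an infinite-quality sentinel.  SSIM follows the
standard windowed luminance/contrast/structure comparison with
stabilizers ``C1 = (k1 L)^2`` and ``C2 = (k2 L)^2``; local statistics
use an 11x11 Gaussian window (sigma = 1.5) by default, computed only at
positions where the window fits entirely inside the image (no padding).
MSIM combines SSIM values across dyadic scales as a weighted geometric
mean, ``(prod_i SSIM_i^alpha_i)^(1/N)``; higher values indicate better
structural agreement.  Metrics are computed on the full intensity
image, with no border crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "SSIMParams",
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "msim",
    "evaluate",
]


@dataclass(frozen=True)
class SSIMParams:
    """Parameters of the SSIM family of metrics.

    ``window`` selects the local-statistics weighting: ``"gaussian"``
    (11x11, sigma = 1.5, the standard choice) or ``"uniform"`` (8x8).
    ``n_scales`` and ``scale_weights`` control MSIM; by default 5 scales
    with unit weights, combined by an outer 1/N root.
    """

    dynamic_range: float = 255.0
    k1: float = 0.01
    k2: float = 0.03
    window: str = "gaussian"
    window_size: int = 11
    sigma: float = 1.5
    n_scales: int = 5
    scale_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.window not in ("gaussian", "uniform"):
            raise ValueError("window must be 'gaussian' or 'uniform'")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.scale_weights is not None and len(self.scale_weights) != self.n_scales:
            raise ValueError("scale_weights length must equal n_scales")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def weights(self) -> np.ndarray:
        if self.scale_weights is None:
            return np.ones(self.n_scales)
        return np.asarray(self.scale_weights, dtype=float)

    def window_array(self) -> np.ndarray:
        if self.window == "uniform":
            size = 8 if self.window_size == 11 else self.window_size
            return np.full((size, size), 1.0 / (size * size))
        half = (self.window_size - 1) / 2.0
        coords = np.arange(self.window_size) - half
        g = np.exp(-(coords**2) / (2.0 * self.sigma**2))
        win = np.outer(g, g)
        return win / win.sum()


@dataclass
class MetricReport:
    """Per-image and aggregate quality numbers for one method."""

    method: str
    psnr: list[float] = field(default_factory=list)
    ssim: list[float] = field(default_factory=list)
    msim: list[float] = field(default_factory=list)

    @property
    def mean_psnr(self) -> float:
        return float(np.mean(self.psnr))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim))

    @property
    def mean_msim(self) -> float:
        return float(np.mean(self.msim))


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared pixel difference on the 0-255 scale."""
    x, y = _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when MSE is zero."""
    err = mse(x, y)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(params.dynamic_range**2 / err))


def _window_stats(x: np.ndarray, y: np.ndarray, win: np.ndarray):
    """Valid-mode windowed means, variances and covariance."""
    mu_x = convolve2d(x, win, mode="valid")
    mu_y = convolve2d(y, win, mode="valid")
    exx = convolve2d(x * x, win, mode="valid")
    eyy = convolve2d(y * y, win, mode="valid")
    exy = convolve2d(x * y, win, mode="valid")
    var_x = exx - mu_x**2
    var_y = eyy - mu_y**2
    cov = exy - mu_x * mu_y
    return mu_x, mu_y, var_x, var_y, cov


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Mean structural similarity over all fully-contained windows."""
    x, y = _check_shapes(x, y)
    win = params.window_array()
    if x.shape[0] < win.shape[0] or x.shape[1] < win.shape[1]:
        raise ValueError(
            f"image {x.shape} smaller than window {win.shape}"
        )
    mu_x, mu_y, var_x, var_y, cov = _window_stats(x, y, win)
    c1, c2 = params.c1, params.c2
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def _downsample2(img: np.ndarray) -> np.ndarray:
    """Dyadic downsampling by 2x2 block averaging (crop to even first)."""
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    return 0.25 * (img[0::2, 0::2] + img[0::2, 1::2] + img[1::2, 0::2] + img[1::2, 1::2])


def msim(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Multi-scale structural similarity.

    SSIM is evaluated at ``n_scales`` dyadic scales (2x block-average
    between scales) and combined as ``(prod_i SSIM_i^alpha_i)^(1/N)``.
    The outer root is applied sign-preservingly so rare negative SSIM
    values do not produce complex results.
    """
    x, y = _check_shapes(x, y)
    win_size = params.window_array().shape[0]
    n = params.n_scales
    min_side = min(x.shape) // 2 ** (n - 1)
    if min_side < win_size:
        raise ValueError(
            f"image {x.shape} too small for {n} scales with a "
            f"{win_size}-pixel window"
        )
    weights = params.weights
    vals = []
    cur_x, cur_y = x, y
    for i in range(n):
        vals.append(ssim(cur_x, cur_y, params))
        if i < n - 1:
            cur_x = _downsample2(cur_x)
            cur_y = _downsample2(cur_y)
    prod = 1.0
    for v, a in zip(vals, weights):
        prod *= float(np.sign(v)) * abs(v) ** a
    return float(np.sign(prod) * abs(prod) ** (1.0 / n))


def adapt_scales(shape: tuple[int, int], params: SSIMParams) -> SSIMParams:
    """Cap ``n_scales`` at what an image of ``shape`` supports.

    MSIM needs the ``n_scales - 1`` times downsampled image to still
    contain the window; small evaluation images therefore use fewer
    dyadic scales (with unit weights), leaving larger images at the
    requested setting.
    """
    win = params.window_array().shape[0]
    min_side = min(shape)
    feasible = int(np.floor(np.log2(min_side / win))) + 1 if min_side >= win else 0
    if feasible < 1:
        raise ValueError(f"image {shape} smaller than the {win}-pixel window")
    n = min(params.n_scales, feasible)
    if n == params.n_scales:
        return params
    from dataclasses import replace
    return replace(params, n_scales=n, scale_weights=None)


def evaluate(
    model,
    test_hr: list[np.ndarray],
    spec,
    params: SSIMParams = SSIMParams(),
) -> tuple[MetricReport, MetricReport]:
    """Degrade, super-resolve and score a test set against ground truth.

    For each HR image the LR input is produced by the forward model,
    super-resolved by ``model`` (anything exposing ``predict_image``)
    and compared to the clean HR; the bicubic-upscaled LR provides the
    model-independent baseline report.
    """
    from .degrade import bicubic_resize, make_lr

    report = MetricReport(method="model")
    baseline = MetricReport(method="bicubic")
    for hr in test_hr:
        lr = make_lr(hr, spec)
        sr = model.predict_image(lr)
        bic = bicubic_resize(lr, float(spec.scale), antialias=False)
        for rep, out in ((report, sr), (baseline, bic)):
            rep.psnr.append(psnr(out, hr, params))
            rep.ssim.append(ssim(out, hr, params))
            rep.msim.append(msim(out, hr, params))
    return report, baseline
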