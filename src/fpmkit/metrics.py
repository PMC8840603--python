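"""Reconstruction quality scores: MSE, PSNR and SSIM.

All three are computed from whole-image statistics:

    MSE  = (1/mn) Σ ‖a − b‖²
    PSNR = 20 · log10( MAX_I / √MSE )            [dB]
    SSIM = l(X,Y) · c(X,Y) · s(X,Y)
         = (2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2))

with C1 = (0.01 L)², C2 = (0.03 L)², C3 = C2/2 (which collapses the
three-factor product into the simplified form above).  ``MAX_I`` and ``L``
are the dynamic range: 255 for 8-bit images, 1.0 for floats — inferred from
the dtype unless given.  Variances and the covariance are population
statistics (divide by the pixel count), consistent with the plain-mean μ.

A Gaussian-windowed SSIM variant (the common 11×11 local form) is available
behind ``windowed=True``; the global form is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InputError

__all__ = ["QualityReport", "mse", "psnr", "ssim", "evaluate_pair", "evaluate_dual_channel"]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise InputError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def _dynamic_range(a: np.ndarray, b: np.ndarray) -> float:
    if a.dtype == np.uint8 or b.dtype == np.uint8:
        return 255.0
    return 1.0


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error over all pixels (complex inputs use |a − b|²)."""
    a, b = _check_shapes(a, b)
    diff = np.abs(np.asarray(a, dtype=complex) - np.asarray(b, dtype=complex))
    return float(np.mean(diff**2))


def psnr(a: np.ndarray, b: np.ndarray, max_i: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    a, b = _check_shapes(a, b)
    if max_i is None:
        max_i = _dynamic_range(a, b)
    if max_i <= 0:
        raise InputError(f"max_i must be > 0, got {max_i}")
    err = mse(a, b)
    if err == 0:
        return math.inf
    return float(20.0 * np.log10(max_i / np.sqrt(err)))


def _global_stats(a: np.ndarray, b: np.ndarray):
    mu_x = float(np.mean(a))
    mu_y = float(np.mean(b))
    var_x = float(np.mean((a - mu_x) ** 2))
    var_y = float(np.mean((b - mu_y) ** 2))
    cov = float(np.mean((a - mu_x) * (b - mu_y)))
    return mu_x, mu_y, var_x, var_y, cov


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    l: float | None = None,
    *,
    windowed: bool = False,
    window_sigma: float = 1.5,
) -> float:
    """Structural similarity from whole-image statistics (default) or as a
    mean over Gaussian-windowed local statistics (``windowed=True``)."""
    a, b = _check_shapes(a, b)
    if l is None:
        l = _dynamic_range(a, b)
    if l <= 0:
        raise InputError(f"dynamic range l must be > 0, got {l}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c1 = (0.01 * l) ** 2
    c2 = (0.03 * l) ** 2
    if not windowed:
        mu_x, mu_y, var_x, var_y, cov = _global_stats(a, b)
        num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
        den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
        return float(num / den)
    mu_x = gaussian_filter(a, window_sigma)
    mu_y = gaussian_filter(b, window_sigma)
    var_x = gaussian_filter(a * a, window_sigma) - mu_x**2
    var_y = gaussian_filter(b * b, window_sigma) - mu_y**2
    cov = gaussian_filter(a * b, window_sigma) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def ssim_components(a: np.ndarray, b: np.ndarray, l: float = 1.0) -> tuple[float, float, float]:
    """The luminance, contrast and structure factors (C3 = C2/2); their
    product equals the simplified single-expression form."""
    a, b = _check_shapes(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c1 = (0.01 * l) ** 2
    c2 = (0.03 * l) ** 2
    c3 = c2 / 2.0
    mu_x, mu_y, var_x, var_y, cov = _global_stats(a, b)
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    struc = (cov + c3) / (sd_x * sd_y + c3)
    return float(lum), float(con), float(struc)


@dataclass
class QualityReport:
    """MSE/PSNR/SSIM of one image pair, with the constants used."""

    mse: float
    psnr: float
    ssim: float
    max_i: float
    l: float
    c1: float
    c2: float
    c3: float

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["psnr"]):
            d["psnr"] = "inf"
        return d


def evaluate_pair(pred: np.ndarray, truth: np.ndarray, max_i: float | None = None) -> QualityReport:
    """Score one predicted image against its reference."""
    pred, truth = _check_shapes(pred, truth)
    if max_i is None:
        max_i = _dynamic_range(pred, truth)
    l = max_i
    return QualityReport(
        mse=mse(pred, truth),
        psnr=psnr(pred, truth, max_i),
        ssim=ssim(pred, truth, l),
        max_i=max_i,
        l=l,
        c1=(0.01 * l) ** 2,
        c2=(0.03 * l) ** 2,
        c3=(0.03 * l) ** 2 / 2.0,
    )


def evaluate_dual_channel(pred, truth, max_i: float | None = None) -> dict:
    """Per-channel reports for a dual-channel (intensity, phase) pair.

    Phase channels are scored as plain images on their wrapped values.
    Accepts ``DualChannelInput`` objects or (2, S, S) arrays.
    """
    p = pred.stacked() if hasattr(pred, "stacked") else np.asarray(pred)
    t = truth.stacked() if hasattr(truth, "stacked") else np.asarray(truth)
    if p.shape != t.shape or p.shape[0] != 2:
        raise InputError(f"expected matching (2, S, S) arrays, got {p.shape} vs {t.shape}")
    return {
        "intensity": evaluate_pair(p[0], t[0], max_i).to_dict(),
        "phase": evaluate_pair(p[1], t[1], max_i).to_dict(),
    }
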