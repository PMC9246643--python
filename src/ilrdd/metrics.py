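"""PSNR and SSIM image quality metrics.

PSNR (for images on a [0, 1] scale) is 10 log10(M / ||ref - test||_2^2) in
decibels, M being the pixel count — identical images report +inf.  SSIM is

    (2 a_x a_y + e1)(2 b_xy + e2)
    -----------------------------------
    (a_x^2 + a_y^2 + e1)(b_x^2 + b_y^2 + e2)

on means a, variances b^2 and covariance b_xy, with the customary
stabilisers e1 = (0.01 L)^2, e2 = (0.03 L)^2 for dynamic range L.  The
default evaluates the formula once on whole-image moments; a sliding-window
mode averages it over all w x w windows at stride 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import Image2D

__all__ = ["SSIMConstants", "MetricReport", "psnr", "ssim"]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilisers e1 = (0.01 L)^2 and e2 = (0.03 L)^2 by default."""

    dynamic_range: float = 1.0
    e1: float | None = None
    e2: float | None = None

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ValueError("dynamic range must be > 0")
        if self.e1 is None:
            object.__setattr__(self, "e1", (0.01 * self.dynamic_range) ** 2)
        if self.e2 is None:
            object.__setattr__(self, "e2", (0.03 * self.dynamic_range) ** 2)
        if self.e1 <= 0 or self.e2 <= 0:
            raise ValueError("stabilisers must be > 0")


@dataclass(frozen=True)
class MetricReport:
    """PSNR/SSIM pair for one image comparison; psnr_db is +inf when equal."""

    psnr_db: float
    ssim: float
    pixel_count: int

    def to_dict(self) -> dict:
        return {
            "psnr_db": "inf" if math.isinf(self.psnr_db) else self.psnr_db,
            "ssim": self.ssim,
            "pixel_count": self.pixel_count,
        }


def _check_shapes(a: Image2D, b: Image2D) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def psnr(ref: Image2D, test: Image2D) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    _check_shapes(ref, test)
    err = float(np.sum((ref.pixels - test.pixels) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(ref.pixels.size / err)


def _ssim_formula(
    mx: np.ndarray, my: np.ndarray, vx: np.ndarray, vy: np.ndarray,
    cxy: np.ndarray, consts: SSIMConstants,
) -> np.ndarray:
    return ((2 * mx * my + consts.e1) * (2 * cxy + consts.e2)) / (
        (mx**2 + my**2 + consts.e1) * (vx + vy + consts.e2)
    )


def ssim(
    x: Image2D,
    y: Image2D,
    consts: SSIMConstants | None = None,
    window: int | None = None,
) -> float:
    """Structural similarity in [-1, 1]; 1 means structurally identical.

    ``window=None`` evaluates the formula once on global moments; an integer
    ``window`` averages per-window values over all w x w sliding windows.
    """
    _check_shapes(x, y)
    if consts is None:
        consts = SSIMConstants()
    a, b = x.pixels, y.pixels
    if window is None:
        val = _ssim_formula(
            a.mean(), b.mean(), a.var(), b.var(),
            np.mean((a - a.mean()) * (b - b.mean())), consts,
        )
        return float(val)
    if window < 2 or window > min(x.shape):
        raise ValueError(f"window {window} invalid for image {x.shape}")
    wa = np.lib.stride_tricks.sliding_window_view(a, (window, window))
    wb = np.lib.stride_tricks.sliding_window_view(b, (window, window))
    mx = wa.mean(axis=(2, 3))
    my = wb.mean(axis=(2, 3))
    vx = wa.var(axis=(2, 3))
    vy = wb.var(axis=(2, 3))
    cxy = (wa * wb).mean(axis=(2, 3)) - mx * my
    return float(_ssim_formula(mx, my, vx, vy, cxy, consts).mean())


def report(ref: Image2D, test: Image2D, window: int | None = None) -> MetricReport:
    """Bundle PSNR and SSIM of ``test`` against the reference image."""
    return MetricReport(
        psnr_db=psnr(ref, test),
        ssim=ssim(ref, test, window=window),
        pixel_count=ref.pixels.size,
    )
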