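"""Synthetic knee-like phantoms and Rician noise.

Magnitude MR images are corrupted by Rician noise: the observed pixel is the
magnitude of a complex signal whose real and imaginary channels each carry
independent zero-mean Gaussian noise of standard deviation ``sigma``.  The
noise level is specified as a percentage of the nominal dynamic range
("rice intensity"): level p% means sigma = p/100 * intensity_max.

A parametric phantom generator stands in for clinical slices so the whole
pipeline is testable without any data download: nested elliptical "tissue"
regions with distinct mean intensities (bone-like blobs surrounded by
cartilage-band-like rings), lightly smoothed and normalised to [0, 1].
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Image2D",
    "NoiseSpec",
    "seed_stream",
    "generate_phantom",
    "add_rician_noise",
    "estimate_sigma",
]

# 3x3 discrete Laplacian; for i.i.d. noise the filtered std is sigma*sqrt(20)
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
# MAD-to-std consistency constant for a Gaussian: 1/Phi^-1(3/4)
_MAD_SCALE = 0.6744897501960817


def seed_stream(seed: int, name: str) -> np.random.Generator:
    """Named, collision-free random substream derived from one global seed.

    Streams are keyed by a CRC32 of ``name`` so that e.g. the phantom and the
    noise draws never share state and adding a stream never shifts another.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class Image2D:
    """A 2-D grayscale raster with its nominal dynamic range.

    ``pixels`` holds finite, nonnegative float64 intensities.  Normalised
    images live in [0, 1] up to noise excursions above 1, which are retained
    rather than clipped so quality metrics see the true corruption.
    """

    pixels: np.ndarray
    intensity_max: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D array, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D pixels must be finite")
        if self.intensity_max <= 0:
            raise ValueError("intensity_max must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level: sigma = level_percent/100 * intensity_max exactly."""

    level_percent: float
    seed: int = 0
    intensity_max: float = 1.0
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.level_percent < 0:
            raise ValueError("noise level must be >= 0")
        if self.intensity_max <= 0:
            raise ValueError("intensity_max must be > 0")
        object.__setattr__(
            self, "sigma", self.level_percent / 100.0 * self.intensity_max
        )


def generate_phantom(
    height: int,
    width: int,
    n_tissues: int = 4,
    smooth_radius: float = 1.0,
    seed: int = 0,
) -> Image2D:
    """Piecewise-smooth phantom of ``n_tissues`` nested elliptical regions.

    The background counts as the first tissue; the remaining ``n_tissues - 1``
    regions are concentric rotated ellipses with shrinking axes and distinct
    mean intensities, so with ``smooth_radius == 0`` the raster holds at most
    ``n_tissues`` distinct values.  Deterministic for a fixed seed.
    """
    if height < 16 or width < 16:
        raise ValueError(
            f"phantom dimensions must be >= 16, got {height}x{width}"
        )
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    if smooth_radius < 0:
        raise ValueError("smooth_radius must be >= 0")

    rng = seed_stream(seed, "phantom")
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    cy = height / 2.0 + rng.uniform(-0.05, 0.05) * height
    cx = width / 2.0 + rng.uniform(-0.05, 0.05) * width

    # Distinct tissue intensities spanning the full range, shuffled so the
    # nesting order is not monotone in brightness.
    levels = np.linspace(0.0, 1.0, n_tissues)
    rng.shuffle(levels[1:-1])

    img = np.full((height, width), levels[0], dtype=np.float64)
    n_ell = n_tissues - 1
    # Outermost ellipse nearly fills the frame; axes shrink geometrically.
    for j in range(n_ell):
        frac = (n_ell - j) / n_ell
        a = 0.45 * width * frac * rng.uniform(0.85, 1.0)
        b = 0.45 * height * frac * rng.uniform(0.85, 1.0)
        theta = rng.uniform(0.0, np.pi)
        jy = cy + rng.uniform(-0.03, 0.03) * height * (j > 0)
        jx = cx + rng.uniform(-0.03, 0.03) * width * (j > 0)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - jx) * ct + (yy - jy) * st
        v = -(xx - jx) * st + (yy - jy) * ct
        mask = (u / max(a, 1.0)) ** 2 + (v / max(b, 1.0)) ** 2 <= 1.0
        img[mask] = levels[j + 1]

    if smooth_radius > 0:
        img = ndimage.gaussian_filter(img, sigma=smooth_radius, mode="nearest")

    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return Image2D(img, intensity_max=1.0)


def add_rician_noise(img: Image2D, spec: NoiseSpec) -> Image2D:
    """Corrupt ``img`` with Rician noise: sqrt((v + n1)^2 + n2^2).

    ``n1, n2`` are independent N(0, sigma^2) draws.  With ``sigma == 0`` the
    output equals the (nonnegative) input bit-for-bit.  The same
    ``(img, spec)`` pair always produces identical output.
    """
    if spec.sigma < 0:
        raise ValueError("sigma must be >= 0")
    if spec.sigma == 0:
        return Image2D(np.abs(img.pixels), intensity_max=img.intensity_max)
    rng = seed_stream(spec.seed, "noise")
    n1 = rng.normal(0.0, spec.sigma, size=img.shape)
    n2 = rng.normal(0.0, spec.sigma, size=img.shape)
    noisy = np.hypot(img.pixels + n1, n2)
    return Image2D(noisy, intensity_max=img.intensity_max)


def estimate_sigma(noisy: Image2D) -> float:
    """Robust Gaussian-channel noise std from high-frequency residuals.

    Convolves with the 3x3 discrete Laplacian (which annihilates constants
    and slow trends) and scales the median absolute deviation of the result
    by the Gaussian consistency constant and the kernel's noise gain
    sqrt(20).  Returns 0 for a constant image.
    """
    if noisy.height < 16 or noisy.width < 16:
        raise ValueError("sigma estimation needs at least a 16x16 image")
    lap = ndimage.convolve(noisy.pixels, _LAPLACIAN, mode="reflect")
    mad = float(np.median(np.abs(lap)))
    return mad / _MAD_SCALE / np.sqrt(20.0)
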