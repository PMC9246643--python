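"""Image readers and writers: 16-bit grayscale PNG and single-slice NIfTI-1.

Both formats store a 16-bit quantisation of the [0, 1] intensity scale, so a
write/read round-trip is exact to one part in 2^16 and the two formats agree
with each other to the same precision.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantom import Image2D

__all__ = ["read_image", "write_image"]

_U16_MAX = 65535


def _to_u16(img: Image2D) -> np.ndarray:
    scaled = np.clip(img.pixels / img.intensity_max, 0.0, 1.0)
    return np.round(scaled * float(_U16_MAX)).astype(np.uint16)


def _from_u16(raw: np.ndarray) -> Image2D:
    return Image2D(raw.astype(np.float64) / float(_U16_MAX), intensity_max=1.0)


def write_image(img: Image2D, path) -> None:
    """Write as 16-bit grayscale PNG or NIfTI-1, chosen by extension."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix == ".png":
        iio.imwrite(path, _to_u16(img), extension=".png")
    elif suffixes.endswith((".nii", ".nii.gz")):
        nifti = nib.Nifti1Image(_to_u16(img).T, affine=np.eye(4))
        nib.save(nifti, path)
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def read_image(path) -> Image2D:
    """Read a 16-bit grayscale PNG or a single-slice NIfTI-1 to [0, 1]."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix == ".png":
        raw = np.asarray(iio.imread(path))
        if raw.ndim != 2:
            raise ValueError(f"{path.name}: expected grayscale, got shape {raw.shape}")
        if raw.dtype == np.uint16:
            return _from_u16(raw)
        if raw.dtype == np.uint8:
            return Image2D(raw.astype(np.float64) / 255.0, intensity_max=1.0)
        raise ValueError(f"{path.name}: unsupported PNG bit depth {raw.dtype}")
    if suffixes.endswith((".nii", ".nii.gz")):
        nifti = nib.load(path)
        data = np.asanyarray(nifti.dataobj)
        extra = data.shape[2:]
        if any(s != 1 for s in extra):
            n_slices = int(np.prod(extra))
            raise ValueError(
                f"{path.name}: expected a single slice, got {n_slices} slices"
            )
        plane = np.squeeze(data).astype(np.float64).T
        # Map by the file's dynamic range: integer dtypes by their full
        # range, floats by their data extent.
        if np.issubdtype(data.dtype, np.integer):
            plane = plane / float(np.iinfo(data.dtype).max)
        else:
            lo, hi = float(plane.min()), float(plane.max())
            if hi > lo:
                plane = (plane - lo) / (hi - lo)
        return Image2D(plane, intensity_max=1.0)
    raise ValueError(f"unsupported image format: {path.name}")
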