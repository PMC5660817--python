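"""Image and configuration file handling.

PNG/TIFF grayscale round-trips losslessly at 8 or 16 bits; a NIfTI volume
contributes a single axial slice rescaled to [0, 255].  Masks are written
as 0/255 PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import FormatError, InputDomainError

NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, to_gray: bool = False, slice_index: int | None = None,
               levels: int | None = None) -> tuple[np.ndarray, int]:
    """Read a 2-D gray image; returns (array, L number of levels).

    8-bit input gives L = 256, 16-bit L = 65536 (or linearly requantized
    to ``levels`` when given).  RGB input is rejected unless ``to_gray``
    asks for a luminance conversion.  NIfTI input needs ``slice_index``
    and is rescaled to [0, 255].
    """
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        if slice_index is None:
            raise FormatError("NIfTI input requires an axial slice index")
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim < 3:
            raise FormatError("NIfTI volume must be 3-D")
        if not 0 <= slice_index < vol.shape[2]:
            raise FormatError(
                f"slice {slice_index} outside 0..{vol.shape[2] - 1}")
        sl = np.asarray(vol[:, :, slice_index], dtype=float)
        lo, hi = sl.min(), sl.max()
        img = np.zeros_like(sl) if hi == lo else (sl - lo) / (hi - lo) * 255.0
        return img, 256

    arr = iio.imread(path)
    if arr.ndim == 3:
        if not to_gray:
            raise FormatError(
                "color input; pass to_gray/--to-gray for luminance conversion")
        arr = arr[..., :3].astype(float) @ np.array([0.2126, 0.7152, 0.0722])
        arr = np.floor(arr + 0.5)
        L = 256
    elif arr.dtype == np.uint16:
        L = 65536
    elif arr.dtype == np.uint8:
        L = 256
    else:
        raise FormatError(f"unsupported image dtype {arr.dtype}")
    if arr.ndim != 2:
        raise FormatError("expected a single-channel 2-D image")
    img = arr.astype(float)
    if levels is not None and levels != L:
        img = np.floor(img / (L - 1) * (levels - 1) + 0.5)
        L = levels
    return img, L


def write_image(img: np.ndarray, path, L: int = 256) -> None:
    """Write a gray image as 8- or 16-bit PNG/TIFF depending on ``L``."""
    img = np.asarray(img)
    if img.min() < 0 or img.max() > L - 1:
        raise InputDomainError(f"image values outside [0, {L - 1}]")
    dtype = np.uint8 if L <= 256 else np.uint16
    iio.imwrite(Path(path), np.floor(img + 0.5).astype(dtype))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as 0/255 8-bit PNG."""
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    """Read a 0/255 (or 0/1) mask image as boolean."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError("mask must be a single-channel 2-D image")
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)


def load_sets_yaml(path) -> dict:
    """Load a ``{kind: [[intensity, membership], ...]}`` fuzzy-set file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError("fuzzy set file must map set kinds to knot lists")
    return data
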