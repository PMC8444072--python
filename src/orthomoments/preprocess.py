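"""Image loading and preprocessing.

Images are plain ``float64`` numpy arrays with values in [0, 1]; row
index is the image *x* (vertical) coordinate and column index is *y*
(horizontal), matching the ``f(x, y)`` convention used by the moment
modules.  Binary images take values in {0.0, 1.0}.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import exposure, transform

__all__ = [
    "load_image",
    "save_image",
    "normalize",
    "resize",
    "hist_equalize",
    "binarize",
    "crop_pad",
    "is_binary",
    "read_manifest",
    "write_manifest",
]

#: expert-feature columns a manifest may carry in addition to path/label
MANIFEST_FEATURE_COLUMNS = ["assessment", "shape", "margin", "density", "subtlety"]


def is_binary(img: np.ndarray) -> bool:
    """True if every pixel is exactly 0 or 1."""
    return bool(np.all((img == 0.0) | (img == 1.0)))


def _validate(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("expected a non-empty 2-D image array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return img


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG (or any raster) as a grayscale image scaled to [0, 1].

    Multi-channel input is reduced by the unweighted channel mean; an
    alpha channel, if present, is dropped first.  Integer images are
    divided by the maximum value of their dtype, so an 8-bit pixel of
    128 maps to 128/255.
    """
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # RGBA
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / float(np.iinfo(raw.dtype).max)
    return _validate(np.clip(arr, 0.0, 1.0))


def save_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write an image in [0, 1] as an 8-bit grayscale PNG."""
    img = _validate(img)
    iio.imwrite(path, np.round(img * 255).astype(np.uint8))


def normalize(img: np.ndarray) -> np.ndarray:
    """Min–max rescale to the full [0, 1] range.

    A constant image is returned unchanged (there is no contrast to
    stretch).
    """
    img = _validate(img)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return img.copy()
    return (img - lo) / (hi - lo)


def resize(img: np.ndarray, height: int, width: int) -> np.ndarray:
    """Resize to exactly (height, width).

    Bilinear interpolation for grayscale input; nearest-neighbour for
    binary input so the output stays in {0, 1}.
    """
    img = _validate(img)
    if height < 1 or width < 1:
        raise ValueError("target dimensions must be positive")
    order = 0 if is_binary(img) else 1
    out = transform.resize(
        img, (height, width), order=order, anti_aliasing=False, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def hist_equalize(img: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Histogram equalization via the empirical CDF.

    Monotone intensity remapping: each gray level is sent to the
    fraction of pixels at or below it.  Constant images are returned
    unchanged (degenerate CDF).
    """
    img = _validate(img)
    if is_binary(img):
        raise ValueError("histogram equalization expects a grayscale image")
    if img.max() == img.min():
        return img.copy()
    return exposure.equalize_hist(img, nbins=n_bins)


def binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold to a {0, 1} image: pixel > threshold maps to 1."""
    img = _validate(img)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return (img > threshold).astype(float)


def crop_pad(img: np.ndarray, height: int, width: int) -> np.ndarray:
    """Center-crop or zero-pad each axis independently to (height, width)."""
    img = _validate(img)
    out = img
    for axis, target in enumerate((height, width)):
        cur = out.shape[axis]
        if cur > target:
            start = (cur - target) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif cur < target:
            before = (target - cur) // 2
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, target - cur - before)
            out = np.pad(out, pad, mode="constant")
    return out


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CSV manifest with at least ``path`` and ``label`` columns."""
    df = pd.read_csv(path)
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    if df["path"].duplicated().any():
        raise ValueError("manifest paths must be unique")
    if df["label"].nunique() < 2:
        raise ValueError("manifest must contain at least two classes")
    return df


def write_manifest(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
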