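"""Image-plane I/O, normalization, and controlled corruption.

This module fixes the conventions every other stage inherits:

* intensities are ``float64`` in ``[0, 1]`` after ingest (raw counts divided
  by the bit-depth maximum, 255 for 8-bit);
* positions are ``(x, y)`` with ``x`` = column index and ``y`` = row index,
  0-based, pixel centers at integer coordinates, ``y`` increasing downward.

The corruption operations (:func:`add_poisson_noise`, :func:`downsample`,
:func:`requantize`) emulate acquisition imperfections typical of fluorescence
micrographs -- detector noise, reduced magnification/resolution, and reduced
dynamic range -- and are the building blocks of the robustness harness in
:mod:`sftrace.evaluate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "ImagePlane",
    "read_plane",
    "write_plane",
    "normalize_to_unit_max",
    "add_poisson_noise",
    "downsample",
    "requantize",
]


@dataclass(frozen=True)
class ImagePlane:
    """A single 2-D grayscale intensity grid.

    Parameters
    ----------
    data
        2-D array of finite intensities in ``[0, 1]``.
    source_bit_depth
        Bit depth of the acquisition the plane was ingested from (default 8).
        Corruptions that operate on the raw count scale (Poisson noise,
        clipping) use ``2**source_bit_depth - 1`` as the full-scale value.
    """

    data: np.ndarray
    source_bit_depth: int = 8
    # kept for provenance display only
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("ImagePlane data must be a non-empty 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("ImagePlane intensities must be finite")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError("ImagePlane intensities must lie in [0, 1]")
        if not (1 <= int(self.source_bit_depth) <= 16):
            raise ValueError("source_bit_depth must be in [1, 16]")
        object.__setattr__(self, "data", np.clip(arr, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def full_scale(self) -> int:
        return (1 << self.source_bit_depth) - 1

    def with_data(self, data: np.ndarray) -> "ImagePlane":
        """Return a plane with new data but the same provenance metadata."""
        return ImagePlane(data, self.source_bit_depth, self.source_path)


_BIT_DEPTH_BY_DTYPE = {np.uint8: 8, np.uint16: 16}


def read_plane(path: str | Path, channel: int = 0) -> ImagePlane:
    """Read one grayscale plane from a TIFF or PNG file.

    ``channel`` addresses either the page of a multi-page TIFF or the channel
    axis of an ``(H, W, C)`` raster.  Intensities are normalized to ``[0, 1]``
    by dividing by the bit-depth maximum of the stored integer dtype.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    channel = int(channel)
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            arr = np.asarray(series.asarray())
            axes = series.axes
        if arr.ndim == 2:
            if channel != 0:
                raise ValueError(f"channel {channel} out of range for single-plane TIFF")
        elif arr.ndim == 3:
            # one non-spatial axis (pages, channels or samples) indexes planes
            non_spatial = [i for i, ax in enumerate(axes) if ax not in "YX"]
            axis = non_spatial[0] if non_spatial else 0
            if not 0 <= channel < arr.shape[axis]:
                raise ValueError(
                    f"channel {channel} out of range for {arr.shape[axis]}-plane TIFF"
                )
            arr = np.take(arr, channel, axis=axis)
        else:
            raise IOError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            if not 0 <= channel < arr.shape[2]:
                raise ValueError(f"channel {channel} out of range for shape {arr.shape}")
            arr = arr[:, :, channel]
        elif channel != 0:
            raise ValueError(f"channel {channel} out of range for single-channel image")
    if arr.ndim != 2:
        raise IOError(f"unsupported image dimensionality {arr.ndim} in {path}")
    depth = _BIT_DEPTH_BY_DTYPE.get(arr.dtype.type)
    if depth is None:
        raise IOError(f"unsupported pixel dtype {arr.dtype} in {path} (need uint8/uint16)")
    scale = float((1 << depth) - 1)
    return ImagePlane(arr.astype(np.float64) / scale, depth, str(path))


def write_plane(img: ImagePlane, path: str | Path) -> None:
    """Write a plane as an integer TIFF/PNG at its source bit depth.

    Values on the quantization grid round-trip bit-exactly through
    :func:`read_plane`.
    """
    path = Path(path)
    scale = img.full_scale
    dtype = np.uint8 if img.source_bit_depth <= 8 else np.uint16
    raw = np.round(img.data * scale).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raw)
    else:
        iio.imwrite(path, raw)


def normalize_to_unit_max(img: ImagePlane) -> ImagePlane:
    """Divide by the maximum intensity so the new maximum is exactly 1.

    An all-zero plane is returned unchanged (there is nothing to scale).
    """
    peak = float(img.data.max())
    if peak <= 0.0:
        return img
    return img.with_data(img.data / peak)


def add_poisson_noise(img: ImagePlane, lam: float, seed: int) -> ImagePlane:
    """Add independent Poisson(λ) counts per pixel on the raw count scale.

    The draw is added to ``value * full_scale``, clipped to the bit-depth
    range, and renormalized to ``[0, 1]``; the mean intensity added (before
    clipping) is ``lam / full_scale``.  Deterministic for a fixed ``seed``.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if lam == 0:
        return img
    rng = np.random.default_rng(seed)
    scale = img.full_scale
    counts = img.data * scale + rng.poisson(lam, size=img.data.shape)
    return img.with_data(np.clip(counts, 0, scale) / scale)


def downsample(img: ImagePlane, factor: int) -> ImagePlane:
    """Reduce resolution by block-mean (area) averaging.

    Each output pixel is the mean of its ``factor x factor`` source block;
    trailing rows/columns that do not fill a block are dropped.
    """
    factor = int(factor)
    if factor < 2:
        raise ValueError(f"downsample factor must be >= 2, got {factor}")
    h, w = img.data.shape
    h2, w2 = h // factor, w // factor
    if h2 < 1 or w2 < 1:
        raise ValueError(f"factor {factor} larger than image {h}x{w}")
    block = img.data[: h2 * factor, : w2 * factor]
    out = block.reshape(h2, factor, w2, factor).mean(axis=(1, 3))
    return img.with_data(out)


def requantize(img: ImagePlane, bits: int) -> ImagePlane:
    """Quantize intensities to ``2**bits`` uniform levels on ``[0, 1]``.

    Rounds to the nearest level, so the output takes at most ``2**bits``
    distinct values and the operation is idempotent.
    """
    bits = int(bits)
    if not 1 <= bits <= 16:
        raise ValueError(f"bits must be in [1, 16], got {bits}")
    levels = (1 << bits) - 1
    return img.with_data(np.round(img.data * levels) / levels)
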