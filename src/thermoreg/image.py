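"""Grayscale image container and file I/O.

All registration stages operate on intensities normalized to [0, 1] so that
thresholds are independent of the acquisition bit depth.  The pixel
coordinate convention throughout the package is 0-based with ``x`` the
column index and ``y`` the row index; pixel centers sit at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["Image", "read_image", "write_image"]

# maximum representable value per input bit depth
_DEPTH_MAX = {8: 255.0, 16: 65535.0}


@dataclass(frozen=True)
class Image:
    """A single-channel 2-D intensity image.

    Parameters
    ----------
    pixels
        2-D float array of intensities.  After :func:`read_image` or
        :meth:`normalized`, values lie in [0, 1].
    bit_depth_in
        Bit depth of the file the image was read from (metadata only;
        8 for arrays constructed in memory).
    """

    pixels: np.ndarray
    bit_depth_in: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"Image requires a 2-D array, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("Image has zero size")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image intensities must be finite")
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

    def normalized(self) -> "Image":
        """Copy with intensities rescaled to [0, 1] (min-max).

        A constant image maps to all zeros.
        """
        px = self.pixels
        lo, hi = float(px.min()), float(px.max())
        if hi - lo < 1e-300:
            return Image(np.zeros_like(px), self.bit_depth_in)
        return Image((px - lo) / (hi - lo), self.bit_depth_in)


def read_image(path: str | Path, channel_collapse: str | None = None) -> Image:
    """Read a grayscale 8/16-bit PNG or TIFF and scale to [0, 1].

    Intensities are divided by the format maximum (255 or 65535), not by
    the image maximum, so absolute levels are comparable across frames of
    a longitudinal series.

    Parameters
    ----------
    path
        Existing PNG or TIFF file.
    channel_collapse
        How to reduce a multi-channel file to one channel: ``"luminance"``
        (mean over channels) or ``"first"``.  Without a rule, multi-channel
        input is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        if channel_collapse == "luminance":
            arr = arr.mean(axis=2)
        elif channel_collapse == "first":
            arr = arr[:, :, 0]
        else:
            raise ValueError(
                f"{path} has {arr.shape[2]} channels; pass channel_collapse="
                "'luminance' or 'first' to reduce it"
            )
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{path}: expected a non-empty 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        depth = 16
    elif arr.dtype == np.uint8:
        depth = 8
    else:
        # float TIFF etc.: assume already on [0, 1]
        return Image(np.asarray(arr, dtype=float), bit_depth_in=8)
    return Image(arr.astype(float) / _DEPTH_MAX[depth], bit_depth_in=depth)


def write_image(path: str | Path, img: Image, bit_depth: int | None = None) -> None:
    """Write ``img`` as PNG/TIFF at ``bit_depth`` (defaults to the input depth).

    Intensities are clipped to [0, 1] and quantized by the format maximum,
    so a read/write round trip at native depth is bit-identical.
    """
    depth = bit_depth if bit_depth is not None else img.bit_depth_in
    if depth not in _DEPTH_MAX:
        raise ValueError(f"unsupported bit depth {depth}")
    scaled = np.clip(img.pixels, 0.0, 1.0) * _DEPTH_MAX[depth]
    arr = np.rint(scaled).astype(np.uint8 if depth == 8 else np.uint16)
    iio.imwrite(Path(path), arr)
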