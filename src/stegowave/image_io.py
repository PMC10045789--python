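"""Image data model and raster I/O.

The whole pipeline works on 8-bit samples. :class:`Image8` is the single
in-memory container: a row-major numpy array, ``(H, W)`` for grayscale or
``(H, W, 3)`` channel-last for RGB, values in [0, 255]. Anything wider
(16-bit sources) is rejected rather than rescaled — silent requantization
would corrupt an embedded payload.

Supported formats: PNG and PGM (P2/P5, maxval 255) for read and write, JPEG
for read only. Stego and compressed outputs must survive bit-exactly, so a
JPEG *write* is refused.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image as _PILImage

from .errors import ContractError, FormatError

__all__ = ["Image8", "WideImage", "read_image", "write_image"]

_READ_FORMATS = {"PNG", "PPM", "JPEG"}  # Pillow reports PGM files as "PPM"
_WRITE_SUFFIX = {".png": "PNG", ".pgm": "PPM"}

#: padding sentinel used by the knight-tour modules; one above the 8-bit range
SENTINEL = 256


class Image8:
    """An 8-bit grayscale or RGB image.

    Parameters
    ----------
    samples
        ``(H, W)`` or ``(H, W, 3)`` integer array with values in [0, 255].
        A ``(H, W, 1)`` array is normalized to 2-D grayscale.
    """

    __slots__ = ("samples",)

    def __init__(self, samples):
        arr = np.asarray(samples)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim not in (2, 3):
            raise ContractError(f"expected 2-D or 3-D samples, got ndim={arr.ndim}")
        if arr.ndim == 3 and arr.shape[2] != 3:
            raise ContractError(f"RGB images need 3 channels, got {arr.shape[2]}")
        if arr.size == 0:
            raise ContractError("image must have at least one pixel")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ContractError("samples must be integers")
        if arr.min() < 0 or arr.max() > 255:
            raise ContractError("samples must lie in [0, 255]")
        self.samples = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.samples.shape[0]

    @property
    def width(self) -> int:
        return self.samples.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 2 else 3

    @property
    def colorspace(self) -> str:
        return "GRAY" if self.samples.ndim == 2 else "RGB"

    def planes(self) -> list[np.ndarray]:
        """Channel planes in R, G, B order (a single plane for GRAY)."""
        if self.samples.ndim == 2:
            return [self.samples]
        return [self.samples[:, :, k] for k in range(3)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Image8):
            return NotImplemented
        return self.samples.shape == other.samples.shape and bool(
            np.array_equal(self.samples, other.samples)
        )

    def __hash__(self):  # pragma: no cover - images are not meant as dict keys
        return hash((self.samples.shape, self.samples.tobytes()))

    def __repr__(self) -> str:
        return f"Image8({self.height}x{self.width} {self.colorspace})"


@dataclass
class WideImage:
    """A single padded plane whose cells may hold the out-of-band sentinel 256.

    ``samples`` uses a 16-bit dtype so the literal value 256 fits;
    ``sentinel_mask`` marks the padded cells.
    """

    samples: np.ndarray
    sentinel_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.int16)
        if self.sentinel_mask is None:
            self.sentinel_mask = self.samples == SENTINEL
        self.sentinel_mask = np.asarray(self.sentinel_mask, dtype=bool)
        if self.sentinel_mask.shape != self.samples.shape:
            raise ContractError("sentinel mask shape must match samples")
        if not np.all(self.samples[self.sentinel_mask] == SENTINEL):
            raise ContractError("sentinel cells must hold exactly 256")
        off = self.samples[~self.sentinel_mask]
        if off.size and (off.min() < 0 or off.max() > 255):
            raise ContractError("non-sentinel cells must lie in [0, 255]")


def _format_of(path: str, hint: str | None) -> str | None:
    if hint is not None:
        return hint.upper()
    return None


def read_image(path: str | os.PathLike, format_hint: str | None = None) -> Image8:
    """Read a PNG, PGM or JPEG file into an :class:`Image8`.

    16-bit sources raise :class:`FormatError`; they are never rescaled.
    """
    with _PILImage.open(path) as im:
        fmt = _format_of(str(path), format_hint) or im.format
        if fmt == "PGM":
            fmt = "PPM"
        if fmt not in _READ_FORMATS:
            raise FormatError(f"unsupported image format: {im.format!r}")
        if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise FormatError("16-bit and float images are not supported")
        if im.mode == "P":
            im = im.convert("RGB")
        if im.mode not in ("L", "1", "RGB"):
            raise FormatError(f"unsupported pixel mode: {im.mode!r}")
        if im.mode == "1":
            im = im.convert("L")
        arr = np.asarray(im)
    return Image8(arr)


def write_image(img: Image8, path: str | os.PathLike, format: str | None = None) -> None:
    """Write ``img`` losslessly as PNG or PGM; JPEG output is refused."""
    suffix = os.path.splitext(str(path))[1].lower()
    fmt = (format or "").upper() or _WRITE_SUFFIX.get(suffix)
    if fmt == "PGM":
        fmt = "PPM"
    if fmt in ("JPEG", "JPG"):
        raise FormatError("JPEG write is lossy and would destroy the payload")
    if fmt not in ("PNG", "PPM"):
        raise FormatError(f"unsupported output format: {format or suffix!r}")
    if fmt == "PPM" and img.channels != 1:
        raise FormatError("PGM holds a single gray plane; use PNG for RGB")
    _PILImage.fromarray(img.samples).save(path, format=fmt)
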