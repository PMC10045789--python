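"""Knight-tour LSB steganography.

The embedding walks the image with a fixed L-shaped move — three rows down,
one column right, both wrapping — instead of raster order, which scatters
the payload bits over the image. The grid is first padded so the row count
is a multiple of 3 and the column count a multiple of 2, using the
out-of-band sentinel value 256 for padded cells; sentinel cells never carry
payload and the padding is stripped again before the stego image is
returned, so the output has the cover's exact shape.

A bare (3, 1) step on the padded torus closes its orbit before covering the
grid, so the tour chains orbits: whenever the step would revisit a cell the
walk restarts from the first unvisited cell in raster order. The result is
a deterministic permutation of all cells.

Payload framing: the text is 7-bit ASCII, each character stored as 8 bits
MSB-first, preceded by a 32-bit big-endian header holding the body length
in bits. For RGB covers the channels are filled in R, G, B order, each with
its own tour of the same padded grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    CapacityError,
    ContractError,
    EncodingError,
    IntegrityError,
    TruncationError,
)
from .image_io import SENTINEL, Image8, WideImage

__all__ = [
    "KnightPath",
    "PayloadBits",
    "pad_for_tour",
    "strip_padding",
    "knight_path",
    "encode_payload",
    "decode_payload",
    "embed",
    "embed_bits",
    "extract",
    "extract_bits",
]

_HEADER_BITS = 32


@dataclass(frozen=True)
class KnightPath:
    """A full-coverage tour of an ``rows × cols`` grid under the (3, 1) move."""

    cells: tuple
    rows: int
    cols: int

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)


@dataclass(frozen=True)
class PayloadBits:
    """Framed payload: 32-bit big-endian bit-length header + 8-bit ASCII body."""

    bits: np.ndarray

    def __len__(self) -> int:
        return len(self.bits)


def _plane(img) -> np.ndarray:
    if isinstance(img, Image8):
        if img.channels != 1:
            raise ContractError("expected a grayscale image or a single plane")
        return img.samples
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ContractError("expected a 2-D plane")
    return arr


def pad_for_tour(img) -> WideImage:
    """Pad a plane to (multiple of 3) rows × (multiple of 2) columns.

    Added cells hold the sentinel value 256, which cannot occur in 8-bit
    data, and are flagged in the mask.
    """
    plane = _plane(img)
    r, c = plane.shape
    rp = max(3, -(-r // 3) * 3)
    cp = max(2, -(-c // 2) * 2)
    wide = np.full((rp, cp), SENTINEL, dtype=np.int16)
    wide[:r, :c] = plane
    mask = np.ones((rp, cp), dtype=bool)
    mask[:r, :c] = False
    return WideImage(wide, mask)


def strip_padding(wide: WideImage) -> Image8:
    """Inverse of :func:`pad_for_tour`: drop trailing sentinel rows/columns."""
    mask = wide.sentinel_mask
    keep_rows = ~mask.all(axis=1)
    keep_cols = ~mask.all(axis=0)
    r = int(keep_rows.sum())
    c = int(keep_cols.sum())
    if not (keep_rows[:r].all() and keep_cols[:c].all()):
        raise IntegrityError("sentinel cells must form whole trailing rows/columns")
    if mask[:r, :c].any():
        raise IntegrityError("sentinel cell inside the image region")
    return Image8(wide.samples[:r, :c].astype(np.uint8))


def knight_path(rows: int, cols: int) -> KnightPath:
    """The orbit-chained (3, 1) tour of an ``rows × cols`` grid.

    Requires ``rows`` a positive multiple of 3 and ``cols`` a positive
    multiple of 2; these are exactly the padded shapes produced by
    :func:`pad_for_tour`.
    """
    if rows < 3 or rows % 3:
        raise ContractError(f"rows must be a multiple of 3 ≥ 3, got {rows}")
    if cols < 2 or cols % 2:
        raise ContractError(f"cols must be a multiple of 2 ≥ 2, got {cols}")
    visited = np.zeros((rows, cols), dtype=bool)
    cells = []
    raster = 0  # first-unvisited scan pointer, advances monotonically
    total = rows * cols
    r = c = 0
    while len(cells) < total:
        visited[r, c] = True
        cells.append((r, c))
        nr, nc = (r + 3) % rows, (c + 1) % cols
        if visited[nr, nc]:
            while raster < total and visited[raster // cols, raster % cols]:
                raster += 1
            if raster == total:
                break
            nr, nc = raster // cols, raster % cols
        r, c = nr, nc
    return KnightPath(tuple(cells), rows, cols)


def encode_payload(text: str) -> PayloadBits:
    """Frame ASCII text as header + MSB-first 8-bit character codes."""
    try:
        body = text.encode("ascii")
    except UnicodeEncodeError as exc:
        raise EncodingError(f"payload must be ASCII: {exc}") from exc
    if any(b > 127 for b in body):  # pragma: no cover - ascii codec guarantees this
        raise EncodingError("payload must be 7-bit ASCII")
    n_bits = 8 * len(body)
    header = np.frombuffer(n_bits.to_bytes(4, "big"), dtype=np.uint8)
    stream = np.concatenate([header, np.frombuffer(body, dtype=np.uint8)])
    bits = np.unpackbits(stream)
    return PayloadBits(bits.astype(np.uint8))


def decode_payload(bits) -> str:
    """Inverse of :func:`encode_payload`.

    Accepts any 0/1 sequence (e.g. raw LSBs read from an image). A stream
    shorter than the 32-bit header is interpreted as zero-extended, so an
    all-zero image decodes to the empty string; a header that claims more
    body bits than are present raises :class:`TruncationError`.
    """
    if isinstance(bits, PayloadBits):
        bits = bits.bits
    arr = np.asarray(bits, dtype=np.uint8).ravel()
    head = arr[:_HEADER_BITS]
    if head.size < _HEADER_BITS:
        head = np.pad(head, (0, _HEADER_BITS - head.size))
    n_bits = int.from_bytes(np.packbits(head).tobytes(), "big")
    avail = max(0, arr.size - _HEADER_BITS)
    if n_bits > avail:
        raise TruncationError(f"header declares {n_bits} body bits, {avail} present")
    if n_bits % 8:
        raise TruncationError(f"body length {n_bits} is not a whole number of octets")
    body = arr[_HEADER_BITS : _HEADER_BITS + n_bits]
    if n_bits == 0:
        return ""
    codes = np.packbits(body)
    if codes.max() > 127:
        raise EncodingError("embedded body is not 7-bit ASCII")
    return codes.tobytes().decode("ascii")


def _capacity(img: Image8) -> int:
    return img.samples.size


def _tour_order(shape) -> np.ndarray:
    """Flat indices of the non-sentinel cells of a padded plane, in tour order."""
    r, c = shape
    wide = pad_for_tour(np.zeros(shape, dtype=np.uint8))
    path = knight_path(*wide.samples.shape)
    rows = np.array([p[0] for p in path.cells])
    cols = np.array([p[1] for p in path.cells])
    inside = (rows < r) & (cols < c)
    return rows[inside] * c + cols[inside]


def embed_bits(img: Image8, bits) -> Image8:
    """Write raw bits into LSBs along the tour (no framing; low-level API)."""
    bits = np.asarray(bits, dtype=np.uint8).ravel()
    if bits.size and (bits.max() > 1):
        raise ContractError("bits must be 0/1")
    capacity = _capacity(img)
    if bits.size > capacity:
        raise CapacityError(required=bits.size, available=capacity)
    out = [p.copy() for p in img.planes()]
    order = _tour_order(out[0].shape)
    k = 0
    for plane in out:
        if k >= bits.size:
            break
        take = min(bits.size - k, order.size)
        idx = order[:take]
        flat = plane.ravel()
        flat[idx] = (flat[idx] & 0xFE) | bits[k : k + take]
        k += take
    if img.channels == 1:
        return Image8(out[0])
    return Image8(np.stack(out, axis=-1))


def extract_bits(stego: Image8, n: int | None = None) -> np.ndarray:
    """Read LSBs along the tour; ``n=None`` reads every non-sentinel cell."""
    order = _tour_order(stego.planes()[0].shape)
    chunks = [plane.ravel()[order] & 1 for plane in stego.planes()]
    bits = np.concatenate(chunks).astype(np.uint8)
    if n is not None:
        if n > bits.size:
            raise TruncationError(f"requested {n} bits, only {bits.size} available")
        bits = bits[:n]
    return bits


def embed(img: Image8, text: str) -> Image8:
    """Embed framed ASCII text into the cover image's LSBs along the tour."""
    payload = encode_payload(text)
    capacity = _capacity(img)
    if len(payload) > capacity:
        raise CapacityError(required=len(payload), available=capacity)
    return embed_bits(img, payload.bits)


def extract(stego: Image8) -> str:
    """Recover the framed payload text written by :func:`embed`."""
    return decode_payload(extract_bits(stego))
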