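"""Wavelet-packet image compression with entropy coding.

Pipeline (per plane): reversible color transform (RGB only) → full
wavelet-packet decomposition to depth L → optional hard/soft thresholding
→ symbolization (integer coefficients directly; float coefficients are
uniformly quantized) → canonical Huffman coding → self-describing
container.

With integer-lifting arithmetic and no threshold the whole chain is
bit-exact: ``decompress(compress(img)) == img`` for any 8-bit image, gray
or RGB. That is the lossless mode and the default. Float arithmetic plus
a threshold gives the classical lossy trade-off, with distortion equal to
the removed coefficient energy divided by the pixel count (Parseval).

Color handling: the lossless path uses the reversible integer transform
Yr = ⌊(2G + R + B)/4⌋, Vr = R − G, Ur = B − G, whose exact inverse is
G = Yr − ⌊(Vr + Ur)/4⌋. A real-valued YCbCr pair is also provided for
analysis; its decoder inverts the forward matrix numerically (the widely
circulated "nice round numbers" inverse is only approximate and is kept
behind a flag).

Container layout (``.msc``, big-endian throughout)::

    magic   "MSC1"
    u8      version (1)
    u16 u16 height, width
    u8      channels (1 | 3)
    u8      arithmetic (0 lifting, 1 float)
    u8      depth L
    u8      threshold mode (0 none, 1 hard, 2 soft)
    f64     threshold T
    f64     quantization step
    channels ×:
        u32     coefficient count
        u32     alphabet size
        ×:      i32 symbol, u8 canonical code length
        u64     body bit count
        bytes   body (bit-packed, MSB-first)
    u32     CRC-32 of everything after the magic

The Huffman table stores only (symbol, length) pairs; both ends assign
canonical codes by sorting on (length, symbol).
"""

from __future__ import annotations

import heapq
import struct
import zlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ContractError, CorruptionError, FormatError, TruncationError
from .image_io import Image8
from .wavelet import PacketTree, packet_decompose, packet_reconstruct

__all__ = [
    "ThresholdRule",
    "SymbolModel",
    "ColorPlanes",
    "CompressionConfig",
    "CompressedContainer",
    "hard_threshold",
    "soft_threshold",
    "threshold_tree",
    "shannon_entropy",
    "huffman_code_lengths",
    "huffman_encode",
    "huffman_decode",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
    "rct_forward",
    "rct_inverse",
    "compress",
    "decompress",
]

_MAGIC = b"MSC1"
_VERSION = 1
_ARITH_CODE = {"lifting": 0, "float": 1}
_ARITH_NAME = {v: k for k, v in _ARITH_CODE.items()}
_MODE_CODE = {"none": 0, "hard": 1, "soft": 2}
_MODE_NAME = {v: k for k, v in _MODE_CODE.items()}

# Algorithm 3's printed YCbCr forward matrix (rows act on an (R, G, B) column).
_YCBCR_FWD = np.array(
    [[0.3, 0.6, 0.1], [-0.2, -0.3, 0.5], [0.5, -0.4, -0.1]]
)
_YCBCR_INV_EXACT = np.linalg.inv(_YCBCR_FWD)
# The companion printed inverse — close to, but not exactly, inv(_YCBCR_FWD).
_YCBCR_INV_PRINTED = np.array(
    [[1.0, 0.1, 1.3], [1.0, 0.3, -0.5], [1.0, 1.8, -0.1]]
)


# ---------------------------------------------------------------------------
# thresholding


@dataclass(frozen=True)
class ThresholdRule:
    """Coefficient shrinkage rule: ``mode`` in {none, hard, soft}, level T ≥ 0."""

    mode: str = "none"
    T: float = 0.0

    def __post_init__(self):
        if self.mode not in _MODE_CODE:
            raise ContractError(f"unknown threshold mode {self.mode!r}")
        if self.T < 0:
            raise ContractError("threshold T must be non-negative")
        if self.mode == "none" and self.T != 0:
            raise ConfigError("mode 'none' is the identity; it cannot carry T > 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return x
        if self.mode == "hard":
            return hard_threshold(x, self.T)
        return soft_threshold(x, self.T)


def hard_threshold(x, T: float):
    """Keep x where |x| > T, zero elsewhere."""
    if T < 0:
        raise ContractError("threshold T must be non-negative")
    x = np.asarray(x)
    return np.where(np.abs(x) > T, x, np.zeros_like(x))


def soft_threshold(x, T: float):
    """Shrink toward zero: sign(x)·(|x| − T) where |x| > T, else 0."""
    if T < 0:
        raise ContractError("threshold T must be non-negative")
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.maximum(np.abs(x) - T, 0.0)


def threshold_tree(tree: PacketTree, rule: ThresholdRule):
    """Apply ``rule`` to every detail leaf of a packet tree.

    The first DFS leaf (the all-lowpass approximation) is left untouched —
    shrinking the mean brightness of the whole image is never wanted.
    Returns ``(new_tree, removed_energy)`` where ``removed_energy`` is
    Σ(x − y)² over all coefficients; under orthonormal float arithmetic
    this equals the reconstruction SSE by Parseval.
    """
    leaves = tree.leaves()
    removed = 0.0
    new_leaves = []
    for i, leaf in enumerate(leaves):
        if i == 0 or rule.mode == "none":
            new_leaves.append(leaf)
            continue
        y = rule.apply(np.asarray(leaf, dtype=np.float64))
        removed += float(np.sum((np.asarray(leaf, dtype=np.float64) - y) ** 2))
        new_leaves.append(y)
    new = PacketTree.from_leaves(new_leaves, tree.shape, tree.depth, tree.arithmetic)
    return new, removed


# ---------------------------------------------------------------------------
# entropy model and canonical Huffman


@dataclass
class SymbolModel:
    """Empirical symbol distribution over an integer alphabet."""

    alphabet: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.alphabet = np.asarray(self.alphabet)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.alphabet.shape != self.probabilities.shape:
            raise ContractError("alphabet and probabilities must align")
        if np.any(self.probabilities <= 0):
            raise ContractError("included symbols must have positive probability")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ContractError("probabilities must sum to 1")

    @classmethod
    def from_symbols(cls, symbols) -> "SymbolModel":
        vals, counts = np.unique(np.asarray(symbols).ravel(), return_counts=True)
        return cls(vals, counts / counts.sum())

    @property
    def entropy(self) -> float:
        return shannon_entropy(self)


def shannon_entropy(model) -> float:
    """h(s) = −Σ p·log2 p in bits per symbol (0·log 0 := 0)."""
    if isinstance(model, SymbolModel):
        p = model.probabilities
    else:
        p = np.asarray(model, dtype=np.float64)
        p = p[p > 0]
        if abs(p.sum() - 1.0) > 1e-9:
            raise ContractError("probabilities must sum to 1")
    return float(-np.sum(p * np.log2(p)))


def huffman_code_lengths(counts: dict) -> dict:
    """Optimal prefix-code lengths per symbol (Huffman tree depths).

    A single-symbol alphabet gets a 1-bit code so the stream is decodable.
    """
    if not counts:
        raise ContractError("cannot build a code for an empty alphabet")
    if len(counts) == 1:
        (sym,) = counts
        return {sym: 1}
    heap = [(int(c), i, 0, (s,)) for i, (s, c) in enumerate(sorted(counts.items()))]
    heapq.heapify(heap)
    tick = len(heap)
    depth = dict.fromkeys(counts, 0)
    while len(heap) > 1:
        c1, _, d1, s1 = heapq.heappop(heap)
        c2, _, d2, s2 = heapq.heappop(heap)
        for s in s1 + s2:
            depth[s] += 1
        heapq.heappush(heap, (c1 + c2, tick, max(d1, d2) + 1, s1 + s2))
        tick += 1
    return depth


def _canonical_codes(lengths: dict) -> dict:
    """Assign canonical codes: sort by (length, symbol), count upward."""
    code = 0
    prev_len = 0
    out = {}
    for sym, ln in sorted(lengths.items(), key=lambda kv: (kv[1], kv[0])):
        code <<= ln - prev_len
        out[sym] = (code, ln)
        code += 1
        prev_len = ln
    return out


def huffman_encode(symbols):
    """Canonical-Huffman encode an integer sequence.

    Returns ``(data, n_bits, lengths)``: the packed bytes, the exact bit
    count, and the symbol→code-length table needed to decode.
    """
    arr = np.asarray(symbols).ravel()
    if arr.size == 0:
        raise ContractError("cannot encode an empty sequence")
    counts = Counter(arr.tolist())
    lengths = huffman_code_lengths(counts)
    codes = _canonical_codes(lengths)
    strings = {s: format(c, f"0{ln}b") for s, (c, ln) in codes.items()}
    bitstr = "".join(map(strings.__getitem__, arr.tolist()))
    n_bits = len(bitstr)
    bits = np.frombuffer(bitstr.encode("ascii"), dtype=np.uint8) - ord("0")
    return np.packbits(bits).tobytes(), n_bits, lengths


def huffman_decode(data: bytes, lengths: dict, count: int, n_bits: int | None = None):
    """Exact inverse of :func:`huffman_encode` for ``count`` symbols."""
    if count < 0:
        raise ContractError("count must be non-negative")
    if count == 0:
        return np.array([], dtype=np.int64)
    max_len = max(lengths.values())
    # canonical decoding tables: first code value and symbol list per length
    by_len: list = [[] for _ in range(max_len + 1)]
    for sym, ln in sorted(lengths.items(), key=lambda kv: (kv[1], kv[0])):
        by_len[ln].append(sym)
    first = [0] * (max_len + 2)
    code = 0
    for ln in range(1, max_len + 1):
        first[ln] = code
        code = (code + len(by_len[ln])) << 1
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    if n_bits is not None:
        bits = bits[:n_bits]
    bit_list = bits.tolist()
    out = np.empty(count, dtype=np.int64)
    pos = 0
    acc = 0
    ln = 0
    n_out = 0
    n = len(bit_list)
    while n_out < count:
        if pos >= n:
            raise TruncationError(
                f"bit stream exhausted after {n_out} of {count} symbols"
            )
        acc = (acc << 1) | bit_list[pos]
        pos += 1
        ln += 1
        if ln > max_len:
            raise CorruptionError("invalid Huffman code in stream")
        row = by_len[ln]
        idx = acc - first[ln]
        if 0 <= idx < len(row):
            out[n_out] = row[idx]
            n_out += 1
            acc = 0
            ln = 0
    return out


def mean_code_length(lengths: dict, counts: dict) -> float:
    """Average code length L̄ = Σ p·len in bits/symbol for a given stream."""
    total = sum(counts.values())
    return sum(counts[s] * lengths[s] for s in counts) / total


# ---------------------------------------------------------------------------
# color transforms


@dataclass
class ColorPlanes:
    """Either real (Y, Cb, Cr) planes or integer reversible (Yr, Vr, Ur)."""

    kind: str  # "ycbcr" | "rct"
    planes: tuple

    def __post_init__(self):
        if self.kind not in ("ycbcr", "rct"):
            raise ContractError(f"unknown color plane kind {self.kind!r}")


def rgb_to_ycbcr(rgb: Image8) -> ColorPlanes:
    """Real-valued luma/chroma transform with the printed 3×3 matrix."""
    if not isinstance(rgb, Image8) or rgb.channels != 3:
        raise ContractError("rgb_to_ycbcr needs an RGB Image8")
    x = rgb.samples.astype(np.float64)
    out = np.einsum("ij,rcj->rci", _YCBCR_FWD, x)
    return ColorPlanes("ycbcr", (out[:, :, 0], out[:, :, 1], out[:, :, 2]))


def ycbcr_to_rgb(planes: ColorPlanes, approximate: bool = False) -> Image8:
    """Invert :func:`rgb_to_ycbcr`.

    By default the exact numerical inverse of the forward matrix is used;
    ``approximate=True`` selects the traditional rounded inverse instead,
    which does not round-trip exactly.
    """
    if planes.kind != "ycbcr":
        raise ContractError("expected YCbCr planes")
    mat = _YCBCR_INV_PRINTED if approximate else _YCBCR_INV_EXACT
    ycc = np.stack(planes.planes, axis=-1)
    rgb = np.einsum("ij,rcj->rci", mat, ycc)
    return Image8(np.clip(np.round(rgb), 0, 255).astype(np.uint8))


def rct_forward(rgb):
    """Reversible color transform Yr = ⌊(2G+R+B)/4⌋, Vr = R−G, Ur = B−G.

    Accepts an RGB :class:`Image8` (returns :class:`ColorPlanes`) or a
    single (R, G, B) integer triple (returns a (Yr, Vr, Ur) tuple).
    """
    if isinstance(rgb, Image8):
        if rgb.channels != 3:
            raise ContractError("rct_forward needs an RGB image")
        r, g, b = (p.astype(np.int64) for p in rgb.planes())
        yr = (2 * g + r + b) >> 2
        return ColorPlanes("rct", (yr, r - g, b - g))
    r, g, b = (int(v) for v in rgb)
    if not all(0 <= v <= 255 for v in (r, g, b)):
        raise ContractError("RGB samples must lie in [0, 255]")
    return ((2 * g + r + b) >> 2, r - g, b - g)


def rct_inverse(yr, vr=None, ur=None):
    """Exact inverse: G = Yr − ⌊(Vr+Ur)/4⌋, R = G + Vr, B = G + Ur."""
    if isinstance(yr, ColorPlanes):
        if yr.kind != "rct":
            raise ContractError("expected reversible (Yr, Vr, Ur) planes")
        yr_, vr_, ur_ = (np.asarray(p, dtype=np.int64) for p in yr.planes)
        g = yr_ - ((vr_ + ur_) >> 2)
        rgb = np.stack([g + vr_, g, g + ur_], axis=-1)
        return Image8(np.clip(rgb, 0, 255).astype(np.uint8))
    yr_, vr_, ur_ = int(yr), int(vr), int(ur)
    g = yr_ - ((vr_ + ur_) >> 2)
    return (g + vr_, g, g + ur_)


# ---------------------------------------------------------------------------
# container


@dataclass(frozen=True)
class CompressionConfig:
    """End-to-end settings for :func:`compress`.

    Defaults (depth 2, integer lifting, no threshold) are the lossless mode.
    ``quant_step`` only matters for float arithmetic, where coefficients are
    uniformly quantized before coding.
    """

    depth: int = 2
    threshold: ThresholdRule = field(default_factory=ThresholdRule)
    arithmetic: str = "lifting"
    quant_step: float = 1.0

    def __post_init__(self):
        if self.arithmetic not in _ARITH_CODE:
            raise ConfigError(f"unknown arithmetic {self.arithmetic!r}")
        if self.quant_step <= 0:
            raise ConfigError("quantization step must be positive")

    @property
    def lossless(self) -> bool:
        return self.arithmetic == "lifting" and self.threshold.mode == "none"


@dataclass
class _Plane:
    n_coeffs: int
    lengths: dict
    n_bits: int
    body: bytes


@dataclass
class CompressedContainer:
    """Serialized compressed image Z (see module docstring for the layout)."""

    height: int
    width: int
    channels: int
    depth: int
    arithmetic: str
    threshold: ThresholdRule
    quant_step: float
    planes: list

    def to_bytes(self) -> bytes:
        head = struct.pack(
            ">BHHBBBBdd",
            _VERSION,
            self.height,
            self.width,
            self.channels,
            _ARITH_CODE[self.arithmetic],
            self.depth,
            _MODE_CODE[self.threshold.mode],
            float(self.threshold.T),
            float(self.quant_step),
        )
        parts = [head]
        for pl in self.planes:
            parts.append(struct.pack(">II", pl.n_coeffs, len(pl.lengths)))
            for sym, ln in sorted(pl.lengths.items()):
                parts.append(struct.pack(">iB", int(sym), int(ln)))
            parts.append(struct.pack(">Q", pl.n_bits))
            parts.append(pl.body)
        payload = b"".join(parts)
        crc = zlib.crc32(payload) & 0xFFFFFFFF
        return _MAGIC + payload + struct.pack(">I", crc)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "CompressedContainer":
        if len(blob) < 4 or blob[:4] != _MAGIC:
            raise FormatError("not a stegowave container (bad magic)")
        if len(blob) < 4 + 21 + 4:
            raise CorruptionError("container truncated")
        payload, (crc,) = blob[4:-4], struct.unpack(">I", blob[-4:])
        if zlib.crc32(payload) & 0xFFFFFFFF != crc:
            raise CorruptionError("container checksum mismatch")
        off = 0

        def take(fmt):
            nonlocal off
            size = struct.calcsize(fmt)
            if off + size > len(payload):
                raise CorruptionError("container truncated")
            vals = struct.unpack_from(fmt, payload, off)
            off += size
            return vals

        version, h, w, ch, arith, depth, mode, t, step = take(">BHHBBBBdd")
        if version != _VERSION:
            raise FormatError(f"unsupported container version {version}")
        if ch not in (1, 3) or arith not in _ARITH_NAME or mode not in _MODE_NAME:
            raise CorruptionError("invalid container header")
        planes = []
        for _ in range(ch):
            n_coeffs, n_syms = take(">II")
            lengths = {}
            for _ in range(n_syms):
                sym, ln = take(">iB")
                lengths[sym] = ln
            (n_bits,) = take(">Q")
            n_bytes = (n_bits + 7) // 8
            if off + n_bytes > len(payload):
                raise CorruptionError("container truncated")
            body = payload[off : off + n_bytes]
            off += n_bytes
            planes.append(_Plane(n_coeffs, lengths, n_bits, body))
        return cls(h, w, ch, depth, _ARITH_NAME[arith], ThresholdRule(_MODE_NAME[mode], t), step, planes)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @classmethod
    def load(cls, path) -> "CompressedContainer":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())

    @property
    def n_bytes(self) -> int:
        return len(self.to_bytes())


# ---------------------------------------------------------------------------
# end-to-end compress / decompress


def _color_planes(img: Image8) -> list:
    if img.channels == 1:
        return [img.samples.astype(np.int64)]
    cp = rct_forward(img)
    return [np.asarray(p, dtype=np.int64) for p in cp.planes]


def compress(img: Image8, config: CompressionConfig | None = None) -> CompressedContainer:
    """Compress an image into a self-describing container.

    With the default config (lifting, no threshold) the result decompresses
    bit-exactly.
    """
    config = config or CompressionConfig()
    encoded = []
    for plane in _color_planes(img):
        tree = packet_decompose(plane, depth=config.depth, arithmetic=config.arithmetic)
        if config.threshold.mode != "none":
            tree, _ = threshold_tree(tree, config.threshold)
        leaves = tree.leaves()
        flat = np.concatenate([np.asarray(leaf).ravel() for leaf in leaves])
        if config.arithmetic == "float":
            symbols = np.round(flat / config.quant_step).astype(np.int64)
        else:
            symbols = np.round(flat).astype(np.int64)
        body, n_bits, lengths = huffman_encode(symbols)
        encoded.append(_Plane(symbols.size, lengths, n_bits, body))
    return CompressedContainer(
        height=img.height,
        width=img.width,
        channels=img.channels,
        depth=config.depth,
        arithmetic=config.arithmetic,
        threshold=config.threshold,
        quant_step=config.quant_step,
        planes=encoded,
    )


def _decode_plane(container: CompressedContainer, pl: _Plane) -> np.ndarray:
    shape = (container.height, container.width)
    shapes = PacketTree.level_shapes(shape, container.depth)
    leaf_shape = shapes[-1]
    n_leaves = 4**container.depth
    if pl.n_coeffs != n_leaves * leaf_shape[0] * leaf_shape[1]:
        raise CorruptionError("coefficient count disagrees with header geometry")
    symbols = huffman_decode(pl.body, pl.lengths, pl.n_coeffs, n_bits=pl.n_bits)
    if container.arithmetic == "float":
        flat = symbols.astype(np.float64) * container.quant_step
    else:
        flat = symbols
    per_leaf = leaf_shape[0] * leaf_shape[1]
    leaves = [
        flat[i * per_leaf : (i + 1) * per_leaf].reshape(leaf_shape)
        for i in range(n_leaves)
    ]
    tree = PacketTree.from_leaves(leaves, shape, container.depth, container.arithmetic)
    return packet_reconstruct(tree)


def decompress(container: CompressedContainer) -> Image8:
    """Invert :func:`compress`; exact in lossless mode."""
    planes = [_decode_plane(container, pl) for pl in container.planes]
    if container.channels == 1:
        plane = np.clip(np.round(planes[0]), 0, 255).astype(np.uint8)
        return Image8(plane)
    ints = [np.round(p).astype(np.int64) for p in planes]
    return rct_inverse(ColorPlanes("rct", tuple(ints)))


def decompress_float(container: CompressedContainer) -> list:
    """Decoded planes before integer rounding (diagnostics for lossy runs)."""
    return [_decode_plane(container, pl) for pl in container.planes]
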