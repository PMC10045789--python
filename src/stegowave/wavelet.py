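"""Haar wavelet transforms: orthonormal float, integer lifting, and packets.

Two arithmetics implement the same 2-tap Haar filter bank:

* ``float`` — the orthonormal analysis pair h = (1/√2, 1/√2),
  g = (1/√2, −1/√2), applied separably (columns then rows) with
  downsampling by 2. Energy is preserved (Parseval), which makes
  distortion bookkeeping exact: the MSE introduced by zeroing
  coefficients equals the removed coefficient energy divided by the
  pixel count.
* ``lifting`` — the integer S-transform factorization of the same step:
  s = ⌊(x0 + x1)/2⌋, d = x0 − x1, inverted exactly by
  x0 = s + ⌊(d + 1)/2⌋, x1 = x0 − d. Bit-exact on integers, so the
  compression path built on it is genuinely lossless.

Odd-sized inputs are extended by replicating the last row/column
(symmetric half-sample extension) before each level; the original shape
is recorded so inversion crops back exactly.

``packet_decompose`` builds the full wavelet-packet quad-tree: every
subband of every node is decomposed recursively to the requested depth
(4^L leaves), unlike the pyramid :func:`multilevel_dwt2` which recurses
only on the approximation band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

__all__ = [
    "WaveletSpec",
    "HAAR",
    "SubbandSet",
    "PacketTree",
    "haar_dwt2",
    "haar_idwt2",
    "lifting_haar_fwd",
    "lifting_haar_inv",
    "multilevel_dwt2",
    "multilevel_idwt2",
    "packet_decompose",
    "packet_reconstruct",
]

_SQRT2 = math.sqrt(2.0)
_MAX_DEPTH = 12


@dataclass(frozen=True)
class WaveletSpec:
    """Analysis filter pair (h low-pass, g high-pass) of an orthogonal wavelet."""

    name: str
    h: tuple
    g: tuple


#: the Haar pair; satisfies Σh² = Σg² = 1 and Σ h·g = 0 (orthogonal quadrature)
HAAR = WaveletSpec("haar", (1.0 / _SQRT2, 1.0 / _SQRT2), (1.0 / _SQRT2, -1.0 / _SQRT2))


@dataclass
class SubbandSet:
    """One level of a separable 2-D decomposition.

    ``ll`` approximation, ``lh`` horizontal detail, ``hl`` vertical detail,
    ``hh`` diagonal detail. ``shape`` is the (pre-extension) parent shape
    needed to undo the transform exactly.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    level: int
    shape: tuple

    def bands(self):
        return (self.ll, self.lh, self.hl, self.hh)


def _extend_even(x: np.ndarray) -> np.ndarray:
    r, c = x.shape
    if r % 2 or c % 2:
        x = np.pad(x, ((0, r % 2), (0, c % 2)), mode="edge")
    return x


def _check_plane(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 2 or arr.size == 0:
        raise ContractError("expected a non-empty 2-D matrix")
    return arr


# ---------------------------------------------------------------------------
# orthonormal float arithmetic


def haar_dwt2(img) -> SubbandSet:
    """One level of the separable orthonormal 2-D Haar transform."""
    x = _check_plane(img).astype(np.float64)
    shape = x.shape
    x = _extend_even(x)
    lo = (x[:, ::2] + x[:, 1::2]) / _SQRT2
    hi = (x[:, ::2] - x[:, 1::2]) / _SQRT2
    ll = (lo[::2] + lo[1::2]) / _SQRT2
    lh = (lo[::2] - lo[1::2]) / _SQRT2
    hl = (hi[::2] + hi[1::2]) / _SQRT2
    hh = (hi[::2] - hi[1::2]) / _SQRT2
    return SubbandSet(ll, lh, hl, hh, level=1, shape=shape)


def haar_idwt2(bands: SubbandSet) -> np.ndarray:
    """Exact (to float precision) inverse of :func:`haar_dwt2`."""
    ll, lh, hl, hh = (np.asarray(b, dtype=np.float64) for b in bands.bands())
    if not (ll.shape == lh.shape == hl.shape == hh.shape):
        raise ContractError("subband shapes are inconsistent")
    hr, hc = ll.shape
    lo = np.empty((2 * hr, hc))
    hi = np.empty((2 * hr, hc))
    lo[::2] = (ll + lh) / _SQRT2
    lo[1::2] = (ll - lh) / _SQRT2
    hi[::2] = (hl + hh) / _SQRT2
    hi[1::2] = (hl - hh) / _SQRT2
    x = np.empty((2 * hr, 2 * hc))
    x[:, ::2] = (lo + hi) / _SQRT2
    x[:, 1::2] = (lo - hi) / _SQRT2
    r, c = bands.shape
    return x[:r, :c]


# ---------------------------------------------------------------------------
# integer lifting (S-transform) arithmetic


def lifting_haar_fwd(x0, x1):
    """Integer mean/difference step: s = ⌊(x0+x1)/2⌋, d = x0 − x1."""
    x0 = np.asarray(x0, dtype=np.int64)
    x1 = np.asarray(x1, dtype=np.int64)
    s = (x0 + x1) >> 1
    d = x0 - x1
    if s.ndim == 0:
        return int(s), int(d)
    return s, d


def lifting_haar_inv(s, d):
    """Exact inverse: x0 = s + ⌊(d+1)/2⌋, x1 = x0 − d."""
    s = np.asarray(s, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    x0 = s + ((d + 1) >> 1)
    x1 = x0 - d
    if x0.ndim == 0:
        return int(x0), int(x1)
    return x0, x1


def _lifting_dwt2(img) -> SubbandSet:
    x = np.asarray(_check_plane(img), dtype=np.int64)
    shape = x.shape
    x = _extend_even(x)
    lo, hi = lifting_haar_fwd(x[:, ::2], x[:, 1::2])
    ll, lh = lifting_haar_fwd(lo[::2], lo[1::2])
    hl, hh = lifting_haar_fwd(hi[::2], hi[1::2])
    return SubbandSet(ll, lh, hl, hh, level=1, shape=shape)


def _lifting_idwt2(bands: SubbandSet) -> np.ndarray:
    ll, lh, hl, hh = (np.asarray(b, dtype=np.int64) for b in bands.bands())
    hr, hc = ll.shape
    lo = np.empty((2 * hr, hc), dtype=np.int64)
    hi = np.empty((2 * hr, hc), dtype=np.int64)
    lo[::2], lo[1::2] = lifting_haar_inv(ll, lh)
    hi[::2], hi[1::2] = lifting_haar_inv(hl, hh)
    x = np.empty((2 * hr, 2 * hc), dtype=np.int64)
    x[:, ::2], x[:, 1::2] = lifting_haar_inv(lo, hi)
    r, c = bands.shape
    return x[:r, :c]


_STEP = {"float": (haar_dwt2, haar_idwt2), "lifting": (_lifting_dwt2, _lifting_idwt2)}


def _steps(arithmetic: str):
    try:
        return _STEP[arithmetic]
    except KeyError:
        raise ContractError(f"unknown arithmetic {arithmetic!r}") from None


# ---------------------------------------------------------------------------
# pyramid (multilevel) decomposition


def multilevel_dwt2(img, levels: int = 2, arithmetic: str = "float") -> list:
    """Pyramid decomposition: each level re-decomposes the previous LL band."""
    x = _check_plane(img)
    if levels < 1:
        raise ContractError("levels must be ≥ 1")
    if 2**levels > max(x.shape):
        raise ContractError(f"{levels} levels is too deep for shape {x.shape}")
    fwd, _ = _steps(arithmetic)
    chain = []
    cur = x
    for lev in range(1, levels + 1):
        bands = fwd(cur)
        bands.level = lev
        chain.append(bands)
        cur = bands.ll
    return chain


def multilevel_idwt2(chain: list, arithmetic: str = "float") -> np.ndarray:
    """Inverse of :func:`multilevel_dwt2`."""
    _, inv = _steps(arithmetic)
    cur = None
    for bands in reversed(chain):
        if cur is not None:
            bands = SubbandSet(cur, bands.lh, bands.hl, bands.hh, bands.level, bands.shape)
        cur = inv(bands)
    return cur


# ---------------------------------------------------------------------------
# wavelet packets (full quad-tree)


@dataclass
class _Node:
    shape: tuple
    children: list | None = None
    data: np.ndarray | None = None


@dataclass
class PacketTree:
    """Full wavelet-packet quad-tree of depth L (4^L leaves)."""

    root: _Node
    depth: int
    arithmetic: str
    shape: tuple = field(init=False)

    def __post_init__(self):
        self.shape = self.root.shape

    def leaves(self) -> list:
        """Leaf coefficient matrices in depth-first LL, LH, HL, HH order."""
        out = []

        def walk(node):
            if node.children is None:
                out.append(node.data)
            else:
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return out

    @staticmethod
    def level_shapes(shape: tuple, depth: int) -> list:
        """Node shape per level; all nodes of one level share a shape."""
        shapes = [tuple(shape)]
        for _ in range(depth):
            r, c = shapes[-1]
            shapes.append(((r + r % 2) // 2, (c + c % 2) // 2))
        return shapes

    @classmethod
    def from_leaves(cls, leaves, shape, depth, arithmetic) -> "PacketTree":
        """Rebuild a tree from its DFS leaf list (container deserialization)."""
        if len(leaves) != 4**depth:
            raise ContractError(f"expected {4 ** depth} leaves, got {len(leaves)}")
        shapes = cls.level_shapes(shape, depth)
        it = iter(leaves)

        def build(level):
            if level == depth:
                return _Node(shape=shapes[level], data=next(it))
            return _Node(shape=shapes[level], children=[build(level + 1) for _ in range(4)])

        return cls(root=build(0), depth=depth, arithmetic=arithmetic)


def packet_decompose(img, depth: int = 2, arithmetic: str = "lifting") -> PacketTree:
    """Decompose ALL subbands recursively to ``depth`` (wavelet packets)."""
    x = _check_plane(img)
    if not 1 <= depth <= _MAX_DEPTH:
        raise ContractError(f"depth must be in [1, {_MAX_DEPTH}], got {depth}")
    fwd, _ = _steps(arithmetic)

    def build(mat, level):
        node = _Node(shape=mat.shape)
        if level == depth:
            node.data = np.asarray(mat)
            return node
        bands = fwd(mat)
        node.children = [build(b, level + 1) for b in bands.bands()]
        return node

    return PacketTree(root=build(x, 0), depth=depth, arithmetic=arithmetic)


def packet_reconstruct(tree: PacketTree) -> np.ndarray:
    """Invert :func:`packet_decompose`; bit-exact under lifting arithmetic."""
    _, inv = _steps(tree.arithmetic)

    def rebuild(node):
        if node.children is None:
            return node.data
        ll, lh, hl, hh = (rebuild(ch) for ch in node.children)
        return inv(SubbandSet(ll, lh, hl, hh, level=0, shape=node.shape))

    return rebuild(tree.root)
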