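"""Deterministic synthetic phantoms and patient-record-like payloads.

Nothing here downloads or resembles real patient data; the phantoms are
simple analytic scenes chosen to span the regimes that matter for the
pipeline: ``constant`` (trivially compressible), ``gradient`` (smooth),
``ellipse`` (nested elliptical structures on a dark background, the
closest stand-in for a tomographic slice), and ``speckle`` (full-entropy
noise, the worst case for the entropy coder). All randomness flows from
an explicit integer seed; the same spec always yields a bit-identical
image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .image_io import Image8

__all__ = ["PhantomSpec", "generate_phantom", "generate_payload", "KINDS"]

KINDS = ("constant", "gradient", "ellipse", "speckle")

_GIVEN = ("Alex", "Bline", "Chandra", "Devi", "Elif", "Farid", "Gia", "Hana")
_DIAGNOSES = ("ICH", "SAH", "SDH", "TBI", "CVA", "TIA", "MEN", "GBM")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom image."""

    rows: int
    cols: int
    kind: str = "ellipse"
    noise_sd: float = 0.0
    seed: int = 0
    level: int = 128  # base intensity for the constant phantom
    rgb: bool = False

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ContractError("phantom dimensions must be positive")
        if self.kind not in KINDS:
            raise ContractError(f"unknown phantom kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be non-negative")


def _ellipse_mask(rows, cols, cy, cx, ry, rx, angle):
    yy, xx = np.mgrid[0:rows, 0:cols]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    return (u / max(rx, 1e-9)) ** 2 + (v / max(ry, 1e-9)) ** 2 <= 1.0


def _base_plane(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    r, c = spec.rows, spec.cols
    if spec.kind == "constant":
        return np.full((r, c), float(spec.level))
    if spec.kind == "gradient":
        ramp = np.linspace(0.0, 255.0, c)[None, :] * 0.7
        ramp = ramp + np.linspace(0.0, 255.0, r)[:, None] * 0.3
        return ramp
    if spec.kind == "speckle":
        return rng.integers(0, 256, size=(r, c)).astype(np.float64)
    # nested-ellipse phantom: dark background, three concentric tissues
    img = np.full((r, c), 20.0)
    cy, cx = (r - 1) / 2.0, (c - 1) / 2.0
    angle = rng.uniform(0, np.pi)
    for scale, intensity in ((0.45, 90.0), (0.30, 150.0), (0.14, 215.0)):
        ry = max(scale * r, 0.5)
        rx = max(scale * c * 0.8, 0.5)
        img[_ellipse_mask(r, c, cy, cx, ry, rx, angle)] = intensity
    return img


def generate_phantom(spec: PhantomSpec) -> Image8:
    """Render a phantom image deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    n_planes = 3 if spec.rgb else 1
    planes = []
    for _ in range(n_planes):
        plane = _base_plane(spec, rng)
        if spec.noise_sd > 0:
            plane = plane + rng.normal(0.0, spec.noise_sd, size=plane.shape)
        planes.append(np.clip(np.round(plane), 0, 255).astype(np.uint8))
    if spec.rgb:
        return Image8(np.stack(planes, axis=-1))
    return Image8(planes[0])


def generate_payload(n_chars: int, seed: int = 0) -> str:
    """A deterministic ASCII record like ``ID:…;Name:…;Dx:…;Date:…`` of
    exactly ``n_chars`` characters."""
    if n_chars < 0:
        raise ContractError("payload length must be non-negative")
    if n_chars == 0:
        return ""
    rng = np.random.default_rng(seed)
    fields = []
    while sum(len(f) for f in fields) < n_chars:
        pid = rng.integers(10_000, 1_000_000)
        name = _GIVEN[rng.integers(0, len(_GIVEN))]
        dx = _DIAGNOSES[rng.integers(0, len(_DIAGNOSES))]
        day = rng.integers(1, 29)
        month = rng.integers(1, 13)
        fields.append(f"ID:{pid};Name:{name};Dx:{dx};Date:2023-{month:02d}-{day:02d};")
    return "".join(fields)[:n_chars]
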