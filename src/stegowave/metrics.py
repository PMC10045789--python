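"""Image and payload quality measures.

MSE, SNR, PSNR (peak 255), SSIM, bit error rate, and the two size
statistics used for compression reporting: the compression ratio
``100·compressed/original`` and its complement, the compression
percentage ``100·(1 − compressed/original)``.

SSIM follows the standard published form: 11×11 Gaussian window with
σ = 1.5, stabilizers K1 = 0.01, K2 = 0.03 on a dynamic range of 255,
population (not sample) local statistics, edge pixels within half a
window of the border excluded from the mean. Identical images score
exactly 1. RGB pairs score the mean of the per-channel indices.

Identical-image PSNR/SNR return ``math.inf`` rather than raising —
lossless comparisons are the common case here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError
from .image_io import Image8

__all__ = [
    "QualityReport",
    "mse",
    "psnr",
    "psnr_from_mse",
    "snr",
    "ssim",
    "ber",
    "compression_stats",
    "quality_report",
]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius int(3.5 * 1.5 + 0.5) = 5 → 11×11 window
_SSIM_PAD = 5
_K1, _K2, _L = 0.01, 0.03, 255.0


def _arr(x) -> np.ndarray:
    if isinstance(x, Image8):
        return x.samples
    return np.asarray(x)


def _pair(a, b):
    a, b = _arr(a), _arr(b)
    if a.shape != b.shape:
        raise ContractError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a.astype(np.float64), b.astype(np.float64)


def mse(a, b) -> float:
    """Mean squared sample difference."""
    a, b = _pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr_from_mse(mse_value: float, peak: float = 255.0) -> float:
    """10·log10(peak²/MSE) in dB; MSE = 0 maps to +inf."""
    if mse_value < 0:
        raise ContractError("MSE cannot be negative")
    if mse_value == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse_value)


def psnr(a, b, peak: float = 255.0) -> float:
    return psnr_from_mse(mse(a, b), peak=peak)


def snr(a, b) -> float:
    """10·log10(Σa² / Σ(a−b)²) in dB, referenced to the first image."""
    a, b = _pair(a, b)
    sig = float(np.sum(a * a))
    if sig == 0:
        raise ContractError("SNR undefined for an all-zero reference")
    noise = float(np.sum((a - b) ** 2))
    if noise == 0:
        return math.inf
    return 10.0 * math.log10(sig / noise)


def _ssim_plane(x: np.ndarray, y: np.ndarray) -> float:
    c1 = (_K1 * _L) ** 2
    c2 = (_K2 * _L) ** 2
    f = lambda z: gaussian_filter(z, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)
    ux, uy = f(x), f(y)
    vx = f(x * x) - ux * ux
    vy = f(y * y) - uy * uy
    vxy = f(x * y) - ux * uy
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    core = s[_SSIM_PAD:-_SSIM_PAD, _SSIM_PAD:-_SSIM_PAD]
    return float(core.mean())


def ssim(a, b) -> float:
    """Mean local structural similarity in [−1, 1]; 1 iff identical."""
    a, b = _pair(a, b)
    if min(a.shape[0], a.shape[1]) < 2 * _SSIM_PAD + 1:
        raise ContractError("image smaller than the 11×11 SSIM window")
    if a.ndim == 2:
        return _ssim_plane(a, b)
    return float(np.mean([_ssim_plane(a[..., k], b[..., k]) for k in range(a.shape[-1])]))


def ber(sent, received):
    """Bit error rate: (error count, error percentage)."""
    s = np.asarray(sent).ravel()
    r = np.asarray(received).ravel()
    if s.size != r.size:
        raise ContractError(f"bit sequences differ in length: {s.size} vs {r.size}")
    if s.size == 0:
        return 0, 0.0
    count = int(np.count_nonzero(s != r))
    return count, 100.0 * count / s.size


def compression_stats(original_bytes: int, compressed_bytes: int):
    """(cr%, cp%) = (100·compressed/original, 100·(1 − compressed/original))."""
    if original_bytes <= 0:
        raise ContractError("original size must be positive")
    ratio = compressed_bytes / original_bytes
    return 100.0 * ratio, 100.0 * (1.0 - ratio)


@dataclass
class QualityReport:
    """Flat bundle of the standard evaluation measures for one image pair."""

    mse: float
    snr: float
    psnr: float
    ssim: float
    ber_count: int | None = None
    ber_ratio: float | None = None
    cr_percent: float | None = None
    cp_percent: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def quality_report(
    a,
    b,
    sent_bits=None,
    received_bits=None,
    original_bytes: int | None = None,
    compressed_bytes: int | None = None,
) -> QualityReport:
    """Compute every applicable measure for a reference/test image pair."""
    rep = QualityReport(mse=mse(a, b), snr=snr(a, b), psnr=psnr(a, b), ssim=ssim(a, b))
    if sent_bits is not None and received_bits is not None:
        rep.ber_count, rep.ber_ratio = ber(sent_bits, received_bits)
    if original_bytes is not None and compressed_bytes is not None:
        rep.cr_percent, rep.cp_percent = compression_stats(original_bytes, compressed_bytes)
    return rep
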