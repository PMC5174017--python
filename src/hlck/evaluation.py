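"""Rate-distortion reporting and the analytic memory models.

PSNR is computed per slice against the original volume,
``10 log10(peak^2 / MSE)`` with ``peak = 2**bit_depth - 1``, matching the
Slice-1..Slice-S reporting convention for 8-slice test volumes. The memory
models are closed-form worst-case expressions: the listless coder needs only
its marker state table (half a byte per coefficient plus the static table),
whereas a list-based SPIHT coder's auxiliary lists grow with the number of
entries times their addressing width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hlck_codec import EmbeddedBitstream, decode_volume, encode_volume, \
    truncate_bitstream
from .volume_io import Volume

__all__ = [
    "RateDistortionPoint",
    "psnr",
    "rd_sweep",
    "hlck_state_memory",
    "hlck_total_memory",
    "spiht_list_memory",
    "jyotheswar_memory",
]


@dataclass
class RateDistortionPoint:
    rate_bpp: float
    psnr_per_slice: np.ndarray   # (S,) dB; +inf for an identical slice
    psnr_mean: float


def psnr(orig: Volume, recon: Volume) -> RateDistortionPoint:
    """Per-slice and mean PSNR of a reconstruction (rate field set to nan)."""
    if orig.shape != recon.shape:
        raise ValueError(f"shape mismatch: {orig.shape} vs {recon.shape}")
    if orig.bit_depth != recon.bit_depth:
        raise ValueError("bit depth mismatch")
    diff = orig.data.astype(np.float64) - recon.data.astype(np.float64)
    mse = (diff ** 2).mean(axis=(1, 2))
    peak2 = float(orig.peak) ** 2
    with np.errstate(divide="ignore"):
        per_slice = np.where(mse > 0, 10.0 * np.log10(peak2 / np.maximum(mse, 1e-300)),
                             np.inf)
    return RateDistortionPoint(rate_bpp=float("nan"),
                               psnr_per_slice=per_slice,
                               psnr_mean=float(np.mean(per_slice)))


def rd_sweep(vol: Volume, rates: list[float],
             **codec_params) -> list[RateDistortionPoint]:
    """One encode at the top rate; every lower rate by stream truncation.

    Truncation decoding is exactly equivalent to encoding directly at the
    lower rate (embedded property), so the sweep costs a single encode.
    """
    rates = list(rates)
    if not rates or any(r <= 0 for r in rates) or sorted(rates) != rates:
        raise ValueError("rates must be positive and ascending")
    bs = encode_volume(vol, rate_bpp=rates[-1], **codec_params)
    n_vox = vol.data.size
    points = []
    for r in rates:
        cut = truncate_bitstream(bs, int(round(r * n_vox)))
        pt = psnr(vol, decode_volume(cut))
        pt.rate_bpp = r
        points.append(pt)
    return points


# ---------------------------------------------------------------------------
# analytic memory models (exact arithmetic, reporting only)
# ---------------------------------------------------------------------------

def hlck_state_memory(R: int, C: int, L: int) -> float:
    """Marker state memory in bytes: R*C/2 dynamic + (8L+1)/2 static."""
    _check_pos(R=R, C=C, L=L)
    return R * C / 2 + (8 * L + 1) / 2


def hlck_total_memory(R: int, C: int, L: int, S: int, Y: int) -> float:
    """State memory plus the S*I*Y-byte coefficient array (Y bytes/coeff)."""
    _check_pos(R=R, C=C, L=L, S=S, Y=Y)
    return S * R * C * Y + hlck_state_memory(R, C, L)


def spiht_list_memory(R: int, C: int, Y_bits: int) -> float:
    """Worst-case 3D-SPIHT auxiliary-list memory in bytes.

    With N_LIP + N_LSP = 3RC and N_LIS = 3RC/4 entries, Y_bits of
    addressing per entry plus one type bit per LIS entry:
    [Y*(N_LIP + N_LIS + N_LSP) + N_LIS] / 8.
    """
    _check_pos(R=R, C=C)
    if Y_bits < 0:
        raise ValueError("Y_bits must be >= 0")
    n_lip_lsp = 3 * R * C
    n_lis = 3 * R * C / 4
    return (Y_bits * (n_lip_lsp + n_lis) + n_lis) / 8


def jyotheswar_memory(R: int, C: int, Y_bits: int, planes: int = 1) -> float:
    """Comparison coder's state memory, (37/16 + 5/16*(Y+1))*R*C*planes bytes."""
    _check_pos(R=R, C=C, planes=planes)
    return (37 / 16 + 5 / 16 * (Y_bits + 1)) * R * C * planes


def _check_pos(**kw: int) -> None:
    for name, v in kw.items():
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v}")
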