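"""3D hybrid transform: spectral KLT across slices, spatial 2D DWT per slice.

The slice axis of a volumetric scan is strongly correlated; a Karhunen-Loeve
transform (the eigenbasis of the inter-slice sample covariance) decorrelates
it optimally in the mean-square sense. Each decorrelated component image is
then decomposed with an L-level separable 2D lifting wavelet:

* ``cdf97`` — Cohen-Daubechies-Feauveau 9/7, the lossy workhorse filter,
  implemented by its four-step lifting factorization with a final scaling
  that gives the lowpass branch a DC gain of ~sqrt(2) per level;
* ``cdf53`` — the integer-reversible 5/3 lifting (floor-rounded steps), so
  the spatial stage is exactly invertible on integer input.

Boundaries use whole-sample symmetric extension. Real coefficients are made
bit-plane-codable by uniform scalar quantization: multiply by 2**qscale and
round half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = [
    "KLTBasis",
    "HybridCoefficients",
    "klt_forward",
    "klt_inverse",
    "dwt2d",
    "idwt2d",
    "hybrid_forward",
    "hybrid_inverse",
    "FILTERS",
    "DEFAULT_QSCALE",
]

FILTERS = ("cdf97", "cdf53")
DEFAULT_QSCALE = {"cdf97": 4, "cdf53": 0}

_ORTHO_TOL = 1e-9


# ---------------------------------------------------------------------------
# Spectral stage: Karhunen-Loeve transform along the slice axis
# ---------------------------------------------------------------------------

@dataclass
class KLTBasis:
    """Per-volume KLT sidecar: slice means and covariance eigenbasis."""

    mean: np.ndarray          # (S,) per-slice mean over voxel positions
    eigenvectors: np.ndarray  # (S, S) orthonormal, columns by falling eigenvalue
    eigenvalues: np.ndarray   # (S,) nonincreasing, >= 0

    def validate(self) -> None:
        S = self.mean.shape[0]
        if self.eigenvectors.shape != (S, S):
            raise ValueError("eigenvector matrix shape mismatch")
        g = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(g, np.eye(S), atol=1e-8):
            raise ValueError("eigenvector matrix is not orthonormal")


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude entry of each column nonnegative.

    Eigenvectors are only defined up to sign; pinning the sign makes the
    coefficient arrays (and hence bitstreams) reproducible across runs and
    LAPACK builds.
    """
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def klt_forward(vol: Volume) -> tuple[np.ndarray, KLTBasis]:
    """Decorrelate the slice axis; returns component images and the basis."""
    X = vol.data.astype(np.float64)
    S = X.shape[0]
    if S == 1:
        basis = KLTBasis(mean=np.zeros(1), eigenvectors=np.eye(1),
                         eigenvalues=np.zeros(1))
        return X.copy(), basis

    mean = X.mean(axis=(1, 2))
    Xc = X - mean[:, None, None]
    flat = Xc.reshape(S, -1)
    cov = (flat @ flat.T) / flat.shape[1]
    w, V = np.linalg.eigh(cov)          # ascending
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = _fix_signs(V[:, order])
    components = np.tensordot(V.T, Xc, axes=(1, 0))
    basis = KLTBasis(mean=mean, eigenvectors=V, eigenvalues=w)
    return components, basis


def klt_inverse(components: np.ndarray, basis: KLTBasis) -> np.ndarray:
    """Rebuild the (real-valued) slice stack from KLT components."""
    basis.validate()
    if components.shape[0] != basis.mean.shape[0]:
        raise ValueError("component count does not match basis size")
    X = np.tensordot(basis.eigenvectors, components, axes=(1, 0))
    return X + basis.mean[:, None, None]


# ---------------------------------------------------------------------------
# Spatial stage: 1D lifting kernels (whole-sample symmetric boundaries)
# ---------------------------------------------------------------------------

# CDF 9/7 lifting constants (Daubechies-Sweldens factorization)
_A = -1.586134342059924
_B = -0.052980118572961
_G = 0.882911075530934
_D = 0.443506852043971
_Z = 1.149604398860098   # scaling: lowpass DC gain ~ sqrt(2)


def _shift_l(a: np.ndarray) -> np.ndarray:
    """a[n+1] with whole-sample symmetric tail (a[N] := a[N-1])."""
    return np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)


def _shift_r(a: np.ndarray) -> np.ndarray:
    """a[n-1] with whole-sample symmetric head (a[-1] := a[0])."""
    return np.concatenate([a[..., :1], a[..., :-1]], axis=-1)


def _fwd97(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = x[..., 0::2].copy()
    d = x[..., 1::2].copy()
    d += _A * (s + _shift_l(s))
    s += _B * (_shift_r(d) + d)
    d += _G * (s + _shift_l(s))
    s += _D * (_shift_r(d) + d)
    return s * _Z, d / _Z


def _inv97(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    s = s / _Z
    d = d * _Z
    s -= _D * (_shift_r(d) + d)
    d -= _G * (s + _shift_l(s))
    s -= _B * (_shift_r(d) + d)
    d -= _A * (s + _shift_l(s))
    x = np.empty(s.shape[:-1] + (2 * s.shape[-1],), dtype=np.float64)
    x[..., 0::2] = s
    x[..., 1::2] = d
    return x


def _fwd53(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = x[..., 0::2].copy()
    d = x[..., 1::2].copy()
    d -= np.floor((s + _shift_l(s)) / 2)
    s += np.floor((_shift_r(d) + d + 2) / 4)
    return s, d


def _inv53(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    s = s - np.floor((_shift_r(d) + d + 2) / 4)
    d = d + np.floor((s + _shift_l(s)) / 2)
    x = np.empty(s.shape[:-1] + (2 * s.shape[-1],), dtype=np.float64)
    x[..., 0::2] = s
    x[..., 1::2] = d
    return x


_FWD = {"cdf97": _fwd97, "cdf53": _fwd53}
_INV = {"cdf97": _inv97, "cdf53": _inv53}


def _check_filter(filter_id: str) -> None:
    if filter_id not in FILTERS:
        raise ValueError(f"unknown filter {filter_id!r}; expected {FILTERS}")


def dwt2d(plane: np.ndarray, L: int, filter_id: str) -> np.ndarray:
    """L-level separable 2D DWT in Mallat layout.

    LL_l lands in the top-left 2**-l corner; at each level the top-right,
    bottom-left and bottom-right quadrants hold the HL, LH and HH subbands.
    """
    _check_filter(filter_id)
    R, C = plane.shape
    if L < 1 or R % (1 << L) or C % (1 << L):
        raise ValueError(f"2^L must divide plane dimensions (L={L}, {R}x{C})")
    fwd = _FWD[filter_id]
    out = plane.astype(np.float64).copy()
    for lev in range(L):
        n_r, n_c = R >> lev, C >> lev
        sub = out[:n_r, :n_c]
        s, d = fwd(sub)                       # along columns axis
        sub = np.concatenate([s, d], axis=1)
        s, d = fwd(sub.T)                     # along rows axis
        out[:n_r, :n_c] = np.concatenate([s, d], axis=1).T
    return out


def idwt2d(coeffs: np.ndarray, L: int, filter_id: str) -> np.ndarray:
    """Inverse of :func:`dwt2d`."""
    _check_filter(filter_id)
    R, C = coeffs.shape
    if L < 1 or R % (1 << L) or C % (1 << L):
        raise ValueError(f"2^L must divide plane dimensions (L={L}, {R}x{C})")
    inv = _INV[filter_id]
    out = coeffs.astype(np.float64).copy()
    for lev in range(L - 1, -1, -1):
        n_r, n_c = R >> lev, C >> lev
        sub = out[:n_r, :n_c].T
        sub = inv(sub[:, :n_r // 2], sub[:, n_r // 2:]).T   # rows axis
        out[:n_r, :n_c] = inv(sub[:, :n_c // 2], sub[:, n_c // 2:])
    return out


# ---------------------------------------------------------------------------
# Full hybrid transform with quantization
# ---------------------------------------------------------------------------

@dataclass
class HybridCoefficients:
    """Quantized integer transform coefficients plus inversion sidecar."""

    coeffs: np.ndarray      # (S, R, C) int64; slice s = pyramid of component s
    levels: int
    filter_id: str
    qscale: int
    basis: KLTBasis


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def hybrid_forward(vol: Volume, L: int, filter_id: str,
                   qscale: int | None = None) -> HybridCoefficients:
    """KLT across slices, per-component 2D DWT, uniform quantization."""
    _check_filter(filter_id)
    if qscale is None:
        qscale = DEFAULT_QSCALE[filter_id]
    if qscale < 0:
        raise ValueError("qscale must be >= 0")
    vol.validate_for_codec(L)
    components, basis = klt_forward(vol)
    S = components.shape[0]
    coeffs = np.empty_like(components)
    for s in range(S):
        coeffs[s] = dwt2d(components[s], L, filter_id)
    q = _round_half_away(np.ldexp(coeffs, qscale)).astype(np.int64)
    return HybridCoefficients(coeffs=q, levels=L, filter_id=filter_id,
                              qscale=qscale, basis=basis)


def hybrid_inverse(hc: HybridCoefficients, bit_depth: int,
                   source: str = "decoded") -> Volume:
    """Dequantize, inverse DWT per slice, inverse KLT, round and clamp."""
    _check_filter(hc.filter_id)
    S = hc.coeffs.shape[0]
    deq = np.ldexp(hc.coeffs.astype(np.float64), -hc.qscale)
    components = np.empty_like(deq)
    for s in range(S):
        components[s] = idwt2d(deq[s], hc.levels, hc.filter_id)
    X = klt_inverse(components, hc.basis)
    data = np.clip(_round_half_away(X), 0, (1 << bit_depth) - 1)
    return Volume(data=data.astype(np.int64), bit_depth=bit_depth,
                  source=source)
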