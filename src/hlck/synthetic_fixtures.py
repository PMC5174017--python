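"""Deterministic synthetic volumes with codec-relevant statistics.

Real volumetric test material (brain MRI, DICOM knee, angiogram series) is
not redistributable, so the test and evaluation fixtures are generated:
volumes with strong inter-slice correlation and smooth spatial structure —
the two properties the spectral KLT and the spatial wavelet respectively
exploit. The default geometry is an 8-slice stack of 128x128 8-bit slices.

Models
------
``blobs``
    A sum of randomly placed 2D Gaussian intensity bumps whose amplitudes
    drift slice-to-slice as an AR(1) process with coefficient ``rho``;
    smooth, highly compressible, anatomical-phantom-like.
``correlated-noise``
    Spatially smoothed white noise, propagated across slices as
    ``slice_s = rho * slice_{s-1} + sqrt(1 - rho^2) * innovation`` so the
    lag-1 inter-slice correlation is ~rho.
``constant`` / ``impulse``
    Degenerate cases for edge-condition tests.

Everything downstream consumes the quantized integer volume, so a fixture
is reproducible bit-for-bit from (model, shape, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Volume

__all__ = ["FixtureSpec", "generate", "worked_example_block"]

MODELS = ("blobs", "correlated-noise", "constant", "impulse")


@dataclass
class FixtureSpec:
    shape: tuple[int, int, int] = (8, 128, 128)
    bit_depth: int = 8
    model: str = "blobs"
    seed: int = 0
    correlation: float = 0.95   # inter-slice AR(1) coefficient rho
    constant_value: int = 100   # used by the constant model only

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected {MODELS}")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [0, 1]")
        S, R, C = self.shape
        if S < 1 or R < 2 or C < 2:
            raise ValueError(f"invalid fixture shape {self.shape}")


def _quantize(field_: np.ndarray, bit_depth: int) -> np.ndarray:
    peak = (1 << bit_depth) - 1
    lo, hi = field_.min(), field_.max()
    if hi - lo < 1e-12:
        return np.zeros(field_.shape, dtype=np.int64)
    scaled = (field_ - lo) / (hi - lo) * peak
    return np.rint(scaled).astype(np.int64)


def _blobs(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    S, R, C = spec.shape
    rho = spec.correlation
    n_blobs = 12
    rows = rng.uniform(0, R, n_blobs)
    cols = rng.uniform(0, C, n_blobs)
    sigmas = rng.uniform(min(R, C) / 16, min(R, C) / 6, n_blobs)
    amps = rng.uniform(0.3, 1.0, n_blobs)

    rr = np.arange(R)[:, None]
    cc = np.arange(C)[None, :]
    bumps = np.stack([
        a * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s0 ** 2))
        for a, r0, c0, s0 in zip(amps, rows, cols, sigmas)
    ])                                   # (n_blobs, R, C)

    # per-blob amplitude drift across slices: AR(1) around 1 with coef rho
    drift = np.empty((S, n_blobs))
    drift[0] = 1.0
    for s in range(1, S):
        drift[s] = rho * drift[s - 1] + (1 - rho) * rng.normal(1.0, 0.3, n_blobs)
    return np.tensordot(drift, bumps, axes=(1, 0))


def _correlated_noise(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    S, R, C = spec.shape
    rho = spec.correlation
    sigma_px = min(R, C) / 32
    out = np.empty((S, R, C))
    out[0] = gaussian_filter(rng.standard_normal((R, C)), sigma_px)
    for s in range(1, S):
        innov = gaussian_filter(rng.standard_normal((R, C)), sigma_px)
        out[s] = rho * out[s - 1] + np.sqrt(1 - rho ** 2) * innov
    return out


def generate(spec: FixtureSpec) -> Volume:
    """Materialize a fixture volume; identical spec -> identical voxels."""
    S, R, C = spec.shape
    rng = np.random.default_rng(spec.seed)
    tag = f"synthetic:{spec.model}:seed={spec.seed}"

    if spec.model == "constant":
        data = np.full(spec.shape, spec.constant_value, dtype=np.int64)
    elif spec.model == "impulse":
        data = np.zeros(spec.shape, dtype=np.int64)
        data[0, 0, 0] = (1 << spec.bit_depth) - 1
    elif spec.model == "blobs":
        data = _quantize(_blobs(spec, rng), spec.bit_depth)
    else:
        data = _quantize(_correlated_noise(spec, rng), spec.bit_depth)
    return Volume(data=data, bit_depth=spec.bit_depth, source=tag)


def worked_example_block() -> np.ndarray:
    """The 2x2 demonstration block [-127, 109, 19, -24].

    Its top bit plane is 6 (|−127| = 127 < 128) and exactly two of its
    entries lie in the plane-6 magnitude window [64, 128).
    """
    return np.array([-127, 109, 19, -24], dtype=np.int64)
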