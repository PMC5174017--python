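import numpy as np
import pytest

from hlck import (
    Volume,
    dwt2d,
    hybrid_forward,
    hybrid_inverse,
    idwt2d,
    klt_forward,
    klt_inverse,
    psnr,
)
from hlck.hybrid_transform import KLTBasis
from hlck.synthetic_fixtures import FixtureSpec, generate


# ---------------------------------------------------------------------------
# KLT stage
# ---------------------------------------------------------------------------

def test_identical_slices_concentrate_in_first_component():
    base = np.arange(64, dtype=np.int64).reshape(8, 8) % 200
    vol = Volume(data=np.stack([base] * 8), bit_depth=8)
    comps, basis = klt_forward(vol)
    assert np.allclose(comps[1:], 0.0, atol=1e-9)
    assert basis.eigenvalues[0] >= 0 and np.allclose(basis.eigenvalues[1:], 0)


def test_components_have_diagonal_covariance(rng):
    vol = Volume(data=rng.integers(0, 256, (8, 32, 32)), bit_depth=8)
    comps, basis = klt_forward(vol)
    flat = comps.reshape(8, -1)
    cov = flat @ flat.T / flat.shape[1]
    off = cov - np.diag(np.diag(cov))
    assert np.abs(off).max() < 1e-8 * cov.max()
    # matches a direct eigendecomposition of the sample covariance
    X = vol.data.astype(float) - vol.data.mean(axis=(1, 2))[:, None, None]
    w = np.linalg.eigvalsh(X.reshape(8, -1) @ X.reshape(8, -1).T / (32 * 32))
    assert np.allclose(sorted(w, reverse=True), basis.eigenvalues, rtol=1e-10)


def test_single_slice_klt_is_identity():
    vol = Volume(data=np.arange(16, dtype=np.int64).reshape(1, 4, 4),
                 bit_depth=8)
    comps, basis = klt_forward(vol)
    assert np.array_equal(comps[0], vol.data[0])
    assert basis.mean[0] == 0 and basis.eigenvectors[0, 0] == 1


def test_klt_round_trip_and_energy(rng):
    vol = Volume(data=rng.integers(0, 256, (8, 16, 16)), bit_depth=8)
    comps, basis = klt_forward(vol)
    rec = klt_inverse(comps, basis)
    assert np.abs(rec - vol.data).max() < 1e-8
    Xc = vol.data - vol.data.mean(axis=(1, 2))[:, None, None]
    assert np.isclose((Xc ** 2).sum(), (comps ** 2).sum(), rtol=1e-8)


def test_zero_components_reconstruct_slice_means(rng):
    vol = Volume(data=rng.integers(0, 256, (4, 8, 8)), bit_depth=8)
    _, basis = klt_forward(vol)
    rec = klt_inverse(np.zeros((4, 8, 8)), basis)
    assert np.allclose(rec, basis.mean[:, None, None])


def test_basis_invariance_under_column_permutation(rng):
    vol = Volume(data=rng.integers(0, 256, (4, 8, 8)), bit_depth=8)
    comps, basis = klt_forward(vol)
    perm = np.array([2, 0, 3, 1])
    permuted = KLTBasis(mean=basis.mean,
                        eigenvectors=basis.eigenvectors[:, perm],
                        eigenvalues=basis.eigenvalues[perm])
    assert np.allclose(klt_inverse(comps[perm], permuted),
                       klt_inverse(comps, basis))


def test_non_orthonormal_basis_rejected():
    bad = KLTBasis(mean=np.zeros(2), eigenvectors=np.ones((2, 2)),
                   eigenvalues=np.zeros(2))
    with pytest.raises(ValueError, match="orthonormal"):
        klt_inverse(np.zeros((2, 4, 4)), bad)


def test_determinism_across_runs(rng):
    vol = Volume(data=rng.integers(0, 256, (8, 16, 16)), bit_depth=8)
    c1, b1 = klt_forward(vol)
    c2, b2 = klt_forward(vol)
    assert np.array_equal(c1, c2)
    assert np.array_equal(b1.eigenvectors, b2.eigenvectors)


# ---------------------------------------------------------------------------
# spatial DWT stage
# ---------------------------------------------------------------------------

def test_constant_plane_has_zero_details():
    c = dwt2d(np.full((16, 16), 9.0), 2, "cdf97")
    assert np.abs(c[:, 8:]).max() < 1e-10 and np.abs(c[8:, :]).max() < 1e-10


def test_cdf53_integer_round_trip_exact(rng):
    ramp = np.add.outer(np.arange(8), np.arange(8)).astype(float)
    assert np.array_equal(idwt2d(dwt2d(ramp, 1, "cdf53"), 1, "cdf53"), ramp)
    x = rng.integers(0, 256, (32, 32)).astype(float)
    c = dwt2d(x, 3, "cdf53")
    assert np.array_equal(c, np.round(c))          # integer output
    assert np.array_equal(idwt2d(c, 3, "cdf53"), x)


def test_cdf97_round_trip_within_float_tolerance(rng):
    x = rng.standard_normal((128, 128)) * 100
    err = np.abs(idwt2d(dwt2d(x, 5, "cdf97"), 5, "cdf97") - x).max()
    assert err < 1e-6


def test_geometry_errors():
    with pytest.raises(ValueError):
        dwt2d(np.zeros((12, 12)), 3, "cdf97")      # 8 does not divide 12
    with pytest.raises(ValueError):
        dwt2d(np.zeros((8, 8)), 1, "haar")         # unknown filter


def test_cdf97_agrees_with_pywavelets_on_smooth_input():
    """Independent cross-check: the coarse band of our lifting 9/7 must be
    essentially a rescaled copy of PyWavelets' bior4.4 periodized analysis."""
    pywt = pytest.importorskip("pywt")
    rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    x = 100 * np.exp(-((rr - 30) ** 2 + (cc - 34) ** 2) / 300.0)
    ours = dwt2d(x, 2, "cdf97")[:16, :16].ravel()
    ref = pywt.wavedec2(x, "bior4.4", mode="periodization", level=2)[0].ravel()
    r = np.corrcoef(ours, ref)[0, 1]
    assert r > 0.999


# ---------------------------------------------------------------------------
# full hybrid transform
# ---------------------------------------------------------------------------

def test_zero_volume_gives_zero_coefficients():
    vol = Volume(data=np.zeros((2, 16, 16), dtype=np.int64), bit_depth=8)
    hc = hybrid_forward(vol, 2, "cdf97")
    assert not hc.coeffs.any()


def test_lossless_path_single_slice_cdf53(rng):
    vol = Volume(data=rng.integers(0, 256, (1, 32, 32)), bit_depth=8)
    hc = hybrid_forward(vol, 3, "cdf53", qscale=0)
    rec = hybrid_inverse(hc, vol.bit_depth)
    assert np.array_equal(rec.data, vol.data)


def test_cdf97_quantization_noise_bound(small_volume):
    hc = hybrid_forward(small_volume, 3, "cdf97", qscale=4)
    rec = hybrid_inverse(hc, small_volume.bit_depth)
    assert psnr(small_volume, rec).psnr_mean > 55.0


def test_multislice_cdf53_coefficient_integrality(small_volume):
    hc = hybrid_forward(small_volume, 3, "cdf53", qscale=0)
    # spatial stage is reversible given its (real) KLT input
    back = hybrid_inverse(hc, small_volume.bit_depth)
    assert psnr(small_volume, back).psnr_mean > 40.0
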