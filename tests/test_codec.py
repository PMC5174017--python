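import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hlck
from hlck import (
    EmbeddedBitstream,
    build_layout,
    decode,
    encode,
    initial_bitplane,
    significance,
    truncate_bitstream,
)
from hlck.coefficient_mapping import LinearCoefficientArray
from hlck.synthetic_fixtures import worked_example_block
from tests.conftest import SMALL_GEOMETRIES, random_linear


def _lin(xi, geom):
    S, R, C, L = geom
    return LinearCoefficientArray(xi=np.asarray(xi, dtype=np.int64),
                                  layout=build_layout(S, R, C, L))


def _payload_bits(bs):
    return [(bs.payload[i >> 3] >> (7 - (i & 7))) & 1
            for i in range(bs.payload_nbits)]


# ---------------------------------------------------------------------------
# plane arithmetic
# ---------------------------------------------------------------------------

def test_initial_bitplane_worked_example():
    n, zero = initial_bitplane(worked_example_block())
    assert (n, zero) == (6, False)


def test_initial_bitplane_edge_cases():
    assert initial_bitplane(np.array([1])) == (0, False)
    assert initial_bitplane(np.array([0, 0, 0])) == (0, True)


def test_significance_worked_example():
    assert significance(worked_example_block(), 6) == 2


def test_significance_window_is_strict_above():
    assert significance(np.array([64]), 6) == 1
    assert significance(np.array([128]), 6) == 0
    assert significance(np.zeros(5), 3) == 0


# ---------------------------------------------------------------------------
# hand-simulated stream
# ---------------------------------------------------------------------------

def test_single_coefficient_stream_matches_hand_simulation():
    """Geometry (1,4,4,1), xi = [+3, 0, ..., 0]; n_max = 1.

    Plane 1, pass 2: coarsest-block significance 1, square significance 1,
    coefficient 1 + sign 0, three insignificant singletons 0 0 0, detail
    block 0. Plane 0: pass 1 retests the three singletons (0 0 0), pass 2
    retests the detail block (0), pass 3 refines +3 with bit 1.
    """
    xi = np.zeros(16, dtype=np.int64)
    xi[0] = 3
    bs = encode(_lin(xi, (1, 4, 4, 1)))
    assert bs.n_max == 1 and not bs.zero_flag
    assert _payload_bits(bs) == [1, 1, 1, 0, 0, 0, 0, 0,   # plane 1
                                 0, 0, 0, 0, 1]            # plane 0
    assert np.array_equal(decode(bs).xi, xi)


def test_midpoint_reconstruction_before_refinement():
    xi = np.zeros(16, dtype=np.int64)
    xi[0] = 3
    bs = encode(_lin(xi, (1, 4, 4, 1)))
    partial = decode(bs, budget_bits=8)   # plane 1 only
    assert partial.xi[0] == 3             # midpoint of [2, 4) is 3
    assert not partial.xi[1:].any()


def test_all_zero_array_gives_empty_payload():
    bs = encode(_lin(np.zeros(16), (1, 4, 4, 1)))
    assert bs.zero_flag and bs.payload_nbits == 0
    assert not decode(bs).xi.any()


def test_decode_at_budget_zero_is_all_zero(rng):
    lin = random_linear((1, 8, 8, 1), rng)
    assert not decode(encode(lin), budget_bits=0).xi.any()


# ---------------------------------------------------------------------------
# round-trip and embedded properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("geom", SMALL_GEOMETRIES)
def test_lossless_round_trip(geom, rng):
    for _ in range(5):
        lin = random_linear(geom, rng)
        assert np.array_equal(decode(encode(lin)).xi, lin.xi)


@given(data=st.lists(st.integers(-4000, 4000), min_size=64, max_size=64))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_lossless_round_trip_property(data):
    lin = _lin(data, (1, 8, 8, 1))
    assert np.array_equal(decode(encode(lin)).xi, lin.xi)


@pytest.mark.parametrize("geom", [(2, 16, 16, 2), (8, 32, 32, 3)])
def test_prefix_decode_equals_truncated_stream(geom, rng):
    lin = random_linear(geom, rng)
    bs = encode(lin)
    for budget in rng.integers(0, bs.payload_nbits, 8):
        b = int(budget)
        direct = decode(bs, budget_bits=b)
        truncated = decode(truncate_bitstream(bs, b))
        assert np.array_equal(direct.xi, truncated.xi)


def test_budget_truncates_encoder_exactly(rng):
    lin = random_linear((2, 16, 16, 2), rng)
    full = encode(lin)
    for b in (1, 7, 64, 1000):
        short = encode(lin, budget_bits=b)
        assert short.payload_nbits == min(b, full.payload_nbits)
        assert _payload_bits(short) == _payload_bits(full)[:short.payload_nbits]


def test_encoder_decoder_marker_trajectories_match(rng):
    """Twin-run symmetry: after coding, both sides hold identical Dm/status."""
    lin = random_linear((2, 16, 16, 2), rng)
    bs, enc_state = encode(lin, return_state=True)
    _, dec_state = decode(bs, return_state=True)
    assert np.array_equal(enc_state.Dm, dec_state.Dm)
    assert np.array_equal(enc_state.status, dec_state.status)


def test_pass2_decisions_match_bruteforce_interval_scan(rng):
    """Every emitted set-significance bit equals the windowed interval count
    of the block's coefficients (all blocks, all planes)."""
    from hlck.hlck_codec import _BitWriter, _EncoderIO, _run_passes
    from hlck.marker_state import init_markers

    lin = random_linear((2, 16, 16, 2), rng)
    n_max, _ = initial_bitplane(lin)

    decisions = []

    class ProbeIO(_EncoderIO):
        def code_block(self, k, extent, n):
            sig = super().code_block(k, extent, n)
            decisions.append((k, extent, n, sig))
            return sig

    st_ = init_markers(lin.layout)
    _run_passes(st_, ProbeIO(lin.xi, _BitWriter(None)), n_max)
    assert len(decisions) > 50
    for k, extent, n, sig in decisions:
        assert sig == (significance(lin.xi[k:k + extent], n) > 0)


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

def test_container_round_trip(rng):
    lin = random_linear((2, 16, 16, 2), rng)
    bs = encode(lin, filter_id="cdf97", qscale=4, bit_depth=12)
    back = EmbeddedBitstream.from_bytes(bs.to_bytes())
    for attr in ("S", "R", "C", "L", "filter_id", "qscale", "bit_depth",
                 "n_max", "zero_flag", "payload", "payload_nbits"):
        assert getattr(back, attr) == getattr(bs, attr)
    assert np.array_equal(decode(back).xi, lin.xi)


def test_bad_magic_rejected():
    with pytest.raises(ValueError, match="magic"):
        EmbeddedBitstream.from_bytes(b"JUNK" + b"\x00" * 64)


# ---------------------------------------------------------------------------
# volume-level API
# ---------------------------------------------------------------------------

def test_volume_embeddedness(small_volume):
    hi = hlck.encode_volume(small_volume, L=3, rate_bpp=2.0)
    lo_direct = hlck.encode_volume(small_volume, L=3, rate_bpp=0.5)
    n_vox = small_volume.data.size
    v1 = hlck.decode_volume(truncate_bitstream(hi, int(0.5 * n_vox)))
    v2 = hlck.decode_volume(lo_direct)
    assert np.array_equal(v1.data, v2.data)


def test_constant_volume_codes_to_near_nothing():
    vol = hlck.Volume(data=np.full((4, 16, 16), 77, dtype=np.int64),
                      bit_depth=8)
    bs = hlck.encode_volume(vol, L=2, rate_bpp=1.0)
    assert bs.payload_nbits < 200
    assert np.array_equal(hlck.decode_volume(bs).data, vol.data)


def test_volume_lossless_path(rng):
    vol = hlck.Volume(data=rng.integers(0, 256, (1, 32, 32)), bit_depth=8)
    bs = hlck.encode_volume(vol, L=3, filter_id="cdf53", lossless=True)
    assert np.array_equal(hlck.decode_volume(bs).data, vol.data)


def test_decode_rate_above_encoded_warns(small_volume):
    bs = hlck.encode_volume(small_volume, L=3, rate_bpp=0.25)
    with pytest.warns(UserWarning, match="decoding everything"):
        hlck.decode_volume(bs, rate_bpp=4.0)
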