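"""Listless embedded bit-plane coder and bitstream container.

Coefficients are coded plane by plane from ``n_max = floor(log2 max|xi|)``
down to plane 0. Each plane runs three passes over the 1D array:

1. *insignificant coefficient pass* — every exposed singleton still marked
   INC is tested against the threshold ``2**n``; a significant one emits
   ``1`` plus a sign bit and becomes NSC;
2. *insignificant set pass* — every surviving block is tested; a significant
   block is split (octal -> tri -> quad, per the marker ladder) and its
   children are tested depth-first within the same pass, down to singletons;
3. *refinement pass* — every SCR coefficient emits bit ``n`` of its
   magnitude; afterwards all NSC coefficients are promoted to SCR, so a
   coefficient is never refined in its discovery plane.

The decoder mirrors the encoder's control flow bit for bit (both sides are
driven by the same pass engine through a read/write adapter), so any prefix
of the payload decodes to a valid lower-rate reconstruction. A coefficient
discovered at plane n reconstructs to the uncertainty-interval midpoint
``±1.5 * 2**n``; each refinement bit halves the interval, and after plane 0
the magnitude is exact.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass

import numpy as np

from .coefficient_mapping import (
    LinearCoefficientArray,
    build_layout,
    map_from_1d,
    map_to_1d,
)
from .hybrid_transform import (
    DEFAULT_QSCALE,
    FILTERS,
    HybridCoefficients,
    KLTBasis,
    hybrid_forward,
    hybrid_inverse,
)
from .marker_state import (INC, NSC, SCR, MarkerState, block_extent,
                           init_markers, octal_split, quad_split, tri_split)
from .volume_io import Volume

__all__ = [
    "EmbeddedBitstream",
    "initial_bitplane",
    "significance",
    "encode",
    "decode",
    "encode_volume",
    "decode_volume",
    "truncate_bitstream",
]

_MAGIC = b"HLCK"
_VERSION = 1
_FLAG_ZERO = 1
_FLAG_HEADER_COUNTED = 2
_FILTER_CODE = {name: i for i, name in enumerate(FILTERS)}
_HEADER_FMT = "<BHHHBBBBBBQ"
_HEADER_LEN = 4 + struct.calcsize(_HEADER_FMT)


# ---------------------------------------------------------------------------
# plane arithmetic
# ---------------------------------------------------------------------------

def initial_bitplane(xi: np.ndarray | LinearCoefficientArray) -> tuple[int, bool]:
    """Top bit plane ``n = floor(log2 max|xi|)`` and an all-zero flag."""
    arr = xi.xi if isinstance(xi, LinearCoefficientArray) else np.asarray(xi)
    peak = int(np.max(np.abs(arr))) if arr.size else 0
    if peak == 0:
        return 0, True
    return peak.bit_length() - 1, False


def significance(block: np.ndarray, n: int) -> int:
    """Count of coefficients with ``2**n <= |c| < 2**(n+1)``.

    The coder only uses the zero / nonzero distinction; the upper bound is
    strict so a magnitude belongs to exactly one plane.
    """
    if n < 0:
        raise ValueError("bit plane index must be >= 0")
    a = np.abs(np.asarray(block))
    return int(np.count_nonzero((a >= (1 << n)) & (a < (1 << (n + 1)))))


# ---------------------------------------------------------------------------
# bit I/O
# ---------------------------------------------------------------------------

class _OutOfBits(Exception):
    """Budget or payload exhausted; coding stops cleanly mid-pass."""


class _BitWriter:
    __slots__ = ("buf", "acc", "nacc", "nbits", "budget")

    def __init__(self, budget: int | None) -> None:
        self.buf = bytearray()
        self.acc = 0
        self.nacc = 0
        self.nbits = 0
        self.budget = budget

    def write(self, bit: int) -> None:
        if self.budget is not None and self.nbits >= self.budget:
            raise _OutOfBits
        self.acc = (self.acc << 1) | (bit & 1)
        self.nacc += 1
        self.nbits += 1
        if self.nacc == 8:
            self.buf.append(self.acc)
            self.acc = 0
            self.nacc = 0

    def getvalue(self) -> bytes:
        out = bytes(self.buf)
        if self.nacc:
            out += bytes([(self.acc << (8 - self.nacc)) & 0xFF])
        return out


class _BitReader:
    __slots__ = ("data", "nbits", "pos", "budget")

    def __init__(self, data: bytes, nbits: int, budget: int | None) -> None:
        self.data = data
        self.nbits = nbits if budget is None else min(nbits, budget)
        self.pos = 0
        self.budget = budget

    def read(self) -> int:
        p = self.pos
        if p >= self.nbits:
            raise _OutOfBits
        self.pos = p + 1
        return (self.data[p >> 3] >> (7 - (p & 7))) & 1


# ---------------------------------------------------------------------------
# encoder / decoder adapters around the shared pass engine
# ---------------------------------------------------------------------------

class _EncoderIO:
    """Computes significance from xi and writes the resulting bits."""

    def __init__(self, xi: np.ndarray, writer: _BitWriter) -> None:
        self.absxi = np.abs(xi)
        self.neg = xi < 0
        self.w = writer

    def code_block(self, k: int, extent: int, n: int) -> bool:
        sig = bool(self.absxi[k:k + extent].max() >= (1 << n))
        self.w.write(1 if sig else 0)
        return sig

    def code_coeff(self, k: int, n: int, st: MarkerState) -> None:
        if self.absxi[k] >= (1 << n):
            self.w.write(1)
            self.w.write(1 if self.neg[k] else 0)
            st.status[k] = NSC
        else:
            self.w.write(0)

    def code_refine(self, k: int, n: int) -> None:
        self.w.write((int(self.absxi[k]) >> n) & 1)


class _DecoderIO:
    """Reads bits and rebuilds coefficient magnitudes and signs."""

    def __init__(self, reader: _BitReader, total_len: int) -> None:
        self.r = reader
        self.mag = np.zeros(total_len, dtype=np.int64)
        self.neg = np.zeros(total_len, dtype=bool)
        self.n_low = np.zeros(total_len, dtype=np.int8)

    def code_block(self, k: int, extent: int, n: int) -> bool:
        return bool(self.r.read())

    def code_coeff(self, k: int, n: int, st: MarkerState) -> None:
        if self.r.read():
            sign = self.r.read()   # may raise: coefficient then uncommitted
            self.mag[k] = 1 << n
            self.neg[k] = bool(sign)
            self.n_low[k] = n
            st.status[k] = NSC

    def code_refine(self, k: int, n: int) -> None:
        bit = self.r.read()
        self.mag[k] += bit << n
        self.n_low[k] = n

    def reconstruction(self) -> np.ndarray:
        """Midpoint reconstruction; exact once plane 0 has been read."""
        offset = np.where((self.mag > 0) & (self.n_low > 0),
                          np.int64(1) << np.maximum(self.n_low - 1, 0), 0)
        xi = self.mag + offset
        xi[self.neg] *= -1
        return xi


def _code_set(st: MarkerState, io, k: int, n: int) -> None:
    """Pass-2 treatment of the insignificant set led by k (recursive)."""
    lay = st.layout
    v = int(st.Dm[k])
    b = st.block_id(k)
    m = lay.marker_of_level[b]

    if not io.code_block(k, block_extent(st, k), n):
        return

    if v == m and k == lay.block_starts[b]:
        octal_split(st, k)
        step = 4 ** (m - 1) if b == 0 else 3 * 4 ** (m - 2)
        for j in range(lay.S):
            _code_set(st, io, k + j * step, n)
    elif b > 0 and v == m - 1:
        tri_split(st, k)
        band = 4 ** (m - 2)
        for j in range(3):
            _code_set(st, io, k + j * band, n)
    elif v >= 2:
        quad_split(st, k)
        child = 4 ** (v - 1)
        for j in range(4):
            _code_set(st, io, k + j * child, n)
    else:
        quad_split(st, k)   # v == 1: four exposed singletons
        for j in range(4):
            io.code_coeff(k + j, n, st)


def _run_passes(st: MarkerState, io, n_max: int) -> None:
    """Drive passes 1-3 over all planes until done or out of bits."""
    N = st.layout.total_len
    Dm = st.Dm
    status = st.status
    try:
        for n in range(n_max, -1, -1):
            # Pass 1: previously exposed, still-insignificant coefficients
            k = 0
            while k < N:
                v = Dm[k]
                if v == 0:
                    if status[k] == INC:
                        io.code_coeff(k, n, st)
                    k += 1
                else:
                    k += block_extent(st, k)
            # Pass 2: insignificant sets
            k = 0
            while k < N:
                v = Dm[k]
                if v == 0:
                    k += 1
                else:
                    extent = block_extent(st, k)
                    _code_set(st, io, k, n)
                    k += extent
            # Pass 3: refinement of previously significant coefficients
            k = 0
            while k < N:
                v = Dm[k]
                if v == 0:
                    if status[k] == SCR:
                        io.code_refine(k, n)
                    k += 1
                else:
                    k += block_extent(st, k)
            status[status == NSC] = SCR
    except _OutOfBits:
        pass


# ---------------------------------------------------------------------------
# bitstream container
# ---------------------------------------------------------------------------

@dataclass
class EmbeddedBitstream:
    """Self-describing header plus MSB-first-packed embedded payload."""

    S: int
    R: int
    C: int
    L: int
    filter_id: str
    qscale: int
    bit_depth: int
    n_max: int
    zero_flag: bool
    basis: KLTBasis
    payload: bytes
    payload_nbits: int
    header_counted: bool = False

    @property
    def header_bytes(self) -> int:
        return _HEADER_LEN + 8 * (self.S * self.S + self.S)

    def to_bytes(self) -> bytes:
        flags = (_FLAG_ZERO if self.zero_flag else 0) | \
                (_FLAG_HEADER_COUNTED if self.header_counted else 0)
        head = _MAGIC + struct.pack(
            _HEADER_FMT,
            _VERSION, self.S, self.R, self.C, self.L,
            _FILTER_CODE[self.filter_id], self.qscale, self.bit_depth,
            flags, self.n_max, self.payload_nbits,
        )
        klt = np.concatenate(
            [self.basis.eigenvectors.reshape(-1), self.basis.mean]
        ).astype("<f8").tobytes()
        return head + klt + self.payload

    @classmethod
    def from_bytes(cls, blob: bytes) -> "EmbeddedBitstream":
        if blob[:4] != _MAGIC:
            raise ValueError("not an HLCK bitstream (bad magic)")
        (version, S, R, C, L, fcode, qscale, bit_depth, flags, n_max,
         payload_nbits) = struct.unpack(_HEADER_FMT, blob[4:_HEADER_LEN])
        if version != _VERSION:
            raise ValueError(f"unsupported bitstream version {version}")
        nk = S * S + S
        klt = np.frombuffer(blob[_HEADER_LEN:_HEADER_LEN + 8 * nk], dtype="<f8")
        V = klt[:S * S].reshape(S, S).copy()
        mean = klt[S * S:].copy()
        basis = KLTBasis(mean=mean, eigenvectors=V,
                         eigenvalues=np.zeros(S))
        return cls(
            S=S, R=R, C=C, L=L, filter_id=FILTERS[fcode], qscale=qscale,
            bit_depth=bit_depth, n_max=n_max,
            zero_flag=bool(flags & _FLAG_ZERO),
            basis=basis, payload=blob[_HEADER_LEN + 8 * nk:],
            payload_nbits=payload_nbits,
            header_counted=bool(flags & _FLAG_HEADER_COUNTED),
        )


def truncate_bitstream(bs: EmbeddedBitstream, budget_bits: int) -> EmbeddedBitstream:
    """Cut the payload to its first budget_bits bits (embedded property)."""
    nbits = min(bs.payload_nbits, max(0, budget_bits))
    nbytes = (nbits + 7) // 8
    payload = bs.payload[:nbytes]
    if nbits % 8:
        tail = payload[-1] & (0xFF << (8 - nbits % 8)) & 0xFF
        payload = payload[:-1] + bytes([tail])
    return EmbeddedBitstream(
        S=bs.S, R=bs.R, C=bs.C, L=bs.L, filter_id=bs.filter_id,
        qscale=bs.qscale, bit_depth=bs.bit_depth, n_max=bs.n_max,
        zero_flag=bs.zero_flag, basis=bs.basis, payload=payload,
        payload_nbits=nbits, header_counted=bs.header_counted,
    )


# ---------------------------------------------------------------------------
# coefficient-level encode / decode
# ---------------------------------------------------------------------------

def _identity_basis(S: int) -> KLTBasis:
    return KLTBasis(mean=np.zeros(S), eigenvectors=np.eye(S),
                    eigenvalues=np.zeros(S))


def encode(xi: LinearCoefficientArray, budget_bits: int | None = None, *,
           levels: int | None = None, filter_id: str = "cdf53",
           qscale: int = 0, bit_depth: int = 8,
           basis: KLTBasis | None = None,
           return_state: bool = False):
    """Encode a linearized coefficient array into an embedded bitstream."""
    lay = xi.layout
    if budget_bits is not None and budget_bits < 0:
        raise ValueError("budget_bits must be >= 0")
    n_max, zero = initial_bitplane(xi)
    st = init_markers(lay)
    writer = _BitWriter(budget_bits)
    if not zero:
        io = _EncoderIO(np.asarray(xi.xi, dtype=np.int64), writer)
        _run_passes(st, io, n_max)
    bs = EmbeddedBitstream(
        S=lay.S, R=lay.R, C=lay.C,
        L=levels if levels is not None else lay.L,
        filter_id=filter_id, qscale=qscale, bit_depth=bit_depth,
        n_max=n_max, zero_flag=zero,
        basis=basis if basis is not None else _identity_basis(lay.S),
        payload=writer.getvalue(), payload_nbits=writer.nbits,
    )
    return (bs, st) if return_state else bs


def decode(bs: EmbeddedBitstream, budget_bits: int | None = None, *,
           return_state: bool = False):
    """Decode (a prefix of) an embedded bitstream back to coefficients."""
    lay = build_layout(bs.S, bs.R, bs.C, bs.L)
    st = init_markers(lay)
    io = _DecoderIO(_BitReader(bs.payload, bs.payload_nbits, budget_bits),
                    lay.total_len)
    if not bs.zero_flag:
        _run_passes(st, io, bs.n_max)
    lin = LinearCoefficientArray(xi=io.reconstruction(), layout=lay)
    return (lin, st) if return_state else lin


# ---------------------------------------------------------------------------
# volume-level API
# ---------------------------------------------------------------------------

def encode_volume(vol: Volume, L: int = 5, filter_id: str = "cdf97",
                  qscale: int | None = None, rate_bpp: float | None = None,
                  lossless: bool = False,
                  count_header: bool = False) -> EmbeddedBitstream:
    """Transform, linearize and embed a volume at a target rate (or all planes).

    budget_bits = round(rate_bpp * S*R*C), counting payload bits only unless
    count_header is set (the header carries the KLT basis and is reported
    separately otherwise).
    """
    if not lossless and (rate_bpp is None or rate_bpp <= 0):
        raise ValueError("specify rate_bpp > 0 or lossless=True")
    if qscale is None:
        qscale = DEFAULT_QSCALE[filter_id]
    hc = hybrid_forward(vol, L, filter_id, qscale)
    lin = map_to_1d(hc)
    budget = None
    if not lossless:
        n_vox = vol.data.size
        budget = int(round(rate_bpp * n_vox))
        if count_header:
            header_bits = 8 * (_HEADER_LEN
                               + 8 * (vol.shape[0] ** 2 + vol.shape[0]))
            budget -= header_bits
            if budget < 0:
                warnings.warn("bit budget smaller than the header; "
                              "emitting a header-only stream")
                budget = 0
    bs = encode(lin, budget, levels=L, filter_id=filter_id, qscale=qscale,
                bit_depth=vol.bit_depth, basis=hc.basis)
    bs.header_counted = count_header
    return bs


def decode_volume(bs: EmbeddedBitstream,
                  rate_bpp: float | None = None) -> Volume:
    """Decode a bitstream (optionally at a reduced rate) back to a volume."""
    budget = None
    if rate_bpp is not None:
        budget = int(round(rate_bpp * bs.S * bs.R * bs.C))
        if budget > bs.payload_nbits:
            warnings.warn(
                f"requested rate needs {budget} bits but the stream holds "
                f"{bs.payload_nbits}; decoding everything available"
            )
    lin = decode(bs, budget)
    hc_meta = HybridCoefficients(
        coeffs=np.zeros((bs.S, bs.R, bs.C), dtype=np.int64),
        levels=bs.L, filter_id=bs.filter_id, qscale=bs.qscale, basis=bs.basis,
    )
    hc = map_from_1d(lin, hc_meta)
    return hybrid_inverse(hc, bs.bit_depth)
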