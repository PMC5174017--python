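"""Hierarchical 1D linearization of the per-slice wavelet pyramids.

The listless coder operates on a single 1D array ``xi`` of length S*R*C.
The arrangement concatenates, coarsest first,

* the combined coarsest block: the LL_L squares of slice 1 .. slice S,
* one combined detail block per decomposition level (level L down to 1),
  each holding, for slice 1 .. slice S, that slice's HL, LH and HH subbands.

Within every square subband (and every LL square) coefficients follow the
Morton (Z) order, which makes every aligned power-of-four block a contiguous
run of indices — the property the quad-split partitioning relies on.

Indices are 0-based internally; the ``*_1based`` layout fields exist because
block leading indices are conventionally quoted 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubbandLayout",
    "LinearCoefficientArray",
    "build_layout",
    "map_to_1d",
    "map_from_1d",
    "morton_index",
    "morton_point",
]


# ---------------------------------------------------------------------------
# Morton (Z-order) indexing
# ---------------------------------------------------------------------------

def _part1by1(v: np.ndarray | int) -> np.ndarray | int:
    """Spread the low 16 bits of *v* so bit i moves to bit 2i."""
    v = np.asarray(v, dtype=np.uint64)
    v = (v | (v << 8)) & np.uint64(0x00FF00FF)
    v = (v | (v << 4)) & np.uint64(0x0F0F0F0F)
    v = (v | (v << 2)) & np.uint64(0x33333333)
    v = (v | (v << 1)) & np.uint64(0x55555555)
    return v


def _compact1by1(v: np.ndarray | int) -> np.ndarray | int:
    v = np.asarray(v, dtype=np.uint64) & np.uint64(0x55555555)
    v = (v | (v >> 1)) & np.uint64(0x33333333)
    v = (v | (v >> 2)) & np.uint64(0x0F0F0F0F)
    v = (v | (v >> 4)) & np.uint64(0x00FF00FF)
    v = (v | (v >> 8)) & np.uint64(0x0000FFFF)
    return v


def _check_side(side: int) -> None:
    if side < 1 or side & (side - 1):
        raise ValueError(f"side must be a positive power of two, got {side}")


def morton_index(row: int, col: int, side: int) -> int:
    """Z-order rank of (row, col) in a side x side square.

    Column bits occupy the even bit positions of the rank and row bits the
    odd positions, so the scan visits quadrants top-left, top-right,
    bottom-left, bottom-right.
    """
    _check_side(side)
    if not (0 <= row < side and 0 <= col < side):
        raise ValueError(f"({row}, {col}) out of range for side {side}")
    return int(_part1by1(col) | (_part1by1(row) << np.uint64(1)))


def morton_point(rank: int, side: int) -> tuple[int, int]:
    """Inverse of :func:`morton_index`."""
    _check_side(side)
    if not (0 <= rank < side * side):
        raise ValueError(f"rank {rank} out of range for side {side}")
    r = np.uint64(rank)
    return int(_compact1by1(r >> np.uint64(1))), int(_compact1by1(r))


def _morton_points(side: int) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) arrays such that rank k sits at (rows[k], cols[k])."""
    ranks = np.arange(side * side, dtype=np.uint64)
    rows = _compact1by1(ranks >> np.uint64(1)).astype(np.int64)
    cols = _compact1by1(ranks).astype(np.int64)
    return rows, cols


# ---------------------------------------------------------------------------
# Subband layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubbandLayout:
    """Geometry of the 1D arrangement and its block leading indices.

    The combined coarsest block carries static marker ``log2(C) - L + 1``;
    the combined detail block of decomposition level ``l`` carries marker
    ``m = log2(C) - l + 2`` and spans ``S * 3 * 4**(m - 2)`` indices.
    """

    S: int
    R: int
    C: int
    L: int
    I: int                      # coefficients per slice, R*C
    total_len: int              # S*I
    # 1-based leading index of each combined block, coarsest first
    combined_level_offsets: tuple[int, ...]
    # per combined block: the S per-slice leading indices (1-based)
    slice_leaders: tuple[tuple[int, ...], ...]
    # per combined detail block, per slice: (HL, LH, HH) leaders (1-based);
    # entry 0 (the coarsest block) is an empty tuple — LL squares have no
    # subband substructure
    subband_leaders: tuple[tuple[tuple[int, ...], ...], ...]
    marker_of_level: tuple[int, ...]   # static marker per combined block
    sentinel: int                      # log2(C) + 2, the "skip me" Dm value
    # 0-based start of each combined block plus total_len as a final fence
    block_starts: tuple[int, ...] = field(repr=False)

    @property
    def n_combined_blocks(self) -> int:
        return len(self.combined_level_offsets)

    def combined_extent(self, block: int) -> int:
        return self.block_starts[block + 1] - self.block_starts[block]

    def block_of(self, k: int) -> int:
        """Combined-block id containing 0-based index k."""
        return int(np.searchsorted(self.block_starts, k, side="right")) - 1


def _validate_geometry(S: int, R: int, C: int, L: int) -> None:
    for name, v in (("S", S), ("R", R), ("C", C)):
        if v < 1 or v & (v - 1):
            raise ValueError(f"{name}={v} must be a power of two")
    if R != C:
        raise ValueError(f"slices must be square, got {R}x{C}")
    if L < 1 or C % (1 << L):
        raise ValueError(f"2^L must divide C (L={L}, C={C})")
    if C >> L < 2:
        raise ValueError(f"coarsest subband would be degenerate (L={L}, C={C})")


def build_layout(S: int, R: int, C: int, L: int) -> SubbandLayout:
    """Compute the block structure of the 1D arrangement."""
    _validate_geometry(S, R, C, L)
    n = int(np.log2(C))
    I = R * C
    total = S * I

    m_coarse = n - L + 1
    markers = [m_coarse] + [n - lev + 2 for lev in range(L, 0, -1)]

    starts = [0]
    slice_leaders: list[tuple[int, ...]] = []
    subband_leaders: list[tuple[tuple[int, ...], ...]] = []

    # combined coarsest: S squares of side C/2^L (4**(m-1) coefficients each)
    sq = 4 ** (m_coarse - 1)
    slice_leaders.append(tuple(starts[0] + j * sq + 1 for j in range(S)))
    subband_leaders.append(tuple(() for _ in range(S)))
    starts.append(starts[0] + S * sq)

    for i, m in enumerate(markers[1:]):
        base = starts[-1]
        band = 4 ** (m - 2)          # one subband
        slab = 3 * band              # one slice's {HL, LH, HH}
        slice_leaders.append(tuple(base + j * slab + 1 for j in range(S)))
        subband_leaders.append(
            tuple(
                (base + j * slab + 1,
                 base + j * slab + band + 1,
                 base + j * slab + 2 * band + 1)
                for j in range(S)
            )
        )
        starts.append(base + S * slab)

    if starts[-1] != total:
        raise AssertionError("combined blocks do not tile the array")

    return SubbandLayout(
        S=S, R=R, C=C, L=L, I=I, total_len=total,
        combined_level_offsets=tuple(s + 1 for s in starts[:-1]),
        slice_leaders=tuple(slice_leaders),
        subband_leaders=tuple(subband_leaders),
        marker_of_level=tuple(markers),
        sentinel=n + 2,
        block_starts=tuple(starts),
    )


# ---------------------------------------------------------------------------
# 3D <-> 1D permutation
# ---------------------------------------------------------------------------

_PERM_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


def _permutation(layout: SubbandLayout) -> np.ndarray:
    """perm[k] = flat (s*R*C + r*C + c) index feeding xi[k]."""
    key = (layout.S, layout.R, layout.C, layout.L)
    if key in _PERM_CACHE:
        return _PERM_CACHE[key]

    S, R, C, L = key
    perm = np.empty(layout.total_len, dtype=np.int64)
    pos = 0

    def emit(s: int, r0: int, c0: int, side: int) -> None:
        nonlocal pos
        rr, cc = _morton_points(side)
        perm[pos:pos + side * side] = s * R * C + (r0 + rr) * C + (c0 + cc)
        pos += side * side

    side_L = C >> L
    for s in range(S):                       # combined coarsest: LL_L squares
        emit(s, 0, 0, side_L)
    for lev in range(L, 0, -1):              # combined detail levels
        side = C >> lev
        for s in range(S):
            emit(s, 0, side, side)           # HL: horizontal detail block
            emit(s, side, 0, side)           # LH
            emit(s, side, side, side)        # HH
    assert pos == layout.total_len

    _PERM_CACHE[key] = perm
    return perm


@dataclass
class LinearCoefficientArray:
    """The coder's 1D view ``xi`` of the hybrid coefficients."""

    xi: np.ndarray
    layout: SubbandLayout

    def __post_init__(self) -> None:
        if self.xi.shape != (self.layout.total_len,):
            raise ValueError(
                f"xi has length {self.xi.shape}, layout expects "
                f"{self.layout.total_len}"
            )


def map_to_1d(hc) -> LinearCoefficientArray:
    """Linearize a :class:`~hlck.hybrid_transform.HybridCoefficients`."""
    S, R, C = hc.coeffs.shape
    layout = build_layout(S, R, C, hc.levels)
    perm = _permutation(layout)
    xi = np.ascontiguousarray(hc.coeffs.reshape(-1)[perm])
    return LinearCoefficientArray(xi=xi, layout=layout)


def map_from_1d(lin: LinearCoefficientArray, meta) -> "HybridCoefficients":
    """Exact inverse of :func:`map_to_1d`.

    *meta* supplies the non-array fields (levels, filter_id, qscale, basis);
    any HybridCoefficients-like object works.
    """
    from .hybrid_transform import HybridCoefficients

    layout = lin.layout
    perm = _permutation(layout)
    flat = np.empty(layout.total_len, dtype=lin.xi.dtype)
    flat[perm] = lin.xi
    return HybridCoefficients(
        coeffs=flat.reshape(layout.S, layout.R, layout.C),
        levels=meta.levels,
        filter_id=meta.filter_id,
        qscale=meta.qscale,
        basis=meta.basis,
    )
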