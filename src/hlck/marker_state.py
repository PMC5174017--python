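"""Static/dynamic marker tables and the set-partitioning split operators.

The listless coder replaces the SPIHT/SPECK auxiliary lists with two marker
tables over the 1D coefficient array:

* ``Sm`` — static markers at block leading indices, never modified. A block
  whose dynamic marker still equals its static marker is a whole combined
  (all-slice) level and can be skipped with a single output bit.
* ``Dm`` — one 4-bit dynamic marker per coefficient position recording the
  current partitioning depth. Positions that are neither block leaders nor
  exposed singletons hold the sentinel ``log2(C) + 2``.

Given a leader k inside a combined block with static marker m, the value
v = Dm[k] encodes the block extent:

===========================  ========================  =====================
v                            combined coarsest block   combined detail block
===========================  ========================  =====================
v == m                       S * 4**(m-1) (all LLs)    S * 3 * 4**(m-2)
v == m - 1                   4**(m-1) (one LL square)  3 * 4**(m-2) (slice)
v <= m - 2 (detail), m - 1   4**v Morton square        4**v Morton square
v == 0                       a singleton coefficient   a singleton
===========================  ========================  =====================

Partitioning moves down this ladder: octal split (combined -> per-slice),
tri split (slice level -> HL/LH/HH subbands, detail blocks only), then
recursive quad splits of Morton squares down to singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coefficient_mapping import SubbandLayout

__all__ = [
    "INC",
    "NSC",
    "SCR",
    "MarkerState",
    "init_markers",
    "quad_split",
    "tri_split",
    "octal_split",
    "block_extent",
]

# coefficient significance statuses (singletons only)
INC = 0  # insignificant or untested this bit plane
NSC = 1  # newly significant: not refined in its discovery plane
SCR = 2  # significant: refined every subsequent plane


@dataclass
class MarkerState:
    """Mutable partitioning state over one :class:`SubbandLayout`."""

    layout: SubbandLayout
    Dm: np.ndarray                 # uint8, one 4-bit value per position
    Sm: dict[int, int]             # 0-based leading index -> static marker
    status: np.ndarray             # uint8 in {INC, NSC, SCR}
    # 0-based: combined-block id per position, for O(1) extent lookup
    _block_of: np.ndarray = field(repr=False)

    def block_id(self, k: int) -> int:
        return int(self._block_of[k])


def init_markers(layout: SubbandLayout) -> MarkerState:
    """Initialize Dm/Sm exactly as the coder expects at the top bit plane.

    Every per-slice leading index of a combined block receives that block's
    static marker in both tables; all other positions hold the sentinel.
    """
    Dm = np.full(layout.total_len, layout.sentinel, dtype=np.uint8)
    Sm: dict[int, int] = {}
    for block, m in enumerate(layout.marker_of_level):
        for lead in layout.slice_leaders[block]:
            Sm[lead - 1] = m
            Dm[lead - 1] = m

    block_of = np.zeros(layout.total_len, dtype=np.uint8)
    for b in range(layout.n_combined_blocks):
        block_of[layout.block_starts[b]:layout.block_starts[b + 1]] = b

    status = np.full(layout.total_len, INC, dtype=np.uint8)
    return MarkerState(layout=layout, Dm=Dm, Sm=Sm, status=status,
                       _block_of=block_of)


def block_extent(st: MarkerState, k: int) -> int:
    """Extent (coefficient count) of the block led by position k."""
    v = int(st.Dm[k])
    lay = st.layout
    if v == lay.sentinel:
        raise ValueError(f"position {k} is not a block leader")
    b = st.block_id(k)
    m = lay.marker_of_level[b]
    if v == m:
        return lay.combined_extent(b)
    if b > 0 and v == m - 1:          # one slice's 3-subband level
        return 3 * 4 ** (m - 2)
    return 4 ** v                     # Morton square (or singleton, 4**0)


def quad_split(st: MarkerState, k: int) -> None:
    """Split the Morton square at leader k into its four quadrants.

    Dm[k] drops from v to v-1 and the three sibling leaders appear at
    offsets j * 4**(v-1); at v == 1 the four positions become exposed
    singleton coefficients (Dm 0, status INC).
    """
    v = int(st.Dm[k])
    lay = st.layout
    b = st.block_id(k)
    m = lay.marker_of_level[b]
    vmax = m - 1 if b == 0 else m - 2
    if not (1 <= v <= vmax):
        raise ValueError(
            f"quad_split at k={k}: Dm={v} is not a splittable square "
            f"(expected 1..{vmax})"
        )
    child = 4 ** (v - 1)
    for j in range(4):
        st.Dm[k + j * child] = v - 1


def tri_split(st: MarkerState, k: int) -> None:
    """Split one slice's wavelet level into its HL, LH, HH subbands."""
    v = int(st.Dm[k])
    lay = st.layout
    b = st.block_id(k)
    m = lay.marker_of_level[b]
    if b == 0 or v != m - 1:
        raise ValueError(
            f"tri_split at k={k}: Dm={v} is not a slice-level block "
            f"(expected marker {m}-1 inside a detail block)"
        )
    band = 4 ** (m - 2)
    for j in range(3):
        st.Dm[k + j * band] = m - 2


def octal_split(st: MarkerState, k: int) -> None:
    """Split a combined block into its S per-slice children."""
    v = int(st.Dm[k])
    lay = st.layout
    b = st.block_id(k)
    m = lay.marker_of_level[b]
    if v != m or st.Sm.get(k) != m or k != lay.block_starts[b]:
        raise ValueError(
            f"octal_split at k={k}: Dm={v} is not a combined-block leader"
        )
    step = 4 ** (m - 1) if b == 0 else 3 * 4 ** (m - 2)
    for j in range(lay.S):
        st.Dm[k + j * step] = m - 1
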