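"""Modified AHA 17-segment model for short-axis wall-motion mapping.

The left ventricle is divided into basal, mid-cavity and apical rings of
short-axis slices; basal and mid rings carry six 60-degree sectors, the
apical ring four 90-degree sectors, and segment 17 (the apical cap) carries
no short-axis wall sites and is excluded from wall-motion analysis.

Angle convention: theta = 0 deg at the anterior junction of the RV free
wall with the septum, increasing counterclockwise as viewed from the apex,
so the septum spans [240, 360) and the free wall [0, 240).  All sector
intervals are half-open [lo, hi) so every angle maps to exactly one segment.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SEGMENT_NAMES = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
    17: "apex",
}

RINGS = ("basal", "mid", "apical")

# (angle_lo_deg, angle_hi_deg, segment_id) per ring; half-open [lo, hi)
BASAL_SECTORS = (
    (0.0, 60.0, 1),
    (60.0, 120.0, 6),
    (120.0, 180.0, 5),
    (180.0, 240.0, 4),
    (240.0, 300.0, 3),
    (300.0, 360.0, 2),
)
MID_SECTORS = (
    (0.0, 60.0, 7),
    (60.0, 120.0, 12),
    (120.0, 180.0, 11),
    (180.0, 240.0, 10),
    (240.0, 300.0, 9),
    (300.0, 360.0, 8),
)
APICAL_SECTORS = (
    (0.0, 90.0, 13),
    (90.0, 180.0, 16),
    (180.0, 270.0, 15),
    (270.0, 360.0, 14),
)

#: Each apical 90-degree sector is adjacent to the two mid 60-degree sectors
#: it overlaps (one fully, one by 30 degrees).
MID_TO_APICAL = {13: (7, 12), 16: (11, 12), 15: (9, 10), 14: (8, 9)}

SEPTAL_SEGMENTS = frozenset({2, 3, 8, 9, 14})

#: Diametrically opposed sector pairs within each ring, used for the
#: opposing-wall delay.
OPPOSING_PAIRS = ((1, 4), (2, 5), (3, 6), (7, 10), (8, 11), (9, 12), (13, 15), (14, 16))

# circumferential order (by increasing angle) per ring
_RING_CYCLES = {
    "basal": (1, 6, 5, 4, 3, 2),
    "mid": (7, 12, 11, 10, 9, 8),
    "apical": (13, 16, 15, 14),
}
# basal sector k sits directly above mid sector k+6
_BASAL_MID_LINKS = ((1, 7), (2, 8), (3, 9), (4, 10), (5, 11), (6, 12))


class InvalidGeometryError(ValueError):
    """Raised when a contour stack cannot support the ring partition."""


def _build_adjacency() -> dict[int, frozenset[int]]:
    adj: dict[int, set[int]] = {s: set() for s in range(1, 17)}
    for cycle in _RING_CYCLES.values():
        n = len(cycle)
        for i, s in enumerate(cycle):
            adj[s].add(cycle[(i - 1) % n])
            adj[s].add(cycle[(i + 1) % n])
    for a, b in _BASAL_MID_LINKS:
        adj[a].add(b)
        adj[b].add(a)
    for ap, mids in MID_TO_APICAL.items():
        for m in mids:
            adj[ap].add(m)
            adj[m].add(ap)
    return {s: frozenset(v) for s, v in adj.items()}


ADJACENCY = _build_adjacency()


@dataclass(frozen=True)
class SegmentModel:
    """Mapping from (slice, circumferential angle) to AHA segment.

    ``ring_of_slice[k]`` gives the ring of short-axis slice ``k`` (slice 0 is
    the most basal).  Remainder slices of a non-divisible stack are assigned
    basal-first (basal slices are anatomically longest).
    """

    n_slices: int
    ring_of_slice: tuple[str, ...]
    adjacency: dict[int, frozenset[int]]
    mid_to_apical: dict[int, tuple[int, int]]

    @property
    def ring_counts(self) -> dict[str, int]:
        return {r: self.ring_of_slice.count(r) for r in RINGS}

    def sectors(self, ring: str):
        return {"basal": BASAL_SECTORS, "mid": MID_SECTORS, "apical": APICAL_SECTORS}[ring]

    def ring_slices(self, ring: str) -> list[int]:
        return [k for k, r in enumerate(self.ring_of_slice) if r == ring]

    def segments_of_ring(self, ring: str) -> list[int]:
        return [seg for _, _, seg in self.sectors(ring)]

    def segment_table(self) -> pd.DataFrame:
        rows = []
        for ring in RINGS:
            for lo, hi, seg in self.sectors(ring):
                rows.append(
                    {
                        "segment_id": seg,
                        "name": SEGMENT_NAMES[seg],
                        "ring": ring,
                        "angle_lo_deg": lo,
                        "angle_hi_deg": hi,
                        "neighbours": ";".join(str(s) for s in sorted(self.adjacency[seg])),
                    }
                )
        return pd.DataFrame(rows).sort_values("segment_id").reset_index(drop=True)


def build_segment_model(n_slices: int, config=None) -> SegmentModel:
    """Partition ``n_slices`` short-axis slices into basal/mid/apical thirds.

    The remainder of a non-divisible count goes to the basal ring first,
    then the mid ring (e.g. 10 slices -> 4/3/3).
    """
    if n_slices < 3:
        raise InvalidGeometryError(f"need at least 3 slices, got {n_slices}")
    base, rem = divmod(n_slices, 3)
    counts = {"basal": base + (1 if rem >= 1 else 0), "mid": base + (1 if rem >= 2 else 0), "apical": base}
    ring_of_slice = tuple(
        ["basal"] * counts["basal"] + ["mid"] * counts["mid"] + ["apical"] * counts["apical"]
    )
    return SegmentModel(
        n_slices=n_slices,
        ring_of_slice=ring_of_slice,
        adjacency=ADJACENCY,
        mid_to_apical=dict(MID_TO_APICAL),
    )


def site_to_segment(slice_index: int, angle_deg: float, model: SegmentModel) -> int:
    """Return the AHA segment (1-16) owning a wall site.

    Boundary angles resolve to the sector whose lower edge they equal.
    """
    if not 0 <= slice_index < model.n_slices:
        raise IndexError(f"slice index {slice_index} out of range 0..{model.n_slices - 1}")
    theta = float(angle_deg) % 360.0
    for lo, hi, seg in model.sectors(model.ring_of_slice[slice_index]):
        if lo <= theta < hi:
            return seg
    raise AssertionError("sector tables must partition [0, 360)")  # pragma: no cover


def adjacent_segments(a: int, b: int, model: SegmentModel) -> bool:
    """True iff segment ``b`` is within one segment of ``a`` (identity counts).

    Segment 17 carries no wall sites and is rejected.
    """
    for s in (a, b):
        if s == 17:
            raise ValueError("segment 17 (apex) is excluded from wall analysis")
        if not 1 <= s <= 16:
            raise ValueError(f"segment id {s} out of range 1..16")
    return a == b or b in model.adjacency[a]
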