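"""LV pacing-lead localization, concordance classification and the T2CL flag.

Biplane fluoroscopy reduces to two coordinates: the RAO projection gives the
fractional long-axis position of the lead tip and the LAO projection its
circumferential angle.  The lead is *concordant* if it sits in a viable
segment within one segment of the latest contracting segment, *remote*
otherwise; a lead in a segment with > 50 % transmural scar is remote
regardless of proximity.  T2CL is the conjunction of a type II wall-motion
pattern and a concordant lead.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .config import DEFAULT_CONFIG, AnalysisConfig
from .patterns import PatternResult
from .segments import RINGS, SegmentModel, adjacent_segments, site_to_segment


@dataclass
class LeadPlacement:
    lead_segment: int
    viable: bool
    classification: str  # "concordant" | "remote"
    t2cl: bool | None = None


def map_lead_to_segment(
    long_fraction: float, circ_angle_deg: float, model: SegmentModel
) -> int:
    """Map (RAO long-axis fraction, LAO angle) to an AHA segment.

    ``long_fraction`` runs 0 (base) to 1 (apex); thirds select the ring, and
    the angle selects the sector via the ring's middle slice.
    """
    if not 0.0 <= long_fraction <= 1.0:
        raise ValueError(f"long_fraction {long_fraction} outside [0, 1]")
    ring = RINGS[min(2, int(long_fraction * 3))]
    ring_slices = model.ring_slices(ring)
    mid_slice = ring_slices[len(ring_slices) // 2]
    return site_to_segment(mid_slice, circ_angle_deg, model)


def classify_lead_position(
    lead_segment: int,
    latest_segment: int,
    scar: dict[int, float] | None,
    model: SegmentModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> LeadPlacement:
    """Concordant iff the lead sits in a viable segment within one segment
    of the latest contracting segment."""
    if scar is None:
        warnings.warn("no scar annotation provided; lead segment treated as viable")
        scar = {}
    viable = scar.get(lead_segment, 0.0) <= config.scar_transmurality_cutoff
    if not viable:
        cls = "remote"
    else:
        cls = (
            "concordant"
            if adjacent_segments(lead_segment, latest_segment, model)
            else "remote"
        )
    return LeadPlacement(lead_segment=lead_segment, viable=viable, classification=cls)


def t2cl_flag(pattern: PatternResult | str, classification: str) -> bool:
    """True iff (type II pattern) AND (concordant lead)."""
    label = pattern.pattern if isinstance(pattern, PatternResult) else pattern
    return label == "type_II" and classification == "concordant"
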