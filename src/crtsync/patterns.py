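"""Segment-level delay summaries and wall-motion pattern classification.

A delay map is reduced to per-segment medians; segments are split into
early / late terciles; an inferred line of block is an adjacent early/late
segment pair whose delay difference exceeds a threshold.  A type II
(U-shaped) pattern is called iff at least one block edge exists, otherwise
the activation is type I (homogeneous).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .segments import OPPOSING_PAIRS, SEPTAL_SEGMENTS, SegmentModel, adjacent_segments
from .wallmotion import DelayMap, DisplacementCurveSet


class PatternError(ValueError):
    pass


@dataclass
class SegmentSummary:
    """Per-segment delay statistics (median over valid sites)."""

    segment_delay_ms: dict[int, float]
    n_valid_sites: dict[int, int]
    early_set: frozenset[int]
    late_set: frozenset[int]
    homogeneous: bool  # delay range below the block threshold

    def delay_range_ms(self) -> float:
        v = list(self.segment_delay_ms.values())
        return max(v) - min(v)


@dataclass
class PatternResult:
    pattern: str  # "type_I" | "type_II"
    block_edges: frozenset[tuple[int, int]]
    septal_flash: bool
    flash_segments: frozenset[int]
    latest_site: tuple[int, int] | None
    latest_segment: int | None


def segment_delays(
    delaymap: DelayMap,
    model: SegmentModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SegmentSummary:
    """Median delay per AHA segment; early/late sets from delay-range terciles."""
    segs = delaymap.site_segments(model)
    delays: dict[int, float] = {}
    n_valid: dict[int, int] = {}
    for seg in range(1, 17):
        mask = (segs == seg) & delaymap.valid
        n_valid[seg] = int(mask.sum())
        if n_valid[seg] > 0:
            delays[seg] = float(np.median(delaymap.delay_ms[mask]))
    if len(delays) < 4:
        raise PatternError(f"only {len(delays)} segments with valid delays; unclassifiable")
    lo = min(delays.values())
    hi = max(delays.values())
    homogeneous = (hi - lo) < config.block_threshold_ms
    if homogeneous:
        # degenerate spread: no meaningful early/late split
        early = frozenset()
        late = frozenset()
    else:
        # terciles of the delay RANGE, not of the segment count: membership
        # then does not shift when scarred/akinetic segments drop out
        third = (hi - lo) / 3.0
        early = frozenset(s for s, d in delays.items() if d <= lo + third)
        late = frozenset(s for s, d in delays.items() if d >= hi - third)
    return SegmentSummary(
        segment_delay_ms=delays,
        n_valid_sites=n_valid,
        early_set=early,
        late_set=late,
        homogeneous=homogeneous,
    )


def find_block_edges(
    summary: SegmentSummary,
    model: SegmentModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> frozenset[tuple[int, int]]:
    """Adjacent (early, late) pairs with delay difference >= threshold."""
    edges = set()
    for a in summary.early_set:
        for b in summary.late_set:
            if a == b or a not in summary.segment_delay_ms or b not in summary.segment_delay_ms:
                continue
            if not adjacent_segments(a, b, model):
                continue
            if (
                abs(summary.segment_delay_ms[b] - summary.segment_delay_ms[a])
                >= config.block_threshold_ms
            ):
                edges.add((min(a, b), max(a, b)))
    return frozenset(edges)


def classify_pattern(
    summary: SegmentSummary,
    model: SegmentModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
    septal_flash: bool = False,
    flash_segments: frozenset[int] = frozenset(),
    latest: tuple[tuple[int, int], int] | None = None,
) -> PatternResult:
    """Type II iff at least one inferred line of block, else type I."""
    edges = find_block_edges(summary, model, config)
    return PatternResult(
        pattern="type_II" if edges else "type_I",
        block_edges=edges,
        septal_flash=septal_flash,
        flash_segments=flash_segments,
        latest_site=latest[0] if latest else None,
        latest_segment=latest[1] if latest else None,
    )


def detect_septal_flash(
    curves: DisplacementCurveSet,
    model: SegmentModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
    ivc_window_ms: tuple[float, float] | None = None,
) -> tuple[bool, frozenset[int]]:
    """Rapid early inward-then-outward septal motion during isovolumic contraction.

    A site flashes if, within the IVC window, its inward excursion reaches
    the amplitude threshold (fraction of end-diastolic radius) and the curve
    then returns toward baseline by at least half that excursion.  A septal
    segment flashes if at least half of its valid sites flash.
    """
    w0, w1 = ivc_window_ms if ivc_window_ms is not None else config.ivc_window_ms
    n_frames = curves.n_frames
    cycle = n_frames * curves.frame_interval_ms
    if not (0 <= w0 < w1 <= cycle):
        raise PatternError(f"IVC window ({w0}, {w1}) ms outside cycle of {cycle} ms")
    t = np.arange(n_frames) * curves.frame_interval_ms
    in_win = np.flatnonzero((t >= w0) & (t <= w1))
    if in_win.size == 0:
        raise PatternError("IVC window contains no frames")
    # return-to-baseline search extends one window length past the IVC window
    search_end = min(n_frames - 1, int(np.ceil((w1 + (w1 - w0)) / curves.frame_interval_ms)))

    flash_segs = set()
    for s in range(curves.n_slices):
        ring_sectors = model.sectors(model.ring_of_slice[s])
        for lo, hi, seg in ring_sectors:
            if seg not in SEPTAL_SEGMENTS:
                continue
            site_idx = [
                i
                for i, ang in enumerate(curves.angles_deg)
                if lo <= ang < hi and curves.valid[s, i]
            ]
            if not site_idx:
                continue
            n_flash = 0
            for i in site_idx:
                y = curves.disp[s, i]
                seg_win = in_win
                e_idx = seg_win[np.argmax(y[seg_win])]
                e = y[e_idx]
                if e < config.flash_amplitude_frac * curves.r0[s, i]:
                    continue
                trough = y[e_idx : search_end + 1].min()
                if e - trough >= config.flash_return_frac * e:
                    n_flash += 1
            if n_flash >= 0.5 * len(site_idx):
                flash_segs.add(seg)
    return bool(flash_segs), frozenset(flash_segs)


def latest_contracting_site(
    delaymap: DelayMap,
    model: SegmentModel,
    flash_segments: frozenset[int] = frozenset(),
) -> tuple[tuple[int, int], int]:
    """Valid site with the maximum time to peak radial displacement.

    At sites in septal-flash segments, time to peak is the initial (first
    local) displacement peak rather than the later global rebound peak.
    Exact ties resolve to the smaller slice index, then site index.
    """
    if not delaymap.valid.any():
        raise PatternError("no valid sites")
    segs = delaymap.site_segments(model)
    ttp = np.where(
        np.isin(segs, list(flash_segments)) if flash_segments else False,
        delaymap.ttp_first_ms,
        delaymap.ttp_ms,
    )
    ttp = np.where(delaymap.valid, ttp, -np.inf)
    flat = int(np.argmax(ttp))  # row-major argmax = smaller slice, then site
    s, i = np.unravel_index(flat, ttp.shape)
    return (int(s), int(i)), int(segs[s, i])


def max_wall_delay(
    summary: SegmentSummary,
    model: SegmentModel,
    mode: str | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Maximum opposing-wall delay (ms).

    ``mode="opposing"`` (default): max |delay difference| between
    diametrically opposed sectors over all rings; ``mode="range"``: global
    spread of segment delays.  NaN if no opposing pair has delays.
    """
    mode = mode or config.max_wall_delay_mode
    d = summary.segment_delay_ms
    if mode == "range":
        return summary.delay_range_ms()
    if mode != "opposing":
        raise ValueError(f"unknown max_wall_delay mode {mode!r}")
    diffs = [abs(d[a] - d[b]) for a, b in OPPOSING_PAIRS if a in d and b in d]
    if not diffs:
        return float("nan")
    return float(max(diffs))
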