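"""Synthetic short-axis cine contours and cohorts with known activation truth.

The motion model places site (slice s, angle theta) at radius

    r(t) = R0(s) - A (1 - scar) g(t - tau(s, theta)) - flash(t) + noise,

where g is a smooth unimodal contraction waveform (raised-cosine rise to 1
then raised-cosine relaxation), tau is the programmed mechanical activation
delay field, the flash term is an early inward-then-outward pulse confined
to septal-flash segments during the isovolumic window, and a rigid per-frame
translation is applied to every point of the heart together with the
long-axis landmarks.  Within a ring, per-site delays interpolate smoothly
between segment-centre values except across declared lines of block, where
the discontinuity is preserved.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segments import SegmentModel, build_segment_model
from .wallmotion import ContourStack


@dataclass
class SimParams:
    """Acquisition and motion parameters for one synthetic patient.

    Defaults emulate a typical retrospectively gated cine acquisition:
    30 frames at 33 ms, nine 8 mm slices, 100 points per contour.
    """

    n_frames: int = 30
    frame_interval_ms: float = 33.0
    n_slices: int = 9
    n_points: int = 100
    base_radius_mm: np.ndarray | None = None  # per-slice; default basal->apical taper
    contraction_amplitude_mm: float = 8.0
    contraction_rise_ms: float = 330.0
    contraction_fall_ms: float = 400.0
    flash_amplitude_frac: float = 0.12
    flash_window_ms: tuple[float, float] = (0.0, 80.0)
    translation_amplitude_mm: float = 0.0
    noise_sd_mm: float = 0.0
    slice_spacing_mm: float = 8.0
    #: rotates the rendered boundary points off the analysis angle grid to
    #: exercise contour resampling; ground-truth site delays are always
    #: reported on the standard grid
    point_angle_offset_deg: float = 0.0
    seed: int = 0

    def radii(self) -> np.ndarray:
        if self.base_radius_mm is not None:
            return np.asarray(self.base_radius_mm, dtype=float)
        return np.linspace(28.0, 14.0, self.n_slices)

    @property
    def cycle_length_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms


@dataclass
class ActivationTruth:
    """Ground-truth activation programmed into a synthetic patient."""

    segment_delays_ms: dict[int, float]
    pattern_label: str  # "type_I" | "type_II"
    block_edges: frozenset[tuple[int, int]]
    flash_segments: frozenset[int]
    scar_segments: dict[int, float]
    latest_segment: int
    site_delay_ms: np.ndarray | None = None  # (n_slices, n_points), filled by generator

    def __post_init__(self):
        if self.pattern_label == "type_II" and not self.block_edges:
            raise ValueError("type_II truth requires at least one block edge")
        if any(not 0.0 <= v <= 1.0 for v in self.scar_segments.values()):
            raise ValueError("scar transmurality fractions must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "pattern": self.pattern_label,
                "segment_delays_ms": {str(k): v for k, v in self.segment_delays_ms.items()},
                "block_edges": sorted(map(list, self.block_edges)),
                "flash_segments": sorted(self.flash_segments),
                "scar_segments": {str(k): v for k, v in self.scar_segments.items()},
                "latest_segment": self.latest_segment,
            },
            indent=2,
        )


# angular centre of each 60/90-degree sector (degrees)
_SEGMENT_CENTER = {
    1: 30.0, 6: 90.0, 5: 150.0, 4: 210.0, 3: 270.0, 2: 330.0,
    7: 30.0, 12: 90.0, 11: 150.0, 10: 210.0, 9: 270.0, 8: 330.0,
    13: 45.0, 16: 135.0, 15: 225.0, 14: 315.0,
}
_SEPTUM_CENTER_DEG = 300.0  # mid-septum, between inferoseptal and anteroseptal


def _angular_distance(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def make_type1_truth(
    base_delay_ms: float = 40.0,
    spread_ms: float = 350.0,
    flash: bool = False,
    scar_segments: dict[int, float] | None = None,
) -> ActivationTruth:
    """Homogeneous septum-to-free-wall gradient; no adjacent early/late pair.

    Delay grows linearly with angular distance from the mid-septum, so
    adjacent 60-degree sectors differ by well under a line-of-block
    threshold while the full septal-lateral spread remains large.
    """
    delays = {
        seg: base_delay_ms + spread_ms * _angular_distance(c, _SEPTUM_CENTER_DEG) / 165.0
        for seg, c in _SEGMENT_CENTER.items()
    }
    scar = dict(scar_segments or {})
    latest = _latest_from_delays(delays, scar)
    return ActivationTruth(
        segment_delays_ms=delays,
        pattern_label="type_I",
        block_edges=frozenset(),
        flash_segments=frozenset({3, 9} if flash else set()),
        scar_segments=scar,
        latest_segment=latest,
    )


def make_type2_truth(
    block: str = "inferior",
    base_delay_ms: float = 40.0,
    rate_ms_per_deg: float = 1.25,
    flash: bool = True,
    scar_segments: dict[int, float] | None = None,
) -> ActivationTruth:
    """U-shaped activation with an inferred line of block.

    ``block="inferior"``: breakout at the inferoseptum, wavefront sweeping
    anteriorly around the free wall so the inferior wall activates last
    across an inferoseptal/inferior line of block.  ``block="anterior"``
    mirrors this (anteroseptal breakout, clockwise sweep, anterior last).
    """
    if block == "inferior":
        breakout = 270.0
        path = lambda c: (c - breakout) % 360.0  # noqa: E731  counterclockwise sweep
        edges = frozenset({(3, 4), (9, 10), (14, 15)})
        flash_segs = {3, 9}
        bump_seg = 10  # unique latest: mid inferior
    elif block == "anterior":
        breakout = 330.0
        path = lambda c: (breakout - c) % 360.0  # noqa: E731  clockwise sweep
        edges = frozenset({(1, 2), (7, 8), (13, 14)})
        flash_segs = {2, 8}
        bump_seg = 7  # unique latest: mid anterior
    else:
        raise ValueError("block must be 'inferior' or 'anterior'")
    delays = {
        seg: base_delay_ms + rate_ms_per_deg * path(c) for seg, c in _SEGMENT_CENTER.items()
    }
    delays[bump_seg] += 30.0
    scar = dict(scar_segments or {})
    latest = _latest_from_delays(delays, scar)
    return ActivationTruth(
        segment_delays_ms=delays,
        pattern_label="type_II",
        block_edges=edges,
        flash_segments=frozenset(flash_segs if flash else set()),
        scar_segments=scar,
        latest_segment=latest,
    )


def _latest_from_delays(delays: dict[int, float], scar: dict[int, float]) -> int:
    viable = {s: d for s, d in delays.items() if scar.get(s, 0.0) <= 0.5}
    return max(viable, key=viable.get)


def contraction_waveform(t_ms: np.ndarray, rise_ms: float, fall_ms: float) -> np.ndarray:
    """Smooth unimodal waveform: 0 before onset, raised-cosine up to 1 at
    ``rise_ms``, raised-cosine back to 0 over ``fall_ms``."""
    t = np.asarray(t_ms, dtype=float)
    g = np.zeros_like(t)
    rising = (t >= 0) & (t <= rise_ms)
    g[rising] = 0.5 * (1 - np.cos(np.pi * t[rising] / rise_ms))
    falling = t > rise_ms
    tf = np.minimum(t[falling] - rise_ms, fall_ms)
    g[falling] = 0.5 * (1 + np.cos(np.pi * tf / fall_ms))
    return g


def _site_delay_field(
    model: SegmentModel, truth: ActivationTruth, angles_deg: np.ndarray
) -> np.ndarray:
    """Per-site delays: circular interpolation between sector centres within
    each ring, stepping (no interpolation) across declared block edges."""
    block = {frozenset(e) for e in truth.block_edges}
    out = np.empty((model.n_slices, angles_deg.size))
    ring_cache: dict[str, np.ndarray] = {}
    for s in range(model.n_slices):
        ring = model.ring_of_slice[s]
        if ring not in ring_cache:
            sectors = model.sectors(ring)
            segs = [seg for _, _, seg in sectors]
            order = np.argsort([_SEGMENT_CENTER[seg] for seg in segs])
            segs = [segs[i] for i in order]
            centers = np.array([_SEGMENT_CENTER[seg] for seg in segs])
            vals = np.array([truth.segment_delays_ms[seg] for seg in segs])
            site_vals = np.empty(angles_deg.size)
            for i, theta in enumerate(angles_deg):
                j = int(np.searchsorted(centers, theta, side="right") - 1) % len(segs)
                j2 = (j + 1) % len(segs)
                c0, c1 = centers[j], centers[j2]
                span = (c1 - c0) % 360.0
                w = ((theta - c0) % 360.0) / span if span > 0 else 0.0
                if frozenset({segs[j], segs[j2]}) in block:
                    # hold each sector's value up to the sector boundary
                    own = _owning_segment(theta, model.sectors(ring))
                    site_vals[i] = truth.segment_delays_ms[own]
                else:
                    site_vals[i] = (1 - w) * vals[j] + w * vals[j2]
            ring_cache[ring] = site_vals
        out[s] = ring_cache[ring]
    return out


def _owning_segment(theta: float, sectors) -> int:
    t = theta % 360.0
    for lo, hi, seg in sectors:
        if lo <= t < hi:
            return seg
    raise AssertionError  # pragma: no cover


def generate_patient(
    params: SimParams, truth: ActivationTruth
) -> tuple[ContourStack, ActivationTruth]:
    """Render a contour stack realizing the given activation truth."""
    if max(truth.segment_delays_ms.values()) >= params.cycle_length_ms:
        raise ValueError("programmed delays must be shorter than the cycle length")
    rng = np.random.default_rng(params.seed)
    model = build_segment_model(params.n_slices)
    F, S, P = params.n_frames, params.n_slices, params.n_points
    t = np.arange(F) * params.frame_interval_ms
    grid_angles = np.arange(P) * 360.0 / P
    angles = (grid_angles + params.point_angle_offset_deg) % 360.0
    tau = _site_delay_field(model, truth, angles)
    # ground truth is reported on the standard analysis angle grid
    tau_truth = tau if params.point_angle_offset_deg == 0 else _site_delay_field(
        model, truth, grid_angles
    )
    truth = replace(truth, site_delay_ms=tau_truth)
    R0 = params.radii()

    seg_of = np.empty((S, P), dtype=int)
    for s in range(S):
        for i, a in enumerate(angles):
            seg_of[s, i] = _owning_segment(a, model.sectors(model.ring_of_slice[s]))
    amp_mult = np.ones((S, P))
    for seg, frac in truth.scar_segments.items():
        amp_mult[seg_of == seg] = 1.0 - frac
    flash_mask = np.isin(seg_of, list(truth.flash_segments))

    g = contraction_waveform(
        t[None, None, :] - tau[:, :, None], params.contraction_rise_ms, params.contraction_fall_ms
    )
    r = R0[:, None, None] - params.contraction_amplitude_mm * amp_mult[:, :, None] * g
    if flash_mask.any():
        w0, w1 = params.flash_window_ms
        pulse = np.zeros(F)
        inside = (t >= w0) & (t <= w1)
        pulse[inside] = np.sin(np.pi * (t[inside] - w0) / (w1 - w0)) ** 2
        r -= (
            params.flash_amplitude_frac
            * R0[:, None, None]
            * flash_mask[:, :, None]
            * pulse[None, None, :]
        )
    if params.noise_sd_mm > 0:
        r = r + rng.normal(0.0, params.noise_sd_mm, size=r.shape)

    # rigid whole-heart in-plane translation, zero at frame 0
    T_xy = np.zeros((F, 2))
    if params.translation_amplitude_mm > 0:
        phase = 2 * np.pi * t / params.cycle_length_ms
        T_xy[:, 0] = params.translation_amplitude_mm * np.sin(phase)
        T_xy[:, 1] = params.translation_amplitude_mm * 0.6 * np.sin(phase + 1.0)

    rad = np.deg2rad(angles)
    unit = np.stack([np.cos(rad), np.sin(rad)], axis=-1)  # (P, 2)
    pts = r.transpose(2, 0, 1)[:, :, :, None] * unit[None, None, :, :]  # (F,S,P,2)
    pts = pts + T_xy[:, None, None, :]

    slice_z = (np.arange(S) + 0.5) * params.slice_spacing_mm
    lv_length = (S + 0.5) * params.slice_spacing_mm
    mitral = np.zeros((F, 3))
    apex = np.zeros((F, 3))
    apex[:, 2] = lv_length
    mitral[:, :2] += T_xy
    apex[:, :2] += T_xy
    stack = ContourStack(
        points=pts,
        mitral_centre=mitral,
        apex=apex,
        slice_z=slice_z,
        frame_interval_ms=params.frame_interval_ms,
        slice_spacing_mm=params.slice_spacing_mm,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohort-level simulation (covariates + outcome; no contour rendering)
# ---------------------------------------------------------------------------

@dataclass
class CohortMix:
    """Stratum prevalences, defaulting to the 33-patient study cohort."""

    p_type2: float = 20 / 33
    p_concordant_given_type2: float = 12 / 20
    p_concordant_given_type1: float = 6 / 13
    p_nicm_given_type2: float = 18 / 20
    p_nicm_given_type1: float = 8 / 13
    p_ecg_given_type2: float = 11 / 20
    p_ecg_given_type1: float = 2 / 13
    p_flash_given_type2: float = 1.0
    p_flash_given_type1: float = 7 / 13
    p_scar_given_type2: float = 2 / 20
    p_scar_given_type1: float = 6 / 13
    maxdelay_type2: tuple[float, float] = (471.0, 106.0)
    maxdelay_type1: tuple[float, float] = (371.0, 117.0)
    esv_mean_ml: float = 150.0
    esv_sd_ml: float = 71.0


@dataclass
class OutcomeModel:
    """Logistic response model: logit(p) = b0 + b_t2cl*T2CL (+ optional terms).

    Defaults reproduce the study's marginal rates: non-T2CL response 1/3
    (b0 = log 0.5) and a T2CL odds ratio of 22.
    """

    intercept: float = float(np.log(0.5))
    beta_t2cl: float = float(np.log(22.0))
    beta_nicm: float = 0.0
    beta_ecg: float = 0.0


def generate_cohort(
    n: int,
    mix: CohortMix | None = None,
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    response_fraction: float = 0.15,
) -> pd.DataFrame:
    """Draw a covariate/outcome table with known generating model.

    ESV follow-up is drawn consistent with the response label and the
    >= 15 % reduction rule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = mix or CohortMix()
    om = outcome_model or OutcomeModel()
    extreme = [
        p
        for p in (mix.p_type2, mix.p_concordant_given_type2, mix.p_concordant_given_type1)
        if p in (0.0, 1.0)
    ]
    if extreme and n < 10:
        warnings.warn("degenerate mixture: 0/1 stratum probabilities with small n")
    rng = np.random.default_rng(seed)
    type2 = rng.random(n) < mix.p_type2
    p_conc = np.where(type2, mix.p_concordant_given_type2, mix.p_concordant_given_type1)
    concordant = rng.random(n) < p_conc
    t2cl = type2 & concordant
    nicm = rng.random(n) < np.where(type2, mix.p_nicm_given_type2, mix.p_nicm_given_type1)
    ecg = rng.random(n) < np.where(type2, mix.p_ecg_given_type2, mix.p_ecg_given_type1)
    flash = rng.random(n) < np.where(type2, mix.p_flash_given_type2, mix.p_flash_given_type1)
    scar = rng.random(n) < np.where(type2, mix.p_scar_given_type2, mix.p_scar_given_type1)
    mwd = np.where(
        type2,
        rng.normal(*mix.maxdelay_type2, size=n),
        rng.normal(*mix.maxdelay_type1, size=n),
    ).clip(min=50.0)
    logit = (
        om.intercept
        + om.beta_t2cl * t2cl
        + om.beta_nicm * nicm
        + om.beta_ecg * ecg
    )
    responder = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    esv0 = rng.normal(mix.esv_mean_ml, mix.esv_sd_ml, size=n).clip(min=50.0)
    red = np.where(
        responder,
        rng.uniform(response_fraction, 0.50, size=n),
        rng.uniform(-0.20, response_fraction, size=n),
    )
    esv1 = esv0 * (1.0 - red)
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "nicm": nicm,
            "favorable_ecg": ecg,
            "type_ii": type2,
            "concordant": concordant,
            "t2cl": t2cl,
            "septal_flash": flash,
            "scar": scar,
            "max_wall_delay_ms": mwd,
            "esv_baseline_ml": esv0,
            "esv_followup_ml": esv1,
            "responder": responder,
        }
    )


def write_patient_csvs(stack: ContourStack, truth: ActivationTruth, outdir, patient_id: int = 0):
    """Emit contours.csv / landmarks.csv / truth.json for one patient."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    F, S, P, _ = stack.points.shape
    f_idx, s_idx, p_idx = np.meshgrid(
        np.arange(F), np.arange(S), np.arange(P), indexing="ij"
    )
    pd.DataFrame(
        {
            "patient_id": patient_id,
            "frame": f_idx.ravel(),
            "slice": s_idx.ravel(),
            "point_index": p_idx.ravel(),
            "x_mm": stack.points[..., 0].ravel(),
            "y_mm": stack.points[..., 1].ravel(),
        }
    ).to_csv(outdir / "contours.csv", index=False)
    lm = []
    for f in range(F):
        for name, arr in (("mitral_centre", stack.mitral_centre), ("apex", stack.apex)):
            lm.append(
                {
                    "patient_id": patient_id,
                    "frame": f,
                    "structure": name,
                    "x_mm": arr[f, 0],
                    "y_mm": arr[f, 1],
                    "z_mm": arr[f, 2],
                }
            )
    pd.DataFrame(lm).to_csv(outdir / "landmarks.csv", index=False)
    (outdir / "truth.json").write_text(truth.to_json())


def read_patient_csvs(outdir, patient_id: int = 0, frame_interval_ms: float = 33.0,
                      slice_spacing_mm: float = 8.0) -> ContourStack:
    """Rebuild a ContourStack from contours.csv / landmarks.csv."""
    from pathlib import Path

    outdir = Path(outdir)
    con = pd.read_csv(outdir / "contours.csv")
    con = con[con.patient_id == patient_id]
    F = con.frame.max() + 1
    S = con["slice"].max() + 1
    P = con.point_index.max() + 1
    pts = np.full((F, S, P, 2), np.nan)
    pts[con.frame, con["slice"], con.point_index, 0] = con.x_mm
    pts[con.frame, con["slice"], con.point_index, 1] = con.y_mm
    lm = pd.read_csv(outdir / "landmarks.csv")
    lm = lm[lm.patient_id == patient_id]
    mitral = np.full((F, 3), np.nan)
    apex = np.full((F, 3), np.nan)
    for _, row in lm.iterrows():
        tgt = mitral if row.structure == "mitral_centre" else apex
        tgt[int(row.frame)] = (row.x_mm, row.y_mm, row.z_mm)
    slice_z = (np.arange(S) + 0.5) * slice_spacing_mm
    return ContourStack(
        points=pts,
        mitral_centre=mitral,
        apex=apex,
        slice_z=slice_z,
        frame_interval_ms=frame_interval_ms,
        slice_spacing_mm=slice_spacing_mm,
    )
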