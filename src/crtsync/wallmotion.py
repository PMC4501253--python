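"""Radial displacement curves and cross-correlation mechanical delay maps.

The measurement chain: per-frame endocardial contours are resampled at 100
circumferentially spaced angles about a translation-corrected LV centroid;
radial displacement (inward positive, zero at the first frame) is computed
per site; each site's curve is cross-correlated against a patient-specific
reference curve and the lag of peak normalized correlation, refined to
sub-frame precision by parabolic interpolation, is the site's mechanical
delay.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .segments import SegmentModel, site_to_segment

N_SITES = 100


class WallMotionError(ValueError):
    pass


@dataclass
class ContourStack:
    """Per-frame, per-slice closed endocardial boundaries plus landmarks.

    ``points``: (n_frames, n_slices, n_points, 2) in-plane mm coordinates.
    ``mitral_centre`` / ``apex``: (n_frames, 3) mm, sharing x/y axes with the
    contours; the long axis is the mitral-centre -> apex line.
    ``slice_z``: (n_slices,) long-axis position of each slice (mm).
    """

    points: np.ndarray
    mitral_centre: np.ndarray
    apex: np.ndarray
    slice_z: np.ndarray
    frame_interval_ms: float
    slice_spacing_mm: float

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_slices(self) -> int:
        return self.points.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ms

    @property
    def cycle_length_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms


@dataclass
class DisplacementCurveSet:
    """Inward-positive radial displacement at 100 sites per slice.

    ``disp``: (n_slices, 100, n_frames) mm; zero at frame 0 by construction.
    ``r0``: (n_slices, 100) end-diastolic radius per site (mm).
    """

    disp: np.ndarray
    r0: np.ndarray
    centroids: np.ndarray  # (n_frames, n_slices, 2)
    valid: np.ndarray  # (n_slices, 100) bool
    angles_deg: np.ndarray  # (100,)
    frame_interval_ms: float

    @property
    def n_slices(self) -> int:
        return self.disp.shape[0]

    @property
    def n_frames(self) -> int:
        return self.disp.shape[2]


@dataclass
class DelayMap:
    """Per-site mechanical delay (ms) relative to the reference curve.

    ``ttp_ms`` is the time of global peak displacement; ``ttp_first_ms`` is
    the time of the first local displacement peak after motion onset, used
    in place of the global peak at septal-flash sites.
    """

    delay_ms: np.ndarray  # (n_slices, 100)
    corr_peak: np.ndarray
    ttp_ms: np.ndarray
    ttp_first_ms: np.ndarray
    valid: np.ndarray
    angles_deg: np.ndarray
    frame_interval_ms: float

    def site_segments(self, model: SegmentModel) -> np.ndarray:
        """(n_slices, 100) array of AHA segment ids."""
        n_slices = self.delay_ms.shape[0]
        out = np.empty((n_slices, self.angles_deg.size), dtype=int)
        for s in range(n_slices):
            for i, ang in enumerate(self.angles_deg):
                out[s, i] = site_to_segment(s, ang, model)
        return out


def centroid_track(stack: ContourStack) -> np.ndarray:
    """Per-frame, per-slice LV centroid from the long-axis landmarks.

    The centroid of slice ``s`` at frame ``f`` is the point on the mitral
    centre -> apex line at the slice's long-axis position, so rigid
    whole-heart translation of the landmarks translates every centroid
    identically.
    """
    m, a = stack.mitral_centre, stack.apex
    if np.isnan(m).any() or np.isnan(a).any():
        raise WallMotionError("landmarks missing for one or more frames")
    dz = a[:, 2] - m[:, 2]
    if np.any(np.abs(dz) < 1e-9):
        raise WallMotionError("degenerate long axis (mitral centre and apex coincide)")
    # fractional long-axis position of each slice, per frame
    frac = (stack.slice_z[None, :] - m[:, 2:3]) / dz[:, None]  # (F, S)
    cent = m[:, None, :2] + frac[..., None] * (a[:, None, :2] - m[:, None, :2])
    return cent


def _resample_radii(contour: np.ndarray, centre: np.ndarray, target_rad: np.ndarray) -> np.ndarray:
    """Radii of a closed polygon along rays from ``centre`` at given angles.

    Uses exact ray/edge intersection (arc-length-parameterized linear
    interpolation along the boundary).  Returns NaN everywhere if the centre
    is not enclosed by the polygon (winding test).
    """
    p = contour - centre[None, :]
    phi = np.arctan2(p[:, 1], p[:, 0])
    dphi = np.diff(np.concatenate([phi, phi[:1]]))
    dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
    winding = dphi.sum() / (2 * np.pi)
    if abs(abs(winding) - 1.0) > 0.1:
        return np.full(target_rad.size, np.nan)
    if winding < 0:  # enforce counterclockwise orientation
        p = p[::-1]
        phi = phi[::-1]
    # roll so that vertex angles are sorted ascending (star-shaped boundary)
    start = int(np.argmin(phi))
    p = np.roll(p, -start, axis=0)
    phi = np.roll(phi, -start)
    phi = np.unwrap(phi)
    # pad with the wrapped-around first vertex to close the cycle
    p_ext = np.vstack([p, p[:1]])
    phi_ext = np.concatenate([phi, phi[:1] + 2 * np.pi])
    theta = target_rad.copy()
    theta = phi_ext[0] + (theta - phi_ext[0]) % (2 * np.pi)
    idx = np.clip(np.searchsorted(phi_ext, theta, side="right") - 1, 0, len(p) - 1)
    p1, p2 = p_ext[idx], p_ext[idx + 1]
    d = np.column_stack([np.cos(theta), np.sin(theta)])
    c1 = d[:, 0] * p1[:, 1] - d[:, 1] * p1[:, 0]
    c2 = d[:, 0] * p2[:, 1] - d[:, 1] * p2[:, 0]
    denom = c1 - c2
    u = np.where(np.abs(denom) > 1e-12, c1 / np.where(denom == 0, 1.0, denom), 0.0)
    pt = p1 + u[:, None] * (p2 - p1)
    return pt[:, 0] * d[:, 0] + pt[:, 1] * d[:, 1]


def radial_displacement_curves(
    stack: ContourStack, centroids: np.ndarray | None = None, n_sites: int = N_SITES
) -> DisplacementCurveSet:
    """Resample contours at ``n_sites`` equal angles and difference radii.

    displacement(t) = r(0) - r(t), inward positive.  A slice whose centroid
    falls outside the contour on any frame is marked invalid.
    """
    if centroids is None:
        centroids = centroid_track(stack)
    F, S = stack.n_frames, stack.n_slices
    angles_deg = np.arange(n_sites) * (360.0 / n_sites)
    target = np.deg2rad(angles_deg)
    radii = np.empty((S, n_sites, F))
    valid = np.ones((S, n_sites), dtype=bool)
    for s in range(S):
        for f in range(F):
            radii[s, :, f] = _resample_radii(stack.points[f, s], centroids[f, s], target)
        if np.isnan(radii[s]).any():
            valid[s, :] = False
            radii[s] = np.nan_to_num(radii[s])
    r0 = radii[:, :, 0].copy()
    disp = r0[:, :, None] - radii
    return DisplacementCurveSet(
        disp=disp,
        r0=r0,
        centroids=centroids,
        valid=valid,
        angles_deg=angles_deg,
        frame_interval_ms=stack.frame_interval_ms,
    )


def reference_curve(curves: DisplacementCurveSet) -> np.ndarray:
    """Patient-specific reference: pointwise mean over all valid site curves."""
    if not curves.valid.any():
        raise WallMotionError("no valid sites to build a reference curve")
    return curves.disp[curves.valid].mean(axis=0)


def _parabolic_offset(ym1: float, y0: float, yp1: float) -> float:
    denom = ym1 - 2 * y0 + yp1
    if denom >= -1e-12:  # not a strict local max on the sampled grid
        return 0.0
    off = 0.5 * (ym1 - yp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def xcorr_delay(
    curve: np.ndarray,
    reference: np.ndarray,
    frame_interval_ms: float,
    max_lag_frames: int | None = None,
) -> tuple[float, float]:
    """Delay (ms) of peak normalized cross-correlation, sub-frame refined.

    Positive delay means the curve lags the reference.  The lag search is
    bounded to +/- half the cycle; ties at the peak resolve toward the
    smaller absolute lag; zero-variance inputs raise.
    """
    d, c = _xcorr_delay_many(curve[None, :], reference, frame_interval_ms, max_lag_frames)
    if np.isnan(d[0]):
        raise WallMotionError("constant (zero-variance) curve has no defined delay")
    return float(d[0]), float(c[0])


def _xcorr_delay_many(
    curves: np.ndarray,
    reference: np.ndarray,
    frame_interval_ms: float,
    max_lag_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized xcorr_delay over rows of ``curves`` (M, T)."""
    M, T = curves.shape
    if reference.shape[0] != T:
        raise WallMotionError("curve and reference must have equal length")
    if max_lag_frames is None:
        max_lag_frames = T // 2
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    cc = np.full((M, lags.size), -np.inf)
    for j, lag in enumerate(lags):
        # positive lag: curve shifted back aligns with reference
        if lag >= 0:
            x = curves[:, lag:]
            y = reference[: T - lag]
        else:
            x = curves[:, :lag]
            y = reference[-lag:]
        if y.size < 3:
            continue
        xm = x - x.mean(axis=1, keepdims=True)
        ym = y - y.mean()
        sx = np.sqrt((xm**2).sum(axis=1))
        sy = np.sqrt((ym**2).sum())
        denom = sx * sy
        ok = denom > 1e-12
        cc[ok, j] = (xm[ok] @ ym) / denom[ok]
    delays = np.full(M, np.nan)
    peaks = np.full(M, np.nan)
    site_var = curves.std(axis=1) > 1e-12
    for m in range(M):
        if not site_var[m] or not np.isfinite(cc[m]).any():
            continue
        row = cc[m]
        best = row.max()
        # ties toward the smaller |lag|
        cand = np.flatnonzero(row >= best - 1e-12)
        k = cand[np.argmin(np.abs(lags[cand]))]
        off = 0.0
        # a perfect correlation is an exact alignment: no sub-frame refinement
        if (
            row[k] < 1.0 - 1e-9
            and 0 < k < lags.size - 1
            and np.isfinite(row[k - 1])
            and np.isfinite(row[k + 1])
        ):
            off = _parabolic_offset(row[k - 1], row[k], row[k + 1])
        delays[m] = (lags[k] + off) * frame_interval_ms
        peaks[m] = min(1.0, row[k] - 0.25 * (row[k - 1] - row[k + 1]) * off) if off else row[k]
    return delays, peaks


def delay_recovery_error(estimated: np.ndarray, true: np.ndarray) -> float:
    """Max absolute delay error after best-constant alignment (ms).

    Cross-correlation delays are relative to the patient-specific reference
    curve, so the absolute origin is not identified; recovery is judged up
    to the constant offset that minimizes the maximum residual.
    """
    resid = np.asarray(estimated, dtype=float) - np.asarray(true, dtype=float)
    resid = resid[np.isfinite(resid)]
    if resid.size == 0:
        raise WallMotionError("no finite delay estimates to compare")
    centre = (resid.max() + resid.min()) / 2.0
    return float(np.abs(resid - centre).max())


def time_to_peak(
    curve: np.ndarray,
    frame_interval_ms: float,
    first_peak: bool = False,
    onset_frac: float = 0.1,
) -> float:
    """Time (ms) of peak radial displacement, refined sub-frame.

    With ``first_peak`` (septal-flash handling) the time of the first local
    maximum at or after motion onset is returned instead of the global
    maximum; a monotone curve returns the last frame's time.
    """
    y = np.asarray(curve, dtype=float)
    T = y.size
    if first_peak:
        peak = y.max()
        onset = int(np.argmax(y > onset_frac * peak)) if peak > 0 else 0
        k = None
        for i in range(max(onset, 1), T - 1):
            if y[i] >= y[i - 1] and y[i] >= y[i + 1] and y[i] >= onset_frac * peak:
                k = i
                break
        if k is None:
            k = int(np.argmax(y))
    else:
        k = int(np.argmax(y))
    if k == 0 or k == T - 1:
        return k * frame_interval_ms
    # parabolic refinement of the maximum of y
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    off = 0.0 if denom >= -1e-12 else float(np.clip(0.5 * (y[k - 1] - y[k + 1]) / denom, -0.5, 0.5))
    return (k + off) * frame_interval_ms


def compute_delay_map(
    curves: DisplacementCurveSet, config: AnalysisConfig = DEFAULT_CONFIG
) -> DelayMap:
    """Cross-correlate every valid site against the reference curve."""
    S, n_sites, F = curves.disp.shape
    if config.reference == "mean":
        ref = reference_curve(curves)
    elif config.reference == "septal":
        from .segments import SEPTAL_SEGMENTS, build_segment_model

        model = build_segment_model(S)
        segs = np.empty((S, n_sites), dtype=int)
        for s in range(S):
            for i, ang in enumerate(curves.angles_deg):
                segs[s, i] = site_to_segment(s, ang, model)
        mask = curves.valid & np.isin(segs, list(SEPTAL_SEGMENTS))
        if not mask.any():
            raise WallMotionError("no valid septal sites for septal reference")
        ref = curves.disp[mask].mean(axis=0)
    else:
        raise ValueError(f"unknown reference mode {config.reference!r}")
    flat = curves.disp.reshape(S * n_sites, F)
    delays, peaks = _xcorr_delay_many(flat, ref, curves.frame_interval_ms)
    delay_ms = delays.reshape(S, n_sites)
    corr = peaks.reshape(S, n_sites)
    valid = curves.valid & np.isfinite(delay_ms)
    ttp = np.empty((S, n_sites))
    ttp_first = np.empty((S, n_sites))
    for s in range(S):
        for i in range(n_sites):
            ttp[s, i] = time_to_peak(curves.disp[s, i], curves.frame_interval_ms)
            ttp_first[s, i] = time_to_peak(
                curves.disp[s, i], curves.frame_interval_ms, first_peak=True
            )
    return DelayMap(
        delay_ms=np.where(valid, delay_ms, np.nan),
        corr_peak=np.where(valid, corr, np.nan),
        ttp_ms=ttp,
        ttp_first_ms=ttp_first,
        valid=valid,
        angles_deg=curves.angles_deg,
        frame_interval_ms=curves.frame_interval_ms,
    )


def exclude_akinetic(
    curves: DisplacementCurveSet,
    delaymap: DelayMap,
    model: SegmentModel,
    scar: dict[int, float] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> DelayMap:
    """Mask akinetic / passively moving sites out of the delay map.

    A site is excluded if its segment's scar transmurality exceeds the
    non-viability cutoff, its peak displacement is below the amplitude
    threshold, or its peak correlation is below the correlation floor.
    """
    scar = scar or {}
    segs = delaymap.site_segments(model)
    peak_disp = curves.disp.max(axis=2)
    valid = delaymap.valid.copy()
    for seg, frac in scar.items():
        if frac > config.scar_transmurality_cutoff:
            valid &= segs != seg
    valid &= peak_disp >= config.akinetic_amplitude_mm
    valid &= np.nan_to_num(delaymap.corr_peak, nan=-1.0) >= config.correlation_floor
    if not valid.any():
        raise WallMotionError("all sites excluded: no analyzable wall motion")
    return replace(
        delaymap,
        valid=valid,
        delay_ms=np.where(valid, delaymap.delay_ms, np.nan),
        corr_peak=np.where(valid, delaymap.corr_peak, np.nan),
    )
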