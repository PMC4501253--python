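"""Validation experiments for the measurement pipeline and the statistics.

These routines regenerate synthetic data with known ground truth, run the
analysis end to end, and score recovery.  They back both the test suite and
the acceptance script; every routine is deterministic given its seed.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from .stats import (
    ContingencyTable2x2,
    fisher_exact_2x2,
    logistic_fit,
    roc_auc_delong,
)
from .synth import (
    OutcomeModel,
    SimParams,
    generate_cohort,
    generate_patient,
    make_type1_truth,
    make_type2_truth,
)
from .wallmotion import (
    compute_delay_map,
    delay_recovery_error,
    radial_displacement_curves,
)


def _study_truth(rng: np.random.Generator, pattern: str):
    """Draw one patient's activation template at the study's stratum rates."""
    if pattern == "type_II":
        block = "inferior" if rng.random() < 0.75 else "anterior"
        scar = {int(rng.integers(4, 7)): 0.8} if rng.random() < 2 / 20 else None
        return make_type2_truth(block=block, flash=True, scar_segments=scar)
    flash = rng.random() < 7 / 13
    scar = {int(rng.integers(4, 7)): 0.8} if rng.random() < 6 / 13 else None
    return make_type1_truth(flash=flash, scar_segments=scar)


def classification_recovery(
    n_patients: int = 200, noise_sd_mm: float = 0.5, seed: int = 0
) -> dict:
    """Fraction of synthetic patients whose pattern call matches truth.

    The cohort mixes patterns at the study rate (13:20) with study-rate
    flash, scar and block-orientation strata.
    """
    from .reproduce import analyze_patient

    rng = np.random.default_rng(seed)
    n_type1 = round(n_patients * 13 / 33)
    labels = ["type_I"] * n_type1 + ["type_II"] * (n_patients - n_type1)
    correct = {"type_I": 0, "type_II": 0}
    totals = {"type_I": 0, "type_II": 0}
    for k, label in enumerate(labels):
        truth = _study_truth(rng, label)
        params = SimParams(seed=int(rng.integers(0, 2**31)), noise_sd_mm=noise_sd_mm)
        stack, truth = generate_patient(params, truth)
        record = analyze_patient(stack, scar=truth.scar_segments or None)
        totals[label] += 1
        correct[label] += record["pattern"] == label
    return {
        "type_I_accuracy": correct["type_I"] / totals["type_I"],
        "type_II_accuracy": correct["type_II"] / totals["type_II"],
        "n": n_patients,
    }


def latest_segment_recovery(n_patients: int = 40, seed: int = 0) -> dict:
    """Noise-free latest-contracting-segment recovery rate."""
    from .reproduce import analyze_patient

    rng = np.random.default_rng(seed)
    hits = 0
    for k in range(n_patients):
        label = "type_I" if k % 3 == 0 else "type_II"
        truth = _study_truth(rng, label)
        stack, truth = generate_patient(
            SimParams(seed=int(rng.integers(0, 2**31))), truth
        )
        record = analyze_patient(stack, scar=truth.scar_segments or None)
        hits += record["latest_segment"] == truth.latest_segment
    return {"recovery_rate": hits / n_patients, "n": n_patients}


def delay_recovery(seed: int = 0) -> dict:
    """Max per-site delay error (ms) on noise-free patients, flash off."""
    worst = 0.0
    cases = (
        make_type2_truth(block="inferior", flash=False),
        make_type2_truth(block="anterior", flash=False),
        make_type1_truth(),
    )
    for offset, truth in enumerate(cases):
        stack, truth = generate_patient(SimParams(seed=seed + offset), truth)
        dm = compute_delay_map(radial_displacement_curves(stack))
        err = delay_recovery_error(dm.delay_ms[dm.valid], truth.site_delay_ms[dm.valid])
        worst = max(worst, err)
    return {"max_error_ms": worst, "n": 3 * 900}


def translation_invariance(seed: int = 0, amplitude_mm: float = 5.0) -> dict:
    """Max delay-map change (ms) under rigid per-frame translation."""
    truth = make_type2_truth(flash=False)
    still, _ = generate_patient(SimParams(seed=seed), truth)
    moved, _ = generate_patient(
        SimParams(seed=seed, translation_amplitude_mm=amplitude_mm), truth
    )
    dm0 = compute_delay_map(radial_displacement_curves(still))
    dm1 = compute_delay_map(radial_displacement_curves(moved))
    both = dm0.valid & dm1.valid
    return {
        "max_shift_ms": float(np.nanmax(np.abs(dm0.delay_ms[both] - dm1.delay_ms[both]))),
        "n": int(both.sum()),
    }


_MULTI_MODEL = OutcomeModel(
    intercept=-2.2,
    beta_t2cl=float(np.log(18.0)),
    beta_nicm=float(np.log(3.1)),
    beta_ecg=float(np.log(3.0)),
)


def multivariate_ci_coverage(n_reps: int = 200, n: int = 330, seed: int = 0) -> dict:
    """Wald 95 % CI coverage of the true multivariate T2CL log-odds."""
    rng = np.random.default_rng(seed)
    covered = 0
    used = 0
    for _ in range(n_reps):
        df = generate_cohort(n, outcome_model=_MULTI_MODEL, seed=int(rng.integers(0, 2**31)))
        X = df[["t2cl", "nicm", "favorable_ecg"]].astype(float).to_numpy()
        y = df["responder"].astype(float).to_numpy()
        fit = logistic_fit(X, y, names=["t2cl", "nicm", "ecg"])
        if fit.separation:
            continue
        lo, hi = np.log(fit.conf_int()[1])  # t2cl row
        used += 1
        covered += lo <= _MULTI_MODEL.beta_t2cl <= hi
    return {"coverage": covered / used, "n_reps": used, "n": n}


def auc_increment_power(n_reps: int = 200, n: int = 330, seed: int = 0) -> dict:
    """Fraction of replications where adding the true T2CL predictor to the
    traditional-covariate model increases AUC with DeLong p < 0.05."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_reps):
        df = generate_cohort(n, outcome_model=_MULTI_MODEL, seed=int(rng.integers(0, 2**31)))
        y = df["responder"].astype(int).to_numpy()
        base_design = df[["nicm", "favorable_ecg"]].astype(float).to_numpy()
        aug_design = df[["nicm", "favorable_ecg", "t2cl"]].astype(float).to_numpy()
        base = logistic_fit(base_design, y).predict(base_design)
        aug = logistic_fit(aug_design, y).predict(aug_design)
        a0, a1, p = roc_auc_delong(base, aug, y)
        wins += (a1 > a0) and (p < 0.05)
    return {"power": wins / n_reps, "n_reps": n_reps, "n": n}


def fisher_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Brute-force enumeration oracle (transposed binomial decomposition,
    exact rational arithmetic); independent of ``fisher_exact_2x2``."""
    r1, r2, c1 = a + b, c + d, a + c
    N = a + b + c + d
    c2 = N - c1
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    lo, hi = max(0, r1 - c2), min(r1, c1)
    weights = {k: math.comb(c1, k) * math.comb(c2, r1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), sum(weights.values())))


def fisher_vs_bruteforce(max_total: int = 40) -> dict:
    """Max |p difference| between the implementation and the oracle over all
    2x2 tables with total <= ``max_total``."""
    worst = 0.0
    n_tables = 0
    for N in range(1, max_total + 1):
        for a in range(N + 1):
            for b in range(N + 1 - a):
                for c in range(N + 1 - a - b):
                    d = N - a - b - c
                    p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
                    p2 = fisher_bruteforce(a, b, c, d)
                    worst = max(worst, abs(p1 - p2))
                    n_tables += 1
    return {"max_abs_diff": worst, "n": n_tables}
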