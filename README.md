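# crtsync

Cardiac resynchronization therapy (CRT) helps many dyssynchronous heart-failure
patients, but roughly one in three fail to respond. Two imaging markers predict
who benefits: the left-ventricular **wall-motion pattern** seen on cine CMR — a
*type I* pattern, where mechanical activation spreads homogeneously from the
septum to the free wall, versus a *type II* ("U-shaped") pattern with an
inferred line of conduction block — and the position of the LV pacing lead
relative to the **latest contracting site**. `crtsync` implements the full
quantitative chain behind these markers for a 33-patient prospective CRT
cohort, together with a synthetic cine-contour generator that provides ground
truth for validating every stage.

## What it computes

**Wall-motion measurement.** Endocardial contours on each short-axis cine frame
are resampled at 100 circumferentially spaced points about a
translation-corrected LV centroid (derived from the mitral-annulus → apex long
axis on every frame). Radial displacement is

    d(θ, s, t) = r(θ, s, 0) − r(θ, s, t)        (inward positive)

and each site's mechanical delay is the lag maximizing the normalized
cross-correlation against a patient-specific reference curve (the mean of all
valid site curves), refined to sub-frame precision by parabolic interpolation:

    τ(θ, s) = argmax_ℓ  corr( d(θ,s,·+ℓ), ref(·) )

Akinetic sites — scar transmurality > 0.5, peak excursion < 2 mm, or peak
correlation < 0.5 — are excluded as passive motion.

**Pattern classification.** Delays map onto a modified AHA 17-segment model
(apex excluded). Per-segment median delays split into early/late terciles of
the delay range; an adjacent early/late pair differing by ≥ 100 ms is an
inferred line of block, and the pattern is **type II** iff at least one block
edge exists. Septal flash (rapid inward-then-outward septal motion during
isovolumic contraction), the latest contracting site (maximum time to peak
displacement, first-peak-adjusted at flash sites), and the maximum opposing-wall
delay are measured from the same curves.

**Lead concordance and T2CL.** The LV lead (segment id, or RAO/LAO fluoroscopy
coordinates) is *concordant* if it sits in a viable segment within one segment
of the latest contracting segment, *remote* otherwise or when its segment has
> 50 % transmural scar. **T2CL** = type II pattern AND concordant lead.

**Cohort statistics.** Echo response = ≥ 15 % ESV reduction at 6 months.
Fisher's exact test (two-sided point-probability rule, exact integer
arithmetic), Woolf odds-ratio CIs, logistic regression with Wald intervals,
separation detection and bootstrap internal validation, paired AUC comparison
by the DeLong method, Cohen's kappa, pooled t and Mann–Whitney tests. The
cohort's printed 2×2 tables are packaged (with per-count provenance) and every
supported statistic is recomputed and checked at printed precision.

## Worked example

Simulate a noisy type II patient with an inferior line of block and a lead
placed mid-inferior, then run the full analysis:

```python
from crtsync import SimParams, analyze_patient, generate_patient, make_type2_truth

params = SimParams(noise_sd_mm=0.5, translation_amplitude_mm=3.0, seed=7)
stack, truth = generate_patient(params, make_type2_truth(block="inferior"))
record = analyze_patient(stack, scar={}, lead=(0.55, 210.0))
```

which prints:

```
pattern: type_II
block_edges: [[3, 4], [9, 10], [9, 15], [14, 15]]
septal_flash: True
latest_segment: 10
max_wall_delay_ms: 268.98132995047536
lead_segment: 10
lead_classification: concordant
t2cl: True
```

The classifier recovers the programmed U-shaped pattern: the line of block
separates the early inferoseptal segments (3, 9, 14) from the late inferior
segments (4, 10, 15), the latest contracting segment is the mid-inferior
segment 10, and the lead — mapped from a mid-ventricular long-axis fraction of
0.55 and an LAO angle of 210° — lands in that same segment, giving a
concordant classification and a positive T2CL flag.

The same pipeline is scriptable from the shell:

```bash
crtsync --seed 7 simulate --outdir pt --pattern type_II --noise-sd 0.5
crtsync analyze --indir pt
crtsync reproduce            # recompute the published statistics; exit 0 iff all match
```

`crtsync reproduce` prints a pass/fail table such as

```
| statistic | table | computed | printed | match |
|---|---|---|---|---|
| fisher_p | t2cl_response | 0.003 | 0.003 | PASS |
| fisher_p | type2_response | 0.038 | 0.038 | PASS |
...
Overall: ALL MATCH
```

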