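"""End-to-end patient analysis and reproduction of the published statistics.

``analyze_patient`` composes the full measurement chain on one contour
stack; ``reproduce_report`` recomputes every statistic the packaged tables
support and compares it, at printed precision, with the published value.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .fixtures import (
    PRINTED_FISHER_P,
    PRINTED_LOGISTIC_P,
    PRINTED_OR,
    PRINTED_TTEST_P,
    StudyFixtures,
    build_study_fixtures,
)
from .leads import classify_lead_position, map_lead_to_segment, t2cl_flag
from .patterns import (
    classify_pattern,
    detect_septal_flash,
    latest_contracting_site,
    max_wall_delay,
    segment_delays,
)
from .segments import build_segment_model
from .stats import fisher_exact_2x2, logistic_fit, odds_ratio_ci, ttest_from_summary
from .wallmotion import (
    ContourStack,
    centroid_track,
    compute_delay_map,
    exclude_akinetic,
    radial_displacement_curves,
)


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    ndigits = sig - 1 - floor(log10(abs(x)))
    return round_half_up(x, ndigits)


def analyze_patient(
    stack: ContourStack,
    scar: dict[int, float] | None = None,
    lead: int | tuple[float, float] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    ivc_window_ms: tuple[float, float] | None = None,
) -> dict:
    """Run centroid -> displacement -> delay map -> pattern -> lead -> T2CL.

    ``lead`` is a segment id or an (RAO long-axis fraction, LAO angle in
    degrees) pair.  Deterministic given its inputs.
    """
    model = build_segment_model(stack.n_slices)
    try:
        centroids = centroid_track(stack)
        curves = radial_displacement_curves(stack, centroids)
    except Exception as err:
        raise RuntimeError(f"wall-motion stage failed: {err}") from err
    delaymap = compute_delay_map(curves, config)
    delaymap = exclude_akinetic(curves, delaymap, model, scar, config)
    summary = segment_delays(delaymap, model, config)
    flash, flash_segs = detect_septal_flash(curves, model, config, ivc_window_ms)
    latest = latest_contracting_site(delaymap, model, flash_segs)
    pattern = classify_pattern(
        summary, model, config, septal_flash=flash, flash_segments=flash_segs, latest=latest
    )
    record: dict = {
        "pattern": pattern.pattern,
        "block_edges": sorted(map(list, pattern.block_edges)),
        "septal_flash": flash,
        "flash_segments": sorted(flash_segs),
        "latest_site": list(latest[0]),
        "latest_segment": latest[1],
        "max_wall_delay_ms": max_wall_delay(summary, model, config=config),
        "segment_delays_ms": summary.segment_delay_ms,
    }
    if lead is not None:
        lead_segment = (
            int(lead) if np.isscalar(lead) else map_lead_to_segment(lead[0], lead[1], model)
        )
        placement = classify_lead_position(lead_segment, latest[1], scar, model, config)
        placement.t2cl = t2cl_flag(pattern, placement.classification)
        record.update(
            {
                "lead_segment": placement.lead_segment,
                "lead_viable": placement.viable,
                "lead_classification": placement.classification,
                "t2cl": placement.t2cl,
            }
        )
    return record


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def reproduce_report(fixtures: StudyFixtures | None = None) -> dict:
    """Recompute every supported published statistic and compare at printed
    precision.  Returns a dict with per-statistic entries and an overall
    ``all_match`` flag."""
    fx = fixtures or build_study_fixtures()
    entries = []

    for name, printed_p in PRINTED_FISHER_P.items():
        p = fisher_exact_2x2(fx.tables[name])
        nd = _decimals(printed_p)
        entries.append(
            {
                "name": name,
                "statistic": "fisher_p",
                "computed": p,
                "computed_rounded": round_half_up(p, nd),
                "printed": float(printed_p),
                "match": round_half_up(p, nd) == float(printed_p),
            }
        )

    for name, printed_or in PRINTED_OR.items():
        orr, _ci = odds_ratio_ci(fx.tables[name])
        entries.append(
            {
                "name": name,
                "statistic": "odds_ratio",
                "computed": orr,
                "computed_rounded": round_sig(orr, 2),
                "printed": printed_or,
                "match": round_sig(orr, 2) == printed_or,
            }
        )

    for name, printed_p in PRINTED_LOGISTIC_P.items():
        exposure, outcome = fx.tables[name].expand()
        fit = logistic_fit(exposure, outcome, names=[name])
        p = float(fit.pvalues[1])
        nd = _decimals(printed_p)
        entries.append(
            {
                "name": name,
                "statistic": "logistic_wald_p",
                "computed": p,
                "computed_rounded": round_half_up(p, nd),
                "printed": float(printed_p),
                "match": round_half_up(p, nd) == float(printed_p),
            }
        )

    for name, printed_p in PRINTED_TTEST_P.items():
        row = fx.summaries[name]
        p = ttest_from_summary(row.mean_1, row.sd_1, row.n_1, row.mean_2, row.sd_2, row.n_2)
        nd = _decimals(printed_p)
        entries.append(
            {
                "name": name,
                "statistic": "pooled_ttest_p",
                "computed": p,
                "computed_rounded": round_half_up(p, nd),
                "printed": float(printed_p),
                "match": round_half_up(p, nd) == float(printed_p),
            }
        )

    # cohort composition from table margins
    t2cl_tab = fx.tables["t2cl_response"]
    comp = {
        "n_patients": t2cl_tab.total,
        "n_responders": t2cl_tab.a + t2cl_tab.c,
        "response_rate_pct": 100.0 * (t2cl_tab.a + t2cl_tab.c) / t2cl_tab.total,
        "t2cl_prevalence_pct": 100.0 * (t2cl_tab.a + t2cl_tab.b) / t2cl_tab.total,
        "n_type2": fx.tables["type2_response"].a + fx.tables["type2_response"].b,
        "n_type1": fx.tables["type2_response"].c + fx.tables["type2_response"].d,
        "n_concordant": fx.tables["concordant_response"].a + fx.tables["concordant_response"].b,
    }
    comp_match = (
        comp["n_patients"] == fx.n_patients
        and comp["n_responders"] == fx.n_responders
        and comp["n_type2"] == fx.n_type2
        and comp["n_type1"] == fx.n_type1
        and comp["n_concordant"] == fx.n_concordant
    )
    return {
        "entries": entries,
        "composition": comp,
        "composition_match": comp_match,
        "all_match": comp_match and all(e["match"] for e in entries),
    }


def report_markdown(report: dict) -> str:
    lines = [
        "# Reproduction report",
        "",
        "| statistic | table | computed | printed | match |",
        "|---|---|---|---|---|",
    ]
    for e in report["entries"]:
        lines.append(
            f"| {e['statistic']} | {e['name']} | {e['computed_rounded']} "
            f"| {e['printed']} | {'PASS' if e['match'] else 'FAIL'} |"
        )
    c = report["composition"]
    lines += [
        "",
        f"Cohort composition: {c['n_responders']}/{c['n_patients']} responders "
        f"({c['response_rate_pct']:.1f} %), T2CL prevalence {c['t2cl_prevalence_pct']:.1f} %, "
        f"pattern split {c['n_type1']}/{c['n_type2']} (type I / type II) — "
        f"{'PASS' if report['composition_match'] else 'FAIL'}",
        "",
        f"Overall: {'ALL MATCH' if report['all_match'] else 'MISMATCH'}",
    ]
    return "\n".join(lines)
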