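"""Analysis thresholds, collected in one place.

Every quantitative cut used by the pipeline lives here so that a single
YAML file can reconfigure a run end to end.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    #: minimum delay difference (ms) across an adjacent early/late segment
    #: pair to count as an inferred line of block
    block_threshold_ms: float = 100.0
    #: isovolumic-contraction window (ms from cycle start) used for septal
    #: flash detection when aortic-valve timing is unavailable
    ivc_window_ms: tuple[float, float] = (0.0, 80.0)
    #: septal-flash inward excursion threshold, as a fraction of the site's
    #: end-diastolic radius
    flash_amplitude_frac: float = 0.10
    #: required outward return after the flash peak, as a fraction of the
    #: inward excursion
    flash_return_frac: float = 0.5
    #: minimum peak cross-correlation for a site to count as actively moving
    correlation_floor: float = 0.5
    #: minimum peak radial displacement (mm) for a site to count as kinetic
    akinetic_amplitude_mm: float = 2.0
    #: scar transmurality above which a segment is non-viable
    scar_transmurality_cutoff: float = 0.5
    #: total LGE fraction of LV myocardium defining "significant scar"
    significant_scar_fraction: float = 0.15
    #: fractional ESV reduction defining echocardiographic response
    esv_response_fraction: float = 0.15
    #: reference curve construction: "mean" (all valid sites) or "septal"
    reference: str = "mean"
    #: "opposing" = max delay difference between diametrically opposed
    #: sectors; "range" = global max-min of segment delays
    max_wall_delay_mode: str = "opposing"

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ivc_window_ms" in raw:
            raw["ivc_window_ms"] = tuple(raw["ivc_window_ms"])
        return cls(**raw)


DEFAULT_CONFIG = AnalysisConfig()
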