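"""Pipeline configuration: element bounds, adducts, tolerances, thresholds.

All knobs the pipeline exposes live here with their defaults; a YAML
file can override any subset.  The ``include_hump_in_total`` switch is
a hook for sensitivity analysis only — the default total-CAD-signal
definition excludes the unresolved baseline hump.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .chem import AdductSpec, adduct_by_name
from .formula_assign import ElementBounds, ScoringWeights

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # formula search
    element_bounds: ElementBounds = field(default_factory=ElementBounds)
    adducts: tuple[str, ...] = (
        "[M+H]+", "[M+NH4]+", "[M+Na]+", "[M+2H]2+",
        "[M-H]-", "[M+HCOO]-",
    )
    tol_ppm: float = 5.0
    nitrogen_rule: bool = True
    scoring: ScoringWeights = field(default_factory=ScoringWeights)
    confident_score: float = 90.0
    # chromatogram
    min_snr: float = 3.0
    min_rel_area_pct: float = 0.05
    baseline_lam: float = 1e9
    baseline_p: float = 1e-3
    include_hump_in_total: bool = False  # config hook; no response model
    # MS features
    eic_tol_ppm: float = 10.0
    min_ms_intensity: float = 0.0
    max_charge: int = 2
    min_scans: int = 3
    rt_window: float = 0.05
    # fusion
    margin: float = 0.1
    low_level_fraction: float = 0.05
    standard_rt_tol: float = 0.1
    ms_to_cad_offset: float = 0.0
    # reporting
    formula_counts_as_identified: bool = False
    # run metadata (recorded, not interpreted)
    ionization_mode: str = "ESI"

    def adduct_specs(self) -> list[AdductSpec]:
        return [adduct_by_name(n) for n in self.adducts]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "element_bounds" in raw:
            kwargs["element_bounds"] = ElementBounds.from_dict(
                {k: tuple(v) for k, v in raw.pop("element_bounds").items()})
        if "scoring" in raw:
            kwargs["scoring"] = ScoringWeights(**raw.pop("scoring"))
        if "adducts" in raw:
            kwargs["adducts"] = tuple(raw.pop("adducts"))
        known = cls.__dataclass_fields__
        for k, v in raw.items():
            if k not in known:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = v
        return cls(**kwargs)

    def thresholds_log(self) -> dict:
        """All thresholds in effect, for the run log."""
        d = asdict(self)
        d["element_bounds"] = self.element_bounds.as_dict()
        d["scoring"] = asdict(self.scoring)
        return d
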