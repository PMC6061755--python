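"""Constituent report assembly and pipeline orchestration.

Builds the table a safety assessor consumes: one row per CAD peak in
elution order with proposed identity, molecular formula, confidence
tier and percent of total CAD signal, plus MS-only analytes flagged as
below the reporting floor, and the summary statistics a
threshold-of-toxicological-concern assessment keys on (largest single
unidentified constituent, total unidentified signal).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .chem import MolecularFormula
from .chromatogram import (
    QuantTable,
    Trace,
    detect_peaks,
    estimate_baseline,
    read_trace_csv,
    relative_quantitation,
    write_peak_table,
    BaselineParams,
)
from .config import PipelineConfig
from .formula_assign import (
    FormulaCandidate,
    enumerate_candidates,
    rank_candidates,
    score_candidate,
)
from .fusion import (
    ConfidenceTier,
    PeakAssignment,
    ReferenceStandard,
    assign_confidence_tier,
    assign_groups_to_peaks,
    match_standard,
)
from .ms_features import (
    AnalyteGroup,
    CentroidSpectrum,
    detect_features,
    group_adducts,
)

__all__ = [
    "Annotation",
    "AnalyteResult",
    "ConstituentRecord",
    "ExtractReport",
    "PipelineError",
    "identify_groups",
    "build_report",
    "unknown_summary",
    "run_pipeline",
]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class Annotation:
    """External annotation text for a proposed identification.

    Matched to analyte groups by molecular formula (Hill string) and,
    when given, retention time.
    """

    formula: str
    name: str
    cas: str | None = None
    comment: str = ""
    rt: float | None = None


@dataclass
class AnalyteResult:
    """Identification outcome for one analyte group.

    ``group`` is None for records built from an external table rather
    than from detected MS features (e.g. the packaged fixture).
    """

    group: AnalyteGroup | None = None
    formula: MolecularFormula | None = None
    ppm_error: float | None = None
    score: float | None = None
    name: str | None = None
    cas: str | None = None
    comment: str = ""
    tier: ConfidenceTier = ConfidenceTier.FORMULA_ONLY
    candidates: list[FormulaCandidate] = field(default_factory=list)


@dataclass
class ConstituentRecord:
    """One Table-style row: a CAD peak and the analytes it contains."""

    peak_number: int
    cad_percent: float
    analytes: list[AnalyteResult] = field(default_factory=list)
    low_level_extra_signals: bool = False
    comment: str = ""

    @property
    def tier(self) -> ConfidenceTier:
        """Best evidence tier among the peak's analytes."""
        order = [ConfidenceTier.STANDARD_MATCH, ConfidenceTier.PROPOSED,
                 ConfidenceTier.FORMULA_ONLY]
        for t in order:
            if any(a.tier == t for a in self.analytes):
                return t
        return ConfidenceTier.UNKNOWN_NO_MS

    @property
    def proposed_name(self) -> str:
        named = [a.name for a in self.analytes if a.name]
        return "; ".join(named) if named else "Unknown"

    def identified(self, formula_counts: bool = False) -> bool:
        """Identified for the unknown-signal statistics.

        Default interpretation: a proposed name or standard match is
        required; a bare molecular formula does not count (the
        ``formula_counts`` switch flips this).
        """
        for a in self.analytes:
            if a.tier in (ConfidenceTier.STANDARD_MATCH, ConfidenceTier.PROPOSED):
                return True
            if a.name:
                return True
            if formula_counts and a.formula is not None:
                return True
        return False


@dataclass
class ExtractReport:
    """The full constituent report for one extract analysis."""

    records: list[ConstituentRecord]
    below_floor: list[AnalyteResult] = field(default_factory=list)
    floor_pct: float = 0.05
    ionization_mode: str = "ESI"

    def __post_init__(self) -> None:
        nums = [r.peak_number for r in self.records]
        if nums != sorted(nums):
            raise ValueError("records must be in elution (peak-number) order")
        if self.records:
            total = sum(r.cad_percent for r in self.records)
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"record percentages sum to {total}, not 100")

    @property
    def n_peaks(self) -> int:
        return len(self.records)

    def summary(self, formula_counts_as_identified: bool = False) -> dict:
        s = unknown_summary(self, formula_counts_as_identified)
        s["n_peaks"] = self.n_peaks
        s["n_below_floor"] = len(self.below_floor)
        return s

    def to_json_dict(self, formula_counts_as_identified: bool = False) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "ionization_mode": self.ionization_mode,
            "summary": self.summary(formula_counts_as_identified),
            "records": [
                {
                    "CAD Peak number": r.peak_number,
                    "Proposed ID (CAS #)": r.proposed_name
                    + (f" ({r.analytes[0].cas})"
                       if r.analytes and r.analytes[0].cas else ""),
                    "Molecular Formula": "; ".join(
                        a.formula.hill() for a in r.analytes
                        if a.formula is not None) or None,
                    "percent_total_cad": round(r.cad_percent, 4),
                    "tier": r.tier.value,
                    "n_analytes": len(r.analytes),
                    "coelution": len(r.analytes) >= 2,
                    "low_level_extra_signals": r.low_level_extra_signals,
                    "analytes": [
                        {
                            "name": a.name,
                            "cas": a.cas,
                            "formula": a.formula.hill() if a.formula else None,
                            "ppm_error": (round(a.ppm_error, 3)
                                          if a.ppm_error is not None else None),
                            "score": (round(a.score, 2)
                                      if a.score is not None else None),
                            "adducts": (list(a.group.adduct_names())
                                        if a.group else []),
                            "tier": a.tier.value,
                            "comment": a.comment,
                        }
                        for a in r.analytes
                    ],
                    "Comments": r.comment,
                }
                for r in self.records
            ],
            "below_floor": [
                {
                    "name": a.name,
                    "formula": a.formula.hill() if a.formula else None,
                    "flag": f"< {self.floor_pct}% of total CAD signal",
                    "rt": round(a.group.rt, 4) if a.group else None,
                }
                for a in self.below_floor
            ],
        }


def identify_groups(
    groups: list[AnalyteGroup],
    config: PipelineConfig,
    standards: list[ReferenceStandard] | None = None,
    annotations: list[Annotation] | None = None,
) -> list[AnalyteResult]:
    """Enumerate, score and rank formula candidates for each group, then
    attach standard matches / annotations and a confidence tier."""
    standards = standards or []
    annotations = annotations or []
    adducts = config.adduct_specs()
    results: list[AnalyteResult] = []
    for g in groups:
        env, adduct = g.best_envelope()
        cands = enumerate_candidates(
            env.mzs[0], env.polarity, adducts,
            bounds=config.element_bounds, tol_ppm=config.tol_ppm,
            nitrogen_rule=config.nitrogen_rule,
        )
        scored = [score_candidate(c, env, config.scoring)
                  for c in cands if abs(c.adduct.charge) == abs(env.charge)]
        ranked = rank_candidates(scored)
        res = AnalyteResult(group=g, candidates=ranked)
        if ranked:
            top = ranked[0]
            res.formula = top.formula
            res.ppm_error = top.ppm_error
            res.score = top.score
        std = match_standard(res.formula, g.rt, standards,
                             rt_tol=config.standard_rt_tol)
        ann = _match_annotation(res.formula, g.rt, annotations)
        if std is not None:
            res.name, res.cas = std.name, std.cas
            res.comment = "RT and MS consistent with authentic standard."
        elif ann is not None:
            res.name, res.cas = ann.name, ann.cas
            res.comment = ann.comment
        res.tier = assign_confidence_tier(
            standard_matched=std is not None,
            ms_present=True,
            top_score=res.score,
            annotated=ann is not None,
            confident_score=config.confident_score,
        )
        results.append(res)
    return results


def _match_annotation(formula: MolecularFormula | None, rt: float,
                      annotations: list[Annotation]) -> Annotation | None:
    if formula is None:
        return None
    hill = formula.hill()
    hits = [a for a in annotations if a.formula == hill
            and (a.rt is None or abs(a.rt - rt) <= 0.2)]
    if not hits:
        return None
    return min(hits, key=lambda a: abs((a.rt or rt) - rt))


def build_report(
    assignments: list[PeakAssignment],
    quant: QuantTable,
    results: list[AnalyteResult],
    unassigned: list[AnalyteGroup] | None = None,
    floor_pct: float = 0.05,
    ionization_mode: str = "ESI",
) -> ExtractReport:
    """Assemble the constituent report.

    One record per CAD peak (coeluting analytes inside the record);
    unassigned MS-only groups become below-floor entries.  Raises if
    the quantitation table and assignments disagree on peak numbers.
    """
    by_group = {id(r.group): r for r in results}
    quant_nums = {n for n, _ in quant.percents}
    assign_nums = {pa.peak.number for pa in assignments}
    if quant_nums != assign_nums:
        orphans = sorted(quant_nums ^ assign_nums)
        raise ValueError(f"peak-number mismatch between quantitation and "
                         f"assignments; orphans: {orphans}")

    records: list[ConstituentRecord] = []
    for pa in sorted(assignments, key=lambda a: a.peak.number):
        analytes = [by_group[id(g)] for g in pa.groups if id(g) in by_group]
        rec = ConstituentRecord(
            peak_number=pa.peak.number,
            cad_percent=quant.percent_of(pa.peak.number),
            analytes=analytes,
            low_level_extra_signals=pa.low_level_extra_signals,
        )
        comments = [a.comment for a in analytes if a.comment]
        if not analytes:
            comments.append("No discernable MS signal obtained for CAD peak.")
        if pa.low_level_extra_signals:
            comments.append(
                "Mass spectra also contain other lower-level signals "
                "indicating analytes not reported.")
        rec.comment = " ".join(comments)
        records.append(rec)

    below = []
    for g in unassigned or []:
        r = by_group.get(id(g))
        if r is None:
            r = AnalyteResult(group=g)
        r.comment = (r.comment + " " if r.comment else "") + \
            f"Not observed by CAD; < {floor_pct}% of the mass of the sample."
        below.append(r)
    return ExtractReport(records=records, below_floor=below,
                         floor_pct=floor_pct, ionization_mode=ionization_mode)


def unknown_summary(report: ExtractReport,
                    formula_counts_as_identified: bool = False) -> dict:
    """Largest and total unidentified signal, % of total CAD signal.

    A record counts as unidentified when none of its analytes carries a
    proposed name or standard match (a bare formula does not identify a
    constituent for these statistics unless the switch says otherwise).
    """
    unknown = [r.cad_percent for r in report.records
               if not r.identified(formula_counts_as_identified)]
    return {
        "max_unknown_percent": max(unknown) if unknown else 0.0,
        "total_unidentified_percent": sum(unknown),
    }


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    cad: str | Path | Trace,
    spectra: list[CentroidSpectrum],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    uv: str | Path | Trace | None = None,
    standards: list[ReferenceStandard] | None = None,
    annotations: list[Annotation] | None = None,
) -> ExtractReport:
    """Baseline -> peaks -> quant -> features -> groups -> formulas ->
    fusion -> report; writes peak/feature tables, the report (CSV +
    JSON) and a log of all thresholds when ``out_dir`` is given.

    Any stage error propagates as :class:`PipelineError` naming the
    stage; partial artifacts are removed.
    """
    config = config or PipelineConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    wrote: list[Path] = []
    try:
        stage = "load"
        cad_trace = cad if isinstance(cad, Trace) else read_trace_csv(cad, "CAD")
        uv_trace = (uv if isinstance(uv, Trace) or uv is None
                    else read_trace_csv(uv, "UV"))

        stage = "baseline"
        params = BaselineParams(lam=config.baseline_lam, p=config.baseline_p)
        baseline = estimate_baseline(cad_trace, params)

        stage = "peaks"
        peaks = detect_peaks(cad_trace, baseline,
                             min_snr=config.min_snr,
                             min_rel_area_pct=config.min_rel_area_pct)

        stage = "quantitation"
        quant = relative_quantitation(peaks)

        stage = "features"
        features = detect_features(
            spectra, min_intensity=config.min_ms_intensity,
            tol_ppm=config.eic_tol_ppm, max_charge=config.max_charge,
            min_scans=config.min_scans)

        stage = "grouping"
        groups = group_adducts(features, config.adduct_specs(),
                               tol_ppm=config.tol_ppm,
                               rt_window=config.rt_window)

        stage = "formulas"
        results = identify_groups(groups, config, standards, annotations)

        stage = "fusion"
        assignments, unassigned = assign_groups_to_peaks(
            peaks, groups, offset=config.ms_to_cad_offset,
            margin=config.margin,
            low_level_fraction=config.low_level_fraction)
        if uv_trace is not None:
            uv_base = estimate_baseline(uv_trace, params)
            try:
                uv_peaks = detect_peaks(uv_trace, uv_base,
                                        min_snr=config.min_snr,
                                        min_rel_area_pct=0.0)
            except ValueError:
                uv_peaks = []
            for pa in assignments:
                pa.uv_detected = any(
                    pa.peak.left_time <= p.apex_time <= pa.peak.right_time
                    for p in uv_peaks)

        stage = "report"
        report = build_report(assignments, quant, results, unassigned,
                              floor_pct=config.min_rel_area_pct,
                              ionization_mode=config.ionization_mode)

        if out_path is not None:
            stage = "artifacts"
            out_path.mkdir(parents=True, exist_ok=True)
            p = out_path / "peaks.csv"
            write_peak_table(peaks, quant, p)
            wrote.append(p)
            p = out_path / "features.csv"
            _write_feature_table(features, p)
            wrote.append(p)
            p = out_path / "report.json"
            with open(p, "w") as fh:
                json.dump(report.to_json_dict(config.formula_counts_as_identified),
                          fh, indent=1, sort_keys=True)
            wrote.append(p)
            p = out_path / "report.csv"
            _write_report_csv(report, p)
            wrote.append(p)
            p = out_path / "thresholds.json"
            with open(p, "w") as fh:
                json.dump(config.thresholds_log(), fh, indent=1, sort_keys=True,
                          default=str)
            wrote.append(p)
        return report
    except PipelineError:
        raise
    except Exception as exc:
        for p in wrote:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc


def _write_feature_table(features, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mz", "charge", "rt_min", "area", "polarity",
                    "envelope_len"])
        for f in features:
            w.writerow([f"{f.mz:.5f}", f.charge, f"{f.rt:.4f}",
                        f"{f.area:.6g}", f.polarity, len(f.envelope.mzs)])


def _write_report_csv(report: ExtractReport, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["CAD Peak number", "Proposed ID (CAS #)",
                    "Molecular Formula", "percent_total_cad", "tier",
                    "Comments"])
        for r in report.records:
            for a in r.analytes or [None]:
                w.writerow([
                    r.peak_number,
                    (a.name or "Unknown") if a else "Unknown",
                    (a.formula.hill() if a and a.formula else ""),
                    f"{r.cad_percent:.4f}",
                    (a.tier.value if a else r.tier.value),
                    (a.comment if a else r.comment),
                ])
        for a in report.below_floor:
            w.writerow(["", a.name or "Unknown",
                        a.formula.hill() if a.formula else "",
                        f"< {report.floor_pct}", a.tier.value, a.comment])
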