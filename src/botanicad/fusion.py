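"""Cross-detector correlation: MS analyte groups vs CAD peaks.

The detectors sit at different points of the post-column split, so
their time axes differ by a constant transit offset; after calibrating
it, each analyte group is assigned to the CAD peak whose window
contains its apex.  CAD peaks explained by several mass-distinct groups
are flagged as coeluting; identification confidence is tiered by the
available evidence (authentic standard, confident formula + annotation,
formula only, or no MS signal at all).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .chem import MolecularFormula
from .chromatogram import Peak
from .ms_features import AnalyteGroup

__all__ = [
    "DetectorOffset",
    "PeakAssignment",
    "ConfidenceTier",
    "ReferenceStandard",
    "calibrate_offset",
    "assign_groups_to_peaks",
    "assign_confidence_tier",
    "match_standard",
    "read_standards_csv",
]


class ConfidenceTier(str, Enum):
    """Identification confidence of one (peak, analyte) record."""

    STANDARD_MATCH = "standard_match"
    PROPOSED = "proposed"
    FORMULA_ONLY = "formula_only"
    UNKNOWN_NO_MS = "unknown_no_ms"


@dataclass
class DetectorOffset:
    """Constant time offsets between ordered detector pairs (minutes)."""

    offsets: dict[tuple[str, str], float] = field(default_factory=dict)

    def set(self, a: str, b: str, offset: float) -> None:
        self.offsets[(a, b)] = offset
        self.offsets[(b, a)] = -offset

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.offsets.get((a, b), 0.0)


def calibrate_offset(matched_apexes: list[tuple[float, float]]) -> float:
    """Median of (t_B - t_A) over matched apex pairs."""
    if not matched_apexes:
        raise ValueError("need at least one matched apex pair")
    return float(np.median([b - a for a, b in matched_apexes]))


@dataclass
class PeakAssignment:
    """MS analyte groups correlated to one CAD peak."""

    peak: Peak
    groups: list[AnalyteGroup] = field(default_factory=list)
    low_level_groups: list[AnalyteGroup] = field(default_factory=list)
    uv_detected: bool = False

    @property
    def n_analytes(self) -> int:
        return len(self.groups)

    @property
    def coelution(self) -> bool:
        return self.n_analytes >= 2

    @property
    def low_level_extra_signals(self) -> bool:
        return bool(self.low_level_groups)


def assign_groups_to_peaks(
    cad_peaks: list[Peak],
    groups: list[AnalyteGroup],
    offset: float = 0.0,
    margin: float = 0.1,
    low_level_fraction: float = 0.05,
) -> tuple[list[PeakAssignment], list[AnalyteGroup]]:
    """Assign each analyte group to at most one CAD peak.

    A group lands on the peak whose [left - margin, right + margin]
    window (MS apexes shifted by ``offset`` onto the CAD time base)
    contains its apex; overlapping windows resolve to the nearest apex.
    Groups matching no window are returned unassigned — their analytes
    are below the CAD reporting floor.  Within a peak, groups below
    ``low_level_fraction`` of the top group's EIC area are recorded as
    low-level extra signals instead of counted analytes.
    """
    assignments = {p.number: PeakAssignment(peak=p) for p in cad_peaks}
    unassigned: list[AnalyteGroup] = []
    for g in groups:
        t = g.rt + offset
        hits = [p for p in cad_peaks
                if p.left_time - margin <= t <= p.right_time + margin]
        if not hits:
            unassigned.append(g)
            continue
        target = min(hits, key=lambda p: (abs(p.apex_time - t), p.number))
        assignments[target.number].groups.append(g)

    for pa in assignments.values():
        if not pa.groups:
            continue
        pa.groups.sort(key=lambda g: -g.total_area())
        top = pa.groups[0].total_area()
        main = [g for g in pa.groups if g.total_area() >= low_level_fraction * top]
        pa.low_level_groups = [g for g in pa.groups if g not in main]
        pa.groups = main
    ordered = [assignments[p.number] for p in cad_peaks]
    return ordered, unassigned


@dataclass(frozen=True)
class ReferenceStandard:
    """An authentic standard: name, formula, expected retention time."""

    name: str
    formula: MolecularFormula
    rt: float
    cas: str | None = None


def read_standards_csv(path: str | Path) -> list[ReferenceStandard]:
    """CSV columns: name, formula, rt_min[, cas]."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ReferenceStandard(
                name=row["name"],
                formula=MolecularFormula.parse(row["formula"]),
                rt=float(row["rt_min"]),
                cas=row.get("cas") or None,
            ))
    return out


def match_standard(
    formula: MolecularFormula | None,
    rt: float,
    standards: list[ReferenceStandard],
    rt_tol: float = 0.1,
) -> ReferenceStandard | None:
    """A standard whose formula matches and whose RT agrees within tolerance."""
    if formula is None:
        return None
    hits = [s for s in standards
            if s.formula == formula and abs(s.rt - rt) <= rt_tol]
    if not hits:
        return None
    return min(hits, key=lambda s: abs(s.rt - rt))


def assign_confidence_tier(
    standard_matched: bool,
    ms_present: bool,
    top_score: float | None = None,
    annotated: bool = False,
    confident_score: float = 90.0,
) -> ConfidenceTier:
    """Evidence -> tier.

    Authentic-standard RT + formula agreement -> ``standard_match``;
    else a confident formula (score >= threshold) with external
    annotation text -> ``proposed``; else any MS evidence ->
    ``formula_only``; no MS signal -> ``unknown_no_ms``.
    """
    if standard_matched:
        return ConfidenceTier.STANDARD_MATCH
    if not ms_present:
        return ConfidenceTier.UNKNOWN_NO_MS
    if annotated and top_score is not None and top_score >= confident_score:
        return ConfidenceTier.PROPOSED
    return ConfidenceTier.FORMULA_ONLY
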