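"""Report assembly, unknown-signal statistics, pipeline orchestration."""

import json

import numpy as np
import pytest

from botanicad.chem import MolecularFormula
from botanicad.chromatogram import Peak, QuantTable
from botanicad.config import PipelineConfig
from botanicad.fusion import ConfidenceTier, PeakAssignment, ReferenceStandard
from botanicad.report import (
    AnalyteResult,
    Annotation,
    ConstituentRecord,
    ExtractReport,
    PipelineError,
    build_report,
    run_pipeline,
    unknown_summary,
)
from botanicad.synthetic import (
    GroundTruthConstituent,
    SimulationConfig,
    example_constituents,
    simulate_extract,
)

F = MolecularFormula.parse


def _peak(n, apex):
    return Peak(number=n, apex_time=apex, left_time=apex - 0.15,
                right_time=apex + 0.15, height=10.0, area=float(n),
                snr=50.0)


def _record(n, pct, tier=ConfidenceTier.STANDARD_MATCH, name="X",
            formula="C6H6"):
    analytes = []
    if tier is not ConfidenceTier.UNKNOWN_NO_MS:
        analytes = [AnalyteResult(
            formula=F(formula),
            name=name if tier in (ConfidenceTier.STANDARD_MATCH,
                                  ConfidenceTier.PROPOSED) else None,
            tier=tier)]
    return ConstituentRecord(peak_number=n, cad_percent=pct,
                             analytes=analytes)


class TestBuildReport:
    def test_empty_inputs_give_empty_report(self):
        report = build_report([], QuantTable(percents=()), [])
        assert report.n_peaks == 0

    def test_peak_number_mismatch_lists_orphans(self):
        quant = QuantTable(percents=((1, 60.0), (2, 40.0)))
        assignments = [PeakAssignment(peak=_peak(1, 5.0))]
        with pytest.raises(ValueError, match=r"\[2\]"):
            build_report(assignments, quant, [])

    def test_unassigned_group_becomes_below_floor_entry(self):
        quant = QuantTable(percents=((1, 100.0),))
        assignments = [PeakAssignment(peak=_peak(1, 5.0))]
        orphan = AnalyteResult(formula=F("C10H12O2"))
        from botanicad.ms_features import AnalyteGroup, MSFeature
        from botanicad.formula_assign import ObservedEnvelope
        from botanicad.chem import adduct_by_name
        env = ObservedEnvelope(mzs=(165.09,), intensities=(5.0,), charge=1,
                               polarity="+")
        feat = MSFeature(mz=165.09, charge=1, rt=9.0, area=5.0, envelope=env,
                         polarity="+")
        group = AnalyteGroup(neutral_mass=164.08, rt=9.0,
                             members=((feat, adduct_by_name("[M+H]+")),))
        orphan.group = group
        report = build_report(assignments, quant, [orphan],
                              unassigned=[group], floor_pct=0.05)
        assert len(report.below_floor) == 1
        assert "< 0.05%" in report.below_floor[0].comment

    def test_record_without_ms_has_no_formula(self):
        quant = QuantTable(percents=((1, 100.0),))
        assignments = [PeakAssignment(peak=_peak(1, 5.0))]
        report = build_report(assignments, quant, [])
        rec = report.records[0]
        assert rec.tier is ConfidenceTier.UNKNOWN_NO_MS
        assert not rec.analytes


class TestUnknownSummary:
    def _report(self, records):
        return ExtractReport(records=records)

    def test_all_identified_gives_zeros(self):
        r = self._report([_record(1, 60.0), _record(2, 40.0)])
        s = unknown_summary(r)
        assert s == {"max_unknown_percent": 0.0,
                     "total_unidentified_percent": 0.0}

    def test_unknowns_accumulate(self):
        r = self._report([
            _record(1, 98.5),
            _record(2, 0.5, tier=ConfidenceTier.FORMULA_ONLY),
            _record(3, 1.0, tier=ConfidenceTier.UNKNOWN_NO_MS),
        ])
        s = unknown_summary(r)
        assert s["max_unknown_percent"] == pytest.approx(1.0)
        assert s["total_unidentified_percent"] == pytest.approx(1.5)

    def test_formula_only_counts_as_identified_when_flipped(self):
        r = self._report([
            _record(1, 99.0),
            _record(2, 1.0, tier=ConfidenceTier.FORMULA_ONLY),
        ])
        assert unknown_summary(r)["total_unidentified_percent"] == 1.0
        assert unknown_summary(
            r, formula_counts_as_identified=True
        )["total_unidentified_percent"] == 0.0

    def test_monotone_under_deidentification(self):
        """Removing an identification can only grow both statistics."""
        identified = self._report([_record(1, 70.0), _record(2, 30.0)])
        partial = self._report([
            _record(1, 70.0),
            _record(2, 30.0, tier=ConfidenceTier.FORMULA_ONLY),
        ])
        s0, s1 = unknown_summary(identified), unknown_summary(partial)
        assert s1["max_unknown_percent"] >= s0["max_unknown_percent"]
        assert (s1["total_unidentified_percent"]
                >= s0["total_unidentified_percent"])


@pytest.fixture(scope="module")
def sim():
    cons = example_constituents(8, seed=2)
    return simulate_extract(cons, SimulationConfig(seed=17))


class TestRunPipeline:
    def test_ground_truth_formulas_recovered(self, sim, tmp_path):
        """Every generating formula appears among the top-ranked
        candidates of its peak.  Adduct ambiguity can tie two readings
        of the same ion formula (e.g. [M+H]+ of a CxHyNOz vs [M+NH4]+
        of the N-free analogue), so the check allows the top 2."""
        report = run_pipeline(sim.cad, sim.spectra["+"], PipelineConfig(),
                              out_dir=tmp_path)
        truth = {c.formula.hill() for c in sim.constituents}
        top2 = {c.formula.hill() for r in report.records
                for a in r.analytes for c in a.candidates[:2]}
        top1 = {a.formula.hill() for r in report.records
                for a in r.analytes if a.formula}
        assert truth <= top2
        assert len(truth & top1) >= len(truth) - 1
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "thresholds.json").exists()

    def test_percentages_conserve_quant(self, sim):
        report = run_pipeline(sim.cad, sim.spectra["+"], PipelineConfig())
        assert sum(r.cad_percent for r in report.records) == \
            pytest.approx(100.0, abs=1e-6)

    def test_determinism_byte_identical_json(self, tmp_path):
        cons = example_constituents(6, seed=4)
        blobs = []
        for d in ("a", "b"):
            sim = simulate_extract(cons, SimulationConfig(seed=23))
            out = tmp_path / d
            run_pipeline(sim.cad, sim.spectra["+"], PipelineConfig(),
                         out_dir=out)
            blobs.append((out / "report.json").read_bytes())
        assert blobs[0] == blobs[1]

    def test_standard_match_promotes_tier(self, sim):
        standards = [ReferenceStandard(c.name, c.formula, rt=c.rt, cas=None)
                     for c in sim.constituents]
        report = run_pipeline(sim.cad, sim.spectra["+"], PipelineConfig(),
                              standards=standards)
        tiers = {r.tier for r in report.records if r.analytes}
        assert ConfidenceTier.STANDARD_MATCH in tiers

    def test_annotation_promotes_to_proposed(self, sim):
        c0 = sim.constituents[1]
        ann = [Annotation(formula=c0.formula.hill(), name="Annotated thing",
                          comment="From a spectral library.")]
        report = run_pipeline(sim.cad, sim.spectra["+"], PipelineConfig(),
                              annotations=ann)
        names = {a.name for r in report.records for a in r.analytes}
        assert "Annotated thing" in names

    def test_stage_error_carries_stage_name(self):
        from botanicad.chromatogram import Trace
        t = np.arange(0.0, 5.0, 1 / 600)
        flat = Trace("CAD", t, np.zeros_like(t))
        with pytest.raises(PipelineError) as err:
            run_pipeline(flat, [], PipelineConfig())
        assert err.value.stage in ("peaks", "quantitation")

    def test_json_summary_fields(self, sim, tmp_path):
        report = run_pipeline(sim.cad, sim.spectra["+"], PipelineConfig(),
                              out_dir=tmp_path)
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["schema_version"] == "1.0"
        assert payload["summary"]["n_peaks"] == report.n_peaks
        assert all("CAD Peak number" in r for r in payload["records"])
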