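"""Centroid spectra -> EICs -> deisotoped features -> adduct groups."""

import numpy as np
import pytest

from botanicad.chem import MolecularFormula, adduct_by_name, adduct_mz, \
    monoisotopic_mass
from botanicad.ms_features import (
    ISOTOPE_SPACING,
    CentroidSpectrum,
    MSFeature,
    detect_features,
    extract_eic,
    group_adducts,
    read_spectra_json,
    write_spectra_json,
)
from botanicad.formula_assign import ObservedEnvelope
from botanicad.synthetic import (
    GroundTruthConstituent,
    SimulationConfig,
    simulate_extract,
)

F = MolecularFormula.parse
ADDUCTS = [adduct_by_name(n) for n in
           ("[M+H]+", "[M+NH4]+", "[M+Na]+", "[M+2H]2+", "[M-H]-", "[M+HCOO]-")]


def _scan(rt, pairs, polarity="+"):
    pairs = sorted(pairs)
    return CentroidSpectrum(rt=rt, polarity=polarity,
                            mzs=np.array([p[0] for p in pairs]),
                            intensities=np.array([p[1] for p in pairs]))


def _gaussian_scans(mz_int: list[tuple[float, float]], rt0=2.0, sigma=0.05,
                    n=60, dt=1 / 300, polarity="+"):
    """Scans carrying co-eluting traces with Gaussian elution profiles."""
    scans = []
    for i in range(n):
        rt = rt0 + (i - n // 2) * dt
        amp = np.exp(-0.5 * ((rt - rt0) / sigma) ** 2)
        pairs = [(mz, inten * amp) for mz, inten in mz_int
                 if inten * amp > 1e-3]
        if pairs:
            scans.append(_scan(rt, pairs, polarity))
    return scans


class TestExtractEic:
    def test_exact_centroids_summed(self):
        scans = [_scan(float(i), [(500.0, 10.0 * (i + 1))]) for i in range(5)]
        eic = extract_eic(scans, 500.0, 10.0)
        np.testing.assert_allclose(eic.intensities, [10, 20, 30, 40, 50])

    def test_offset_beyond_tolerance_contributes_zero(self):
        scans = [_scan(float(i), [(500.0 * (1 + 20e-6), 10.0)])
                 for i in range(3)]
        eic = extract_eic(scans, 500.0, 10.0)
        assert np.all(eic.intensities == 0.0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            extract_eic([_scan(0.0, [(500.0, 1.0)]),
                         _scan(1.0, [(500.0, 1.0)])], 500.0, 0.0)

    def test_apex_time_matches_ground_truth(self):
        scans = _gaussian_scans([(500.0, 1000.0)], rt0=2.0)
        eic = extract_eic(scans, 500.0, 10.0)
        apex = eic.times[np.argmax(eic.intensities)]
        assert abs(apex - 2.0) <= 1 / 300


class TestDetectFeatures:
    def test_profile_mode_rejected(self):
        mzs = np.arange(400.0, 401.0, 0.002)
        dense = CentroidSpectrum(rt=1.0, polarity="+", mzs=mzs,
                                 intensities=np.ones(mzs.size))
        with pytest.raises(ValueError, match="centroid"):
            detect_features([dense] * 4)

    def test_isotopologue_traces_merge_z1(self):
        scans = _gaussian_scans([(611.1607, 1000.0),
                                 (611.1607 + ISOTOPE_SPACING, 300.0)])
        feats = detect_features(scans)
        assert len(feats) == 1
        assert feats[0].charge == 1
        assert feats[0].mz == pytest.approx(611.1607, abs=1e-3)
        assert len(feats[0].envelope.mzs) == 2

    def test_half_spacing_assigns_z2(self):
        scans = _gaussian_scans([(749.2000, 1000.0),
                                 (749.2000 + ISOTOPE_SPACING / 2, 800.0),
                                 (749.2000 + ISOTOPE_SPACING, 350.0)])
        feats = detect_features(scans)
        assert len(feats) == 1
        assert feats[0].charge == 2

    def test_isolated_trace_defaults_to_z1(self):
        scans = _gaussian_scans([(321.0, 500.0)])
        feats = detect_features(scans)
        assert len(feats) == 1
        assert feats[0].charge == 1
        assert len(feats[0].envelope.mzs) == 1

    def test_short_trace_dropped(self):
        scans = [_scan(1.0, [(400.0, 10.0)]), _scan(1.003, [(400.0, 12.0)])]
        assert detect_features(scans, min_scans=3) == []

    def test_eic_area_matches_generator(self):
        """Noiseless simulated feature: EIC integral within 1 %."""
        c = GroundTruthConstituent(
            name="rutin", formula=F("C27H30O16"), rt=2.0,
            mass_fraction_pct=100.0, adducts={"+": ("[M+H]+",)})
        sim = simulate_extract([c], SimulationConfig(
            seed=3, noise_sigma=0.0, hump_amplitude=0.0,
            mass_error_ppm=0.0, abundance_error_pct=0.0))
        feats = detect_features(sim.spectra["+"])
        mono = [f for f in feats
                if abs(f.mz - 611.1607) < 0.01]
        assert len(mono) == 1
        # generator: EMG area = ms_scale x fraction; trapezoid vs truth
        expected = sim.config.ms_scale
        assert mono[0].area == pytest.approx(expected, rel=0.01)


class TestGroupAdducts:
    def _feature(self, mz, rt, area=100.0, z=1, polarity="+"):
        env = ObservedEnvelope(mzs=(mz,), intensities=(area,), charge=z,
                               polarity=polarity)
        return MSFeature(mz=mz, charge=z, rt=rt, area=area, envelope=env,
                         polarity=polarity)

    def test_proton_and_ammonium_merge(self):
        m = 610.15338
        f1 = self._feature(adduct_mz(m, adduct_by_name("[M+H]+")), 5.0)
        f2 = self._feature(adduct_mz(m, adduct_by_name("[M+NH4]+")), 5.01,
                           area=40.0)
        groups = group_adducts([f1, f2], ADDUCTS)
        assert len(groups) == 1
        assert groups[0].neutral_mass == pytest.approx(m, abs=m * 5e-6)
        assert set(groups[0].adduct_names()) == {"[M+H]+", "[M+NH4]+"}

    def test_unrelated_features_stay_separate(self):
        f1 = self._feature(400.0, 5.0)
        f2 = self._feature(400.9, 5.0)
        groups = group_adducts([f1, f2], ADDUCTS)
        assert len(groups) == 2

    def test_doubly_and_singly_charged_merge(self):
        """A 2+ ion and the 1+ ion of the same neutral (flavonoid dimer
        case) collapse to one neutral mass."""
        m = 1496.38541
        f1 = self._feature(adduct_mz(m, adduct_by_name("[M+2H]2+")), 5.0, z=2)
        f2 = self._feature(adduct_mz(m, adduct_by_name("[M+H]+")), 5.02)
        groups = group_adducts([f1, f2], ADDUCTS)
        assert len(groups) == 1
        assert groups[0].neutral_mass == pytest.approx(m, abs=m * 5e-6)

    def test_rt_window_blocks_grouping(self):
        m = 610.15338
        f1 = self._feature(adduct_mz(m, adduct_by_name("[M+H]+")), 5.0)
        f2 = self._feature(adduct_mz(m, adduct_by_name("[M+NH4]+")), 5.5)
        assert len(group_adducts([f1, f2], ADDUCTS, rt_window=0.05)) == 2

    def test_partition_property(self, rng):
        feats = [self._feature(float(mz), float(rt))
                 for mz, rt in zip(rng.uniform(200, 900, 25),
                                   rng.uniform(1, 10, 25))]
        groups = group_adducts(feats, ADDUCTS)
        members = [f for g in groups for f, _ in g.members]
        assert len(members) == len(feats)
        assert {id(f) for f in members} == {id(f) for f in feats}

    def test_negative_mode_default_is_deprotonation(self):
        f = self._feature(609.14610, 5.0, polarity="-")
        groups = group_adducts([f], ADDUCTS)
        assert groups[0].adduct_names() == ("[M-H]-",)
        assert groups[0].neutral_mass == pytest.approx(610.15338, abs=0.01)


class TestRoundTrip:
    def test_simulated_analytes_recovered_as_groups(self):
        """N well-separated (formula, adduct-set) analytes -> exactly N
        groups with correct neutral masses."""
        formulas = ["C15H18O8", "C27H30O16", "C20H24O9", "C48H78O18"]
        cons = [GroundTruthConstituent(
            name=f, formula=F(f), rt=2.0 + i * 1.5,
            mass_fraction_pct=25.0,
            adducts={"+": ("[M+H]+", "[M+NH4]+")})
            for i, f in enumerate(formulas)]
        sim = simulate_extract(cons, SimulationConfig(seed=21, noise_sigma=0.2))
        feats = detect_features(sim.spectra["+"])
        groups = group_adducts(feats, ADDUCTS)
        assert len(groups) == len(formulas)
        got = sorted(g.neutral_mass for g in groups)
        want = sorted(monoisotopic_mass(F(f)) for f in formulas)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=w * 5e-6)

    def test_spectra_json_round_trip(self, tmp_path):
        scans = _gaussian_scans([(500.0, 800.0)])
        path = tmp_path / "spectra.json"
        write_spectra_json(scans, path)
        back = read_spectra_json(path)
        assert len(back) == len(scans)
        assert back[0].polarity == "+"
        np.testing.assert_allclose(back[0].mzs, scans[0].mzs, atol=1e-5)
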