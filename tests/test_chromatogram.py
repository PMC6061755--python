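"""Baseline estimation, peak detection, USP shape metrics, quantitation."""

import numpy as np
import pytest

from botanicad.chromatogram import (
    BaselineParams,
    Peak,
    QuantTable,
    Trace,
    detect_peaks,
    estimate_baseline,
    read_trace_csv,
    relative_quantitation,
    usp_shape_metrics,
    write_trace_csv,
)
from botanicad.synthetic import emg_profile
from oracles import emg_usp_oracle


def _grid(t0=0.0, t1=10.0, hz=10.0):
    return np.arange(t0, t1, 1.0 / (60.0 * hz))


class TestTrace:
    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            Trace("CAD", np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Trace("CAD", np.array([0.0, 1.0]), np.array([1.0, np.nan]))

    def test_rejects_unknown_detector(self):
        with pytest.raises(ValueError):
            Trace("NMR", np.array([0.0, 1.0]), np.zeros(2))

    def test_csv_round_trip(self, tmp_path):
        t = _grid(0, 1)
        tr = Trace("CAD", t, np.sin(t))
        path = tmp_path / "sample_cad.csv"
        write_trace_csv(tr, path)
        back = read_trace_csv(path)  # detector inferred from filename
        assert back.detector == "CAD"
        np.testing.assert_allclose(back.intensities, tr.intensities, atol=1e-6)


class TestBaseline:
    def test_zero_trace_gives_zero_baseline(self):
        t = _grid()
        b = estimate_baseline(Trace("CAD", t, np.zeros_like(t)))
        assert np.all(b.intensities == 0.0)

    def test_constant_offset_recovered_exactly(self):
        t = _grid()
        b = estimate_baseline(Trace("CAD", t, np.full(t.size, 7.5)))
        np.testing.assert_allclose(b.intensities, 7.5, atol=7.5e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(Trace("CAD", np.arange(5.0), np.zeros(5)))

    def test_recovers_broad_hump_under_narrow_peaks(self):
        """Hump sigma 10 min >> peak sigma 0.05 min: the asymmetric
        smoother follows the hump, not the peaks (<= 5 % RMS)."""
        t = _grid(0, 60)
        hump = 40.0 * np.exp(-0.5 * ((t - 30.0) / 10.0) ** 2)
        y = hump.copy()
        for rt in np.linspace(5, 55, 20):
            y += 30.0 * emg_profile(t, rt, 0.05, 0.0)
        b = estimate_baseline(Trace("CAD", t, y))
        rms = np.sqrt(np.mean((b.intensities - hump) ** 2))
        assert rms <= 0.05 * 40.0

    def test_baseline_stays_below_peaks(self):
        t = _grid(0, 20)
        y = 10.0 + 100.0 * emg_profile(t, 10.0, 0.05, 0.0)
        b = estimate_baseline(Trace("CAD", t, y))
        apex = np.argmax(y)
        assert b.intensities[apex] < 0.2 * y[apex]


class TestDetectPeaks:
    def test_noiseless_gaussian_found_at_center(self, gaussian_trace,
                                                zero_baseline):
        peaks = detect_peaks(gaussian_trace, zero_baseline(gaussian_trace),
                             min_snr=0)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_time - 5.0) <= 1.0 / 600.0
        assert peaks[0].area == pytest.approx(100.0, rel=1e-3)

    def test_misaligned_baseline_rejected(self, gaussian_trace):
        t = gaussian_trace.times[:-1]
        bad = Trace("CAD", t, np.zeros_like(t))
        with pytest.raises(ValueError):
            detect_peaks(gaussian_trace, bad)

    def test_noiseless_nonzero_signal_requires_min_snr_zero(self,
                                                            gaussian_trace,
                                                            zero_baseline):
        with pytest.raises(ValueError, match="min_snr=0"):
            detect_peaks(gaussian_trace, zero_baseline(gaussian_trace),
                         min_snr=3.0)

    def test_snr_gate_excludes_subthreshold_peak(self, zero_baseline):
        """Threshold semantics: measured snr < min_snr -> excluded.

        The dither lives only in peak-free regions so the measured
        apex heights are exact: 2 x noise is rejected, 10 x noise kept.
        """
        t = _grid(0, 12)
        small = 2.0 * np.sqrt(2 * np.pi) * 0.05 * emg_profile(t, 4.0, 0.05, 0.0)
        big = 10.0 * np.sqrt(2 * np.pi) * 0.05 * emg_profile(t, 8.0, 0.05, 0.0)
        dither = np.where(np.arange(t.size) % 2 == 0, 1.0, -1.0) / 1.4826
        quiet = (np.abs(t - 4.0) < 0.5) | (np.abs(t - 8.0) < 0.5)
        y = small + big + np.where(quiet, 0.0, dither)
        tr = Trace("CAD", t, y)
        peaks = detect_peaks(tr, zero_baseline(tr), min_snr=3.0,
                             min_rel_area_pct=0.0)
        apexes = [p.apex_time for p in peaks]
        assert any(abs(a - 8.0) < 0.1 for a in apexes)
        assert not any(abs(a - 4.0) < 0.1 for a in apexes)

    def test_rel_area_floor_is_second_pass(self, zero_baseline):
        t = _grid(0, 12)
        y = (1000.0 * emg_profile(t, 4.0, 0.05, 0.0)
             + 0.2 * emg_profile(t, 8.0, 0.05, 0.0))  # 0.02 % of total
        tr = Trace("CAD", t, y)
        kept = detect_peaks(tr, zero_baseline(tr), min_snr=0,
                            min_rel_area_pct=0.05)
        assert len(kept) == 1
        both = detect_peaks(tr, zero_baseline(tr), min_snr=0,
                            min_rel_area_pct=0.0)
        assert len(both) == 2

    def test_fused_peaks_split_at_shared_valley(self, zero_baseline):
        t = _grid(0, 10)
        y = (50.0 * emg_profile(t, 5.0, 0.05, 0.0)
             + 50.0 * emg_profile(t, 5.18, 0.05, 0.0))
        tr = Trace("CAD", t, y)
        peaks = detect_peaks(tr, zero_baseline(tr), min_snr=0,
                             min_rel_area_pct=0.0)
        assert len(peaks) == 2
        assert peaks[0].right_time == pytest.approx(peaks[1].left_time,
                                                    abs=2 / 600)

    def test_numbering_in_elution_order(self, rng, zero_baseline):
        t = _grid(0, 20)
        y = np.zeros_like(t)
        rts = [3.0, 7.0, 12.0, 17.0]
        for rt in rts:
            y += 50.0 * emg_profile(t, rt, 0.05, 0.05)
        tr = Trace("CAD", t, y)
        peaks = detect_peaks(tr, zero_baseline(tr), min_snr=0)
        assert [p.number for p in peaks] == [1, 2, 3, 4]
        assert all(abs(p.apex_time - rt) < 0.1
                   for p, rt in zip(peaks, rts))

    def test_constant_offset_invariance(self, rng):
        """Adding a constant changes no area, snr, or shape metric."""
        t = _grid(0, 10)
        y = 80.0 * emg_profile(t, 5.0, 0.05, 0.05) + rng.normal(0, 0.4, t.size)
        a = Trace("CAD", t, y)
        b = Trace("CAD", t, y + 123.0)
        pa = detect_peaks(a, estimate_baseline(a))
        pb = detect_peaks(b, estimate_baseline(b))
        assert len(pa) == len(pb) == 1
        assert pa[0].area == pytest.approx(pb[0].area, rel=1e-6)
        assert pa[0].snr == pytest.approx(pb[0].snr, rel=1e-6)


class TestUspShapeMetrics:
    def test_symmetric_gaussian_is_unity(self, gaussian_trace, zero_baseline):
        base = zero_baseline(gaussian_trace)
        peak = detect_peaks(gaussian_trace, base, min_snr=0)[0]
        m = usp_shape_metrics(gaussian_trace, base, peak)
        assert m.asymmetry_factor == pytest.approx(1.0, abs=0.01)
        assert m.tailing_factor == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("k", [1.0, 2.0, 3.0])
    def test_emg_matches_dense_grid_oracle(self, k, zero_baseline):
        t = _grid(0, 10)
        y = 100.0 * emg_profile(t, 5.0, 0.05, 0.05 * k)
        tr = Trace("CAD", t, y)
        base = zero_baseline(tr)
        peak = detect_peaks(tr, base, min_snr=0)[0]
        m = usp_shape_metrics(tr, base, peak)
        af, tf = emg_usp_oracle(k)
        assert m.asymmetry_factor == pytest.approx(af, rel=0.02)
        assert m.tailing_factor == pytest.approx(tf, rel=0.02)

    def test_time_reversal_inverts_asymmetry(self, zero_baseline):
        """A fronting peak (mirror-image EMG) has A_f < 1, T < 1, and
        A_f maps to 1/A_f."""
        t = _grid(0, 10)
        y = 100.0 * emg_profile(t, 5.0, 0.05, 0.1)
        fwd = Trace("CAD", t, y)
        rev = Trace("CAD", t, y[::-1].copy())
        mf = usp_shape_metrics(fwd, zero_baseline(fwd),
                               detect_peaks(fwd, zero_baseline(fwd), 0)[0])
        mr = usp_shape_metrics(rev, zero_baseline(rev),
                               detect_peaks(rev, zero_baseline(rev), 0)[0])
        assert mf.asymmetry_factor > 1 and mf.tailing_factor > 1
        assert mr.asymmetry_factor < 1 and mr.tailing_factor < 1
        assert mr.asymmetry_factor == pytest.approx(1 / mf.asymmetry_factor,
                                                    rel=0.01)
        assert mr.a10 == pytest.approx(mf.b10, rel=0.01)

    def test_unbracketed_crossing_names_side(self, zero_baseline):
        t = _grid(4.9, 5.4)
        y = 100.0 * emg_profile(t, 5.0, 0.05, 0.0)
        tr = Trace("CAD", t, y)
        peak = Peak(number=1, apex_time=5.0, left_time=4.9, right_time=5.39,
                    height=float(y.max()), area=1.0, snr=np.inf)
        with pytest.raises(ValueError, match="front"):
            usp_shape_metrics(tr, zero_baseline(tr), peak)


class TestRelativeQuantitation:
    def _peak(self, n, area):
        return Peak(number=n, apex_time=float(n), left_time=n - 0.2,
                    right_time=n + 0.2, height=1.0, area=area, snr=10.0)

    def test_single_peak_is_100(self):
        q = relative_quantitation([self._peak(1, 3.3)])
        assert q.percent_of(1) == 100.0

    def test_equal_areas_split_evenly(self):
        q = relative_quantitation([self._peak(i, 2.0) for i in range(1, 5)])
        assert all(q.percent_of(i) == pytest.approx(25.0) for i in range(1, 5))

    def test_proportional_split(self):
        q = relative_quantitation([self._peak(1, 1.0), self._peak(2, 1.0),
                                   self._peak(3, 2.0)])
        assert (q.percent_of(1), q.percent_of(2), q.percent_of(3)) == \
            pytest.approx((25.0, 25.0, 50.0))

    def test_sums_to_exactly_100(self, rng):
        peaks = [self._peak(i, float(a)) for i, a in
                 enumerate(rng.uniform(0.1, 10, 37), start=1)]
        q = relative_quantitation(peaks)
        assert sum(p for _, p in q.percents) == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            relative_quantitation([])
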