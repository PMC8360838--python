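"""Rule-based FaST algorithm: envelope, periodicity, candidates, graph
search, morphology and the composed decision."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fastegm import (FaSTParams, SynthConfig, classify_fast,
                     classify_morphology, detect_candidates,
                     make_complex_template, preprocess_bipolar,
                     select_periodic_train, spectral_periodicity, synth_record)

FS = 1000.0


def _gaussian_bump(amplitude, sigma_ms, center_ms, n=5000):
    t = np.arange(n)
    return amplitude * np.exp(-((t - center_ms) ** 2) / (2 * sigma_ms ** 2))


def _envelope_train(cl_ms, n=5000, width=40):
    x = np.zeros(n)
    bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))
    for start in range(100, n - width, int(cl_ms)):
        x[start:start + width] += bump
    return x


class TestPreprocess:
    def test_zero_in_zero_out(self):
        out = preprocess_bipolar(np.zeros(5000), FS)
        assert np.allclose(out, 0.0)
        assert len(out) == 5000

    def test_pure_sinusoid_envelope_is_low_frequency(self):
        # a 100 Hz carrier rectifies to DC + harmonics at 200 Hz+; band2
        # removes both, so what remains lives below 20 Hz (edge effects)
        t = np.arange(5000) / FS
        out = preprocess_bipolar(np.sin(2 * np.pi * 100 * t), FS)
        spec = np.abs(np.fft.rfft(out)) ** 2
        freqs = np.fft.rfftfreq(5000, 1 / FS)
        assert spec[freqs > 25].sum() < 0.05 * spec.sum()

    def test_burst_train_envelope_peaks_at_train_rate(self):
        # impulse train at CL 200 ms convolved with a 10-ms 100 Hz burst:
        # envelope spectrum peaks at 5 Hz (oracle: direct FFT of the output)
        t = np.arange(5000) / FS
        x = np.zeros(5000)
        burst = np.sin(2 * np.pi * 100 * np.arange(10) / FS)
        for start in range(100, 4900, 200):
            x[start:start + 10] += burst
        env = preprocess_bipolar(x, FS)
        spec = np.abs(np.fft.rfft(env)) ** 2
        freqs = np.fft.rfftfreq(5000, 1 / FS)
        band = (freqs >= 0.5) & (freqs <= 20)
        peak = freqs[band][np.argmax(spec[band])]
        assert peak == pytest.approx(5.0, abs=0.2)

    def test_sampling_rate_too_low_raises(self):
        with pytest.raises(ValueError):
            preprocess_bipolar(np.zeros(2000), 400.0)


class TestSpectralPeriodicity:
    def test_clean_train_detected_at_200ms(self):
        res = spectral_periodicity(_envelope_train(200), FS)
        assert res.is_periodic
        assert res.periodicity_cl == pytest.approx(200, abs=5)
        assert res.peak_power_fraction >= 0.10

    def test_cl_outside_atrial_window_rejected(self):
        # CL 500 ms (2 Hz) lies outside the 100-250 ms physiologic window
        res = spectral_periodicity(_envelope_train(500), FS)
        assert not res.is_periodic

    def test_white_noise_not_periodic(self):
        rng = np.random.default_rng(12)
        env = preprocess_bipolar(rng.normal(0, 0.05, 5000), FS)
        res = spectral_periodicity(env, FS)
        # oracle: recompute the fraction by direct FFT on this fixed draw
        spec = np.abs(np.fft.rfft(env)) ** 2
        freqs = np.fft.rfftfreq(5000, 1 / FS)
        band = (freqs >= 0.5) & (freqs <= 20)
        idx = np.flatnonzero(band)
        pk = idx[np.argmax(spec[idx])]
        frac = spec[pk - 1:pk + 2].sum() / spec[band].sum()
        assert res.peak_power_fraction == pytest.approx(frac, rel=1e-9)
        assert not res.is_periodic
        # even the best bin inside the 4-10 Hz atrial window is weak
        win = np.flatnonzero((freqs >= 4.0) & (freqs <= 10.0))
        pw = win[np.argmax(spec[win])]
        assert spec[pw - 1:pw + 2].sum() / spec[band].sum() < 0.10

    def test_all_zero_envelope_is_not_an_error(self):
        res = spectral_periodicity(np.zeros(5000), FS)
        assert not res.is_periodic
        assert res.peak_power_fraction == 0.0

    @pytest.mark.parametrize("cl", [100, 150, 200, 250])
    def test_cl_recovery_on_noiseless_synthetic_trains(self, cl):
        config = SynthConfig(noise_sd=1e-9, baseline_wander_amplitude=0.0,
                             jitter_sd=1e-9)
        rec, _ = synth_record("FAST_QS", config, seed=2, cycle_length=float(cl))
        env = preprocess_bipolar(rec.bipolar, FS)
        res = spectral_periodicity(env, FS)
        assert res.is_periodic
        assert res.periodicity_cl == pytest.approx(cl, abs=5)


class TestCandidates:
    def test_flat_signal_yields_no_candidates(self):
        assert len(detect_candidates(np.zeros(5000), FS)) == 0

    def test_amplitude_threshold_is_exact(self):
        below = _gaussian_bump(0.049, 1, 2500)
        above = _gaussian_bump(0.051, 1, 2500)
        assert len(detect_candidates(below, FS)) == 0
        assert len(detect_candidates(above, FS)) == 1

    def test_slew_threshold_rejects_slow_deflections(self):
        # Gaussian deflection: max slew = 0.607 A / sigma at t = sigma,
        # kept inside the +/-10 ms slew window by fixing sigma = 8 ms
        slow = _gaussian_bump(0.010 * 8 / 0.607, 8, 2500)   # slew ~ 0.010
        sharp = _gaussian_bump(0.020 * 8 / 0.607, 8, 2500)  # slew ~ 0.020
        assert len(detect_candidates(slow, FS)) == 0
        cands = detect_candidates(sharp, FS)
        assert len(cands) == 1
        assert cands[0] == pytest.approx(2500, abs=2)

    def test_refractory_separation(self):
        x = _gaussian_bump(0.5, 4, 2480) + _gaussian_bump(0.5, 4, 2510)
        cands = detect_candidates(x, FS)  # 30 ms apart < 50 ms refractory
        assert len(cands) == 1

    def test_raising_noise_threshold_never_adds_candidates(self):
        rec, _ = synth_record("FRACTIONATED", SynthConfig(), seed=8)
        counts = []
        for thr in (0.05, 0.1, 0.2, 0.4):
            p = FaSTParams(noise_threshold=thr)
            counts.append(len(detect_candidates(rec.bipolar, FS, p)))
        assert counts == sorted(counts, reverse=True)


def brute_force_best_chain(cands, cl, tol):
    """Exhaustive enumeration over all increasing subsequences."""
    best = None
    m = len(cands)
    for r in range(1, m + 1):
        for combo in itertools.combinations(range(m), r):
            ts = [cands[i] for i in combo]
            deltas = np.diff(ts)
            if np.all(np.abs(deltas - cl) < tol):
                cost = float(np.sum(np.abs(deltas - cl)))
                key = (-len(ts), cost, ts[0])
                if best is None or key < best[0]:
                    best = (key, ts)
    return best[1], -best[0][0], best[0][1]


class TestGraphSearch:
    def test_single_candidate(self):
        tr = select_periodic_train(np.array([100.0]), 200.0)
        assert tr.chain.tolist() == [100.0]
        assert tr.chain_length == 1

    def test_periodic_subset_selected_with_zero_cost(self):
        cands = np.array([100.0, 300.0, 500.0, 700.0, 950.0])
        tr = select_periodic_train(cands, 200.0)
        assert tr.chain.tolist() == [100.0, 300.0, 500.0, 700.0]
        assert tr.total_cost == pytest.approx(0.0)

    def test_cost_breaks_length_ties(self):
        # two disjoint length-3 chains: costs 12 ms vs 4 ms
        cands = np.array([0.0, 206.0, 412.0, 2000.0, 2202.0, 2404.0])
        tr = select_periodic_train(cands, 200.0)
        assert tr.chain.tolist() == [2000.0, 2202.0, 2404.0]
        assert tr.total_cost == pytest.approx(4.0)

    def test_empty_candidates(self):
        tr = select_periodic_train(np.empty(0), 200.0)
        assert tr.chain_length == 0

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 5000), min_size=1, max_size=10, unique=True),
           st.floats(100, 250))
    def test_dp_equals_exhaustive_enumeration(self, cands, cl):
        cands = sorted(cands)
        params = FaSTParams()
        tol = params.chain_tolerance_fraction * cl
        tr = select_periodic_train(np.array(cands), cl, params)
        chain, length, cost = brute_force_best_chain(cands, cl, tol)
        assert tr.chain_length == length
        assert tr.total_cost == pytest.approx(cost, abs=1e-9)
        assert tr.chain.tolist() == pytest.approx(chain)


class TestMorphology:
    def _complex_at(self, kind, ratio, onset_ms=1000, amp=1.0, n=3000):
        x = np.zeros(n)
        tpl = make_complex_template(kind, 40.0, amp, r_to_s_ratio=ratio)
        i = int(onset_ms)
        x[i:i + len(tpl)] = tpl
        return x

    def test_small_r_complex_is_qs(self):
        x = self._complex_at("rS", 0.05)
        (call,) = classify_morphology(x, FS, np.array([1000.0]))
        assert call.rs_ratio == pytest.approx(0.05, abs=1e-6)
        assert call.is_qs

    def test_pure_qs_ratio_zero(self):
        x = self._complex_at("QS", 0.0)
        (call,) = classify_morphology(x, FS, np.array([1000.0]))
        assert call.rs_ratio == pytest.approx(0.0, abs=1e-9)
        assert call.is_qs

    def test_rs_complex_is_not_qs(self):
        x = self._complex_at("RS", 0.2)
        (call,) = classify_morphology(x, FS, np.array([1000.0]))
        assert call.rs_ratio == pytest.approx(0.2, abs=1e-6)
        assert not call.is_qs

    def test_sub_noise_complex_flagged_indeterminate(self):
        x = self._complex_at("QS", 0.0, amp=0.03)
        (call,) = classify_morphology(x, FS, np.array([1000.0]))
        assert call.indeterminate

    def test_empty_onsets(self):
        assert classify_morphology(np.zeros(3000), FS, np.empty(0)) == []

    def test_raising_ratio_threshold_never_lowers_qs_fraction(self):
        rec, _ = synth_record("SMALL_R_RS", SynthConfig(), seed=4)
        fracs = []
        for thr in (0.05, 0.1, 0.2, 0.5):
            p = FaSTParams(rs_ratio_threshold=thr)
            d = classify_fast(rec, p)
            fracs.append(d.qs_fraction)
        assert fracs == sorted(fracs)


class TestClassifyFast:
    def test_fast_qs_record_is_fast(self):
        rec, _ = synth_record("FAST_QS", SynthConfig(), seed=1,
                              cycle_length=200.0)
        d = classify_fast(rec)
        assert d.is_fast
        assert d.qs_fraction >= 0.9
        assert d.periodicity.is_periodic and d.sustained

    def test_switching_record_fails_qs_dominance(self):
        rec, _ = synth_record("SWITCHING", SynthConfig(), seed=5,
                              cycle_length=200.0)
        d = classify_fast(rec)
        assert not d.is_fast
        assert d.qs_fraction == pytest.approx(0.72, abs=0.04)

    def test_noise_record_short_circuits(self):
        from fastegm.records import EgmRecord
        rng = np.random.default_rng(3)
        rec = EgmRecord("n", "p", FS, rng.normal(0, 0.01, 5000),
                        rng.normal(0, 0.01, 5000), 5.0)
        d = classify_fast(rec)
        assert not d.is_fast
        assert not d.periodicity.is_periodic
        assert d.calls == []

    def test_short_record_rejected(self):
        from fastegm.records import EgmRecord
        rec = EgmRecord("s", "p", FS, np.zeros(1000), np.zeros(1000), 1.0)
        with pytest.raises(ValueError):
            classify_fast(rec)

    @pytest.mark.parametrize("scale", [1.0, 2.0, 10.0])
    def test_decision_scale_invariance_above_thresholds(self, scale):
        """Scaling both channels up never flips a morphology-driven call:
        the R/S ratio is scale-free and amplitude thresholds are absolute."""
        from fastegm.records import EgmRecord
        for cname, seed in (("FAST_QS", 1), ("PERIODIC_RS", 2), ("SWITCHING", 3)):
            rec, _ = synth_record(cname, SynthConfig(), seed=seed)
            scaled = EgmRecord(rec.record_id, rec.patient_id, rec.sampling_rate,
                               rec.unipolar * scale, rec.bipolar * scale,
                               rec.duration)
            assert classify_fast(rec).is_fast == classify_fast(scaled).is_fast
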