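import numpy as np
import pytest

from assemblage.rhythm import (
    Correlogram,
    acg_modulation_index,
    autocorrelogram,
    ccg_band_contrast,
    ccg_spectrum,
    classify_assembly_phase,
    crosscorrelogram,
    error_activation_contrast,
    lead_lag_balance,
    pair_coherence,
)


def cosine_poisson(rng, rate, m, f, duration, phi=0.0):
    """Inhomogeneous Poisson train with (1 + m cos(2 pi f t + phi)) intensity."""
    t = np.arange(0, duration, 1e-3)
    lam = rate * (1 + m * np.cos(2 * np.pi * f * t + phi))
    return t[rng.random(t.size) < lam * 1e-3]


class TestAutocorrelogram:
    def test_homogeneous_poisson_flat_near_one(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 600, rng.poisson(8.0 * 600)))
        acg = autocorrelogram(spikes, bin_s=0.02, max_lag=0.5)
        assert abs(np.nanmean(acg.values) - 1.0) < 0.05
        assert np.nanstd(acg.values) < 0.1

    def test_symmetric_about_zero_lag(self):
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, 100, 800))
        acg = autocorrelogram(spikes, bin_s=0.02, max_lag=0.3)
        half = acg.values.size // 2
        np.testing.assert_allclose(acg.values[:half][::-1], acg.values[half:])

    def test_cosine_modulated_train_peaks_at_period(self):
        rng = np.random.default_rng(2)
        spikes = cosine_poisson(rng, 10.0, 0.8, 4.5, 500.0)
        acg = autocorrelogram(spikes, bin_s=0.02, max_lag=1.0)
        lags = acg.lags
        # closed form: ACG of cosine-modulated Poisson ~ 1 + (m^2/2) cos(2 pi f tau)
        expected = 1 + 0.5 * 0.8**2 * np.cos(2 * np.pi * 4.5 * lags)
        mask = np.abs(lags) > 0.03
        assert np.corrcoef(acg.values[mask], expected[mask])[0, 1] > 0.9
        # first side peak near 1/4.5 s = 222 ms
        pos = (lags > 0.1) & (lags < 0.35)
        assert abs(lags[pos][np.argmax(acg.values[pos])] - 1 / 4.5) < 0.04

    def test_low_spike_count_flagged(self):
        with pytest.warns(UserWarning, match="low-confidence"):
            acg = autocorrelogram(np.linspace(0, 10, 20), bin_s=0.02)
        assert acg.low_confidence


class TestModulationIndex:
    def test_flat_acg_near_zero(self):
        lags = np.arange(-1, 1.0001, 0.02)
        acg = Correlogram(lags, np.ones(lags.size), 0.02)
        assert acg_modulation_index(acg) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_modulation_depth(self):
        # against a fixed broadband background, the in-band power fraction
        # grows with the rhythm's modulation depth
        lags = np.arange(-1, 1.0001, 0.02)
        background = 0.2 * np.exp(-np.abs(lags) / 0.05)
        vals = []
        for m in (0.2, 0.5, 0.8):
            acg = Correlogram(
                lags,
                1 + background + 0.5 * m * m * np.cos(2 * np.pi * 4.5 * lags),
                0.02,
            )
            vals.append(acg_modulation_index(acg))
        assert vals[0] < vals[1] < vals[2]

    def test_full_band_normalizes_to_one(self):
        lags = np.arange(-1, 1.0001, 0.02)
        acg = Correlogram(
            lags, 1 + 0.3 * np.cos(2 * np.pi * 4.5 * lags), 0.02
        )
        assert acg_modulation_index(
            acg, band_hz=(1.0, 15.0), total_band_hz=(1.0, 15.0)
        ) == pytest.approx(1.0)


class TestPairCoherence:
    def test_bounded_and_floor_for_independent_pairs(self):
        rng = np.random.default_rng(3)
        epochs = [(10.0 * k, 10.0 * k + 4.0) for k in range(40)]
        a = np.sort(rng.uniform(0, 400, rng.poisson(5 * 400)))
        b = np.sort(rng.uniform(0, 400, rng.poisson(5 * 400)))
        freqs, coh, band = pair_coherence(a, b, epochs)
        assert np.all((coh >= 0) & (coh <= 1))
        # bias floor ~ 1/(tapers x epochs) = 1/200
        assert band < 0.1

    def test_shared_modulation_raises_band_coherence(self):
        rng = np.random.default_rng(4)
        epochs = [(10.0 * k, 10.0 * k + 4.0) for k in range(40)]
        a_parts, b_parts = [], []
        for t0, t1 in epochs:
            phi = rng.uniform(0, 2 * np.pi)
            a_parts.append(t0 + cosine_poisson(rng, 8, 0.6, 4.5, 4.0, phi))
            b_parts.append(t0 + cosine_poisson(rng, 8, 0.6, 4.5, 4.0, phi))
        a = np.concatenate(a_parts)
        b = np.concatenate(b_parts)
        _, _, band_ab = pair_coherence(a, b, epochs)
        c = np.sort(rng.uniform(0, 400, a.size))
        _, _, band_ac = pair_coherence(a, c, epochs)
        assert band_ab > 3 * band_ac


class TestCrossCorrelogram:
    def test_planted_lag_peak_and_antisymmetry(self):
        rng = np.random.default_rng(5)
        events = 20.0 * np.arange(1, 31)
        ref_parts, tgt_parts = [], []
        for ev in events:
            r = np.sort(rng.uniform(ev - 4.0, ev, 40))
            ref_parts.append(r)
            tgt_parts.append(r + 0.01)  # target follows reference by 10 ms
        ref = np.concatenate(ref_parts)
        tgt = np.concatenate(tgt_parts)
        ccg = crosscorrelogram(ref, tgt, events, bin_s=0.02, max_lag=0.2,
                               n_draws=5, rng=np.random.default_rng(6))
        peak_lag = ccg.lags[int(np.nanargmax(ccg.values))]
        assert 0.0 < peak_lag < 0.02  # the bin containing +10 ms
        rev = crosscorrelogram(tgt, ref, events, bin_s=0.02, max_lag=0.2,
                               n_draws=5, rng=np.random.default_rng(6))
        peak_rev = rev.lags[int(np.nanargmax(rev.values))]
        assert peak_rev == pytest.approx(-peak_lag)

    def test_independent_trains_flat(self):
        rng = np.random.default_rng(7)
        events = 20.0 * np.arange(1, 41)
        a = np.sort(rng.uniform(0, 840, rng.poisson(6 * 840)))
        b = np.sort(rng.uniform(0, 840, rng.poisson(6 * 840)))
        ccg = crosscorrelogram(a, b, events, bin_s=0.02, max_lag=0.3,
                               n_draws=10, rng=rng)
        v = ccg.values
        assert v.std() / v.mean() < 0.25

    def test_empty_window_returns_none(self):
        ccg = crosscorrelogram(np.array([100.0]), np.array([]),
                               np.array([50.0]), rng=np.random.default_rng(0))
        assert ccg is None


class TestCCGSpectrumAndBalance:
    def _rhythmic_ccg(self, m=0.6, f=4.5):
        lags = np.arange(-1, 1.0001, 0.02)
        return Correlogram(lags, 1 + 0.5 * m * m * np.cos(2 * np.pi * f * lags),
                           0.02, kind="cross")

    def test_spectrum_peaks_in_band(self):
        freqs, power = ccg_spectrum(self._rhythmic_ccg())
        inband = (freqs >= 1.0)
        assert 3.5 <= freqs[inband][np.argmax(power[inband])] <= 5.5

    def test_band_contrast_flags_attenuation(self):
        rng = np.random.default_rng(8)
        n_pairs = 20
        fa, fb = [], []
        for _ in range(n_pairs):
            _, pa = ccg_spectrum(self._rhythmic_ccg(m=0.6))
            _, pb = ccg_spectrum(self._rhythmic_ccg(m=0.15))
            fa.append(pa + rng.normal(0, 0.01, pa.size))
            fb.append(pb + rng.normal(0, 0.01, pb.size))
        sig = ccg_band_contrast(np.array(fa), np.array(fb), n_perm=300,
                                rng=np.random.default_rng(9))
        freqs, _ = ccg_spectrum(self._rhythmic_ccg())
        band = (freqs >= 3.5) & (freqs <= 5.5)
        assert sig[band].any()

    def test_identical_conditions_unflagged(self):
        rng = np.random.default_rng(10)
        spec = np.abs(rng.normal(1, 0.1, size=(15, 26)))
        sig = ccg_band_contrast(spec, spec, n_perm=200,
                                rng=np.random.default_rng(11))
        assert not sig.any()

    def test_lead_lag_extremes_and_zero(self):
        lags = np.arange(-1, 1.0001, 0.1)
        sym = Correlogram(lags, np.abs(np.cos(lags)), 0.1, kind="cross")
        assert lead_lag_balance(sym) == pytest.approx(0.0, abs=1e-12)
        onesided = np.where(lags > 0, 1.0, 0.0)
        assert lead_lag_balance(Correlogram(lags, onesided, 0.1)) == 1.0
        assert lead_lag_balance(
            Correlogram(lags, onesided[::-1], 0.1)
        ) == -1.0


class TestAssemblyPhase:
    def _session_bins(self):
        from assemblage.core import Session, Trial

        trials = [
            Trial(k, "L", 4.0, "correct", 40.0 * k + 10, 40.0 * k + 11,
                  40.0 * k + 15, 40.0 * k + 15.5, 40.0 * k + 20)
            for k in range(6)
        ]
        n_bins = 6 * 800
        bin_times = 0.05 * np.arange(n_bins)
        return trials, bin_times

    def test_pre_sample_peak_is_sample_active(self):
        trials, bin_times = self._session_bins()
        act = np.zeros(bin_times.size)
        for tr in trials:
            act[(bin_times >= tr.t_sample - 1.0) & (bin_times < tr.t_sample)] = 2.0
        assert classify_assembly_phase(act, bin_times, trials) == "sample-active"

    def test_pre_choice_peak_is_choice_active(self):
        trials, bin_times = self._session_bins()
        act = np.zeros(bin_times.size)
        for tr in trials:
            act[(bin_times >= tr.t_choice - 1.0) & (bin_times < tr.t_choice)] = 2.0
        assert classify_assembly_phase(act, bin_times, trials) == "choice-active"

    def test_tie_breaks_to_sample(self):
        trials, bin_times = self._session_bins()
        act = np.ones(bin_times.size)
        assert classify_assembly_phase(act, bin_times, trials) == "sample-active"

    def test_no_significant_activation_is_none(self):
        trials, bin_times = self._session_bins()
        act = np.ones(bin_times.size)
        sig = np.zeros(bin_times.size, dtype=bool)
        assert classify_assembly_phase(act, bin_times, trials,
                                       sig_mask=sig) == "none"


class TestErrorActivationContrast:
    def test_identical_groups_no_flags(self):
        rng = np.random.default_rng(12)
        act = rng.normal(size=(30, 20))
        outcomes = np.array(["correct"] * 24 + ["error"] * 6)
        sig = error_activation_contrast(act, outcomes, n_perm=300,
                                        rng=np.random.default_rng(13))
        assert sig.sum() <= 1

    def test_planted_attenuation_flagged(self):
        rng = np.random.default_rng(14)
        act = rng.normal(size=(40, 20))
        outcomes = np.array(["correct"] * 30 + ["error"] * 10)
        act[30:, 12:16] -= 3.0  # strong drop on error trials at bins 12-15
        sig = error_activation_contrast(act, outcomes, n_perm=500,
                                        rng=np.random.default_rng(15))
        assert sig[12:16].all()
        assert sig[:10].sum() == 0

    def test_all_one_outcome_returns_empty_mask(self):
        act = np.random.default_rng(0).normal(size=(10, 5))
        sig = error_activation_contrast(act, np.array(["correct"] * 10))
        assert not sig.any()


class TestThetaRatio:
    def test_theta_locked_unit_ratio_above_one(self):
        from assemblage.rhythm import theta_to_low_ratio
        from scipy.signal import butter, filtfilt, hilbert

        rng = np.random.default_rng(21)
        fs = 250.0
        t = np.arange(0, 400, 1 / fs)
        lfp = (np.cos(2 * np.pi * 9.0 * t)
               + 0.8 * np.cos(2 * np.pi * 4.5 * t)
               + 0.2 * rng.standard_normal(t.size))

        def phase(band):
            b, a = butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)], "band")
            return np.angle(hilbert(filtfilt(b, a, lfp)))

        # strong theta locking, weak 4-5 Hz locking
        lam = 4.0 * np.exp(1.5 * np.cos(phase((8, 12)))
                           + 0.4 * np.cos(phase((3.5, 5.5))))
        lam *= 4.0 / lam.mean()
        counts = rng.poisson(lam / fs)
        spikes = np.repeat(t, counts) + rng.random(int(counts.sum())) / fs
        ratio = theta_to_low_ratio(np.sort(spikes), lfp, fs)
        assert np.isfinite(ratio) and ratio > 1.0
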