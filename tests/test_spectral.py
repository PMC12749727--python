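"""Spectral timescale estimation: Welch PSD, Lorentz/knee fit, decay fits."""

import numpy as np
import pytest
from scipy import stats

from hiertime import (
    SpectralConfig,
    estimate_timescales,
    fit_aperiodic,
    fit_exp_decay,
    synth_timeseries,
    welch_psd,
)

CAL_CFG = SpectralConfig(window_s=4.0, fit_range_hz=(0.25, 80.0))


class TestWelch:
    def test_white_noise_is_flat_and_parseval_holds(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(120_000)
        freqs, psd = welch_psd(x, 1000.0)
        power = np.trapezoid(psd, freqs)
        assert power == pytest.approx(x.var(), rel=0.10)
        low = psd[(freqs > 10) & (freqs < 100)].mean()
        high = psd[(freqs > 300) & (freqs < 490)].mean()
        assert low == pytest.approx(high, rel=0.1)

    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(30_000) / 1000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs, psd = welch_psd(x, 1000.0)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0, abs=0.5)

    def test_identical_channels_average_to_single_channel_psd(self):
        x = synth_timeseries([100.0], duration=10.0, fs=500.0, seed=1)
        f1, p1 = welch_psd(x[0], 500.0)
        f2, p2 = welch_psd(np.vstack([x[0], x[0]]), 500.0)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            welch_psd(np.zeros(500), 1000.0)


class TestAperiodicFit:
    def test_exact_lorentzian_recovered_to_high_precision(self):
        f = np.arange(0.5, 80.01, 0.25)
        fit = fit_aperiodic(f, 1.0 / (1.0 + f**2))
        assert fit.A == pytest.approx(1.0, abs=1e-3)
        assert fit.k == pytest.approx(1.0, abs=1e-3)
        assert fit.chi == pytest.approx(2.0, abs=1e-3)
        assert fit.f_knee == pytest.approx(1.0, abs=1e-3)
        assert fit.tau == pytest.approx(1 / (2 * np.pi), abs=1e-3)

    def test_tau_is_derived_from_knee_not_stored(self):
        f = np.arange(0.5, 80.01, 0.5)
        fit = fit_aperiodic(f, 2.0 / (4.0 + f**2))
        assert fit.tau == 1.0 / (2 * np.pi * fit.k ** (1 / fit.chi))

    def test_scale_equivariance(self):
        f = np.arange(0.5, 80.01, 0.25)
        rng = np.random.default_rng(3)
        psd = (1.0 / (2.5 + f**2.1)) * np.exp(rng.normal(0, 0.05, f.size))
        a = fit_aperiodic(f, psd)
        b = fit_aperiodic(f, 7.3 * psd)
        assert b.A == pytest.approx(7.3 * a.A, rel=1e-6)
        assert b.k == pytest.approx(a.k, rel=1e-6)
        assert b.chi == pytest.approx(a.chi, rel=1e-6)

    def test_ou_timescale_recovered_within_ten_percent(self):
        taus = []
        for seed in range(5):
            x = synth_timeseries([100.0], duration=60.0, fs=1000.0, seed=seed)
            freqs, psd = welch_psd(x, 1000.0, CAL_CFG)
            fit = fit_aperiodic(freqs, psd, CAL_CFG)
            assert 1.8 <= fit.chi <= 2.2
            taus.append(fit.tau * 1000)
        assert np.median(taus) == pytest.approx(100.0, rel=0.10)

    def test_oscillatory_peak_does_not_corrupt_timescale(self):
        taus = []
        for seed in range(5):
            x = synth_timeseries([100.0], duration=60.0, fs=1000.0,
                                 peaks=[(10.0, 0.2, 2.0)], seed=seed)
            freqs, psd = welch_psd(x, 1000.0, CAL_CFG)
            fit = fit_aperiodic(freqs, psd, CAL_CFG)
            taus.append(fit.tau * 1000)
        assert np.median(taus) == pytest.approx(100.0, rel=0.10)

    def test_knee_outside_fit_range_flagged_undefined(self):
        f = np.arange(0.5, 80.01, 0.25)
        # pure power law: fitted k collapses to the lower bound -> knee
        # far below the fit range
        fit = fit_aperiodic(f, 1.0 / f**2)
        assert not fit.knee_defined

    def test_nonpositive_psd_rejected(self):
        f = np.arange(0.5, 10.01, 0.5)
        with pytest.raises(ValueError, match="positive"):
            fit_aperiodic(f, np.zeros_like(f))


class TestEstimateTimescales:
    def test_tau_ladder_rank_order_recovered(self):
        truth = [25.0, 50.0, 100.0, 200.0, 400.0]
        est = []
        for seed in range(3):
            x = synth_timeseries(truth, duration=60.0, fs=1000.0, seed=seed)
            df = estimate_timescales(x, 1000.0, [f"a{i}" for i in range(5)], CAL_CFG)
            est.append(df["tau_ms"].to_numpy())
        med = np.median(est, axis=0)
        assert np.all(np.diff(med) > 0)  # perfect rank order
        assert stats.spearmanr(med, truth).statistic > 0.999
        np.testing.assert_allclose(med, truth, rtol=0.15)

    def test_single_channel_equals_composition(self):
        x = synth_timeseries([80.0], duration=30.0, fs=1000.0, seed=4)
        df = estimate_timescales(x, 1000.0, ["only"], CAL_CFG)
        freqs, psd = welch_psd(x, 1000.0, CAL_CFG)
        fit = fit_aperiodic(freqs, psd, CAL_CFG)
        assert df.loc[0, "tau_ms"] == pytest.approx(fit.tau * 1000, abs=1e-9)
        assert df.loc[0, "chi"] == pytest.approx(fit.chi, abs=1e-12)
        assert df.loc[0, "n_channels"] == 1

    def test_channels_sharing_an_area_are_averaged(self):
        x = synth_timeseries([60.0, 60.0, 150.0], duration=30.0, fs=1000.0, seed=5)
        df = estimate_timescales(x, 1000.0, ["A", "A", "B"], CAL_CFG)
        assert list(df["area"]) == ["A", "B"]
        assert list(df["n_channels"]) == [2, 1]

    def test_incomplete_channel_map_rejected(self):
        x = synth_timeseries([60.0, 80.0], duration=30.0, fs=1000.0, seed=6)
        with pytest.raises(ValueError, match="cover"):
            estimate_timescales(x, 1000.0, ["A"], CAL_CFG)


class TestExpDecay:
    def test_exact_exponential_recovered_exactly(self):
        t = np.arange(0, 300.0, 1.0)
        fit = fit_exp_decay(2.0 * np.exp(-t / 50.0), t)
        assert fit.a == pytest.approx(2.0, abs=1e-9)
        assert fit.tau_tilde == pytest.approx(50.0, abs=1e-7)

    def test_noisy_decay_recovered_within_five_percent(self):
        t = np.arange(0, 300.0, 1.0)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 2.0 * np.exp(-t / 50.0) + rng.normal(0, 0.02, t.size)
            fit = fit_exp_decay(y, t, window=(t[np.argmax(y)], 250.0))
            errs.append(abs(fit.tau_tilde - 50.0) / 50.0)
        assert np.median(errs) < 0.05

    def test_constant_trace_rejected(self):
        t = np.arange(0, 100.0, 1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_exp_decay(np.full_like(t, 3.0), t)

    def test_window_before_peak_rejected(self):
        t = np.arange(0, 100.0, 1.0)
        y = np.exp(-((t - 50) ** 2) / 100.0)
        with pytest.raises(ValueError, match="maximum"):
            fit_exp_decay(y, t, window=(10.0, 90.0))
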