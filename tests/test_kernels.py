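"""Neural-activity kernels, interaction model, M1 -> visual cross-correlation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.special import expit

from decidecode._rng import substream
from decidecode.kernels import (
    _residualize_on_contrast,
    correlate_kernels,
    crosscorr_choice_feedback,
    frequency_resolved_kernels,
    group_crosscorr,
    highres_kernel,
    interaction_logreg,
    leakage_reference,
    neural_kernel,
)
from decidecode.neural import NeuralGenParams, default_frequency_grid, generate_power_tensor
from decidecode.spectral import GAMMA_BAND, LOW_FREQUENCY_BAND, hemi_average, lateralize
from decidecode.trials import SAMPLE_COLUMNS, generate_trial_table


def _band_tensor(values_by_sample, trials, freq=10.0):
    """Build a (trial, freq, time) tensor whose power at each sample's
    190-ms latency equals the given (trial, 10) array."""
    n = values_by_sample.shape[0]
    times = np.arange(10) * 0.1 + 0.19
    return xr.DataArray(
        values_by_sample[:, None, :], dims=("trial", "freq", "time"),
        coords={"trial": np.arange(n), "freq": [freq], "time": times},
        attrs={"units": "pct_change"})


def _make_trials(rng, n, choice=None):
    c = rng.normal(0.5, 0.1, size=(n, 10))
    t = pd.DataFrame(c, columns=SAMPLE_COLUMNS)
    t["stimulus_category"] = np.where(rng.random(n) < 0.5, "stronger", "weaker")
    if choice is None:
        choice = rng.random(n) < 0.5
    t["choice"] = np.where(choice, "stronger", "weaker")
    return t


class TestResidualization:
    def test_matches_closed_form_ols_on_six_trials(self, rng):
        t = _make_trials(rng, 6)
        values = rng.normal(size=(6, 10))
        resid = _residualize_on_contrast(values, t)
        for i in range(10):
            c = t[SAMPLE_COLUMNS[i]].to_numpy()
            X = np.column_stack([np.ones(6), c])
            beta, *_ = np.linalg.lstsq(X, values[:, i], rcond=None)
            np.testing.assert_allclose(resid[:, i], values[:, i] - X @ beta, atol=1e-12)

    def test_idempotent(self, rng):
        t = _make_trials(rng, 100)
        values = rng.normal(size=(100, 10))
        once = _residualize_on_contrast(values, t)
        twice = _residualize_on_contrast(once, t)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_stimulus_driven_channel_nulls_residual_kernel(self, rng):
        """Power = f(contrast) + noise: overall kernel > 0.5 early, residual at chance."""
        n = 4000
        w = np.exp(-0.3 * np.arange(10))
        c = rng.normal(0.5, 0.1, size=(n, 10))
        dv = (c - 0.5) @ w + rng.normal(0, 0.1, n)
        t = pd.DataFrame(c, columns=SAMPLE_COLUMNS)
        t["stimulus_category"] = np.where(c.mean(axis=1) > 0.5, "stronger", "weaker")
        t["choice"] = np.where(dv > 0, "stronger", "weaker")
        power = 3.0 * c + rng.normal(0, 0.5, (n, 10))  # stimulus-driven only
        tensor = _band_tensor(power, t, freq=55.0)
        overall = neural_kernel(tensor, t, GAMMA_BAND, "overall")
        residual = neural_kernel(tensor, t, GAMMA_BAND, "residual")
        assert np.nanmean(overall[:3]) > 0.53
        np.testing.assert_allclose(residual, 0.5, atol=0.03)
        # overall dominates residual early in the trial
        assert np.nanmean(overall[:5] - residual[:5]) > 0.01

    def test_endogenous_channel_unchanged_by_residualization(self, rng):
        """Power = choice signal independent of contrast: residual == overall."""
        n = 4000
        t = _make_trials(rng, n)
        s = np.where(t["choice"] == "stronger", 1.0, -1.0)
        power = 0.5 * s[:, None] * np.linspace(0.2, 1.0, 10)[None, :]
        power = power + rng.normal(0, 1.0, (n, 10))
        tensor = _band_tensor(power, t)
        overall = neural_kernel(tensor, t, LOW_FREQUENCY_BAND, "overall")
        residual = neural_kernel(tensor, t, LOW_FREQUENCY_BAND, "residual")
        np.testing.assert_allclose(residual, overall, atol=0.02)
        assert np.nanmean(overall[5:]) > 0.55


def test_frequency_resolved_kernels_localize_bands(small_tensor, observer_trials):
    """Collapsed kernels are positive in gamma and low bins, slopes dissociate."""
    v1 = hemi_average(small_tensor.sel(roi="V1"))
    ds = frequency_resolved_kernels(v1, observer_trials)
    freqs = ds["freq"].values
    low = freqs <= 20
    gamma = (freqs >= 40) & (freqs <= 75)
    silent = (freqs > 75) | ((freqs > 20) & (freqs < 40))
    assert ds["kernel_mean"].values[low].mean() > 0.005
    assert ds["kernel_mean"].values[gamma].mean() > 0.005
    assert abs(ds["kernel_mean"].values[silent].mean()) < 0.01
    # late-rising feedback: positive slope at 10 Hz; decaying drive: negative in gamma
    assert ds["kernel_slope"].sel(freq=10.0).item() > 0
    assert ds["kernel_slope"].values[gamma].mean() < 0


class TestCorrelateKernels:
    def test_identical_series(self, rng):
        k = rng.random(10)
        assert correlate_kernels(k, k) == pytest.approx(1.0)

    def test_reversed_monotone_series(self):
        k = np.linspace(0.4, 0.6, 10)
        assert correlate_kernels(k, k[::-1]) == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        assert np.isnan(correlate_kernels(np.full(10, 0.5), np.linspace(0, 1, 10)))

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            correlate_kernels([0.5, np.nan, np.nan, 0.6] + [np.nan] * 6,
                              [0.5, np.nan, np.nan, 0.6] + [np.nan] * 6)


class TestInteractionModel:
    def test_recovers_generating_coefficients(self, rng):
        n = 20000
        a = rng.normal(size=(n, 2))
        g = rng.normal(size=(n, 2))
        beta = np.array([0.5, 0.2, 0.8, 0.4, 0.1, -0.5])  # a1 a2 g1 g2 ag1 ag2
        eta = np.column_stack([a, g, a * g]) @ beta
        y = rng.random(n) < expit(eta)
        t = pd.DataFrame({"choice": np.where(y, "stronger", "weaker")})
        low = np.repeat(a, 5, axis=1)
        gam = np.repeat(g, 5, axis=1)
        fit = interaction_logreg(t, low, gam)
        np.testing.assert_allclose(fit.coefficients[1:], beta, atol=0.06)
        assert fit.asymmetry["interaction"] == pytest.approx(
            beta[5] - beta[4], abs=0.1)

    def test_no_interaction_gives_null_beta3(self, rng):
        n = 20000
        a = rng.normal(size=(n, 2))
        g = rng.normal(size=(n, 2))
        y = rng.random(n) < expit(0.7 * a.sum(axis=1) + 0.7 * g.sum(axis=1))
        t = pd.DataFrame({"choice": np.where(y, "stronger", "weaker")})
        fit = interaction_logreg(t, np.repeat(a, 5, axis=1), np.repeat(g, 5, axis=1))
        np.testing.assert_allclose(fit.coefficients[5:], 0.0, atol=0.05)

    def test_symmetric_halves_have_zero_expected_asymmetry(self, rng):
        n = 20000
        a = rng.normal(size=(n, 2))
        g = rng.normal(size=(n, 2))
        y = rng.random(n) < expit(0.6 * (a.sum(axis=1) + g.sum(axis=1)))
        t = pd.DataFrame({"choice": np.where(y, "stronger", "weaker")})
        fit = interaction_logreg(t, np.repeat(a, 5, axis=1), np.repeat(g, 5, axis=1))
        assert abs(fit.asymmetry["low_frequency"]) < 0.06
        assert abs(fit.asymmetry["gamma"]) < 0.06


class TestHighresKernel:
    def test_null_is_flat_at_chance(self, rng):
        n = 2000
        t = _make_trials(rng, n)
        times = np.linspace(0, 1.0, 11)
        power = xr.DataArray(
            rng.normal(size=(n, 1, 11)), dims=("trial", "freq", "time"),
            coords={"trial": np.arange(n), "freq": [10.0], "time": times})
        _, k = highres_kernel(power, t, LOW_FREQUENCY_BAND)
        np.testing.assert_allclose(k, 0.5, atol=0.04)

    def test_injected_late_signal_raises_late_kernel(self, rng):
        n = 2000
        t = _make_trials(rng, n)
        s = np.where(t["choice"] == "stronger", 1.0, -1.0)
        times = np.linspace(0, 1.0, 11)
        sig = np.clip((times - 0.5) / 0.5, 0, 1)
        power = rng.normal(size=(n, 1, 11)) + s[:, None, None] * sig[None, None, :]
        power = xr.DataArray(
            power, dims=("trial", "freq", "time"),
            coords={"trial": np.arange(n), "freq": [10.0], "time": times})
        _, k = highres_kernel(power, t, LOW_FREQUENCY_BAND)
        assert np.all(k[:5] < k[8:].min() + 0.02)
        assert k[-1] > 0.7


class TestCrossCorrelation:
    def test_exact_copy_peaks_at_zero_with_unit_r(self, rng):
        times = np.arange(0, 1.0, 1 / 60)
        curve = 0.5 + 0.2 * np.cumsum(rng.random(times.size)) / times.size
        lags = np.arange(-6, 7) / 60
        r = crosscorr_choice_feedback(times, curve, times, curve, lags)
        res = group_crosscorr(r, lags)
        assert res.peak_lag == 0.0
        assert res.group_r[6] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k_shift", [-3, 2, 5])
    def test_shifted_copy_recovers_shift_exactly(self, rng, k_shift):
        dt = 1 / 60
        times = np.arange(-0.25, 1.35, dt)
        base = np.sin(np.linspace(0, 5, times.size)) + 0.1 * rng.random(times.size)
        # delay the kernel copy by k_shift bins: positive lag = base (M1) leads
        shifted = np.roll(base, k_shift)
        lags = np.arange(-8, 9) * dt
        sel = (times >= 0) & (times <= 0.8)
        r = crosscorr_choice_feedback(times[sel], base[sel], times, shifted, lags)
        res = group_crosscorr(r, lags)
        assert res.peak_lag == pytest.approx(k_shift * dt, abs=1e-12)

    def test_out_of_support_lags_marked_missing(self):
        times = np.arange(0, 0.9, 1 / 60)
        curve = np.sin(np.linspace(0, 4, times.size))
        lags = np.array([-5.0, 0.0])
        r = crosscorr_choice_feedback(times, curve, times[36:40], curve[36:40], lags)
        assert np.isnan(r[0])        # shifted window misses the kernel support
        assert np.isfinite(r[1])     # zero lag overlaps (truncated) support

    def test_leakage_reference_null_for_independent_series(self, rng):
        times = np.arange(0, 0.8, 1 / 60)
        refs = [leakage_reference(times, rng.normal(size=times.size),
                                  times, rng.normal(size=times.size))
                for _ in range(200)]
        assert abs(np.mean(refs)) < 0.03


class TestGeneratorLagRecovery:
    """Bias of the full recovery chain across configured feedback delays."""

    @pytest.mark.parametrize("lag", [0.05, 0.1, 0.2])
    def test_peak_lag_bias_below_one_bin(self, lag):
        params = NeuralGenParams(feedback_lag=lag,
                                 frequency_grid=default_frequency_grid(coarse=True))
        from decidecode.spectral import baseline_normalize

        lags = np.arange(-12, 13) / 60
        rng_t = substream(33, "trials")
        rng_n = substream(33, "neural")
        recovered = []
        for _cohort in range(2):
            rows = []
            for _s in range(10):
                t = generate_trial_table(1, 700, rng=rng_t).iloc[100:].reset_index(drop=True)
                pt = baseline_normalize(generate_power_tensor(t, params, rng=rng_n))
                hand = t.loc[t["choice"] == "stronger", "response_hand"].iloc[0]
                m1 = lateralize(pt.sel(roi="M1-hand"), hand)
                mt, mk = highres_kernel(m1, t, LOW_FREQUENCY_BAND)
                msel = (mt >= 0) & (mt <= 0.8 + 1e-9)
                v1 = hemi_average(pt.sel(roi="V1"))
                kt, kv = highres_kernel(v1, t, LOW_FREQUENCY_BAND)
                rows.append(crosscorr_choice_feedback(mt[msel], mk[msel], kt, kv, lags))
            recovered.append(group_crosscorr(np.array(rows), lags).peak_lag)
        bias = np.mean(recovered) - lag
        assert abs(bias) <= 1 / 60 + 1e-9


def test_leakage_reference_large_when_signals_share_source(small_tensor, observer_trials):
    """M1 decoder features and the M1 lateralized kernel share the motor signal."""
    hand = observer_trials.loc[observer_trials["choice"] == "stronger",
                               "response_hand"].iloc[0]
    m1 = lateralize(small_tensor.sel(roi="M1-hand"), hand)
    mt, mk = highres_kernel(m1, observer_trials, LOW_FREQUENCY_BAND)
    msel = (mt >= 0) & (mt <= 0.8 + 1e-9)
    # scalar stand-in for the decoder time course: the same kernel statistic
    ref = leakage_reference(mt[msel], mk[msel], mt, mk)
    assert ref == pytest.approx(1.0, abs=1e-9)  # self-pairing upper bound
    shuffled = observer_trials.copy()
    shuffled["choice"] = np.random.default_rng(0).permutation(
        shuffled["choice"].to_numpy())
    _, mk_null = highres_kernel(m1, shuffled, LOW_FREQUENCY_BAND)
    ref_null = leakage_reference(mt[msel], mk[msel], mt, mk_null)
    assert abs(ref_null) < 0.45
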