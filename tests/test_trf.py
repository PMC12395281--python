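import numpy as np
import pytest
from scipy import signal as sp_signal

from seltrack.tracking import LagSpec
from seltrack.trf import (
    COMPONENT_WINDOWS_MS,
    TRFEstimate,
    component_amplitudes,
    fit_trf,
    group_trfs,
    normalize_trf,
    permutation_null,
    quantile_bins,
    significant_components,
)

LAGS = LagSpec(400.0)


def make_trial(kernel, T, noise, rng):
    env = rng.standard_normal(T)
    eeg = sp_signal.fftconvolve(kernel, env[None, :], axes=1)[:, :T]
    eeg += noise * rng.standard_normal(eeg.shape)
    return env, eeg


def smooth_kernel(n_ch, rng, scale=1.0):
    lags = LAGS.lags_ms
    k = np.zeros((n_ch, LAGS.n_lags))
    for ch in range(n_ch):
        k[ch] = scale * (
            np.exp(-0.5 * ((lags - 60) / 20) ** 2)
            - 0.7 * np.exp(-0.5 * ((lags - 150) / 30) ** 2) * (1 + 0.2 * rng.random())
        )
    return k


class TestFitTrf:
    def test_kernel_recovery(self):
        rng = np.random.default_rng(0)
        k_true = smooth_kernel(4, rng)
        trials = [make_trial(k_true, 2000, 0.5, rng) for _ in range(4)]
        est = fit_trf([e for e, _ in trials], [x for _, x in trials])
        for ch in range(4):
            r = np.corrcoef(est.kernel[ch], k_true[ch])[0, 1]
            assert r >= 0.9

    def test_strong_shrinkage_kills_kernel(self):
        rng = np.random.default_rng(1)
        env, eeg = make_trial(smooth_kernel(2, rng), 1500, 0.5, rng)
        est = fit_trf(env, eeg, lam=1e9)
        assert np.max(np.abs(est.kernel)) < 1e-4

    def test_white_noise_eeg_predicts_nothing(self):
        rng = np.random.default_rng(2)
        envs = [rng.standard_normal(2500) for _ in range(3)]
        eegs = [rng.standard_normal((2, 2500)) for _ in range(3)]
        est = fit_trf(envs, eegs)
        assert abs(est.heldout_corr) < 0.05

    def test_lambda_selected_by_heldout_correlation(self):
        rng = np.random.default_rng(3)
        k_true = smooth_kernel(2, rng)
        trials = [make_trial(k_true, 1500, 2.0, rng) for _ in range(4)]
        est = fit_trf([e for e, _ in trials], [x for _, x in trials],
                      lambda_grid=(1e-3, 1.0, 1e3))
        assert est.lam in (1e-3, 1.0, 1e3)
        assert est.heldout_corr > 0.2

    def test_empty_lambda_grid_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            fit_trf(np.zeros(100), np.zeros((2, 100)), lambda_grid=())


class TestPermutationNull:
    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        envs = [rng.standard_normal(800) for _ in range(4)]
        eegs = [rng.standard_normal((2, 800)) for _ in range(4)]
        a = permutation_null(envs, eegs, n_perm=20, seed=7)
        b = permutation_null(envs, eegs, n_perm=20, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="mismatched pairing"):
            permutation_null([np.zeros(500)], [np.zeros((2, 500))], n_perm=10)

    def test_circular_scheme_available(self):
        rng = np.random.default_rng(5)
        envs = [rng.standard_normal(800) for _ in range(3)]
        eegs = [rng.standard_normal((2, 800)) for _ in range(3)]
        null = permutation_null(envs, eegs, n_perm=10, seed=1, scheme="circular")
        assert null.shape == (10, LAGS.n_lags)

    def test_injected_component_detected_group_level(self):
        """A strong 50-ms response is flagged by the paired subject-level test."""
        rng = np.random.default_rng(6)
        lags = LAGS.lags_ms
        k = np.tile(5.0 * np.exp(-0.5 * ((lags - 50) / 10) ** 2), (2, 1))
        obs, null_means = [], []
        for _ in range(6):  # subjects
            envs, eegs = zip(*[make_trial(k, 1000, 1.0, rng) for _ in range(4)])
            est = fit_trf(list(envs), list(eegs), lam=1.0)
            null = permutation_null(envs, eegs, n_perm=60,
                                    seed=int(rng.integers(2**31)), lam=1.0)
            obs.append(est.channel_average())
            null_means.append(null.mean(axis=0))
        mask = significant_components(np.array(obs), np.array(null_means), alpha=0.05)
        assert mask.mask[np.argmin(np.abs(lags - 50))]

    def test_single_subject_empirical_p_floor(self):
        """With few permutations the empirical p cannot beat 1/(n_perm+1)."""
        rng = np.random.default_rng(60)
        null = rng.standard_normal((50, 8))
        obs = null.mean(axis=0) + 100.0  # far outside the null
        mask = significant_components(obs[None, :], null, alpha=0.05)
        assert np.allclose(mask.p_corrected, min(8 / 51, 1.0))


class TestSignificance:
    def test_null_equal_observed_gives_empty_mask(self):
        rng = np.random.default_rng(7)
        null = rng.standard_normal((200, 10))
        obs = null.mean(axis=0)
        mask = significant_components(obs[None, :], null, alpha=0.05)
        assert not mask.mask.any()

    def test_single_extreme_lag_flagged_alone(self):
        rng = np.random.default_rng(8)
        null = rng.standard_normal((500, 12))
        obs = null.mean(axis=0).copy()
        obs[4] += 10 * null[:, 4].std()
        mask = significant_components(obs[None, :], null, alpha=0.05)
        assert mask.mask[4]
        assert mask.mask.sum() == 1

    def test_alpha_one_flags_everything(self):
        rng = np.random.default_rng(9)
        null = rng.standard_normal((100, 6))
        mask = significant_components(null.mean(axis=0)[None, :], null, alpha=1.0)
        assert mask.mask.all()

    def test_zero_variance_null_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            significant_components(np.zeros((1, 5)), np.zeros((50, 5)))


class TestComponents:
    def test_delta_kernel_isolated_to_its_window(self):
        kernel = np.zeros((4, LAGS.n_lags))
        kernel[1, np.argmin(np.abs(LAGS.lags_ms - 50))] = 1.0
        amps = component_amplitudes(TRFEstimate(kernel, lam=1.0))
        assert amps["TRF_50"][1] == 1.0
        assert np.all(amps["TRF_50"][[0, 2, 3]] == 0)
        assert np.all(amps["TRF_100"] == 0) and np.all(amps["TRF_200"] == 0)

    def test_sign_pattern_recovered(self):
        lags = LAGS.lags_ms
        kernel = np.tile(
            -np.exp(-0.5 * ((lags - 120) / 15) ** 2)
            + np.exp(-0.5 * ((lags - 220) / 15) ** 2),
            (2, 1),
        )
        amps = component_amplitudes(TRFEstimate(kernel, lam=1.0))
        assert np.all(amps["TRF_100"] < 0) and np.all(amps["TRF_200"] > 0)

    def test_zero_kernel_zero_amplitudes(self):
        amps = component_amplitudes(TRFEstimate(np.zeros((3, LAGS.n_lags)), lam=1.0))
        assert all(np.all(v == 0) for v in amps.values())

    def test_window_outside_lags_rejected(self):
        est = TRFEstimate(np.zeros((2, LAGS.n_lags)), lam=1.0)
        with pytest.raises(ValueError, match="outside"):
            component_amplitudes(est, {"late": (500.0, 600.0)})


class TestGroupTrfs:
    def test_single_bin_equals_grand_average(self):
        rng = np.random.default_rng(10)
        k = smooth_kernel(2, rng)
        trials = [make_trial(k, 1200, 1.0, rng) for _ in range(6)]
        factor = np.arange(6.0)
        out = group_trfs(trials, factor, bins=[(0.0, 6.0)], lam=1.0)
        grand = fit_trf([e for e, _ in trials], [x for _, x in trials], lam=1.0)
        np.testing.assert_allclose(
            out["bin0"].kernel, normalize_trf(grand.kernel), atol=1e-10
        )

    def test_amplitude_scales_with_factor_bin(self):
        """Trials whose kernel amplitude doubles land in the high bin with
        a larger (pre-normalization) fitted TRF peak."""
        rng = np.random.default_rng(11)
        base = smooth_kernel(2, rng)
        trials, factor = [], []
        for j in range(8):
            scale = 0.5 if j < 4 else 2.0
            trials.append(make_trial(scale * base, 1200, 0.5, rng))
            factor.append(0.2 if j < 4 else 0.8)
        out = group_trfs(trials, factor, bins=[(0.0, 0.5), (0.5, 1.0)],
                         bin_labels=["low", "high"], lam=1.0)
        # normalized kernels: compare via the raw fit instead
        low = fit_trf([e for e, _ in trials[:4]], [x for _, x in trials[:4]], lam=1.0)
        high = fit_trf([e for e, _ in trials[4:]], [x for _, x in trials[4:]], lam=1.0)
        assert np.max(np.abs(high.kernel)) > np.max(np.abs(low.kernel))
        assert set(out) == {"low", "high"}

    def test_empty_bin_warns_and_drops(self):
        rng = np.random.default_rng(12)
        trials = [make_trial(smooth_kernel(2, rng), 1000, 1.0, rng) for _ in range(3)]
        with pytest.warns(UserWarning, match="empty"):
            out = group_trfs(trials, [0.1, 0.2, 0.3], bins=[(0.0, 0.5), (0.5, 1.0)],
                             lam=1.0)
        assert list(out) == ["bin0"]

    def test_quantile_bins_split_evenly(self):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal(91)
        bins = quantile_bins(vals, 3)
        counts = []
        for j, (lo, hi) in enumerate(bins):
            last = j == len(bins) - 1
            sel = (vals >= lo) & ((vals <= hi) if last else (vals < hi))
            counts.append(sel.sum())
        assert max(counts) - min(counts) <= 1

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(14)
        k = rng.standard_normal((3, 10))
        np.testing.assert_allclose(normalize_trf(normalize_trf(k)), normalize_trf(k))
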