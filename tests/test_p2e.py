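"""Cycle pairing, DCT truncation and the coefficient-regression configurations."""

import numpy as np
import pytest

from ppgvitals.benchmarks import detrended_pair
from ppgvitals.p2e import (
    CyclePair,
    P2eSpec,
    PulseToEcgModel,
    coefficient_sweep,
    dct_truncate,
    fit_p2e,
    idct_reconstruct,
    pair_cycles,
    reconstruct_ecg,
    split_cycles,
)
from ppgvitals.siggen import SimConfig


class TestDct:
    def test_full_length_round_trip(self, rng):
        x = rng.normal(size=300)
        back = idct_reconstruct(dct_truncate(x, 300), 300)
        assert np.max(np.abs(x - back)) < 1e-9

    def test_constant_cycle_is_pure_dc(self):
        x = np.full(120, 2.5)
        coeffs = dct_truncate(x, 120)
        assert np.max(np.abs(coeffs[1:])) < 1e-9
        back = idct_reconstruct(dct_truncate(x, 1), 120)
        assert np.max(np.abs(back - 2.5)) < 1e-12

    def test_smooth_ecg_cycle_compacts_into_150_coefficients(self, small_cycle_bank):
        cyc = small_cycle_bank[0].ecg
        rec = idct_reconstruct(dct_truncate(cyc, 150), 300)
        rel = np.linalg.norm(cyc - rec) / np.linalg.norm(cyc)
        assert rel < 0.02

    def test_truncation_error_non_increasing_in_kept_coefficients(self, small_cycle_bank):
        cyc = small_cycle_bank[1].ecg
        errs = [
            np.linalg.norm(cyc - idct_reconstruct(dct_truncate(cyc, k), 300))
            for k in (10, 50, 150, 300)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_out_of_range_kept_rejected(self):
        with pytest.raises(ValueError):
            dct_truncate(np.zeros(100), 0)
        with pytest.raises(ValueError):
            dct_truncate(np.zeros(100), 101)


class TestPairCycles:
    def test_lag_estimate_exact_in_noise_free_case(self):
        cfg = SimConfig(hr=70, fs=125, duration=30, ptt_lag=200, noise_sd=0.0, drift_amp=0.0)
        ppg_d, ecg_d, p_peaks, r_peaks, rec = detrended_pair(cfg, use_truth_peaks=True)
        from ppgvitals.p2e import estimate_lag

        assert estimate_lag(rec.r_peaks, rec.pulse_peaks, cfg.fs) == 25

    def test_beat_count_for_one_minute_at_60_bpm(self):
        cfg = SimConfig(hr=60, fs=125, duration=60, noise_sd=0.0, drift_amp=0.0)
        ppg_d, ecg_d, p_peaks, r_peaks, _ = detrended_pair(cfg, use_truth_peaks=True)
        pairs = pair_cycles(ppg_d, ecg_d, p_peaks, r_peaks)
        assert abs(len(pairs) - 59) <= 1

    def test_noise_free_periodic_cycles_identical_after_resampling(self):
        from ppgvitals.siggen import generate_recording

        cfg = SimConfig(hr=72, fs=125, duration=30, noise_sd=0.0, drift_amp=0.0)
        rec = generate_recording(cfg)
        cycles = split_cycles(rec.ppg.channel("green"), rec.pulse_peaks)
        stack = np.stack([c.ppg for c in cycles[1:-1]])
        assert np.max(np.abs(stack - stack[0])) < 1e-6

    def test_unmatched_peaks_beyond_tolerance_rejected(self):
        cfg = SimConfig(hr=72, fs=125, duration=30, noise_sd=0.0, drift_amp=0.0)
        ppg_d, ecg_d, p_peaks, r_peaks, _ = detrended_pair(cfg, use_truth_peaks=True)
        from ppgvitals.core import PeakSet

        shifted = PeakSet(r_peaks.indices[::2])  # half the beats missing
        with pytest.raises(ValueError, match="could not be matched"):
            pair_cycles(ppg_d, ecg_d, p_peaks, shifted, unmatched_tol=0.1)


def _planted_linear_pairs(rng, n=2000, L_P=150, L_E=150, sigma=0.01):
    W = rng.normal(size=(L_P, L_E)) / np.sqrt(L_P)
    X = rng.normal(size=(n, L_P))
    Y = X @ W + sigma * rng.normal(size=(n, L_E))
    return X, Y, W


class TestRidge:
    def test_matches_normal_equations_oracle(self, rng):
        from ppgvitals.p2e import _RidgeMap

        X = rng.normal(size=(60, 8))
        Y = rng.normal(size=(60, 5))
        lam = 0.5
        m = _RidgeMap(lam)
        m.fit(X, Y)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        W = np.linalg.inv(Xc.T @ Xc + lam * np.eye(8)) @ Xc.T @ Yc
        assert np.max(np.abs(m.W - W)) < 1e-8

    def test_cross_checked_against_sklearn(self, rng):
        from sklearn.linear_model import Ridge

        from ppgvitals.p2e import _RidgeMap

        X = rng.normal(size=(80, 10))
        Y = rng.normal(size=(80, 4))
        m = _RidgeMap(2.0)
        m.fit(X, Y)
        sk = Ridge(alpha=2.0).fit(X, Y)
        np.testing.assert_allclose(m.predict(X), sk.predict(X), atol=1e-8)

    def test_planted_map_recovery(self, rng):
        from ppgvitals.p2e import _RidgeMap

        X, Y, W = _planted_linear_pairs(rng)
        m = _RidgeMap(1e-3)
        m.fit(X, Y)
        rel = np.linalg.norm(m.W - W) / np.linalg.norm(W)
        assert rel < 0.05

    def test_huge_penalty_shrinks_weights_to_zero(self, rng):
        from ppgvitals.p2e import _RidgeMap

        X, Y, _ = _planted_linear_pairs(rng, n=200, L_P=20, L_E=10)
        free = _RidgeMap(1e-8)
        free.fit(X, Y)
        shrunk = _RidgeMap(1e9)
        shrunk.fit(X, Y)
        assert np.linalg.norm(shrunk.W) < 1e-3 * np.linalg.norm(free.W)

    def test_singular_design_without_penalty_suggests_lambda(self, rng):
        from ppgvitals.p2e import _RidgeMap

        X = np.tile(rng.normal(size=(1, 6)), (30, 1))  # rank-1 design
        Y = rng.normal(size=(30, 3))
        m = _RidgeMap(0.0)
        with pytest.raises(np.linalg.LinAlgError, match="ridge_lambda"):
            m.fit(X, Y)

    def test_ridge_closed_form_equals_gradient_descent(self, rng):
        # independent oracle: plain full-batch gradient descent on the
        # centered least-squares objective, no penalty on either side
        from ppgvitals.p2e import _RidgeMap

        X = rng.normal(size=(50, 5))
        Y = rng.normal(size=(50, 3))
        m = _RidgeMap(0.0)
        m.fit(X, Y)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        W = np.zeros((5, 3))
        lr = 1.0 / np.linalg.eigvalsh(Xc.T @ Xc).max()
        for _ in range(20000):
            W -= lr * (Xc.T @ (Xc @ W - Yc))
        assert np.max(np.abs(W - m.W)) < 1e-4


class TestFfnn:
    def test_seed_reproducible_and_history_records_best(self, small_cycle_bank):
        spec = P2eSpec(config="ffnn", max_epochs=10, patience=0)
        a = fit_p2e(small_cycle_bank, spec, seed=1)
        b = fit_p2e(small_cycle_bank, spec, seed=1)
        assert a.history.val_loss == b.history.val_loss
        assert a.history.best_epoch >= 0

    def test_parameter_count_near_printed_budget(self, small_cycle_bank):
        spec = P2eSpec(config="ffnn", max_epochs=1, patience=0)
        res = fit_p2e(small_cycle_bank, spec, seed=0)
        n = res.mapper.n_parameters()
        assert abs(n - 83700) / 83700 < 0.02  # ~84K parameters

    def test_identity_target_is_learnable(self, small_cycle_bank):
        # train with the ECG cycle replaced by the PPG cycle itself
        pairs = [CyclePair(p.ppg, p.ppg.copy(), p.start, p.end) for p in small_cycle_bank]
        res = fit_p2e(pairs, P2eSpec(config="ridge", ridge_lambda=1e-8), seed=0)
        maes = [np.mean(np.abs(res.predict_cycle(p.ppg) - p.ppg)) for p in pairs]
        assert np.mean(maes) < 0.01

    def test_too_few_pairs_rejected(self, small_cycle_bank):
        with pytest.raises(ValueError, match="at least 10"):
            PulseToEcgModel(small_cycle_bank[:5])


class TestReconstruct:
    def test_output_covers_input_cycles(self, small_cycle_bank):
        cfg = SimConfig(hr=75, fs=125, duration=20, noise_sd=0.02, seed=31)
        ppg_d, _, p_peaks, _, _ = detrended_pair(cfg)
        res = fit_p2e(small_cycle_bank, P2eSpec(config="ridge"), seed=0)
        ecg, offset = reconstruct_ecg(ppg_d, p_peaks, res)
        cycles = split_cycles(ppg_d, p_peaks)
        assert ecg.n_samples == cycles[-1].end - cycles[0].start
        assert offset == cycles[0].start

    def test_no_detectable_cycles_rejected(self, small_cycle_bank):
        from ppgvitals.core import PeakSet, Signal

        res = fit_p2e(small_cycle_bank, P2eSpec(config="ridge"), seed=0)
        with pytest.raises(ValueError, match="cycles"):
            reconstruct_ecg(Signal(np.zeros(100), 125), PeakSet(np.array([50])), res)


class TestCoefficientSweep:
    def test_more_coefficients_never_much_worse(self):
        # nested-model property holds on noise-free cycles
        from ppgvitals.benchmarks import make_cycle_bank

        bank = make_cycle_bank(200, seed=17, noise_sd=0.0, use_truth_peaks=True)
        table = coefficient_sweep(bank, [10, 150, 300], seed=0)
        assert np.all(np.isfinite(table[["mae", "p_corr", "l_dir"]].to_numpy()))
        by = table.set_index("L_P")
        assert by.loc[300, "p_corr"] >= by.loc[10, "p_corr"] - 0.02
        # beyond ~150 coefficients the gain is marginal
        assert by.loc[300, "p_corr"] - by.loc[150, "p_corr"] < 0.05

    def test_empty_grid_rejected(self, small_cycle_bank):
        with pytest.raises(ValueError, match="empty"):
            coefficient_sweep(small_cycle_bank, [])
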