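"""Spectral front-ends, architecture contracts and training protocols."""

import numpy as np
import pandas as pd
import pytest

from ppgvitals.nn import Tensor, mae_loss
from ppgvitals.preprocess import SegmentDataset
from ppgvitals.vitals_models import (
    FrontendSpec,
    ModelSpec,
    TrainSpec,
    VitalsRegressor,
    build_model,
    frontend_apply,
    lesso_evaluate,
    lesso_split,
    load_checkpoint,
    save_checkpoint,
    train_vitals,
    window_size_search,
)


class TestFrontend:
    def test_dct_of_constant_segment_is_pure_dc(self):
        L, c = 64, 3.0
        out = frontend_apply(np.full((1, L, 1), c), FrontendSpec(mode="dct"))
        assert out[0, 0, 0] == pytest.approx(c * np.sqrt(L))
        assert np.max(np.abs(out[0, 1:, 0])) < 1e-9

    def test_dct_skip_of_zero_is_zero(self):
        out = frontend_apply(np.zeros((2, 32, 1)), FrontendSpec(mode="dct", add_skip=True))
        assert np.all(out == 0)

    def test_stft_tone_peaks_at_tone_frequency(self):
        fs, f0 = 125.0, 1.25
        t = np.arange(int(10 * fs)) / fs
        seg = np.sin(2 * np.pi * f0 * t)[None, :, None]
        mag, freqs = frontend_apply(seg, FrontendSpec(mode="stft"), fs=fs)
        df = freqs[1] - freqs[0]
        for frame in range(mag.shape[1]):
            peak = freqs[np.argmax(mag[0, frame])]
            assert abs(peak - f0) <= df + 1e-9

    def test_skip_requires_length_preserving_mode(self):
        with pytest.raises(ValueError, match="length-preserving"):
            FrontendSpec(mode="stft", add_skip=True)


class TestBuildModel:
    def test_joint_configuration_has_three_outputs(self):
        model = build_model(ModelSpec(name="mt_net", n_outputs=3), input_len=200)
        out = model(Tensor(np.random.default_rng(0).normal(size=(4, 200, 1))))
        assert out.shape == (4, 3)

    @pytest.mark.parametrize("name", ["cnn_net", "mt_net", "vit_net"])
    def test_forward_pass_finite(self, name):
        model = build_model(ModelSpec(name=name, n_outputs=1), input_len=300, n_channels=3)
        out = model(Tensor(np.random.default_rng(1).normal(size=(5, 300, 3))))
        assert out.shape == (5, 1)
        assert np.all(np.isfinite(out.data))

    def test_doubling_filters_increases_parameter_count(self):
        small = build_model(ModelSpec(conv_filters=(8, 16)), input_len=250)
        big = build_model(ModelSpec(conv_filters=(16, 32)), input_len=250)
        assert big.n_parameters() > small.n_parameters()


def _toy_dataset(rng, n=40, L=64, n_vitals=1, subjects=None):
    segs = rng.normal(size=(n, L, 1))
    labels = rng.uniform(60, 100, size=(n, n_vitals))
    names = tuple(["hr", "spo2", "rr"][:n_vitals])
    return SegmentDataset(segs, labels, w_s=float(L), fs=1.0, vital_names=names, subjects=subjects)


class TestTraining:
    def test_zero_labels_zero_head_give_zero_initial_loss(self, rng):
        ds = _toy_dataset(rng)
        ds.labels[:] = 0.0
        model = build_model(ModelSpec(name="mt_net", n_outputs=1), input_len=64)
        head = model.net.layers[-1]
        head.weight.data[:] = 0.0
        head.bias.data[:] = 0.0
        model.eval()
        pred = model(Tensor(ds.segments))
        assert float(mae_loss(pred, ds.labels).data) == 0.0

    def test_batch_loss_equals_hand_computed_mae(self, rng):
        # four-sample batch, no regularization: L = (1/|B|) sum |y - yhat|
        pred = Tensor(rng.normal(size=(4, 1)))
        y = rng.normal(size=(4, 1))
        hand = np.mean([abs(y[i, 0] - pred.data[i, 0]) for i in range(4)])
        assert float(mae_loss(pred, y).data) == pytest.approx(hand, abs=1e-6)

    def test_loss_scale_equivariance(self, rng):
        pred = Tensor(rng.normal(size=(8, 2)))
        y = rng.normal(size=(8, 2))
        base = float(mae_loss(pred, y).data)
        scaled = float(mae_loss(pred * (-3.0), -3.0 * y).data)
        assert scaled == pytest.approx(3.0 * base)

    def test_train_vitals_smoke_and_history(self, rng):
        ds = _toy_dataset(rng, n=60)
        res = train_vitals(
            ds,
            ModelSpec(name="mt_net", n_outputs=1, conv_filters=(4,)),
            TrainSpec(max_epochs=5, patience=0, batch_size=16),
            seed=0,
        )
        assert len(res.history.epochs) == 5
        assert np.all(np.isfinite(res.history.train_loss))
        pred = res.predict(ds.segments)
        assert pred.shape == (60, 1)

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            VitalsRegressor(
                _toy_dataset(rng, n=0), ModelSpec(n_outputs=1)
            )

    def test_checkpoint_round_trip(self, tmp_path, rng):
        ds = _toy_dataset(rng, n=30)
        res = train_vitals(
            ds,
            ModelSpec(name="mt_net", n_outputs=1, conv_filters=(4,)),
            TrainSpec(max_epochs=2, patience=0),
            seed=0,
        )
        path = tmp_path / "model.npz"
        save_checkpoint(res, path)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.predict(ds.segments), res.predict(ds.segments))


class TestLesso:
    def test_split_is_subject_disjoint(self, rng):
        subs = np.repeat(np.arange(20), 3)
        ds = _toy_dataset(rng, n=60, subjects=subs)
        train, held = lesso_split(ds, k=5, seed=1)
        assert len(held) == 5
        assert len(set(train.subjects)) == 15
        held_ids = {h.subjects[0] for h in held}
        assert held_ids.isdisjoint(set(train.subjects))

    def test_same_seed_same_split(self, rng):
        subs = np.repeat(np.arange(10), 4)
        ds = _toy_dataset(rng, n=40, subjects=subs)
        _, h1 = lesso_split(ds, k=3, seed=9)
        _, h2 = lesso_split(ds, k=3, seed=9)
        assert [h.subjects[0] for h in h1] == [h.subjects[0] for h in h2]

    def test_mu_sigma_match_independent_loop(self, rng):
        subs = np.repeat(np.arange(8), 5)
        ds = _toy_dataset(rng, n=40, subjects=subs)
        train, held = lesso_split(ds, k=3, seed=2)
        res = train_vitals(
            train,
            ModelSpec(name="mt_net", n_outputs=1, conv_filters=(4,)),
            TrainSpec(max_epochs=2, patience=0, test_fraction=0.0),
            seed=0,
        )
        table = lesso_evaluate(res, held)
        maes = []
        for h in held:
            pred = res.predict(h.segments)[:, 0]
            maes.append(np.mean(np.abs(pred - h.labels[:, 0])))
        assert table["mu"].iloc[0] == pytest.approx(np.mean(maes))
        assert table["sigma"].iloc[0] == pytest.approx(np.std(maes))

    def test_missing_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="provenance"):
            lesso_split(_toy_dataset(rng), k=2)


class TestWindowSearch:
    def test_grid_rows_finite_and_sae_matches_definition(self, rng):
        def segmenter(w_s):
            return _toy_dataset(rng, n=30, L=int(w_s))

        spec = ModelSpec(name="mt_net", n_outputs=1, conv_filters=(4,))
        tr = TrainSpec(max_epochs=2, patience=0, test_fraction=0.0)
        table = window_size_search(segmenter, [16.0, 32.0], spec, tr, seed=0)
        assert len(table) == 2
        assert np.all(np.isfinite(table[["mae", "sae"]].to_numpy()))
        assert table["sae"].min() >= 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            window_size_search(lambda w: None, [], ModelSpec(n_outputs=1))
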