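"""Caption templating, encoder architecture and contrastive retrieval."""

import numpy as np
import pytest

from ppgvitals.nn import Tensor
from ppgvitals.siggen import gen_caption_corpus
from ppgvitals.vitals_clip import (
    ConvSpec,
    PpgEncoder,
    PpgEncoderSpec,
    VitalsClip,
    make_caption,
    parse_caption,
)


class TestCaptions:
    def test_three_vitals_one_line_with_units(self):
        cap = make_caption({"hr": 72, "spo2": 97, "rr": 16})
        assert "\n" not in cap.text
        assert "72 beats/min" in cap.text
        assert "97 %" in cap.text
        assert "16 breaths/min" in cap.text

    def test_bp_fields_parse_but_are_ignored_for_vitals(self):
        cap = make_caption({"hr": 80, "spo2": 95, "rr": 14, "sbp": 120, "dbp": 80})
        full = parse_caption(cap.text, ("hr", "spo2", "rr", "sbp", "dbp"))
        assert full["sbp"] == 120 and full["dbp"] == 80
        core = parse_caption(cap.text)
        assert set(core) == {"hr", "spo2", "rr"}

    def test_round_trip_for_100_random_label_sets(self, rng):
        for _ in range(100):
            labels = {
                "hr": round(float(rng.uniform(40, 180)), 1),
                "spo2": round(float(rng.uniform(70, 100)), 1),
                "rr": round(float(rng.uniform(6, 40)), 1),
            }
            cap = make_caption(labels)
            assert parse_caption(cap.text) == labels

    def test_no_vitals_rejected(self):
        with pytest.raises(ValueError):
            make_caption({})


class TestPpgEncoder:
    def test_default_spec_flattens_to_9728(self):
        spec = PpgEncoderSpec(input_len=1250)
        assert spec.flatten_size() == 9728

    def test_conv_arithmetic_valid_convolution(self):
        # L_out = L_in - K_s + 1 at stride 1: 1250 -> 1241 with kernel 10
        spec = PpgEncoderSpec(input_len=1250)
        rng = np.random.default_rng(0)
        enc = PpgEncoder(spec, rng)
        x = Tensor(rng.normal(size=(1, 1250, 1)))
        first_conv = enc.conv.layers[0]
        assert first_conv(x).shape == (1, 1241, 8)
        flat = enc.conv(x)
        assert flat.shape == (1, 9728)

    def test_identical_segments_identical_unit_embeddings(self):
        spec = PpgEncoderSpec(input_len=200)
        enc = PpgEncoder(spec, np.random.default_rng(0))
        enc.eval()
        seg = np.sin(np.linspace(0, 20, 200))
        a = enc(Tensor(seg[None, :, None])).data
        b = enc(Tensor(seg[None, :, None])).data
        np.testing.assert_array_equal(a, b)
        assert np.linalg.norm(a[0]) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_conv_spec_rejected(self):
        with pytest.raises(ValueError):
            ConvSpec(0, 3)


@pytest.fixture(scope="module")
def tiny_corpus():
    return gen_caption_corpus(150, seed=8, w_s=4, fs=25)


class TestPretraining:
    def test_single_pair_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="at least 2"):
            VitalsClip(tiny_corpus[:1])

    def test_untrained_retrieval_is_near_chance(self, tiny_corpus):
        model = VitalsClip(tiny_corpus[:50])
        res = model.fit(epochs=0, seed=0)  # initial weights, no updates
        segs = np.stack([r["segment"] for r in tiny_corpus[:50]])
        emb = res.encode_ppg(segs)
        top1 = np.argmax(emb @ res.bank_embeddings.T, axis=1)
        accuracy = np.mean(top1 == np.arange(50))
        assert accuracy < 0.2  # chance is 1/50

    def test_training_aligns_matched_pairs(self, tiny_corpus):
        res = VitalsClip(tiny_corpus).fit(epochs=8, batch_size=64, seed=0, val_fraction=0.1)
        segs = np.stack([r["segment"] for r in tiny_corpus])
        emb = res.encode_ppg(segs)
        sims = emb @ res.bank_embeddings.T
        diag = np.mean(np.diag(sims))
        off = (sims.sum() - np.trace(sims)) / (sims.size - len(sims))
        assert diag > off

    def test_seeded_rerun_reproduces_loss(self, tiny_corpus):
        a = VitalsClip(tiny_corpus[:60]).fit(epochs=2, batch_size=32, seed=4)
        b = VitalsClip(tiny_corpus[:60]).fit(epochs=2, batch_size=32, seed=4)
        assert abs(a.history["loss"].iloc[-1] - b.history["loss"].iloc[-1]) < 1e-6


class TestQuerying:
    @pytest.fixture()
    def planted(self, tiny_corpus):
        res = VitalsClip(tiny_corpus[:10]).fit(epochs=1, batch_size=8, seed=0)
        return res

    def test_identical_embedding_ranks_first(self, planted):
        n = 5
        bank = np.eye(256)[:n]  # orthogonal caption embeddings
        planted.bank_embeddings = bank
        planted.bank_captions = [
            make_caption({"hr": 60 + i}).text for i in range(n)
        ]
        planted.encode_ppg = lambda seg: bank[[2]]
        pred, captions = planted.query(np.zeros(100), k=1)
        assert captions[0] == planted.bank_captions[2]
        assert pred["hr"] == 62

    def test_top3_mean_of_parsed_hr(self, planted):
        q = np.zeros(256)
        q[0] = 1.0
        bank = np.stack([q * s for s in (0.9, 0.8, 0.7, -0.5)])
        planted.bank_embeddings = bank
        planted.bank_captions = [
            make_caption({"hr": h}).text for h in (70, 72, 74, 200)
        ]
        planted.encode_ppg = lambda seg: q[None]
        pred, captions = planted.query(np.zeros(100), k=3)
        assert pred["hr"] == pytest.approx(72.0)
        assert len(captions) == 3

    def test_bp_only_captions_warn_for_missing_vitals(self, planted):
        q = np.eye(256)[0]
        planted.bank_embeddings = q[None]
        planted.bank_captions = [make_caption({"sbp": 120, "dbp": 80}).text]
        planted.encode_ppg = lambda seg: q[None]
        with pytest.warns(UserWarning, match="no caption"):
            pred, _ = planted.query(np.zeros(100), k=1)
        assert pred == {}

    def test_ranking_invariant_to_bank_order_and_scale(self, planted, rng):
        emb = rng.normal(size=(6, 256))
        emb /= np.linalg.norm(emb, axis=1, keepdims=True)
        caps = [make_caption({"hr": 60 + 2 * i}).text for i in range(6)]
        q = emb[3] + 0.01 * rng.normal(size=256)
        planted.encode_ppg = lambda seg: q[None]

        planted.bank_embeddings = emb
        planted.bank_captions = caps
        pred1, caps1 = planted.query(np.zeros(100), k=2)

        order = rng.permutation(6)
        planted.bank_embeddings = 5.0 * emb[order]  # global positive scaling
        planted.bank_captions = [caps[i] for i in order]
        pred2, caps2 = planted.query(np.zeros(100), k=2)
        assert caps1 == caps2
        assert pred1 == pred2
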