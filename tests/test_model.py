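"""Masking, composite loss, encoder/decoder contracts, training."""

import numpy as np
import pytest

from emomusic import model as md
from emomusic.discretize import DiscreteSequence
from emomusic.tokens import TokenSequence


def _token_pair(rng, L=15, d=32, eeg_vocab=4, audio_vocab=8, mapping=None):
    eids = rng.integers(0, eeg_vocab, L)
    aids = mapping(eids) if mapping else rng.integers(0, audio_vocab, L)
    e = TokenSequence(rng.normal(scale=0.1, size=(L, d)),
                      DiscreteSequence(eids, np.arange(L)), "eeg")
    a = TokenSequence(rng.normal(scale=0.1, size=(L, d)),
                      DiscreteSequence(aids, np.arange(L)), "audio")
    return e, a


def _small_cfg(**kw):
    base = dict(d_layers=2, n_heads=4, d_model=32, d_ff=64, epochs=5,
                batch_size=4, seed=0)
    base.update(kw)
    return md.ModelConfig(**base)


class TestMasking:
    def test_zero_ratio_identity(self, rng):
        _, a = _token_pair(rng)
        batch = md.apply_mask(a, 0.0, seed=1)
        assert batch.mask_set.size == 0
        from emomusic.tokens import positional_encoding
        pe = positional_encoding(len(a), a.d_model).matrix
        np.testing.assert_allclose(batch.tokens, a.content + pe)

    def test_full_ratio_masks_everything(self, rng):
        _, a = _token_pair(rng)
        batch = md.apply_mask(a, 1.0, seed=1)
        assert batch.mask_set.size == len(a)

    def test_count_and_reproducibility(self):
        m1 = md.choose_mask(100, 0.15, seed=7)
        m2 = md.choose_mask(100, 0.15, seed=7)
        assert m1.size == 15
        np.testing.assert_array_equal(m1, m2)
        assert md.choose_mask(100, 0.15, seed=8).tolist() != m1.tolist()

    def test_reference_ids_retained(self, rng):
        _, a = _token_pair(rng)
        batch = md.apply_mask(a, 0.5, seed=3)
        np.testing.assert_array_equal(batch.reference_ids, a.ids.ids)

    def test_invalid_ratio_rejected(self, rng):
        _, a = _token_pair(rng)
        with pytest.raises(md.ModelConfigError):
            md.apply_mask(a, 1.5, seed=0)


class TestLosses:
    def _uniform_output(self, L, V):
        probs = np.full((L, V), 1.0 / V)
        return md.DecoderOutput(np.zeros((L, V)), np.zeros((L, V)), probs,
                                probs.argmax(axis=1))

    def test_uniform_predictor_gives_log_vocab(self, rng):
        L, V = 100, 32
        out = self._uniform_output(L, V)
        batch = md.MaskedBatch(np.zeros((L, 2)), np.arange(0, L, 2),
                               rng.integers(0, V, L))
        assert md.masked_loss(out, batch) == pytest.approx(np.log(32), abs=1e-9)
        assert md.unmasked_loss(out, batch) == pytest.approx(np.log(32), abs=1e-9)

    def test_perfect_predictor_gives_zero(self):
        L, V = 20, 8
        refs = np.arange(L) % V
        probs = np.zeros((L, V))
        probs[np.arange(L), refs] = 1.0
        out = md.DecoderOutput(probs, probs, probs, probs.argmax(axis=1))
        batch = md.MaskedBatch(np.zeros((L, 2)), np.arange(L // 2), refs)
        assert md.masked_loss(out, batch) == pytest.approx(0.0, abs=1e-9)
        assert md.unmasked_loss(out, batch) == pytest.approx(0.0, abs=1e-9)

    def test_loss_decreases_as_mass_moves_to_reference(self):
        V = 8
        refs = np.zeros(4, dtype=int)
        losses = []
        for p_ref in (0.2, 0.5, 0.9):
            probs = np.full((4, V), (1 - p_ref) / (V - 1))
            probs[:, 0] = p_ref
            out = md.DecoderOutput(probs, probs, probs, probs.argmax(axis=1))
            batch = md.MaskedBatch(np.zeros((4, 2)), np.arange(4), refs)
            losses.append(md.masked_loss(out, batch))
        assert losses[0] > losses[1] > losses[2]

    def test_empty_mask_rejected(self, rng):
        out = self._uniform_output(10, 4)
        batch = md.MaskedBatch(np.zeros((10, 2)), np.array([], dtype=int),
                               rng.integers(0, 4, 10))
        with pytest.raises(md.UndefinedLossError):
            md.masked_loss(out, batch)
        full = md.MaskedBatch(np.zeros((10, 2)), np.arange(10),
                              rng.integers(0, 4, 10))
        with pytest.raises(md.UndefinedLossError):
            md.unmasked_loss(out, full)

    def test_composite_limits_and_affine(self):
        assert md.composite_loss(2.0, 4.0, 0.0).total == pytest.approx(2.0)
        assert md.composite_loss(2.0, 4.0, 1.0).total == pytest.approx(4.0)
        assert md.composite_loss(2.0, 4.0, 0.5).total == pytest.approx(3.0)
        with pytest.raises(md.ModelConfigError):
            md.composite_loss(1.0, 1.0, 1.2)

    def test_composite_identity_random_alphas(self, rng):
        for _ in range(20):
            flm, flu = rng.uniform(0, 5, 2)
            alpha = rng.uniform()
            lv = md.composite_loss(flm, flu, alpha)
            assert lv.total == pytest.approx((1 - alpha) * flm + alpha * flu,
                                             abs=1e-6)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(md.ModelConfigError):
            md.ModelConfig(d_model=65)
        with pytest.raises(md.ModelConfigError):
            md.ModelConfig(d_model=64, n_heads=5)
        with pytest.raises(md.ModelConfigError):
            md.ModelConfig(alpha=1.5)
        with pytest.raises(md.ModelConfigError):
            md.ModelConfig(backbone="gru")


class TestNetworkContracts:
    def test_encoder_shape_and_attention_rows(self, rng):
        cfg = _small_cfg()
        net = md._Network(cfg, 4, 8)
        content = rng.normal(size=(2, 9, 32))
        ids = rng.integers(0, 4, (2, 9))
        out = net.encode(content, ids)
        assert out.data.shape == (2, 9, 32)
        attn = net.enc_layers[0].attn.last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)

    def test_standalone_encode_checks_dimension(self, rng):
        e, _ = _token_pair(rng, d=16)
        with pytest.raises(md.ModelConfigError):
            md.encode(e, _small_cfg(d_model=32))

    def test_decoder_probs_rows_sum_to_one(self, rng):
        cfg = _small_cfg()
        net = md._Network(cfg, 4, 8)
        content = rng.normal(size=(1, 7, 32))
        ids = rng.integers(0, 8, (1, 7))
        mask = np.zeros((1, 7), dtype=bool)
        mask[0, :3] = True
        mem = net.encode(rng.normal(size=(1, 7, 32)), rng.integers(0, 4, (1, 7)))
        logits = net.decode(content, ids, mask, mem)
        from emomusic._autodiff import softmax
        probs = softmax(logits).data[0]
        assert probs.shape == (7, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_zero_length_decode_rejected(self, rng):
        net = md._Network(_small_cfg(), 4, 8)
        with pytest.raises(ValueError):
            net.decode(np.zeros((1, 0, 32)), np.zeros((1, 0), dtype=int),
                       np.zeros((1, 0), dtype=bool),
                       net.encode(np.zeros((1, 3, 32)), np.zeros((1, 3), dtype=int)))

    def test_positional_encoding_breaks_permutation_equivariance(self, rng):
        """Permuting the input sequence does not just permute the output."""
        cfg = _small_cfg(aligned_memory=False)
        net = md._Network(cfg, 4, 8)
        content = rng.normal(size=(1, 5, 32))
        ids = rng.integers(0, 4, (1, 5))
        perm = np.array([4, 2, 0, 3, 1])
        out1 = net.encode(content, ids).data[0]
        out2 = net.encode(content[:, perm], ids[:, perm]).data[0]
        assert not np.allclose(out2, out1[perm], atol=1e-8)


class TestFit:
    def test_loss_decreases_on_learnable_mapping(self, rng):
        mapping = lambda eids: (2 * eids + 1) % 8
        pairs = [_token_pair(rng, mapping=mapping) for _ in range(8)]
        res = md.EEGMusicModel(pairs, 4, 8, _small_cfg(epochs=8)).fit()
        hist = res.loss_history
        assert hist.iloc[-1]["FL"] < hist.iloc[0]["FL"]

    def test_zero_learning_rate_freezes_loss(self, rng):
        pairs = [_token_pair(rng) for _ in range(4)]
        # mask_ratio=1 removes mask-draw variation, so with no updates the
        # recorded loss must be exactly constant
        res = md.EEGMusicModel(pairs, 4, 8,
                               _small_cfg(lr=0.0, epochs=4, mask_ratio=1.0)).fit()
        fl = res.loss_history["FLm"].to_numpy()
        np.testing.assert_allclose(fl, fl[0], atol=1e-12)

    def test_overfit_single_pair_memorizes(self, rng):
        pair = _token_pair(rng)
        cfg = _small_cfg(epochs=400, batch_size=1, mask_ratio=0.5)
        res = md.EEGMusicModel([pair], 4, 8, cfg).fit()
        hits = res.evaluate_pairs([pair], n_draws=6)
        assert hits.hits[1] == 1.0

    def test_seeded_fit_reproducible(self, rng):
        pairs = [_token_pair(rng) for _ in range(4)]
        r1 = md.EEGMusicModel(pairs, 4, 8, _small_cfg(epochs=3)).fit()
        r2 = md.EEGMusicModel(pairs, 4, 8, _small_cfg(epochs=3)).fit()
        np.testing.assert_array_equal(r1.loss_history["FL"], r2.loss_history["FL"])
        for p1, p2 in zip(r1.network.parameters(), r2.network.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_generate_is_deterministic_with_expected_length(self, rng):
        pairs = [_token_pair(rng) for _ in range(4)]
        res = md.EEGMusicModel(pairs, 4, 8, _small_cfg(epochs=2)).fit()
        out1 = res.generate(pairs[0][0])
        out2 = res.generate(pairs[0][0])
        assert len(out1) == len(pairs[0][0])
        np.testing.assert_array_equal(out1.ids, out2.ids)

    def test_summary_mentions_key_facts(self, rng):
        pairs = [_token_pair(rng) for _ in range(2)]
        res = md.EEGMusicModel(pairs, 4, 8, _small_cfg(epochs=1)).fit()
        text = res.summary()
        assert "transformer" in text
        assert "audio vocab" in text

    def test_mismatched_lengths_rejected(self, rng):
        p1 = _token_pair(rng, L=15)
        p2 = _token_pair(rng, L=10)
        with pytest.raises(ValueError):
            md.EEGMusicModel([p1, p2], 4, 8, _small_cfg())


class TestBackbones:
    @pytest.mark.parametrize("backbone", ["lstm", "cnn"])
    def test_alternative_backbones_train(self, rng, backbone):
        pairs = [_token_pair(rng) for _ in range(4)]
        cfg = _small_cfg(backbone=backbone, d_layers=1, epochs=3)
        res = md.EEGMusicModel(pairs, 4, 8, cfg).fit()
        assert np.isfinite(res.loss_history["FL"]).all()
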