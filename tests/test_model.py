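"""Encoder/decoder contracts and decoding-strategy oracles."""

import itertools

import numpy as np
import pytest

from rrg.model import ModelConfig, VEDModel
from rrg.text import BOS_ID, EOS_ID


@pytest.fixture(scope="module")
def feats(tiny_model, small_corpus):
    return tiny_model.encode_study(small_corpus.train[0].images)


class TestEncoder:
    def test_sequence_length_formula(self, small_vocab):
        cfg = ModelConfig(vocab_size=len(small_vocab), image_size=64,
                          patch_size=8, dim=16, enc_depth=1, enc_heads=2,
                          dec_layers=1, dec_heads=2)
        model = VEDModel(cfg, seed=0)
        img = np.zeros((64, 64))
        assert model.encode_study([img]).shape == (64, 16)  # (64/8)^2 patches

    def test_two_identical_views_concatenate(self, tiny_model):
        img = np.random.default_rng(0).uniform(0, 1, (64, 64))
        one = tiny_model.encode_study([img]).data
        two = tiny_model.encode_study([img, img]).data
        np.testing.assert_allclose(two, np.concatenate([one, one]), atol=1e-12)

    def test_view_permutation_equivariance(self, tiny_model):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, (64, 64)), rng.uniform(0, 1, (64, 64))
        ab = tiny_model.encode_study([a, b]).data
        ba = tiny_model.encode_study([b, a]).data
        t = ab.shape[0] // 2
        np.testing.assert_allclose(ba, np.concatenate([ab[t:], ab[:t]]),
                                   atol=1e-12)

    def test_too_many_views_rejected(self, tiny_model):
        img = np.zeros((64, 64))
        with pytest.raises(ValueError):
            tiny_model.encode_study([img] * 4)

    def test_wrong_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode_study([np.zeros((32, 32))])


class TestStepLogits:
    def test_normalization(self, tiny_model, feats):
        lp = tiny_model.step_logits([BOS_ID, 5, 6], feats)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-5)

    def test_causality_prefix_extension(self, tiny_model, feats, small_vocab):
        """Logits at position t agree whether computed from the length-t
        prefix or inside a longer teacher-forced pass."""
        seq = [BOS_ID, 4, 9, 12, 7, EOS_ID]
        full = tiny_model.teacher_forced_logprobs(np.asarray([seq]), feats).data[0]
        for t in range(1, len(seq)):
            step = tiny_model.step_logits(seq[:t], feats)
            np.testing.assert_allclose(step, full[t - 1], atol=1e-5)

    def test_visual_order_sensitivity(self, tiny_model, feats):
        """Decoder-side positional encoding of visual features: shuffling
        the feature sequence changes the prediction."""
        lp1 = tiny_model.step_logits([BOS_ID], feats)
        shuffled = feats.data[::-1].copy()
        from rrg._tensor import Tensor
        lp2 = tiny_model.step_logits([BOS_ID], Tensor(shuffled))
        assert np.abs(lp1 - lp2).max() > 1e-8

    def test_empty_prefix_rejected(self, tiny_model, feats):
        with pytest.raises(ValueError):
            tiny_model.step_logits([], feats)


class TestDecoding:
    def test_greedy_deterministic(self, tiny_model, feats):
        a = tiny_model.decode_greedy(feats)
        b = tiny_model.decode_greedy(feats)
        assert a.token_ids == b.token_ids
        assert a.token_logprobs == b.token_logprobs

    def test_greedy_matches_stepwise_argmax(self, tiny_model, feats):
        dec = tiny_model.decode_greedy(feats, max_len=8)
        ids = [BOS_ID]
        for expect in dec.token_ids[1:]:
            lp = tiny_model.step_logits(ids, feats).copy()
            lp[[0, 1]] = -np.inf  # PAD/BOS never emitted
            assert int(np.argmax(lp)) == expect
            ids.append(expect)

    def test_logprobs_nonpositive_and_sum(self, tiny_model, feats):
        dec = tiny_model.decode_beam(feats, beam_width=3)
        assert all(lp <= 0 for lp in dec.token_logprobs)
        assert dec.cumulative_logprob == pytest.approx(sum(dec.token_logprobs))

    def test_beam_width_one_equals_greedy(self, tiny_model, feats):
        g = tiny_model.decode_greedy(feats)
        b = tiny_model.decode_beam(feats, beam_width=1)
        assert g.token_ids == b.token_ids

    def test_beam_matches_exhaustive_search(self, small_vocab):
        """A beam wide enough to hold every prefix equals brute-force
        enumeration over all 4^3 emission paths (4 emittable tokens)."""
        cfg = ModelConfig(vocab_size=6, image_size=16, patch_size=8, dim=8,
                          enc_depth=1, enc_heads=1, dec_layers=1, dec_heads=1,
                          max_len=3, beam_width=16)
        model = VEDModel(cfg, seed=3)
        feats = model.encode_study([np.random.default_rng(0).uniform(0, 1, (16, 16))])
        emittable = [2, 3, 4, 5]  # everything except PAD/BOS

        def score(seq):
            total = 0.0
            ids = [BOS_ID]
            for tok in seq:
                total += float(model.step_logits(ids, feats)[tok])
                ids.append(tok)
            return total

        best_score = -np.inf
        # every emission: EOS may only terminate; length <= 3
        for length in (1, 2, 3):
            for seq in itertools.product(emittable, repeat=length):
                if EOS_ID in seq[:-1]:
                    continue
                if length < 3 and seq[-1] != EOS_ID:
                    continue
                best_score = max(best_score, score(seq))
        dec = model.decode_beam(feats, beam_width=16, max_len=3,
                                length_normalize=False)
        assert dec.cumulative_logprob == pytest.approx(best_score, abs=1e-9)

    def test_beam_dominates_greedy_unnormalized(self, tiny_model, feats):
        g = tiny_model.decode_greedy(feats)
        b = tiny_model.decode_beam(feats, beam_width=4, length_normalize=False)
        assert b.cumulative_logprob >= g.cumulative_logprob - 1e-9

    def test_sampling_deterministic_under_seed(self, tiny_model, feats):
        a = tiny_model.decode_beam_multinomial(feats, rng=np.random.default_rng(8))
        b = tiny_model.decode_beam_multinomial(feats, rng=np.random.default_rng(8))
        assert a.token_ids == b.token_ids

    def test_sampling_converges_to_beam_at_large_scale(self, tiny_model, feats):
        beam = tiny_model.decode_beam(feats, beam_width=4, length_normalize=False)
        sampled = tiny_model.decode_beam_multinomial(
            feats, beam_width=4, rng=np.random.default_rng(0), logit_scale=1e9)
        assert sampled.token_ids == beam.token_ids

    def test_width_one_sampling_frequencies(self):
        """First-token frequencies of width-1 sampling follow the model's
        next-token distribution (3-sigma binomial bounds, 10k draws)."""
        cfg = ModelConfig(vocab_size=5, image_size=16, patch_size=8, dim=8,
                          enc_depth=1, enc_heads=1, dec_layers=1, dec_heads=1,
                          max_len=2, beam_width=1)
        model = VEDModel(cfg, seed=1)
        feats = model.encode_study([np.zeros((16, 16))])
        lp = model.step_logits([BOS_ID], feats).copy()
        lp[[0, 1]] = -np.inf  # PAD/BOS are suppressed at decode time
        probs = np.exp(lp - np.log(np.exp(lp[2:]).sum()))
        rng = np.random.default_rng(123)
        n = 10_000
        counts = np.zeros(5)
        for _ in range(n):
            dec = model.decode_beam_multinomial(feats, beam_width=1, max_len=1,
                                                rng=rng)
            counts[dec.token_ids[1]] += 1
        assert counts[0] == 0 and counts[1] == 0
        for tok in range(2, 5):
            sigma = np.sqrt(n * probs[tok] * (1 - probs[tok]))
            assert abs(counts[tok] - n * probs[tok]) <= 3 * sigma + 1

    def test_rescoring_consistency(self, tiny_model, feats, rng):
        """Every strategy's recorded log-probs match teacher-forced
        re-scoring of the emitted sequence."""
        for dec in (tiny_model.decode_greedy(feats),
                    tiny_model.decode_beam(feats, beam_width=3),
                    tiny_model.decode_beam_multinomial(feats, rng=rng)):
            lp = tiny_model.teacher_forced_logprobs(
                np.asarray([dec.token_ids]), feats).data[0]
            rescored = [lp[t, tok] for t, tok in enumerate(dec.token_ids[1:])]
            assert np.abs(np.asarray(rescored)
                          - np.asarray(dec.token_logprobs)).max() < 1e-5


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_model, feats, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = VEDModel.load(path)
        a = tiny_model.decode_greedy(feats)
        b = loaded.decode_greedy(feats)
        assert a.token_ids == b.token_ids
        assert a.token_logprobs == b.token_logprobs

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, dec_layers=0)
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, max_len=1)
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, image_size=30, patch_size=16)
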