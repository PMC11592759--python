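"""Slice-sequence encoding, volume generation and reconstruction training."""

import numpy as np
import pytest

from tumorscope import (FeatureSequence, ReconTrainConfig, SliceImage,
                        VolumeGANSpec, encode_sequence, extract_features,
                        generate_volume, reconstruct, train_reconstruction,
                        volume_critic_loss)
from tumorscope.nn import LSTM, AdditiveAttention, Tensor
from tumorscope.reconstruction import (PlainCNNEncoder, TumorReconstructionModel,
                                       VGGStyleEncoder, VolumeCritic,
                                       VolumeGenerator, ellipsoid_tumor_sample)


@pytest.fixture(scope="module")
def samples():
    return [ellipsoid_tumor_sample(16, seed=s) for s in range(10)]


class TestFeatureExtraction:
    def test_one_vector_per_slice_in_order(self, samples, rng):
        enc = VGGStyleEncoder(rng, image_size=16)
        seq = extract_features(enc, samples[0].slices)
        assert len(seq) == len(samples[0].slices)
        assert seq.dim == enc.feature_dim

    def test_identical_slices_give_identical_vectors(self, rng):
        enc = VGGStyleEncoder(rng, image_size=16)
        s = SliceImage(np.random.default_rng(1).random((16, 16)))
        twin = SliceImage(s.pixels.copy(), slice_index=1)
        seq = extract_features(enc, [s, twin])
        assert np.allclose(seq.vectors[0], seq.vectors[1])

    def test_dimensionality_reduction_contract(self, rng):
        enc = VGGStyleEncoder(rng, image_size=16, feature_dim=32)
        assert enc.feature_dim < 16 * 16
        with pytest.raises(ValueError):
            VGGStyleEncoder(rng, image_size=16, feature_dim=256)

    def test_mixed_slice_sizes_rejected(self, rng):
        enc = VGGStyleEncoder(rng, image_size=16)
        a = SliceImage(np.zeros((16, 16)))
        b = SliceImage(np.zeros((8, 8)), slice_index=1)
        with pytest.raises(ValueError):
            extract_features(enc, [a, b])

    def test_empty_slice_list_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_features(VGGStyleEncoder(rng, image_size=16), [])


class TestSequenceEncoding:
    def test_single_element_gets_full_attention(self, rng):
        lstm = LSTM(4, 6, rng)
        att = AdditiveAttention(6, 4, rng)
        _, w = encode_sequence(lstm, att,
                               FeatureSequence(np.ones((1, 4)) * 0.3))
        assert w.shape == (1,)
        assert w[0] == pytest.approx(1.0)

    def test_weights_normalised_for_any_sequence(self, rng):
        lstm = LSTM(4, 6, rng)
        att = AdditiveAttention(6, 4, rng)
        for T in (2, 5, 9):
            seq = FeatureSequence(np.random.default_rng(T).random((T, 4)))
            _, w = encode_sequence(lstm, att, seq)
            assert w.min() >= 0.0
            assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_context_is_the_logged_linear_combination(self, rng):
        lstm = LSTM(3, 5, rng)
        att = AdditiveAttention(5, 4, rng)
        seq = FeatureSequence(np.random.default_rng(2).random((2, 3)))
        ctx, w = encode_sequence(lstm, att, seq)
        hidden = lstm(Tensor(seq.vectors)).data  # (2, 5)
        manual = w[0] * hidden[0] + w[1] * hidden[1]
        assert np.allclose(ctx, manual, atol=1e-10)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            encode_sequence(LSTM(3, 5, rng), AdditiveAttention(5, 4, rng),
                            FeatureSequence(np.empty((0, 3))))


class TestVolumeGeneration:
    def test_output_shape_and_range(self, rng):
        gen = VolumeGenerator(rng, context_dim=6, output_shape=(8, 8, 8))
        vol = generate_volume(gen, np.random.default_rng(0).random(6))
        assert vol.shape == (8, 8, 8)
        assert vol.voxels.min() >= 0.0 and vol.voxels.max() <= 1.0

    def test_same_context_gives_identical_volumes(self, rng):
        gen = VolumeGenerator(rng, context_dim=6, output_shape=(8, 8, 8))
        ctx = np.random.default_rng(1).random(6)
        v1 = generate_volume(gen, ctx)
        v2 = generate_volume(gen, ctx)
        assert np.array_equal(v1.voxels, v2.voxels)

    def test_dimension_mismatch_rejected(self, rng):
        gen = VolumeGenerator(rng, context_dim=6, output_shape=(8, 8, 8))
        with pytest.raises(ValueError):
            generate_volume(gen, np.zeros(7))

    def test_critic_loss_shares_em_form(self):
        assert volume_critic_loss([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert volume_critic_loss([0.1], [0.9]) == pytest.approx(-0.8)
        assert volume_critic_loss([3.0, 3.0], [3.0]) == 0.0

    def test_volume_critic_requires_dilation(self, rng):
        with pytest.raises(ValueError):
            VolumeCritic(rng, dilation_rates=(1,))


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self, samples):
        cfg = ReconTrainConfig(epochs=0, seed=3)
        res = train_reconstruction(samples, VolumeGANSpec(), cfg)
        rng = np.random.default_rng(3)
        fresh, *_ = TumorReconstructionModel(samples)._build(rng)
        for a, b in zip(res.encoder.parameters(), fresh.parameters()):
            assert np.array_equal(a.data, b.data)
        assert len(res.history) == 0

    def test_history_rows_equal_epochs(self, samples):
        cfg = ReconTrainConfig(epochs=3, seed=0)
        res = train_reconstruction(samples, VolumeGANSpec(), cfg)
        assert len(res.history) == 3
        assert list(res.history.columns) == ["epoch", "critic_loss",
                                             "val_hd", "val_ed"]

    def test_reconstruct_equals_manual_composition(self, samples):
        cfg = ReconTrainConfig(epochs=1, seed=1)
        res = train_reconstruction(samples[:4], VolumeGANSpec(), cfg)
        sample = samples[0]
        via_api = reconstruct(res, sample.slices)
        seq = extract_features(res.encoder, sample.slices)
        ctx, _ = encode_sequence(res.lstm, res.attention, seq)
        manual = generate_volume(res.generator, ctx, spacing=res.spacing)
        assert np.array_equal(via_api.voxels, manual.voxels)

    def test_reproducible_under_fixed_seed(self, samples):
        cfg = ReconTrainConfig(epochs=2, seed=4)
        h1 = train_reconstruction(samples[:4], VolumeGANSpec(), cfg).history
        h2 = train_reconstruction(samples[:4], VolumeGANSpec(), cfg).history
        assert h1.equals(h2)

    def test_plain_encoder_swap_keeps_contracts(self, samples):
        spec = VolumeGANSpec(encoder="plain")
        cfg = ReconTrainConfig(epochs=1, seed=0)
        res = train_reconstruction(samples[:4], spec, cfg)
        assert isinstance(res.encoder, PlainCNNEncoder)
        vol = res.reconstruct(samples[0].slices)
        assert vol.shape == spec.output_shape
        assert vol.voxels.min() >= 0.0 and vol.voxels.max() <= 1.0

    def test_unknown_encoder_rejected(self, samples):
        with pytest.raises(ValueError):
            train_reconstruction(samples[:2], VolumeGANSpec(encoder="resnet"),
                                 ReconTrainConfig(epochs=1))

    def test_empty_volume_sample_rejected(self):
        sample = ellipsoid_tumor_sample(16, seed=0)
        sample.volume.voxels[:] = 0.0
        with pytest.raises(ValueError):
            TumorReconstructionModel([sample])

    def test_voxel_count_recovery_on_held_out_cases(self, samples):
        # after toy training, the thresholded voxel count of reconstructed
        # held-out tumors is within a factor of two of truth for most cases
        hits, total = 0, 0
        for seed in range(3):
            model = TumorReconstructionModel(
                samples, VolumeGANSpec(),
                ReconTrainConfig(epochs=25, seed=seed))
            res = model.fit()
            for i in res.val_indices:
                pred = res.reconstruct(samples[i].slices)
                got = int(pred.binarize().sum())
                want = int(samples[i].volume.binarize().sum())
                total += 1
                if want / 2 <= got <= want * 2:
                    hits += 1
        assert hits / total >= 0.6
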