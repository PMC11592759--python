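"""Reward shaping, the policy-gradient update and segmentation training."""

import numpy as np
import pandas as pd
import pytest

from tumorscope import (MaskImage, PixelDecision, RewardConfig, SegTrainConfig,
                        SliceImage, average_reward, critic_loss,
                        masked_product, pixel_reward, policy_gradient_step,
                        segment, train_segmentation)
from tumorscope.nn import Module, Tensor
from tumorscope.segmentation import (DilatedCritic, LungSegmentationModel,
                                     UNetPolicy, reward_map)


class TinyLogisticPolicy(Module):
    """Two-parameter per-pixel policy: sigmoid(w * intensity + b)."""

    def __init__(self, w=0.8, b=-0.2):
        self.w = Tensor(np.array(w), requires_grad=True)
        self.b = Tensor(np.array(b), requires_grad=True)

    def forward(self, x):
        return (x * self.w + self.b).sigmoid()


class TestReward:
    @pytest.mark.parametrize("action,truth,lam,expected", [
        (1, 1, 0.4, 1.0),     # correct minority (lung)
        (0, 1, 0.4, -1.0),    # incorrect minority
        (0, 0, 0.4, 0.4),     # correct majority at the tuned optimum
        (1, 0, 0.4, -0.4),    # incorrect majority
        (0, 0, 0.9, 0.9),
        (1, 0, 0.05, -0.05),
    ])
    def test_four_branch_table(self, action, truth, lam, expected):
        d = PixelDecision(action=action, truth=truth)
        assert pixel_reward(d, RewardConfig(lam)) == expected

    def test_sign_flips_with_correctness_within_each_class(self):
        cfg = RewardConfig(0.3)
        for truth in (0, 1):
            r_ok = pixel_reward(PixelDecision(truth, truth), cfg)
            r_bad = pixel_reward(PixelDecision(1 - truth, truth), cfg)
            assert r_ok == -r_bad

    def test_reward_range_is_the_four_values(self):
        cfg = RewardConfig(0.4)
        values = {pixel_reward(PixelDecision(a, y), cfg)
                  for a in (0, 1) for y in (0, 1)}
        assert values == {1.0, -1.0, 0.4, -0.4}

    def test_lam_outside_open_interval_rejected(self):
        for lam in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                RewardConfig(lam)

    def test_non_binary_decision_rejected(self):
        with pytest.raises(ValueError):
            PixelDecision(action=2, truth=0)

    def test_average_reward_hand_enumeration(self):
        cfg = RewardConfig(0.5)
        decisions = [PixelDecision(1, 1), PixelDecision(1, 1),
                     PixelDecision(1, 0), PixelDecision(1, 0)]
        # (1 + 1 - 0.5 - 0.5) / 4
        assert average_reward(decisions, cfg) == pytest.approx(0.25)

    def test_average_reward_constant_branches(self):
        cfg = RewardConfig(0.4)
        all_min = [PixelDecision(1, 1)] * 5
        assert average_reward(all_min, cfg) == 1.0
        all_maj_bad = [PixelDecision(1, 0)] * 5
        assert average_reward(all_maj_bad, cfg) == pytest.approx(-0.4)

    def test_average_reward_empty_rejected(self):
        with pytest.raises(ValueError):
            average_reward([], RewardConfig(0.4))

    def test_reward_map_matches_scalar_function(self, rng):
        cfg = RewardConfig(0.7)
        actions = rng.integers(0, 2, size=(5, 5))
        truth = rng.integers(0, 2, size=(5, 5))
        grid = reward_map(actions, truth, cfg)
        for (i, j), a in np.ndenumerate(actions):
            assert grid[i, j] == pixel_reward(
                PixelDecision(int(a), int(truth[i, j])), cfg)
        assert np.abs(grid).max() <= 1.0


class TestMaskedProductAndCriticLoss:
    def test_identity_and_zero_masks(self):
        x = np.array([[0.5, 1.0], [0.2, 0.0]])
        assert np.array_equal(masked_product(x, np.ones_like(x)), x)
        assert np.array_equal(masked_product(x, np.zeros_like(x)),
                              np.zeros_like(x))

    def test_elementwise_arithmetic(self):
        x = np.array([[0.5, 1.0], [0.2, 0.0]])
        m = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert np.array_equal(masked_product(x, m),
                              np.array([[0.5, 0.0], [0.2, 0.0]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            masked_product(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_critic_loss_closed_forms(self):
        assert critic_loss([0.3, 0.5], [0.4, 0.4]) == pytest.approx(0.0)
        assert critic_loss([0.2], [0.7]) == pytest.approx(-0.5)
        assert critic_loss([0.9, 0.9, 0.9], [0.9]) == pytest.approx(0.0)

    def test_critic_loss_empty_rejected(self):
        with pytest.raises(ValueError):
            critic_loss([], [0.5])


class TestPolicyGradientStep:
    img = SliceImage(np.array([[0.2, 0.9], [0.4, 0.1]]))
    truth = MaskImage(np.array([[1, 1], [0, 0]], dtype=np.uint8))

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        pol = TinyLogisticPolicy()
        before = (pol.w.data.copy(), pol.b.data.copy())
        policy_gradient_step(pol, self.img, self.truth, RewardConfig(0.5),
                             alpha=0.0, rng=np.random.default_rng(1))
        assert pol.w.data == before[0] and pol.b.data == before[1]

    def test_zero_mean_reward_is_a_fixed_point(self):
        # seed 4 samples actions whose four rewards (+1, -1, +0.5, -0.5)
        # cancel exactly, so the Rbar-weighted update vanishes
        pol = TinyLogisticPolicy()
        before = (pol.w.data.copy(), pol.b.data.copy())
        info = policy_gradient_step(pol, self.img, self.truth,
                                    RewardConfig(0.5), alpha=0.1,
                                    rng=np.random.default_rng(4))
        assert info["mean_reward"] == 0.0
        assert pol.w.data == before[0] and pol.b.data == before[1]

    def test_update_matches_central_finite_differences(self):
        # the update direction is alpha * grad of sum(log pi(a|s)) * Rbar
        pol = TinyLogisticPolicy()
        theta0 = np.array([pol.w.data.copy(), pol.b.data.copy()])
        alpha = 1e-3
        info = policy_gradient_step(pol, self.img, self.truth,
                                    RewardConfig(0.5), alpha=alpha,
                                    rng=np.random.default_rng(11))
        grad_impl = (np.array([pol.w.data, pol.b.data]) - theta0) / alpha
        actions, r_bar = info["actions"], info["mean_reward"]

        def objective(w, b):
            p = 1.0 / (1.0 + np.exp(-(self.img.pixels * w + b)))
            log_p = np.where(actions == 1, np.log(p), np.log(1.0 - p))
            return log_p.sum() * r_bar

        eps = 1e-6
        fd = np.array([
            (objective(theta0[0] + eps, theta0[1])
             - objective(theta0[0] - eps, theta0[1])) / (2 * eps),
            (objective(theta0[0], theta0[1] + eps)
             - objective(theta0[0], theta0[1] - eps)) / (2 * eps),
        ])
        assert np.allclose(grad_impl, fd, rtol=1e-4, atol=1e-8)

    def test_log_probability_of_actions_rises_along_positive_reward(self):
        # when the sampled step carries positive mean reward, a small ascent
        # step increases the log-likelihood of the sampled actions
        for seed in range(30):
            pol = TinyLogisticPolicy()
            info = policy_gradient_step(pol, self.img, self.truth,
                                        RewardConfig(0.5), alpha=1e-3,
                                        rng=np.random.default_rng(seed))
            if info["mean_reward"] <= 0:
                continue
            actions = info["actions"]
            p = 1.0 / (1.0 + np.exp(-(self.img.pixels * pol.w.data.item()
                                      + pol.b.data.item())))
            after = np.where(actions == 1, np.log(p), np.log(1 - p)).sum()
            p0 = 1.0 / (1.0 + np.exp(-(self.img.pixels * 0.8 - 0.2)))
            before = np.where(actions == 1, np.log(p0), np.log(1 - p0)).sum()
            assert after > before
            return
        pytest.fail("no positive-reward sample found")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            policy_gradient_step(TinyLogisticPolicy(), self.img,
                                 MaskImage(np.zeros((3, 3), dtype=np.uint8)),
                                 RewardConfig(0.5), alpha=0.1,
                                 rng=np.random.default_rng(0))


class TestSegmentOp:
    def test_output_shape_and_binarity(self, small_case, rng):
        gen = UNetPolicy(rng)
        mask = segment(gen, small_case.slices[0], threshold=0.5)
        assert mask.shape == small_case.slices[0].pixels.shape
        assert set(np.unique(mask.labels)) <= {0, 1}

    def test_threshold_binarization_matches_elementwise_oracle(self,
                                                               small_case,
                                                               rng):
        gen = UNetPolicy(rng)
        img = small_case.slices[0]
        prob = gen.prob_map(img.pixels)
        for thr in (0.3, 0.5, 0.7):
            mask = segment(gen, img, threshold=thr)
            assert np.array_equal(mask.labels, (prob >= thr).astype(np.uint8))

    def test_all_below_threshold_gives_empty_mask(self, small_case, rng):
        gen = UNetPolicy(rng)
        prob_max = gen.prob_map(small_case.slices[0].pixels).max()
        thr = min(0.999, prob_max + 1e-6)
        mask = segment(gen, small_case.slices[0], threshold=thr)
        assert mask.labels.sum() == 0

    def test_invalid_threshold_rejected(self, small_case, rng):
        with pytest.raises(ValueError):
            segment(UNetPolicy(rng), small_case.slices[0], threshold=1.2)


class TestCritic:
    def test_requires_a_dilated_layer(self, rng):
        with pytest.raises(ValueError):
            DilatedCritic(rng, dilation_rates=(1, 1))

    def test_scalar_score_per_image(self, rng):
        critic = DilatedCritic(rng)
        scores = critic(Tensor(np.random.default_rng(1).random((3, 1, 8, 8))))
        assert scores.shape == (3,)

    def test_weight_clipping_bounds_parameters(self, rng):
        critic = DilatedCritic(rng)
        for p in critic.parameters():
            p.data += 10.0
        critic.clip_weights(0.05)
        for p in critic.parameters():
            assert np.abs(p.data).max() <= 0.05


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self, small_dataset):
        cfg = SegTrainConfig(epochs=0, seed=5)
        res = train_segmentation(small_dataset, cfg)
        fresh = UNetPolicy(np.random.default_rng(5),
                           base_channels=cfg.base_channels)
        for a, b in zip(res.generator.parameters(), fresh.parameters()):
            assert np.array_equal(a.data, b.data)
        assert len(res.history) == 0

    def test_history_schema_and_reward_bounds(self, small_dataset):
        cfg = SegTrainConfig(epochs=2, batch_size=8, seed=0)
        res = train_segmentation(small_dataset, cfg)
        assert list(res.history.columns) == [
            "epoch", "mean_reward", "critic_loss", "val_iou", "val_hd"]
        assert len(res.history) == 2
        assert res.history["mean_reward"].between(-1, 1).all()
        assert res.history["val_iou"].between(0, 1).all()

    def test_fixed_seed_reproduces_training(self, small_dataset):
        cfg = SegTrainConfig(epochs=2, batch_size=8, seed=9)
        r1 = train_segmentation(small_dataset, cfg)
        r2 = train_segmentation(small_dataset, cfg)
        pd.testing.assert_frame_equal(r1.history, r2.history)
        for a, b in zip(r1.generator.parameters(), r2.generator.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_no_rl_arm_trains_by_cross_entropy(self, small_dataset):
        cfg = SegTrainConfig(epochs=2, batch_size=8, seed=0)
        rl = train_segmentation(small_dataset, cfg, use_rl=True)
        ce = train_segmentation(small_dataset, cfg, use_rl=False)
        assert not np.array_equal(rl.generator.parameters()[0].data,
                                  ce.generator.parameters()[0].data)
        assert "cross-entropy" in ce.summary()

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            LungSegmentationModel([])
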