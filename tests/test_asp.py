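"""Sample-level prioritizing: grouping models and the ASP loss family."""

import numpy as np
import pytest

from aspseg import (
    AdaptiveFocalConfig,
    DaspConfig,
    GroupingModel,
    LraspWeightNet,
    PixelLossConfig,
    RaspConfig,
    SampleMeta,
    adaptive_focal_loss,
    adaptive_upsilon,
    assign_group,
    bce_loss,
    dasp_loss,
    dasp_region_coefficient,
    dice_loss,
    fit_grouping,
    focal_loss,
    hybrid_pixel_loss,
    hybrid_region_loss,
    lrasp_loss,
    lrasp_weights,
    mass_ratio,
    rasp_loss,
)
from aspseg.asp import rasp_weights
from aspseg.autodiff import Tensor
from aspseg.exceptions import ConfigError, DataError, DomainError, StateError

from .oracles import kmeans2_oracle, numeric_grad


class TestMassRatio:
    def test_extremes(self):
        assert mass_ratio(np.zeros((7, 9))) == 0.0
        assert mass_ratio(np.ones((7, 9))) == 1.0

    def test_exact_count_arithmetic(self):
        m = np.zeros((256, 256))
        m.flat[:655] = 1
        assert mass_ratio(m) == pytest.approx(655 / 65536, abs=1e-15)


class TestGrouping:
    def test_median_split_of_four(self):
        model = fit_grouping([0.01, 0.02, 0.03, 0.04], "quantile")
        assert model.threshold == pytest.approx(0.025)

    def test_mean_split_of_four(self):
        model = fit_grouping([0.01, 0.02, 0.03, 0.06], "value")
        assert model.threshold == pytest.approx(0.03)

    def test_cluster_recovers_planted_bimodal_modes(self):
        r = np.random.default_rng(7)
        small = np.clip(r.normal(0.01, 0.002, 50), 0, 1)
        large = np.clip(r.normal(0.20, 0.02, 50), 0, 1)
        ratios = np.concatenate([small, large])
        model = fit_grouping(ratios, "cluster", k=2, seed=7)
        assert abs(model.centers[0] - 0.01) < 0.01
        assert abs(model.centers[1] - 0.20) < 0.01
        for v in small:
            assert assign_group(model, float(v)) == 0
        for v in large:
            assert assign_group(model, float(v)) == 1

    def test_cluster_matches_bruteforce_two_means(self, rng):
        for _ in range(10):
            ratios = rng.uniform(0, 0.4, 30)
            model = fit_grouping(ratios, "cluster", k=2)
            expected = kmeans2_oracle(ratios)
            assert model.centers[0] == pytest.approx(expected[0], abs=1e-12)
            assert model.centers[1] == pytest.approx(expected[1], abs=1e-12)

    def test_threshold_boundary_goes_small(self):
        model = GroupingModel("quantile", threshold=0.025, fitted_on=4)
        assert assign_group(model, 0.01) == 0
        assert assign_group(model, 0.025) == 0
        assert assign_group(model, 0.04) == 1

    def test_cluster_equidistant_tie_goes_small(self):
        model = GroupingModel("cluster", centers=(0.01, 0.20), fitted_on=10)
        assert assign_group(model, 0.105) == 0

    def test_quantile_split_nonempty_groups(self, rng):
        ratios = rng.uniform(0, 0.3, 31)
        model = fit_grouping(ratios, "quantile")
        groups = {assign_group(model, float(v)) for v in ratios}
        assert groups == {0, 1}

    def test_empty_ratio_list_rejected(self):
        with pytest.raises(DataError):
            fit_grouping([], "quantile")

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigError):
            fit_grouping([0.1, 0.2], "cluster", k=1)

    def test_json_roundtrip(self):
        model = fit_grouping([0.01, 0.05, 0.2, 0.3], "cluster")
        again = GroupingModel.from_json(model.to_json())
        assert again == model

    def test_metadata_csv_roundtrip(self, tmp_path):
        from aspseg.asp import assign_groups, read_metadata_csv, write_metadata_csv
        metas = [SampleMeta(0.01, 2, sample_id="a"),
                 SampleMeta(0.30, 4, sample_id="b")]
        model = fit_grouping([m.ratio for m in metas], "quantile")
        assign_groups(model, metas)
        path = tmp_path / "meta.csv"
        write_metadata_csv(path, metas)
        again = read_metadata_csv(path)
        assert [(m.ratio, m.density_category, m.group, m.sample_id)
                for m in again] == \
            [(m.ratio, m.density_category, m.group, m.sample_id) for m in metas]


class TestRasp:
    def test_large_group_prioritizes_bce(self, mask_pair):
        pred, gt = mask_pair
        cfg = RaspConfig(i_dice=1.0, i_bce=1.0)
        expected = dice_loss(pred, gt) + 2.0 * bce_loss(pred, gt)
        assert rasp_loss(pred, gt, 1, cfg) == pytest.approx(expected, abs=1e-10)

    def test_small_group_prioritizes_dice(self, mask_pair):
        pred, gt = mask_pair
        cfg = RaspConfig(i_dice=1.0, i_bce=1.0)
        expected = 2.0 * dice_loss(pred, gt) + bce_loss(pred, gt)
        assert rasp_loss(pred, gt, 0, cfg) == pytest.approx(expected, abs=1e-10)

    def test_continuous_mode_hand_arithmetic(self):
        cfg = RaspConfig(i_dice=1.0, i_bce=1.0, gamma_dice=0.25, gamma_bce=0.25,
                         p_mode="continuous")
        w_d, w_b = rasp_weights(0.5, cfg)
        assert w_d == pytest.approx(1.0 + 0.5 ** 0.25, abs=1e-12)
        assert w_b == pytest.approx(1.0 + 0.5 ** 0.25, abs=1e-12)

    def test_coefficient_ordering_flips_with_group(self):
        cfg = RaspConfig(i_dice=0.125, i_bce=0.125)
        wd0, wb0 = rasp_weights(0, cfg)
        wd1, wb1 = rasp_weights(1, cfg)
        assert wd0 > wb0      # small group: dice dominates
        assert wd1 < wb1      # large group: BCE dominates

    def test_binary_mode_gamma_inert(self, mask_pair):
        # regression guard: 0^g = 0 and 1^g = 1 for every g > 0, so the
        # exponent cannot act on a binary group indicator
        pred, gt = mask_pair
        a = rasp_loss(pred, gt, 1, RaspConfig(gamma_dice=0.25, gamma_bce=0.25))
        b = rasp_loss(pred, gt, 1, RaspConfig(gamma_dice=3.0, gamma_bce=7.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_binary_mode_rejects_fractional_p(self, mask_pair):
        with pytest.raises(DomainError):
            rasp_loss(*mask_pair, 0.5, RaspConfig())


class TestLrasp:
    def test_zeroed_final_layer_gives_unit_weights(self):
        net = LraspWeightNet(image_size=(16, 16), seed=3)
        net.w2.data[:] = 0.0
        net.b2.data[:] = 0.0
        gt = np.zeros((16, 16))
        gt[4:8, 4:8] = 1
        w = lrasp_weights(gt, net)
        assert w == pytest.approx((1.0, 1.0), abs=1e-12)

    def test_deterministic_and_positive_sum_two(self, rng):
        net = LraspWeightNet(image_size=(16, 16), seed=5)
        gt = (rng.random((16, 16)) < 0.2).astype(float)
        w1, w2 = lrasp_weights(gt, net)
        assert (w1, w2) == lrasp_weights(gt, net)
        assert w1 > 0 and w2 > 0
        assert w1 + w2 == pytest.approx(2.0, abs=1e-9)

    def test_unnormalized_mode_positive(self, rng):
        net = LraspWeightNet(image_size=(16, 16), seed=5, normalization="none")
        gt = (rng.random((16, 16)) < 0.2).astype(float)
        w1, w2 = lrasp_weights(gt, net)
        assert w1 > 0 and w2 > 0

    def test_forced_unit_weights_recompose(self):
        pred = np.random.default_rng(0).uniform(0.1, 0.9, (16, 16))
        gt = (np.random.default_rng(1).random((16, 16)) < 0.3).astype(float)
        net = LraspWeightNet(image_size=(16, 16), seed=0)
        net.w2.data[:] = 0.0
        net.b2.data[:] = 0.0
        # softmax x2 with zero logits -> (1, 1): the static hybrid
        assert lrasp_loss(pred, gt, net) == pytest.approx(
            hybrid_pixel_loss(pred, gt, PixelLossConfig(alpha=1, beta=1)), abs=1e-12)

    def test_recomposition_from_weights(self, rng):
        pred = rng.uniform(0.1, 0.9, (16, 16))
        gt = (rng.random((16, 16)) < 0.3).astype(float)
        net = LraspWeightNet(image_size=(16, 16), seed=11)
        w_d, w_b = lrasp_weights(gt, net)
        expected = w_d * dice_loss(pred, gt) + w_b * bce_loss(pred, gt)
        assert lrasp_loss(pred, gt, net) == pytest.approx(expected, abs=1e-12)

    def test_weight_gradients_match_finite_differences(self, rng):
        gt = (rng.random((16, 16)) < 0.3).astype(float)
        net = LraspWeightNet(image_size=(16, 16), seed=2)
        out = net.forward(gt)
        (out[0] * 1.0 + out[1] * 3.0).backward()
        for param in (net.w2, net.b2, net.b1):
            analytic = param.grad

            def scalar(vals, p=param):
                old = p.data.copy()
                p.data = vals.reshape(p.data.shape)
                o = net.forward(gt)
                val = float(o.data[0] + 3.0 * o.data[1])
                p.data = old
                return val

            num = numeric_grad(scalar, param.data.copy().ravel(), eps=1e-6)
            assert np.abs(analytic.ravel() - num).max() < 1e-4


class TestDasp:
    def test_inbreast_category_three_coefficient(self):
        assert dasp_region_coefficient(3, (0.5, 0.5, 0.85, 0.95)) == 0.85

    def test_cbis_category_one_coefficient(self):
        assert dasp_region_coefficient(1, (0.25, 0.25, 0.85, 0.95)) == 0.25

    def test_zero_vector(self):
        for c in (1, 2, 3, 4):
            assert dasp_region_coefficient(c, (0, 0, 0, 0)) == 0.0

    def test_category_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            dasp_region_coefficient(5, (0.5, 0.5, 0.85, 0.95))

    def test_zero_theta_reduces_to_pixel_hybrid(self, rng):
        pred = rng.uniform(0.05, 0.95, (32, 32))
        gt = (rng.random((32, 32)) < 0.2).astype(float)
        cfg = DaspConfig(theta=(0, 0, 0, 0))
        assert dasp_loss(pred, gt, 2, cfg) == pytest.approx(
            hybrid_pixel_loss(pred, gt, cfg.pixel), abs=1e-12)

    def test_recomposition_category_four(self, rng):
        pred = rng.uniform(0.05, 0.95, (32, 32))
        gt = (rng.random((32, 32)) < 0.2).astype(float)
        cfg = DaspConfig(theta=(0.5, 0.5, 0.85, 0.95))
        expected = 0.95 * hybrid_region_loss(pred, gt, cfg.region) + \
            hybrid_pixel_loss(pred, gt, cfg.pixel)
        assert dasp_loss(pred, gt, 4, cfg) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_density_when_region_loss_positive(self, rng):
        pred = rng.uniform(0.05, 0.95, (32, 32))
        gt = (rng.random((32, 32)) < 0.2).astype(float)
        cfg = DaspConfig(theta=(0.1, 0.2, 0.5, 0.9))
        if hybrid_region_loss(pred, gt, cfg.region) >= 0:
            assert dasp_loss(pred, gt, 4, cfg) >= dasp_loss(pred, gt, 1, cfg)

    def test_dominates_pixel_hybrid_for_nonnegative_region_terms(self, rng):
        pred = rng.uniform(0.05, 0.95, (32, 32))
        gt = (rng.random((32, 32)) < 0.2).astype(float)
        cfg = DaspConfig()
        hr = hybrid_region_loss(pred, gt, cfg.region)
        if hr >= 0:
            for c in (1, 2, 3, 4):
                assert dasp_loss(pred, gt, c, cfg) >= \
                    hybrid_pixel_loss(pred, gt, cfg.pixel) - 1e-12


class TestAdaptiveFocal:
    def test_ratio_mode_small_group_default(self):
        meta = SampleMeta(ratio=0.01, group=0)
        assert adaptive_upsilon(meta, AdaptiveFocalConfig(mode="ratio")) == 0.25

    def test_ratio_mode_large_group_default(self):
        meta = SampleMeta(ratio=0.2, group=1)
        assert adaptive_upsilon(meta, AdaptiveFocalConfig(mode="ratio")) == 0.5

    def test_density_mode_table(self):
        cfg = AdaptiveFocalConfig(mode="density")
        expected = {1: 0.2, 2: 0.25, 3: 0.3, 4: 0.35}
        for cat, u in expected.items():
            assert adaptive_upsilon(SampleMeta(0.1, cat), cfg) == u

    def test_degenerate_equal_table(self):
        cfg = AdaptiveFocalConfig(mode="ratio", upsilon_by_group=(0.4, 0.4))
        for g in (0, 1):
            assert adaptive_upsilon(SampleMeta(0.1, group=g), cfg) == 0.4

    def test_unassigned_group_rejected_in_ratio_mode(self):
        with pytest.raises(StateError):
            adaptive_upsilon(SampleMeta(0.1), AdaptiveFocalConfig(mode="ratio"))

    def test_reduces_to_plain_focal(self, mask_pair):
        pred, gt = mask_pair
        meta = SampleMeta(ratio=0.01, group=0)
        assert adaptive_focal_loss(pred, gt, meta, AdaptiveFocalConfig(mode="ratio")) \
            == pytest.approx(focal_loss(pred, gt, 0.25), abs=1e-12)

    def test_large_group_never_larger_loss(self, mask_pair):
        # larger upsilon shrinks every per-pixel term when Y_t is interior
        pred, gt = mask_pair
        cfg = AdaptiveFocalConfig(mode="ratio", upsilon_by_group=(0.25, 0.5))
        small = adaptive_focal_loss(pred, gt, SampleMeta(0.01, group=0), cfg)
        large = adaptive_focal_loss(pred, gt, SampleMeta(0.20, group=1), cfg)
        assert large <= small + 1e-12


class TestAspGradients:
    def test_asp_losses_match_finite_differences(self, rng):
        gt = (rng.random((16, 16)) < 0.3).astype(float)
        pred0 = rng.uniform(0.2, 0.8, (16, 16))
        meta = SampleMeta(ratio=float(gt.mean()), density_category=3, group=0)
        net = LraspWeightNet(image_size=(16, 16), seed=4)
        cases = {
            "rasp": lambda p: rasp_loss(p, gt, 0),
            "lrasp": lambda p: lrasp_loss(p, gt, net),
            "dasp": lambda p: dasp_loss(p, gt, 3, DaspConfig()),
            "adaptive_focal": lambda p: adaptive_focal_loss(
                p, gt, meta, AdaptiveFocalConfig(mode="ratio")),
        }
        pixels = [tuple(rng.integers(0, 16, 2)) for _ in range(5)]
        for name, fn in cases.items():
            t = Tensor(pred0.copy(), requires_grad=True)
            fn(t).backward()
            num = numeric_grad(lambda x: float(fn(x)), pred0)
            for px in pixels:
                assert t.grad[px] == pytest.approx(num[px], abs=1e-3), name
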