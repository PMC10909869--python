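"""Grad-CAM weights/maps against closed forms and finite differences, and
atlas-region attribution."""

import numpy as np
import pytest

from neurofuse.explain import (
    CamMap,
    cam_to_scan_grid,
    coverage_mask,
    fusion_gradcam,
    gradcam,
    group_attribution,
    region_attribution,
    upsample_cam,
)
from neurofuse.models import ArchitectureConfig, ModelVariant, build_model
from neurofuse.nn import Conv, Dense, Flatten, ReLU, Sequential


def mean_readout_net(scale, k=1, size=6, seed=0):
    """Tiny net whose logit is ``scale * mean(conv output)``: the Grad-CAM
    closed form is alpha_k = scale/Z and L = ReLU(sum_k (scale/Z) A_k)."""
    conv = Conv(1, k, 3, 2, np.random.default_rng(seed))
    dense = Dense(k * size * size, 1, np.random.default_rng(seed + 1))
    dense.w.value[...] = scale / (k * size * size)
    dense.b.value[...] = 0.0
    return Sequential([conv, Flatten(), dense]), conv


class TestGradcamClosedForm:
    def test_linear_mean_readout_single_map(self, rng):
        scale = 2.5
        net, conv = mean_readout_net(scale)
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        cam = gradcam(net, x, class_index=1, layer=0)
        A = conv.forward(x)[0, 0]
        Z = 36
        assert cam.Z == Z
        assert cam.alpha.shape == (1,)
        assert cam.alpha[0] == pytest.approx(scale / Z, rel=1e-5)
        expected = np.maximum((scale / Z) * A, 0.0)
        assert np.allclose(cam.L, expected, atol=1e-6)

    def test_negative_combination_gives_zero_map(self, rng):
        net, conv = mean_readout_net(-1.0)
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        A = conv.forward(x)[0, 0]
        if not (A > 0).any():  # make sure ReLU floor is actually exercised
            x = np.abs(x)
            A = conv.forward(x[None] if x.ndim == 3 else x)[0, 0]
        cam = gradcam(net, x, class_index=1, layer=0)
        # alpha < 0 wherever the map is positive-mean: combination clipped
        assert (cam.L >= 0).all()
        assert np.allclose(cam.L, np.maximum(cam.alpha[0] * A, 0.0), atol=1e-6)

    def test_negative_class_flips_score_sign(self, rng):
        net, conv = mean_readout_net(1.5)
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        cam_pos = gradcam(net, x, class_index=1, layer=0)
        cam_neg = gradcam(net, x, class_index=0, layer=0)
        assert cam_neg.alpha[0] == pytest.approx(-cam_pos.alpha[0], rel=1e-5)

    def test_scale_covariance(self, rng):
        """Multiplying the logit by a positive constant scales L by it."""
        net1, _ = mean_readout_net(1.0, k=3)
        net4, _ = mean_readout_net(4.0, k=3)
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        c1 = gradcam(net1, x, layer=0)
        c4 = gradcam(net4, x, layer=0)
        assert np.allclose(c4.L, 4.0 * c1.L, atol=1e-5)

    def test_non_conv_layer_rejected(self, rng):
        net, _ = mean_readout_net(1.0)
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        with pytest.raises(ValueError, match="convolutional"):
            gradcam(net, x, layer=1)


class TestGradcamFiniteDifference:
    def fd_alpha_and_cam(self, model, x, layer, eps=1e-4):
        """Brute-force alpha: perturb each activation entry of the chosen
        layer, re-run the rest of the network, pool the resulting score
        differences; then form ReLU(sum alpha*A).

        Central differences are invalid where the activation sits within
        ``eps`` of a ReLU kink (the difference quotient straddles the
        nondifferentiable point), so those maps are flagged and excluded
        from the comparison.
        """
        net = model.net
        net.forward(model._check(x), training=False, keep_outputs=True)
        A = net._outputs[layer][0].copy()
        score = lambda a: float(net.forward_from(layer, a[None])[0, 0])
        G = np.zeros_like(A)
        for idx in np.ndindex(*A.shape):
            ap = A.copy()
            ap[idx] += eps
            am = A.copy()
            am[idx] -= eps
            G[idx] = (score(ap) - score(am)) / (2 * eps)
        spatial = tuple(range(1, A.ndim))
        alpha = G.mean(axis=spatial)
        L = np.maximum(
            (alpha.reshape((-1,) + (1,) * (A.ndim - 1)) * A).sum(0), 0.0)
        map_valid = (np.abs(A) > 10 * eps).all(axis=spatial)
        return alpha, L, map_valid

    def test_alpha_and_map_match_finite_differences(self, rng):
        arch = ArchitectureConfig(dims=2, conv_filters=(2, 3, 4, 5),
                                  dense_widths=(4,))
        model = build_model(ModelVariant.MRI_2D, arch, (12, 12), seed=5)
        layer = model.conv_layer_indices()[-1]
        full_map_trials = 0
        for trial in range(5):
            x = rng.normal(size=(12, 12)).astype(np.float32)
            cam = gradcam(model, x, layer=layer)
            alpha_fd, L_fd, valid = self.fd_alpha_and_cam(model, x, layer)
            assert valid.sum() >= 2  # comparison must not be vacuous
            scale = np.abs(alpha_fd[valid]).max() + 1e-12
            assert np.allclose(cam.alpha[valid], alpha_fd[valid],
                               atol=1e-3 * scale + 1e-6)
            if valid.all():
                full_map_trials += 1
                lscale = np.abs(L_fd).max() + 1e-12
                assert np.allclose(cam.L, L_fd, atol=1e-3 * lscale + 1e-6)
        assert full_map_trials >= 1


class TestUpsample:
    def test_identity_and_constant(self):
        g = np.ones((4, 4, 2))
        assert np.array_equal(upsample_cam(g, (4, 4, 2)), g)
        up = upsample_cam(np.full((3, 3, 2), 0.7), (9, 9, 6))
        assert np.allclose(up, 0.7)

    def test_hot_voxel_peak_location_preserved(self):
        g = np.zeros((4, 4, 4))
        g[1, 2, 3] = 1.0
        up = upsample_cam(g, (8, 8, 8))
        peak = np.unravel_index(np.argmax(up), up.shape)
        # corner-aligned mapping: index i maps to i*(t-1)/(s-1)
        expected = tuple(round(i * 7 / 3) for i in (1, 2, 3))
        assert all(abs(p - e) <= 1 for p, e in zip(peak, expected))
        assert up.min() >= 0.0

    def test_smaller_target_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            upsample_cam(np.ones((4, 4)), (2, 4))


class TestRegionAttribution:
    def test_indicator_relevance_selects_that_region(self, atlas):
        relevance = (atlas.labels == 3).astype(float)
        att = region_attribution(relevance, atlas)
        assert att.means["region_03"] == pytest.approx(1.0)
        others = [v for k, v in att.means.items() if k != "region_03"]
        assert max(others) == 0.0
        assert att.selected == frozenset({"region_03"})

    def test_constant_relevance_selects_everything(self, atlas):
        att = region_attribution(np.full(atlas.grid_shape, 0.4), atlas)
        assert att.selected == frozenset(att.means)

    def test_means_match_per_region_loops(self, atlas, rng):
        relevance = rng.random(atlas.grid_shape)
        att = region_attribution(relevance, atlas)
        for r in atlas.region_ids:
            voxels = [relevance[tuple(v)] for v in np.argwhere(atlas.labels == r)]
            assert att.means[atlas.names[r]] == pytest.approx(
                float(np.mean(voxels)), abs=1e-12)

    def test_partition_consistency(self, atlas, rng):
        """Voxel-count-weighted mean of region means = brain-wide mean."""
        relevance = rng.random(atlas.grid_shape)
        att = region_attribution(relevance, atlas)
        weights = {atlas.names[r]: int((atlas.labels == r).sum())
                   for r in atlas.region_ids}
        weighted = sum(att.means[n] * weights[n] for n in att.means)
        total = sum(weights.values())
        brain_mean = float(relevance[atlas.labels > 0].mean())
        assert weighted / total == pytest.approx(brain_mean, abs=1e-9)

    def test_mask_restricts_means(self, atlas, rng):
        relevance = rng.random(atlas.grid_shape)
        mask = np.zeros(atlas.grid_shape, dtype=bool)
        mask[:, :, 10:20] = True
        att = region_attribution(relevance, atlas, mask=mask)
        for name, m in att.means.items():
            r = [k for k, v in atlas.names.items() if v == name][0]
            sel = (atlas.labels == r) & mask
            assert m == pytest.approx(float(relevance[sel].mean()), abs=1e-12)

    def test_shape_mismatch_rejected(self, atlas):
        with pytest.raises(ValueError, match="shape"):
            region_attribution(np.ones((8, 8, 8)), atlas)


class TestCamToScanGrid:
    def test_inverts_crop_geometry(self, atlas):
        info = {"box_lo": (4, 6, 8), "box_hi": (24, 26, 28),
                "slice_lo": 4, "slice_hi": 16}
        cam = np.ones((2, 2, 1))
        out = cam_to_scan_grid(cam, info, (32, 32, 32))
        # 12 slices kept, pasted at box z-origin (8) + window start (4)
        inside = out[4:24, 6:26, 12:24]
        assert np.allclose(inside, 1.0)
        assert out.sum() == pytest.approx(inside.size)
        mask = coverage_mask(info, (32, 32, 32))
        assert mask.sum() == inside.size
        assert np.array_equal(out > 0, mask)


class TestGroupAttribution:
    def selective_model(self):
        """A hand-built 'well-trained' classifier: one conv feature detects
        high intensity, and the head reads its mean with positive weight, so
        Grad-CAM provably highlights bright voxels."""
        arch = ArchitectureConfig(dims=3, conv_filters=(2, 3, 4, 5),
                                  dense_widths=(4,))
        model = build_model(ModelVariant.MRI_3D, arch, (16, 16, 8), seed=0)
        conv1 = model.net.layers[0]
        conv1.w.value[...] = 0.0
        conv1.w.value[0, 0, 1, 1, 1] = 1.0  # channel 0 = identity/intensity
        return model

    def test_group_of_identical_scans_equals_single_scan(self, rng):
        model = self.selective_model()
        from neurofuse.synth import make_toy_atlas

        atlas16 = make_toy_atlas((16, 16, 16), 5, seed=1)
        x = rng.random((16, 16, 8)).astype(np.float32)
        single = group_attribution(model, [x], atlas16, layer=0)
        triple = group_attribution(model, [x, x, x], atlas16, layer=0)
        assert single.means == pytest.approx(triple.means, abs=1e-12)
        assert single.selected == triple.selected
        assert all(v in (0.0, 1.0) for v in triple.selection_frequency.values())

    def test_planted_bright_regions_recovered_with_selective_model(self):
        """With a class-selective intensity feature, the positive group's
        top-percentile selection contains the regions where the effect was
        planted (here the signal is constructed, not trained, so the test
        isolates the attribution machinery)."""
        from neurofuse.synth import EffectSpec, make_toy_atlas, simulate_volume

        atlas16 = make_toy_atlas((16, 16, 16), 6, seed=2)
        spec = EffectSpec("MRI", frozenset({2, 5}), effect_size=3.0,
                          noise_sd=0.05, brain_offset_sd=0.0)
        arch = ArchitectureConfig(dims=3, conv_filters=(2, 3, 4, 5),
                                  dense_widths=(4,))
        model = build_model(ModelVariant.MRI_3D, arch, (16, 16, 16), seed=0)
        conv1 = model.net.layers[0]
        conv1.w.value[...] = 0.0
        conv1.w.value[0, 0, 1, 1, 1] = 1.0
        vols = [simulate_volume(atlas16, 1, spec, seed=s) for s in range(4)]
        att = group_attribution(model, [v.astype(np.float32) for v in vols],
                                atlas16, layer=0, percentile=60.0)
        assert {"region_02", "region_05"} <= set(att.selected)
        assert all(0.0 <= f <= 1.0 for f in att.selection_frequency.values())

    def test_empty_group_rejected(self, atlas):
        model = self.selective_model()
        with pytest.raises(ValueError, match="at least one"):
            group_attribution(model, [], atlas, layer=0)


class TestFusionGradcam:
    def test_one_cam_per_branch_nonnegative(self, rng):
        arch = ArchitectureConfig(dims=3, conv_filters=(2, 3, 4, 5),
                                  dense_widths=(4,))
        model = build_model(ModelVariant.FUSION_3D, arch, (16, 16, 8), seed=1)
        xm = rng.random((1, 1, 16, 16, 8)).astype(np.float32)
        xp = rng.random((1, 1, 16, 16, 8)).astype(np.float32)
        cm = fusion_gradcam(model, (xm, xp), "MRI")
        cp = fusion_gradcam(model, (xm, xp), "PET")
        assert (cm.L >= 0).all() and (cp.L >= 0).all()
        assert cm.L.shape == cp.L.shape
        assert not np.array_equal(cm.L, cp.L)  # branches are independent
        with pytest.raises(ValueError, match="branch"):
            fusion_gradcam(model, (xm, xp), "CT")
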