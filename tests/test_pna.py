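"""Protein-network morphometrics: binarization, skeleton topology, lacunarity."""

import numpy as np
import pytest

import doughrheo as dr
from doughrheo.pna import (
    Micrograph,
    NetworkMask,
    binarize,
    classify_skeleton,
    compute_pna,
    lacunarity,
    lacunarity_curve,
    skeletonize_mask,
)


def _plus_mask(n=25, arm=8, pixel_size=1.0):
    m = np.zeros((n, n), dtype=bool)
    c = n // 2
    m[c, c - arm : c + arm + 1] = True
    m[c - arm : c + arm + 1, c] = True
    return NetworkMask(m, pixel_size)


class TestBinarize:
    def test_two_level_image_recovered_exactly(self):
        truth = np.zeros((32, 32), dtype=bool)
        truth[8:20, 5:25] = True
        img = Micrograph(np.where(truth, 255, 0).astype(np.uint8), 1.0)
        assert np.array_equal(binarize(img).mask, truth)

    def test_noisy_strands_recovered(self):
        img, truth = dr.simulate_network_image(dr.NetworkSimSpec(seed=0, noise_sigma=10.0))
        mask = binarize(img)
        agreement = np.mean(mask.mask == truth.mask)
        assert agreement >= 0.99

    def test_blank_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="blank"):
            mask = binarize(Micrograph(np.zeros((16, 16)), 1.0))
        assert not mask.mask.any()


class TestSkeleton:
    def test_wide_bar_thins_to_single_pixel_line(self):
        bar = np.zeros((20, 40), dtype=bool)
        bar[8:13, 5:35] = True
        skel = skeletonize_mask(NetworkMask(bar, 1.0))
        cols = np.count_nonzero(skel.mask, axis=0)
        assert cols[cols > 0].max() == 1  # one pixel per column: a line

    def test_crossing_bars_have_single_junction(self):
        plus = np.zeros((25, 25), dtype=bool)
        plus[10:15, 2:23] = True
        plus[2:23, 10:15] = True
        skel = skeletonize_mask(NetworkMask(plus, 1.0))
        junctions, endpoints, _, _ = classify_skeleton(skel)
        assert junctions == 1
        assert endpoints == 4

    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize_mask(NetworkMask(np.zeros((8, 8), dtype=bool), 1.0))
        assert not skel.mask.any()


class TestClassify:
    def test_straight_line(self):
        m = np.zeros((9, 20), dtype=bool)
        m[4, 2:18] = True
        j, e, length, segs = classify_skeleton(NetworkMask(m, 2.0))
        assert (j, e) == (0, 2)
        assert length == pytest.approx(15 * 2.0)  # 16 pixels -> 15 unit steps
        assert len(segs) == 1

    def test_plus_sign_topology(self):
        j, e, _, _ = classify_skeleton(_plus_mask())
        assert (j, e) == (1, 4)

    def test_diagonal_steps_weighted_sqrt2(self):
        m = np.zeros((10, 10), dtype=bool)
        np.fill_diagonal(m, True)
        _, _, length, _ = classify_skeleton(NetworkMask(m, 1.0))
        assert length == pytest.approx(9 * np.sqrt(2.0))

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_counts_rotation_invariant(self, k):
        img, _ = dr.simulate_network_image(dr.NetworkSimSpec(seed=4))
        base = skeletonize_mask(NetworkMask(_truth_mask(img, 4), img.pixel_size))
        j0, e0, _, _ = classify_skeleton(base)
        rot = skeletonize_mask(NetworkMask(np.rot90(_truth_mask(img, 4), k), img.pixel_size))
        j, e, _, _ = classify_skeleton(rot)
        assert (j, e) == (j0, e0)

    def test_counts_mirror_invariant(self):
        img, _ = dr.simulate_network_image(dr.NetworkSimSpec(seed=5))
        m = _truth_mask(img, 5)
        j0, e0, _, _ = classify_skeleton(skeletonize_mask(NetworkMask(m, 1.0)))
        j, e, _, _ = classify_skeleton(skeletonize_mask(NetworkMask(m[:, ::-1], 1.0)))
        assert (j, e) == (j0, e0)


def _truth_mask(img, seed):
    _, truth = dr.simulate_network_image(dr.NetworkSimSpec(seed=seed))
    return truth.mask


class TestLacunarity:
    def test_full_image_is_one_at_every_size(self):
        mask = NetworkMask(np.ones((64, 64), dtype=bool), 1.0)
        np.testing.assert_allclose(lacunarity_curve(mask, [2, 4, 8, 16]), 1.0)
        assert lacunarity(mask) == pytest.approx(1.0)

    @pytest.mark.parametrize("p, r", [(0.5, 8), (0.3, 8), (0.5, 16)])
    def test_bernoulli_mask_matches_binomial_closed_form(self, p, r):
        """For iid Bernoulli(p) pixels, Lambda(r) = 1 + (1-p)/(p r^2)."""
        rng = np.random.default_rng(12345)
        mask = NetworkMask(rng.random((256, 256)) < p, 1.0)
        lam = lacunarity_curve(mask, [r])[0]
        assert lam == pytest.approx(1.0 + (1.0 - p) / (p * r * r), rel=0.01)

    def test_checkerboard_below_random_at_coarse_boxes(self):
        tile = 4
        n = 64
        yy, xx = np.mgrid[0:n, 0:n]
        checker = ((yy // tile + xx // tile) % 2).astype(bool)
        rng = np.random.default_rng(0)
        rand = rng.random((n, n)) < checker.mean()
        for r in (8, 16):
            lam_c = lacunarity_curve(NetworkMask(checker, 1.0), [r])[0]
            lam_r = lacunarity_curve(NetworkMask(rand, 1.0), [r])[0]
            assert lam_c <= lam_r

    def test_lambda_at_least_one(self):
        rng = np.random.default_rng(3)
        mask = NetworkMask(rng.random((64, 64)) < 0.2, 1.0)
        assert np.all(lacunarity_curve(mask, [2, 4, 8, 16]) >= 1.0)

    def test_empty_mask_flagged_undefined(self):
        mask = NetworkMask(np.zeros((32, 32), dtype=bool), 1.0)
        with pytest.warns(UserWarning, match="undefined"):
            lam = lacunarity_curve(mask, [4])[0]
        assert np.isnan(lam)


class TestComputePNA:
    def test_generator_topology_recovered_exactly(self):
        for seed in range(20):
            img, truth = dr.simulate_network_image(dr.NetworkSimSpec(seed=seed))
            m = compute_pna(img)
            assert m.junction_count == truth.junction_count
            assert m.endpoint_count == truth.endpoint_count

    def test_rate_definitions_are_identities(self):
        img, _ = dr.simulate_network_image(dr.NetworkSimSpec(seed=2))
        m = compute_pna(img)
        assert m.branching_rate * m.protein_area == pytest.approx(m.junction_count, rel=1e-12)
        assert m.endpoint_rate * m.protein_area == pytest.approx(m.endpoint_count, rel=1e-12)
        assert m.protein_width == pytest.approx(m.protein_area / m.vessel_length, rel=1e-12)

    def test_width_recovered_within_15_percent(self):
        spec = dr.NetworkSimSpec(seed=8, strand_width=5)
        img, _ = dr.simulate_network_image(spec)
        m = compute_pna(img)
        true_width_um = spec.strand_width * spec.pixel_size
        assert abs(m.protein_width - true_width_um) / true_width_um < 0.15

    def test_empty_image_flagged(self):
        with pytest.warns(UserWarning):
            m = compute_pna(Micrograph(np.zeros((64, 64)), 1.0))
        assert m.junction_count == 0 and m.endpoint_count == 0
        assert np.isnan(m.branching_rate) and np.isnan(m.endpoint_rate)
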