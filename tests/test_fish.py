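"""Nucleus segmentation, equal-area shells, spot detection, chi-square."""

import numpy as np
import pytest
from scipy import stats

from britepipe import (
    ImageParams,
    RadialDistribution,
    SimConfig,
    VoxelStack,
    compare_radial,
    detect_spots,
    equal_area_shells,
    radial_distribution,
    segment_nuclei,
    simulate_radial_counts,
)
from britepipe.fish import FishSpot, assign_shell
from britepipe.synth.images import render_field


def _disc(radius=30, pad=20):
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2, c


def _ellipse(a=60, b=30, pad=15, theta=0.0):
    size = 2 * (max(a, b) + pad) + 1
    c = max(a, b) + pad
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - c, xx - c
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    return u**2 + v**2 <= 1.0, c


class TestEqualAreaShells:
    def test_disc_boundary_radii_match_analytic(self):
        disc, c = _disc(radius=30)
        sm = equal_area_shells(disc)
        yy, xx = np.mgrid[0 : disc.shape[0], 0 : disc.shape[1]]
        r2 = (yy - c) ** 2 + (xx - c) ** 2
        for shell, analytic in [(1, 30 * np.sqrt(1 / 3)), (2, 30 * np.sqrt(2 / 3))]:
            boundary = np.sqrt(r2[sm.labels == shell].max())
            assert abs(boundary - analytic) <= 1.0  # within one pixel

    def test_disc_areas_within_tolerance(self):
        disc, _ = _disc(radius=30)
        sm = equal_area_shells(disc)
        target = disc.sum() / 3
        assert np.all(np.abs(sm.areas - target) / target <= 0.02)

    def test_ellipse_areas_within_tolerance(self):
        ell, _ = _ellipse(a=60, b=30)
        sm = equal_area_shells(ell)
        target = ell.sum() / 3
        assert np.all(np.abs(sm.areas - target) / target <= 0.02)

    def test_random_ellipses_area_balance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(15, 45)
            sm = equal_area_shells(
                _ellipse(a=a, b=a / rng.uniform(1, 3), theta=rng.uniform(0, np.pi))[0]
            )
            target = sm.areas.sum() / 3
            assert np.all(np.abs(sm.areas - target) / target <= 0.02)

    def test_single_shell_labels_everything(self):
        disc, _ = _disc(radius=10)
        sm = equal_area_shells(disc, n_shells=1)
        assert sm.areas.tolist() == [int(disc.sum())]
        assert np.array_equal(sm.labels > 0, disc)

    def test_labels_partition_footprint(self):
        disc, _ = _disc(radius=20)
        sm = equal_area_shells(disc)
        assert np.array_equal(sm.labels > 0, disc)
        assert set(np.unique(sm.labels[disc])) == {1, 2, 3}

    def test_tiny_mask_raises(self):
        tiny = np.zeros((10, 10), dtype=bool)
        tiny[4:6, 4:6] = True  # 4 px: 2% tolerance unattainable
        with pytest.raises(ValueError):
            equal_area_shells(tiny)


class TestRadialDistribution:
    def test_centroid_spots_all_central(self):
        disc, c = _disc(radius=25)
        sm = equal_area_shells(disc)
        sm.nucleus_id = 1
        spots = [FishSpot(1, "probe1", 5.0, float(c), float(c), 100.0) for _ in range(4)]
        dist = radial_distribution(spots, {1: sm}, "Control", n_nuclei=2)
        assert dist.counts.tolist() == [4, 0, 0]
        assert dist.n_nuclei == 2

    def test_uniform_points_give_thirds(self):
        disc, _ = _disc(radius=40)
        sm = equal_area_shells(disc)
        sm.nucleus_id = 1
        rng = np.random.default_rng(1)
        pix = np.argwhere(disc)
        draw = pix[rng.choice(len(pix), size=10000)]
        spots = [FishSpot(1, "p", 0.0, float(y), float(x), 1.0) for y, x in draw]
        dist = radial_distribution(spots, {1: sm}, "X")
        assert np.all(np.abs(dist.fractions - 1 / 3) < 0.02)

    def test_spot_outside_footprint_raises(self):
        disc, _ = _disc(radius=10)
        sm = equal_area_shells(disc)
        sm.nucleus_id = 1
        spot = FishSpot(1, "p", 0.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            assign_shell(spot, sm)

    def test_percent_formatting_one_decimal(self):
        dist = RadialDistribution("cPGI2", np.array([26, 21, 13]), 30)
        assert dist.format_percent()[0] == "43.3%"


class TestChiSquare:
    def test_identical_distributions(self):
        a = RadialDistribution("A", np.array([30, 10, 10]), 25)
        b = RadialDistribution("B", np.array([30, 10, 10]), 25)
        res = compare_radial(a, b)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_matches_hand_computed_oracle(self):
        counts_a, counts_b = np.array([30, 10, 10]), np.array([10, 10, 30])
        res = compare_radial(
            RadialDistribution("A", counts_a, 25), RadialDistribution("B", counts_b, 25)
        )
        # textbook contingency computation from pooled margins
        table = np.vstack([counts_a, counts_b]).astype(float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=2)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df == 2
        assert np.allclose(res.expected, expected)

    def test_low_expected_count_flagged(self):
        res = compare_radial(
            RadialDistribution("A", np.array([2, 3, 20]), 10),
            RadialDistribution("B", np.array([3, 2, 20]), 10),
        )
        assert res.low_expected_warning

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            compare_radial(
                RadialDistribution("A", np.array([0, 0, 0]), 5),
                RadialDistribution("B", np.array([1, 1, 1]), 5),
            )

    def test_significance_convention_p_at_most_0_05(self):
        res = compare_radial(
            RadialDistribution("A", np.array([50, 30, 20]), 50),
            RadialDistribution("B", np.array([20, 30, 50]), 50),
        )
        assert res.p_value <= 0.05 and res.significant


class TestSegmentation:
    def test_blank_image_gives_no_nuclei(self):
        rng = np.random.default_rng(0)
        data = 100.0 + rng.normal(0, 3, (1, 6, 80, 80))
        assert segment_nuclei(VoxelStack(data, {"dapi": 0})) == []

    def test_constant_image_gives_no_nuclei(self):
        assert segment_nuclei(VoxelStack(np.full((1, 4, 50, 50), 7.0), {"dapi": 0})) == []

    def test_single_nucleus_iou(self):
        cfg = SimConfig(seed=5)
        stack, truths = render_field(cfg, "cPGI2", np.random.default_rng(7))
        masks = segment_nuclei(stack)
        assert len(masks) == 1
        t = truths[0]
        inter = (masks[0].footprint & t.footprint).sum()
        union = (masks[0].footprint | t.footprint).sum()
        assert inter / union > 0.9

    def test_two_separated_nuclei(self):
        cfg = SimConfig(
            seed=6,
            image=ImageParams(frame_shape=(14, 110, 200), nuclei_per_field=2),
        )
        stack, truths = render_field(cfg, "Control", np.random.default_rng(3), n_nuclei=2)
        masks = segment_nuclei(stack)
        assert len(masks) == 2

    def test_missing_dapi_channel_rejected(self):
        with pytest.raises(ValueError):
            VoxelStack(np.zeros((1, 2, 10, 10)), {"probe1": 0})


class TestSpotDetection:
    def _noiseless_stack(self, seed=3):
        cfg = SimConfig(
            seed=seed,
            image=ImageParams(psf_sigma=0.0, poisson_noise=False, noise_read_sd=0.0),
        )
        return render_field(cfg, "cPGI2", np.random.default_rng(seed)), cfg

    def test_noiseless_centroids_exact(self):
        (stack, truths), _ = self._noiseless_stack()
        mask = segment_nuclei(stack)[0]
        spots = detect_spots(stack, mask, "probe1")
        got = sorted((s.z, s.y, s.x) for s in spots)
        expected = sorted((t["z"], t["y"], t["x"]) for t in truths[0].spots)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert np.allclose(g, e, atol=1e-6)

    def test_moderate_noise_within_one_voxel(self):
        cfg = SimConfig(seed=12)
        stack, truths = render_field(cfg, "Control", np.random.default_rng(12))
        mask = segment_nuclei(stack)[0]
        spots = detect_spots(stack, mask, "probe1")
        assert len(spots) >= 1
        for s in spots:
            d = min(
                max(abs(s.z - t["z"]), abs(s.y - t["y"]), abs(s.x - t["x"]))
                for t in truths[0].spots
            )
            assert d <= 1.0

    def test_top_two_of_three_blobs_kept(self):
        (stack, truths), cfg = self._noiseless_stack(seed=4)
        # inject a third, dimmer blob inside the nucleus
        t = truths[0]
        ys, xs = np.nonzero(t.footprint)
        pos = (stack.data.shape[1] // 2, int(ys.mean()), int(xs.mean()))
        ch = stack.channels["probe1"]
        stack.data[ch][pos] += cfg.image.spot_intensity * 0.3
        mask = segment_nuclei(stack)[0]
        spots = detect_spots(stack, mask, "probe1", max_per_nucleus=2)
        assert len(spots) == 2
        bright = sorted((s.z, s.y, s.x) for s in spots)
        expected = sorted((s["z"], s["y"], s["x"]) for s in t.spots)
        for g, e in zip(bright, expected):
            assert np.allclose(g, e, atol=1.0)

    def test_no_signal_gives_empty(self):
        cfg = SimConfig(
            seed=5,
            image=ImageParams(spot_intensity=0.0),
        )
        stack, _ = render_field(cfg, "Control", np.random.default_rng(5))
        mask = segment_nuclei(stack)[0]
        assert detect_spots(stack, mask, "probe1") == []


class TestSimulation:
    def test_multinomial_counts_sum(self):
        rng = np.random.default_rng(0)
        counts = simulate_radial_counts((0.2, 0.3, 0.5), 100, rng)
        assert counts.sum() == 100

    def test_end_to_end_shell_agreement(self):
        cfg = SimConfig(
            seed=11, n_nuclei=1,
            image=ImageParams(psf_sigma=0.0, poisson_noise=False, noise_read_sd=0.0),
        )
        rng = np.random.default_rng(11)
        agree = total = 0
        for _ in range(15):
            stack, truths = render_field(cfg, "cPGI2", rng)
            masks = segment_nuclei(stack)
            if len(masks) != 1:
                continue
            sm = equal_area_shells(masks[0])
            for s in detect_spots(stack, masks[0], "probe1"):
                nearest = min(
                    truths[0].spots,
                    key=lambda t: abs(s.z - t["z"]) + abs(s.y - t["y"]) + abs(s.x - t["x"]),
                )
                agree += assign_shell(s, sm) == nearest["shell"]
                total += 1
        assert total >= 25
        assert agree / total >= 0.95
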