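"""Spot detection, basal-body/foot pairing and circular statistics."""

import math

import numpy as np
import pytest

from ciliaquant.polarity import (
    SpotSet,
    cell_polarity,
    circular_summary,
    detect_spots,
    pair_spots,
    rayleigh_test,
)
from ciliaquant.simulate import SpotFieldSpec, generate_spot_field


def blob_image(positions, shape=(128, 128), sigma=1.6, amp=1000.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for y, x in positions:
        img += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return img


def spot_set(coords):
    coords = np.asarray(coords, dtype=float)
    return SpotSet(0, coords, np.ones(len(coords)))


class TestDetectSpots:
    PX = 100.0  # nm/px

    def test_single_blob_subpixel(self):
        img = blob_image([(50.0, 40.0)])
        spots = detect_spots(img, self.PX, sigma_nm=160.0)
        assert len(spots) == 1
        assert np.hypot(*(spots.coordinates[0] - (50.0, 40.0))) < 0.5

    def test_two_separated_blobs(self):
        img = blob_image([(40.0, 40.0), (40.0, 49.0)])  # 3x min separation
        spots = detect_spots(img, self.PX, sigma_nm=160.0, min_separation_nm=300.0)
        assert len(spots) == 2

    def test_blank_image_is_empty_not_error(self):
        assert len(detect_spots(np.zeros((64, 64)), self.PX)) == 0
        assert len(detect_spots(np.full((64, 64), 3.0), self.PX)) == 0

    def test_generator_field_recovery_with_noise(self):
        spec = SpotFieldSpec(n_cells=2, spots_per_cell=30, noise_sd=50.0, seed=4)
        img, _, truth = generate_spot_field(spec)
        spots = detect_spots(img[0], spec.pixel_size, sigma_nm=spec.psf_sigma,
                             rel_threshold=0.15)
        truth_pos = truth[["bb_y", "bb_x"]].to_numpy()
        from scipy.spatial.distance import cdist

        d = cdist(truth_pos, spots.coordinates)
        matched = (d.min(axis=1) < 1.0).sum()
        spurious = (d.min(axis=0) > 1.0).sum()
        assert matched >= 57 and spurious <= 2


class TestPairSpots:
    PX = 100.0

    def test_collinear_pair_along_x(self):
        pairs, ub, uf = pair_spots(spot_set([(10, 10)]), spot_set([(10, 13)]), self.PX)
        assert len(pairs) == 1 and len(ub) == 0 and len(uf) == 0
        assert pairs[0].angle == pytest.approx(0.0)
        assert pairs[0].separation == pytest.approx(300.0)

    def test_foot_above_gives_plus_half_pi(self):
        # image y grows downward, so "above" is the mathematical +y
        pairs, _, _ = pair_spots(spot_set([(10, 10)]), spot_set([(7, 10)]), self.PX)
        assert pairs[0].angle == pytest.approx(math.pi / 2)

    def test_equidistant_tie_pairs_nothing(self):
        pairs, ub, uf = pair_spots(spot_set([(10, 10), (16, 10)]), spot_set([(13, 10)]), self.PX)
        assert pairs == [] and len(ub) == 2 and len(uf) == 1

    def test_distance_cap(self):
        pairs, _, _ = pair_spots(spot_set([(10, 10)]), spot_set([(10, 20)]), self.PX, max_dist_nm=500.0)
        assert pairs == []

    def test_swap_yields_same_unordered_pairs(self):
        rng = np.random.default_rng(0)
        bbs = rng.uniform(10, 90, size=(12, 2))
        feet = bbs + rng.normal(0, 1.0, size=bbs.shape)
        p1, _, _ = pair_spots(spot_set(bbs), spot_set(feet), self.PX)
        p2, _, _ = pair_spots(spot_set(feet), spot_set(bbs), self.PX)
        s1 = {(tuple(np.round(p.bb_pos, 6)), tuple(np.round(p.foot_pos, 6))) for p in p1}
        s2 = {(tuple(np.round(p.foot_pos, 6)), tuple(np.round(p.bb_pos, 6))) for p in p2}
        assert s1 == s2


class TestCircularSummary:
    def test_identical_angles(self):
        mean, r, sd = circular_summary([0.3, 0.3, 0.3])
        assert mean == pytest.approx(0.3)
        assert r == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_antipodal_pair_is_undefined(self):
        mean, r, sd = circular_summary([0.0, math.pi])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(mean) and math.isnan(sd)

    def test_quarter_turn_pair(self):
        mean, r, _ = circular_summary([0.0, math.pi / 2])
        assert mean == pytest.approx(math.pi / 4)
        assert r == pytest.approx(math.sqrt(2) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_summary([])


class TestRayleigh:
    def test_perfect_alignment_is_significant(self):
        assert rayleigh_test([0.5] * 100) < 1e-10

    def test_balanced_uniform_angles_give_p_one(self):
        assert rayleigh_test([0.0, math.pi / 2, math.pi, 3 * math.pi / 2] * 25) == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 1.0, 2.0])

    def test_agrees_with_monte_carlo_null(self, rng):
        # oracle: null distribution of R from 10,000 uniform samples of size 50
        angles = rng.vonmises(0.0, 2.0, size=50)
        r_obs = abs(np.exp(1j * angles).sum()) / 50
        null_r = np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, size=(10000, 50))).sum(axis=1)) / 50
        p_mc = (np.sum(null_r >= r_obs) + 1) / 10001
        p = rayleigh_test(angles)
        assert p <= 2 * max(p_mc, 1e-4) and p_mc <= 2 * max(p, 1e-4)


def test_rose_plot_bins_all_angles(rng):
    import matplotlib

    matplotlib.use("Agg")
    from ciliaquant.polarity import rose_plot

    angles = rng.vonmises(0.3, 4.0, size=80)
    ax = rose_plot(angles, n_bins=12)
    heights = [p.get_height() for p in ax.patches]
    assert sum(heights) == 80
    assert max(heights) == heights[np.argmax(heights)]  # one dominant petal exists
    import matplotlib.pyplot as plt

    plt.close("all")


class TestCellPolarity:
    def test_parameter_recovery_kappa8(self, rng):
        # von Mises draws: per-cell mean near mu, R near I1(8)/I0(8) ~ 0.94
        from scipy.special import i0, i1

        r_theory = i1(8.0) / i0(8.0)
        labels = np.zeros((10, 20), dtype=int)
        labels[:, :10] = 1
        labels[:, 10:] = 2
        rs, mean_errs = [], []
        for _ in range(20):
            angles = rng.vonmises(np.pi / 6, 8.0, size=50)
            mean, r, _ = circular_summary(angles)
            rs.append(r)
            mean_errs.append(abs(np.angle(np.exp(1j * (mean - np.pi / 6)))))
        assert np.median(rs) == pytest.approx(r_theory, abs=0.05)
        assert np.median(mean_errs) < np.deg2rad(5.0)

    def test_uniform_cells_have_low_r(self, rng):
        rs = [circular_summary(rng.uniform(-np.pi, np.pi, 50))[1] for _ in range(20)]
        assert np.median(rs) < 0.3

    def test_r_monotone_in_kappa(self, rng):
        medians = []
        for kappa in [0.0, 1.0, 2.0, 4.0, 8.0, 32.0]:
            rs = []
            for _ in range(20):
                draws = (rng.uniform(-np.pi, np.pi, 50) if kappa == 0
                         else rng.vonmises(0.0, kappa, 50))
                rs.append(circular_summary(draws)[1])
            medians.append(np.median(rs))
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_small_cell_unscored(self):
        from ciliaquant.polarity import PairedBasalUnit

        labels = np.ones((20, 20), dtype=int)
        pairs = [PairedBasalUnit((5.0, 5.0 + i), (6.0, 5.0 + i), 0.1, 100.0) for i in range(3)]
        (cell,) = cell_polarity(pairs, labels)
        assert not cell.scored and cell.n_pairs == 3

    def test_rotation_equivariance(self, rng):
        from ciliaquant.polarity import PairedBasalUnit

        labels = np.ones((200, 200), dtype=int)
        n = 30
        bb = rng.uniform(50, 150, size=(n, 2))
        theta = rng.vonmises(0.5, 4.0, size=n)
        # image coords: angle theta displaces (-sin, +cos) in (y, x)
        feet = bb + 3.0 * np.column_stack([-np.sin(theta), np.cos(theta)])
        phi = 0.7

        def summarize(bbp, footp):
            pairs = [
                PairedBasalUnit(tuple(b), tuple(f),
                                math.atan2(-(f[0] - b[0]), f[1] - b[1]), 100.0)
                for b, f in zip(bbp, footp)
            ]
            (cell,) = cell_polarity(pairs, labels)
            return cell

        # rotate all coordinates by phi about the image centre; in y-down
        # (y, x) coordinates a CCW mathematical rotation is [[c, -s], [s, c]]
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        centre = np.array([100.0, 100.0])
        bb_r = (bb - centre) @ rot.T + centre
        feet_r = (feet - centre) @ rot.T + centre
        c0, c1 = summarize(bb, feet), summarize(bb_r, feet_r)
        assert c1.resultant_length == pytest.approx(c0.resultant_length, abs=1e-9)
        assert c1.circular_sd == pytest.approx(c0.circular_sd, abs=1e-9)
        assert c1.rayleigh_p == pytest.approx(c0.rayleigh_p, abs=1e-9)
        shift = np.angle(np.exp(1j * (c1.circular_mean - c0.circular_mean)))
        assert shift == pytest.approx(phi, abs=1e-9)
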