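"""Generator self-consistency: the rendered images match their ground truth."""

import numpy as np
import pandas as pd
import pytest

from ciliaquant.simulate import (
    BeadVideoSpec,
    CiliaVideoSpec,
    CiliationStackSpec,
    SpotFieldSpec,
    generate_bead_video,
    generate_cilia_video,
    generate_ciliation_stack,
    generate_spot_field,
    rect_motif,
)

from conftest import make_cbf_video


class TestCiliaVideo:
    def test_static_noiseless_frames_identical(self):
        spec = make_cbf_video([0.0], noise_sd=0.0)
        video, _, _ = generate_cilia_video(spec)
        assert np.array_equal(video.data, np.broadcast_to(video.data[0], video.data.shape))

    def test_beating_pixel_has_spectral_peak_at_truth(self):
        # 8 Hz at 100 fps over 200 frames: direct periodogram of the trace
        spec = make_cbf_video([8.0], phase_gradient=(0.0, 0.0))
        video, labels, _ = generate_cilia_video(spec)
        y, x = np.argwhere(labels == 1)[0]
        trace = video.data[:, y, x] - video.data[:, y, x].mean()
        power = np.abs(np.fft.rfft(trace)) ** 2
        freqs = np.fft.rfftfreq(200, d=0.01)
        assert freqs[np.argmax(power)] == pytest.approx(8.0)
        # 8 Hz at 100 fps = 12.5-frame period: trace repeats after 25 frames
        np.testing.assert_allclose(trace[:-25], trace[25:], atol=1e-9)

    def test_truth_table_echoes_spec(self):
        spec = make_cbf_video([5.0, 12.0])
        _, _, truth = generate_cilia_video(spec)
        assert truth["beat_frequency"].tolist() == [5.0, 12.0]
        assert truth["label"].tolist() == [1, 2]

    def test_nyquist_frequency_rejected(self):
        spec = make_cbf_video([50.0], fps=100.0)
        with pytest.raises(ValueError, match="alias"):
            generate_cilia_video(spec)

    def test_region_outside_image_rejected(self):
        cell = rect_motif(1, 0, 40, 0, 40, beat_frequency=5.0, amplitude=1.0)
        spec = CiliaVideoSpec(n_frames=32, fps=100.0, height=20, width=20, cells=[cell])
        with pytest.raises(ValueError, match="outside"):
            generate_cilia_video(spec)

    def test_seed_reproducibility(self):
        spec = make_cbf_video([8.0], noise_sd=50.0, seed=9)
        v1, _, _ = generate_cilia_video(spec)
        v2, _, _ = generate_cilia_video(spec)
        assert np.array_equal(v1.data, v2.data)
        spec_other = make_cbf_video([8.0], noise_sd=50.0, seed=10)
        v3, _, _ = generate_cilia_video(spec_other)
        assert not np.array_equal(v1.data, v3.data)


class TestSpotField:
    def test_degenerate_von_mises_concentrates_at_mu(self):
        spec = SpotFieldSpec(n_cells=1, spots_per_cell=20, kappa=1e6, mu_per_cell=0.0, seed=0)
        _, _, truth = generate_spot_field(spec)
        assert np.abs(truth["theta"]).max() < 1e-2

    def test_kappa_zero_is_uniform(self):
        # 10,000 draws from the generator: resultant length of a uniform
        # sample of size n concentrates near sqrt(pi)/2/sqrt(n) ~ 0.009
        thetas = []
        for seed in range(5):
            spec = SpotFieldSpec(
                n_cells=4, spots_per_cell=500, kappa=0.0, cell_size=220,
                min_separation=100.0, seed=seed,
            )
            _, _, truth = generate_spot_field(spec)
            thetas.append(truth["theta"].to_numpy())
        thetas = np.concatenate(thetas)
        assert len(thetas) == 10000
        assert np.abs(np.exp(1j * thetas).mean()) < 0.05

    def test_von_mises_mean_recovery(self):
        # kappa >= 4: circular mean of 10,000 draws within 2 degrees of mu
        mu = 0.8
        spec = SpotFieldSpec(
            n_cells=4, spots_per_cell=500, kappa=4.0, mu_per_cell=mu,
            cell_size=220, min_separation=100.0, seed=3,
        )
        _, _, t1 = generate_spot_field(spec)
        spec5 = SpotFieldSpec(
            n_cells=4, spots_per_cell=500, kappa=4.0, mu_per_cell=mu,
            cell_size=220, min_separation=100.0, seed=5,
        )
        _, _, t2 = generate_spot_field(spec5)
        thetas = np.concatenate([t1["theta"], t2["theta"]])[:10000]
        mean = np.angle(np.exp(1j * thetas).sum())
        assert abs(mean - mu) < np.deg2rad(2.0)

    def test_single_pair(self):
        spec = SpotFieldSpec(n_cells=1, spots_per_cell=1, seed=0)
        _, _, truth = generate_spot_field(spec)
        assert len(truth) == 1

    def test_pair_geometry_matches_offset(self):
        spec = SpotFieldSpec(n_cells=2, spots_per_cell=10, seed=1)
        _, _, truth = generate_spot_field(spec)
        d = np.hypot(truth.foot_y - truth.bb_y, truth.foot_x - truth.bb_x)
        np.testing.assert_allclose(d * spec.pixel_size, spec.foot_offset, rtol=1e-9)

    def test_rendered_peak_near_truth(self):
        spec = SpotFieldSpec(n_cells=1, spots_per_cell=1, noise_sd=0.0, seed=2)
        img, _, truth = generate_spot_field(spec)
        py, px = np.unravel_index(np.argmax(img[0]), img[0].shape)
        assert abs(py - truth.bb_y[0]) <= 0.5 and abs(px - truth.bb_x[0]) <= 0.5

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            generate_spot_field(SpotFieldSpec(kappa=-1.0))


class TestCiliationStack:
    def test_filament_count_follows_fraction(self):
        spec = CiliationStackSpec(n_basal_bodies=12, ciliated_fraction=0.5, seed=0)
        _, truth = generate_ciliation_stack(spec)
        assert truth["ciliated"].sum() == 6

    def test_straight_z_filament_spans_21_voxel_centers(self):
        spec = CiliationStackSpec(
            n_basal_bodies=1, ciliated_fraction=1.0, cilium_length=6.0,
            orientation_jitter=0.0, voxel_size=(0.3, 0.1, 0.1), seed=0,
        )
        stack, _ = generate_ciliation_stack(spec)
        zs = np.unique(np.argwhere(stack[1] > 0)[:, 0])
        assert len(zs) == 21  # 20 steps of 0.3 um = 6.0 um
        assert np.all(np.diff(zs) == 1)

    def test_zero_fraction_leaves_cilia_channel_empty(self):
        spec = CiliationStackSpec(ciliated_fraction=0.0, noise_sd=0.0, seed=1)
        stack, truth = generate_ciliation_stack(spec)
        assert not np.any(stack[1])
        assert truth["ciliated"].sum() == 0

    def test_cilium_outside_stack_rejected(self):
        spec = CiliationStackSpec(
            n_basal_bodies=1, ciliated_fraction=1.0, cilium_length=20.0,
            orientation_jitter=0.0, shape=(30, 128, 128), seed=0,
        )
        with pytest.raises(ValueError, match="outside"):
            generate_ciliation_stack(spec)

    def test_basal_body_channel_has_blobs(self):
        spec = CiliationStackSpec(seed=2)
        stack, truth = generate_ciliation_stack(spec)
        assert len(truth) == spec.n_basal_bodies
        vox = np.asarray(spec.voxel_size)
        for _, row in truth.iterrows():
            pos = np.round(np.array([row.z_um, row.y_um, row.x_um]) / vox).astype(int)
            assert stack[0][tuple(pos)] > 0.5 * spec.amplitude


class TestBeadVideo:
    def test_pure_drift_step_is_exact(self):
        spec = BeadVideoSpec(n_beads=3, drift_velocity=(0.0, 2.0), diffusion_coeff=0.0,
                             fps=10.0, n_frames=10, seed=0)
        _, truth = generate_bead_video(spec)
        for _, trk in truth.groupby("bead"):
            steps = trk[["y_um", "x_um"]].diff().dropna()
            np.testing.assert_allclose(steps["x_um"], 0.2, rtol=1e-12)
            np.testing.assert_allclose(steps["y_um"], 0.0, atol=1e-12)

    def test_pure_diffusion_has_zero_mean_displacement(self):
        nets = []
        for seed in range(10):
            spec = BeadVideoSpec(n_beads=40, drift_velocity=(0.0, 0.0), diffusion_coeff=0.05,
                                 fps=10.0, n_frames=20, seed=seed)
            _, truth = generate_bead_video(spec)
            for _, trk in truth.groupby("bead"):
                nets.append(trk[["y_um", "x_um"]].iloc[-1].to_numpy()
                            - trk[["y_um", "x_um"]].iloc[0].to_numpy())
        nets = np.asarray(nets)
        # net displacement ~ N(0, 2 D T) per axis; |mean| < 3 SE
        se = nets.std(axis=0, ddof=1) / np.sqrt(len(nets))
        assert np.all(np.abs(nets.mean(axis=0)) < 3 * se)

    def test_no_beads_gives_empty_output(self):
        spec = BeadVideoSpec(n_beads=0, seed=0)
        video, truth = generate_bead_video(spec)
        assert len(truth) == 0
        assert np.all(video.data == spec.background_level)

    def test_escaping_bead_is_truncated_and_flagged(self):
        spec = BeadVideoSpec(n_beads=5, drift_velocity=(0.0, 10.0), diffusion_coeff=0.0,
                             fps=10.0, n_frames=40, seed=1)
        _, truth = generate_bead_video(spec)
        last = truth.groupby("bead")["frame"].max()
        assert (last < spec.n_frames - 1).any()
        assert truth.loc[truth["bead"].map(last < spec.n_frames - 1), "truncated"].all()
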