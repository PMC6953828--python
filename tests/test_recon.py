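import numpy as np
import pytest

from eitptx import forward as fw
from eitptx import recon as rc
from eitptx import detect as det


@pytest.fixture(scope="module")
def sigma_ref(phantom):
    sig = np.where(phantom.body_mask, phantom.background_conductivity, 1.0)
    return sig


class TestJacobian:
    def test_shape(self, ctx, sigma_ref, phantom):
        J, fs = rc.jacobian(sigma_ref, phantom.body_mask, ctx.belt)
        assert J.shape == (208, int(phantom.body_mask.sum()))

    def test_adjoint_matches_perturbation(self, ctx, sigma_ref, phantom, rng):
        J, fs = rc.jacobian(sigma_ref, phantom.body_mask, ctx.belt)
        f0 = fw.acquire_frame(sigma_ref, phantom.body_mask, ctx.belt, solver=fs).measurements
        for p in rng.choice(fs.n_pix, 10, replace=False):
            sig = sigma_ref.copy()
            r, c = fs.pixel_coords[p]
            sig[r, c] += 1e-4
            f1 = fw.acquire_frame(sig, phantom.body_mask, ctx.belt, solver=fs).measurements
            fd = (f1 - f0) / 1e-4
            assert np.abs(fd - J[:, p]).max() <= 0.01 * np.abs(fd).max()

    def test_boundary_pixel_more_sensitive_than_center(self, ctx, sigma_ref, phantom):
        J, fs = rc.jacobian(sigma_ref, phantom.body_mask, ctx.belt)
        cy, cx = phantom.body_center
        center_pix = np.argmin(((fs.pixel_coords - [cy, cx]) ** 2).sum(axis=1))
        near_pix = np.argmin(((fs.pixel_coords - ctx.belt.points[4]) ** 2).sum(axis=1))
        assert np.abs(J[:, near_pix]).max() > np.abs(J[:, center_pix]).max()


class TestReconstructDifference:
    def test_null_difference_exactly_zero(self, ctx, rng):
        frame = rng.normal(size=208)
        img = rc.reconstruct_difference(frame, frame.copy(), ctx.recon_op)
        assert np.all(img == 0.0)

    def test_zero_outside_mask(self, ctx, rng):
        img = rc.reconstruct_difference(rng.normal(size=208), rng.normal(size=208), ctx.recon_op)
        assert np.all(img[~ctx.recon_op.mask] == 0.0)
        assert np.isfinite(img).all()

    def test_linear_in_difference(self, ctx, rng):
        ref = rng.normal(size=208)
        d = rng.normal(size=208)
        img1 = rc.reconstruct_difference(ref - d, ref, ctx.recon_op)
        img2 = rc.reconstruct_difference(ref - 2 * d, ref, ctx.recon_op)
        assert np.allclose(img2, 2 * img1, atol=1e-12)

    def test_shape_mismatch_rejected(self, ctx):
        with pytest.raises(ValueError):
            rc.reconstruct_difference(np.zeros(100), np.zeros(208), ctx.recon_op)

    def test_regularization_limit_shrinks_norm(self, phantom, ctx, sigma_ref, rng):
        frame = fw.acquire_frame(sigma_ref, phantom.body_mask, ctx.belt).measurements
        sig2 = sigma_ref.copy()
        sig2[phantom.lung_mask] *= 0.8
        frame2 = fw.acquire_frame(sig2, phantom.body_mask, ctx.belt).measurements
        norms = []
        for lam_rel in (0.03, 0.3, 3.0):
            op = rc.build_recon_operator(sigma_ref, phantom.body_mask, ctx.belt, lam_rel=lam_rel)
            norms.append(np.linalg.norm(rc.reconstruct_difference(frame2, frame, op)))
        assert norms[0] > norms[1] > norms[2]

    def test_orientation_ventral_right_lesion(self, ctx, lesion_case, reference):
        """Guard against the classic EIT left/right flip: a segment-2 (ventral,
        animal's right) lesion must be flagged in the ventral-right quadrant."""
        result = det.detect_ptx(lesion_case.tidal, reference, segment_labels=ctx.segment_labels32)
        assert result.is_positive
        centroid = np.argwhere(result.region_mask).mean(axis=0)
        assert centroid[0] < 16  # ventral half (row 0 = ventral)
        assert centroid[1] < 16  # animal's right = image left


class TestDetectBreaths:
    def test_sinusoid_breath_count(self):
        # 62.5 s so the 20th breath's end-inspiration peak is not clipped by
        # the record edge (edge peaks lose their prominence).
        fr = 25.0
        t = np.arange(int(62.5 * fr)) / fr
        x = np.sin(2 * np.pi * (20 / 60) * t)
        seg = rc.detect_breaths(rc.ROIWaveform("global", x, fr))
        assert len(seg) == 20

    def test_constant_signal_empty(self):
        seg = rc.detect_breaths(rc.ROIWaveform("global", np.ones(500), 25.0))
        assert len(seg) == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rc.detect_breaths(rc.ROIWaveform("global", np.ones(10), 25.0))

    def test_robust_to_cardiac_spikes(self):
        fr = 50.0
        t = np.arange(int(62.5 * fr)) / fr
        x = 10 * np.sin(2 * np.pi * (20 / 60) * t)
        for b in range(int(62.5 / (60 / 90))):
            f0 = int(round(b * (60 / 90) * fr))
            if f0 + 1 < len(x):
                x[f0 : f0 + 2] -= 1.0  # 10% of tidal swing
        seg = rc.detect_breaths(rc.ROIWaveform("global", x, fr))
        assert len(seg) == 20

    def test_indices_ordered(self, lesion_case):
        flat = [i for pair in lesion_case.breaths for i in pair]
        assert all(b > a for a, b in zip(flat, flat[1:]))


class TestTidalImage:
    def test_degenerate_breath_zero(self, healthy_case):
        img = rc.tidal_image(healthy_case.images, (3, 3))
        assert np.all(img == 0.0)

    def test_out_of_range_rejected(self, healthy_case):
        with pytest.raises(IndexError):
            rc.tidal_image(healthy_case.images, (0, 10**6))

    def test_healthy_tidal_positive_over_lung(self, ctx, healthy_case):
        lung32 = ctx.segment_labels32 > 0
        assert healthy_case.tidal[lung32].sum() > 0

    def test_lesion_footprint_deficit(self, ctx, healthy_case, lesion_case):
        lesion = lesion_case.truth.lesions[0]
        fp = rc.project_to_recon_grid(
            lesion.in_plane_mask.astype(float), ctx.phantom.body_mask
        ) > 0.5
        assert lesion_case.tidal[fp].sum() < healthy_case.tidal[fp].sum()


class TestQuadrantWaveforms:
    def test_partition_conservation(self, healthy_case):
        waves = healthy_case.waveforms
        total = sum(
            waves[q].samples
            for q in ("ventral-right", "ventral-left", "dorsal-right", "dorsal-left")
        )
        assert np.abs(total - waves["global"].samples).max() < 1e-9

    def test_zero_images_zero_waveforms(self):
        waves = rc.quadrant_waveforms(np.zeros((5, 32, 32)), 10.0)
        for w in waves.values():
            assert np.all(w.samples == 0.0)

    def test_quadrants_partition_mask(self):
        quads = rc.quadrant_masks()
        combined = np.zeros((32, 32), dtype=int)
        for m in quads.values():
            combined += m.astype(int)
        assert np.array_equal(combined > 0, rc.circular_mask())
        assert combined.max() == 1

    def test_lesion_reduces_ventral_right_amplitude(self, healthy_case, lesion_case):
        def swing(case):
            s = case.waveforms["ventral-right"].samples
            return np.percentile(s, 95) - np.percentile(s, 5)

        assert swing(lesion_case) < swing(healthy_case)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rc.quadrant_waveforms(np.empty((0, 32, 32)), 10.0)


def synthetic_stack(n=300, fr=10.0, f_resp=0.33, lag_region=None, lag=0.0):
    """Image stack with uniform in-phase oscillation over the mask, optionally
    phase-lagged in a sub-region; amplitude zero outside the mask."""
    mask = rc.circular_mask()
    t = np.arange(n) / fr
    images = np.zeros((n, 32, 32))
    base = np.sin(2 * np.pi * f_resp * t)
    images[:, mask] = base[:, None]
    if lag_region is not None:
        lagged = np.sin(2 * np.pi * f_resp * t - lag)
        images[:, lag_region & mask] = lagged[:, None]
    g = rc.ROIWaveform("global", images[:, mask].sum(axis=1), fr)
    return images, g, mask


class TestPhaseMap:
    def test_homogeneous_synchrony(self):
        images, g, mask = synthetic_stack()
        pm = rc.phase_map(images, g)
        vals = pm[mask]
        assert np.all(np.abs(vals[~np.isnan(vals)]) < 0.1)

    def test_injected_lag_recovered(self):
        region = np.zeros((32, 32), dtype=bool)
        region[8:14, 8:14] = True
        images, g, mask = synthetic_stack(lag_region=region, lag=np.pi / 2)
        pm = rc.phase_map(images, g)
        vals = pm[region & mask]
        assert np.nanmedian(vals) == pytest.approx(np.pi / 2, abs=0.2)

    def test_zero_amplitude_flagged_undefined(self):
        images, g, mask = synthetic_stack()
        pm = rc.phase_map(images, g)
        assert np.isnan(pm[~mask]).all()

    def test_no_peak_rejected(self):
        images = np.zeros((100, 32, 32))
        g = rc.ROIWaveform("global", np.zeros(100), 10.0)
        with pytest.raises(ValueError):
            rc.phase_map(images, g)

    def test_pipeline_lagged_lesion_detected_as_asynchronous(self, ctx):
        from eitptx import harness as hz
        from eitptx import phantom as ph

        dyn = ph.DynamicsConfig(
            frame_rate=15, duration=12, lesion_ventilation_fraction=1.0,
            lesion_phase_lag=np.pi / 2, seed=3, noise_sd_frac=0.005,
        )
        case = hz.simulate_case(ctx, hz.CaseSetup("lagged", 2, 0.25, 6.0, dyn))
        fp = rc.project_to_recon_grid(
            case.truth.lesions[0].in_plane_mask.astype(float), ctx.phantom.body_mask
        ) > 0.5
        pm = rc.phase_map(case.images, case.waveforms["global"])
        # Reconstruction blur mixes the synchronous surround into the lesion,
        # biasing the recovered lag low; require a clearly positive lag.
        assert np.nanmedian(pm[fp]) > 0.5


class TestProjection:
    def test_forward_pixels_land_in_mask(self, ctx, phantom):
        labels32 = rc.project_labels(np.zeros(phantom.grid_shape, dtype=int), phantom.body_mask)
        assert labels32.shape == rc.RECON_SHAPE

    def test_segment_projection_preserves_all_segments(self, ctx):
        present = set(np.unique(ctx.segment_labels32[ctx.segment_labels32 > 0]))
        assert present == set(range(1, 11))
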