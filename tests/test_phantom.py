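import numpy as np
import pytest
from scipy import ndimage

from eitptx import phantom as ph


class TestBuildPhantom:
    def test_sternovertebral_distance_from_geometry(self):
        p = ph.build_phantom(grid_shape=(64, 64), pixel_size=0.5, body_axes_px=(28, 22))
        assert p.sternovertebral_distance == pytest.approx(11.0)

    def test_determinism(self):
        a = ph.build_phantom(seed=3)
        b = ph.build_phantom(seed=3)
        assert np.array_equal(a.body_mask, b.body_mask)
        assert np.array_equal(a.heart_mask, b.heart_mask)
        for k in a.lung_masks:
            assert np.array_equal(a.lung_masks[k], b.lung_masks[k])

    def test_lung_area_fraction(self, phantom):
        frac = phantom.lung_mask.sum() / phantom.body_mask.sum()
        assert 0.25 <= frac <= 0.55

    def test_masks_disjoint_and_contained(self, phantom):
        lung = phantom.lung_mask
        assert not (lung & phantom.heart_mask).any()
        assert (lung & ~phantom.body_mask).sum() == 0
        assert (phantom.heart_mask & ~phantom.body_mask).sum() == 0
        masks = list(phantom.lung_masks.values())
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not (masks[i] & masks[j]).any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"grid_shape": (16, 64)},
            {"pixel_size": 0.0},
            {"background_conductivity": -1.0},
            {"body_axes_px": (100.0, 44.0)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ph.build_phantom(**kwargs)


class TestSegmentMap:
    def test_labels_partition_lung(self, phantom):
        labels = ph.segment_map(phantom)
        lung = phantom.lung_mask
        assert (labels[lung] > 0).all()
        assert (labels[~lung] == 0).all()

    def test_every_segment_nonempty(self, phantom):
        labels = ph.segment_map(phantom)
        assert set(np.unique(labels[labels > 0])) == set(range(1, 11))

    def test_anterior_segments_ventral(self, phantom):
        labels = ph.segment_map(phantom)
        cy, _ = phantom.body_center
        rr, _ = np.nonzero(np.isin(labels, list(ph.ANTERIOR_SEGMENTS)))
        assert rr.max() < cy

    def test_accessory_segment_ventromedial(self, phantom):
        labels = ph.segment_map(phantom)
        cy, cx = phantom.body_center
        centroid = np.argwhere(labels == ph.ACCESSORY_SEGMENT).mean(axis=0)
        assert centroid[0] < cy  # ventral half
        half_width = (phantom.body_mask.any(axis=0).sum()) / 2.0
        assert abs(centroid[1] - cx) <= 0.25 * half_width

    def test_stable_across_runs(self, phantom):
        assert np.array_equal(ph.segment_map(phantom), ph.segment_map(phantom))

    def test_adjacency_symmetric(self, phantom):
        adj = ph.segment_adjacency(ph.segment_map(phantom))
        for s, neigh in adj.items():
            for t in neigh:
                assert s in adj[t]


class TestPlaceLesion:
    def test_diameter_matches_request(self, phantom):
        lesion = ph.place_lesion(phantom, 2, 0.25, 4.0, seed=1)
        target = 0.25 * phantom.sternovertebral_distance
        assert abs(lesion.transversal_diameter - target) <= phantom.pixel_size

    def test_small_phantom_example(self):
        p = ph.build_phantom(grid_shape=(64, 64), pixel_size=0.5, body_axes_px=(56, 44))
        lesion = ph.place_lesion(p, 2, 0.25, 4.0, seed=0)
        assert abs(lesion.transversal_diameter - 0.25 * p.sternovertebral_distance) <= 0.5

    def test_oversized_lesion_rejected(self, phantom):
        with pytest.raises(ph.LesionFitError, match="does not fit"):
            ph.place_lesion(phantom, 1, 10.0, 2.0, seed=0)

    def test_determinism(self, phantom):
        a = ph.place_lesion(phantom, 3, 0.2, 3.0, seed=7)
        b = ph.place_lesion(phantom, 3, 0.2, 3.0, seed=7)
        assert np.array_equal(a.in_plane_mask, b.in_plane_mask)

    def test_mask_connected_inside_body(self, phantom):
        for seg in (1, 2, 5, 6, 9):
            lesion = ph.place_lesion(phantom, seg, 0.2, 3.0, seed=2)
            assert not (lesion.in_plane_mask & ~phantom.body_mask).any()
            _, n = ndimage.label(lesion.in_plane_mask)
            assert n == 1


class TestClassifyRelevance:
    def test_boundary_is_strict(self):
        lesion = _lesion_stub(trans=2.2, cc=2.0)
        lab = ph.classify_relevance(lesion, 11.0)
        assert not lab.is_trans20 and not lab.is_cc3
        assert not lab.is_transcc and not lab.is_relevant

    def test_both_rules(self):
        lab = ph.classify_relevance(_lesion_stub(trans=2.75, cc=4.0), 11.0)
        assert lab.is_trans20 and lab.is_cc3 and lab.is_transcc and lab.is_relevant

    def test_cc3_only(self):
        lab = ph.classify_relevance(_lesion_stub(trans=1.0, cc=3.5), 11.0)
        assert lab.is_cc3 and not lab.is_trans20 and not lab.is_transcc
        assert lab.is_relevant

    def test_position_invariance(self, phantom):
        # Same diameters, different segments -> identical labels.
        a = ph.place_lesion(phantom, 2, 0.22, 3.5, seed=1)
        b = ph.place_lesion(phantom, 9, 0.22, 3.5, seed=5)
        sv = phantom.sternovertebral_distance
        la, lb = ph.classify_relevance(a, sv), ph.classify_relevance(b, sv)
        assert (la.is_trans20, la.is_cc3) == (lb.is_trans20, lb.is_cc3)


def _lesion_stub(trans: float, cc: float) -> ph.PTXLesion:
    mask = np.zeros((4, 4), dtype=bool)
    mask[1, 1] = True
    return ph.PTXLesion(
        segment_id=1, center=(1.0, 1.0), transversal_diameter=trans,
        craniocaudal_extent=cc, in_plane_mask=mask,
    )


class TestPartialVolumeWeight:
    @pytest.mark.parametrize("cc,expected", [(0.0, 0.0), (3.0, 0.5), (6.0, 1.0), (9.0, 1.0)])
    def test_formula(self, cc, expected):
        assert ph.partial_volume_weight(cc, 3.0) == pytest.approx(expected)

    def test_monotone_and_bounded(self):
        grid = np.linspace(0, 12, 40)
        w = [ph.partial_volume_weight(c) for c in grid]
        assert all(0.0 <= x <= 1.0 for x in w)
        assert all(b >= a for a, b in zip(w, w[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ph.partial_volume_weight(-1.0)


class TestConductivitySeries:
    def test_static_limit(self, phantom):
        dyn = ph.DynamicsConfig(
            frame_rate=10, duration=1, tidal_modulation=0.0, noise_sd_frac=0.0
        )
        series = ph.conductivity_series(phantom, [], dyn)
        assert np.allclose(series.fields, series.fields[0])

    def test_respiratory_period_count(self, phantom):
        dyn = ph.DynamicsConfig(
            frame_rate=20, duration=60, respiratory_rate=20, noise_sd_frac=0.0
        )
        series = ph.conductivity_series(phantom, [], dyn)
        lung_mean = series.fields[:, phantom.lung_mask].mean(axis=1)
        spectrum = np.abs(np.fft.rfft(lung_mean - lung_mean.mean()))
        assert np.argmax(spectrum) == 20  # 20 cycles in the record

    def test_seed_reproducible(self, phantom):
        dyn = ph.DynamicsConfig(frame_rate=10, duration=2, seed=5)
        a = ph.conductivity_series(phantom, [], dyn)
        b = ph.conductivity_series(phantom, [], dyn)
        assert np.array_equal(a.fields, b.fields)

    def test_lesion_static_when_unventilated(self, phantom):
        lesion = ph.place_lesion(phantom, 2, 0.25, 6.0, seed=1)  # weight 1
        dyn = ph.DynamicsConfig(
            frame_rate=10, duration=3, lesion_ventilation_fraction=0.0, noise_sd_frac=0.0
        )
        series = ph.conductivity_series(phantom, [lesion], dyn)
        assert series.fields[:, lesion.in_plane_mask].std(axis=0).max() == pytest.approx(0.0)

    def test_spike_event_count(self, phantom):
        lesion = ph.place_lesion(phantom, ph.ACCESSORY_SEGMENT, 0.25, 6.0, seed=1)
        dyn = ph.DynamicsConfig(
            frame_rate=50, duration=60, spike_enabled=True, heart_rate=96, seed=2
        )
        series = ph.conductivity_series(phantom, [lesion], dyn)
        assert abs(len(series.spike_frames) - 96) <= 1

    def test_spikes_require_lesion(self, phantom):
        dyn = ph.DynamicsConfig(frame_rate=10, duration=1, spike_enabled=True)
        with pytest.raises(ValueError, match="lesion"):
            ph.conductivity_series(phantom, [], dyn)


class TestCaseTruth:
    def test_no_lesion(self, phantom):
        truth = ph.case_truth(phantom, [])
        assert truth.largest_relevant_segment is None
        assert truth.quadrant_labels == set()
        assert not truth.heart_contact

    def test_relevant_lesion_reported(self, phantom):
        lesion = ph.place_lesion(phantom, 2, 0.25, 6.0, seed=1)
        truth = ph.case_truth(phantom, [lesion])
        assert truth.largest_relevant_segment == 2
        assert truth.labels[0].is_transcc

    def test_heart_contact_near_accessory(self, phantom):
        lesion = ph.place_lesion(phantom, ph.ACCESSORY_SEGMENT, 0.25, 6.0, seed=1)
        truth = ph.case_truth(phantom, [lesion])
        assert truth.heart_contact

    def test_lateral_lesion_no_heart_contact(self, phantom):
        lesion = ph.place_lesion(phantom, 1, 0.15, 2.0, seed=1)
        truth = ph.case_truth(phantom, [lesion])
        assert not truth.heart_contact
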