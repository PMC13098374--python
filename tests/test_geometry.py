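"""Saddle-ring reconstruction and the annular metric panel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from madct.geometry import (
    AnnulusLandmarkSet,
    DegenerateLandmarksError,
    annulus_area,
    annulus_metrics,
    aortoparietal_distance,
    intercommissural_distance,
    leaflet_annulus_index,
    LeafletMeasurement,
    resample_ring,
    sphericity_index,
    trigone_distance,
)
from madct.phases import PhaseLabel

from conftest import random_rigid, saddle_markers


def dense_polygon_area(a, b, h, n=100_000):
    """Independent area oracle: shoelace on n analytic curve points projected
    onto the symmetry plane z=0 (the exact best-fit plane of this family)."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x, y = a * np.cos(th), b * np.sin(th)
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class TestLandmarkValidation:
    def test_wrong_marker_count_rejected(self):
        with pytest.raises(ValueError, match="16 markers"):
            AnnulusLandmarkSet("s", "pre", "ES", np.zeros((15, 3)), (0, 8))

    def test_coincident_consecutive_markers_rejected(self):
        m = saddle_markers(6, 6.5, 1)
        m[5] = m[4]
        with pytest.raises(DegenerateLandmarksError):
            AnnulusLandmarkSet("s", "pre", "ES", m, (1, 15))

    @pytest.mark.parametrize("trigones", [(3, 3), (-1, 5), (0, 16)])
    def test_bad_trigone_indices_rejected(self, trigones):
        with pytest.raises(ValueError, match="trigone"):
            AnnulusLandmarkSet("s", "pre", "ES", saddle_markers(6, 6.5, 1), trigones)

    def test_minimum_resampling_density_enforced(self, make_saddle_landmarks):
        with pytest.raises(ValueError, match="64"):
            resample_ring(make_saddle_landmarks(), M=32)


class TestRingReconstruction:
    def test_circle_interpolated_within_tenth_of_mm(self, make_saddle_landmarks):
        ring = resample_ring(make_saddle_landmarks(a=10, b=10, h=1e-9))
        radii = np.linalg.norm(ring.curve[:, :2], axis=1)
        assert np.all(np.abs(radii - 10.0) < 0.1)
        assert np.all(np.abs(ring.curve[:, 2]) < 0.1)

    def test_saddle_plane_normal_is_z_by_symmetry(self, make_saddle_landmarks):
        ring = resample_ring(make_saddle_landmarks(a=6, b=6.5, h=1))
        assert abs(abs(ring.plane_normal[2]) - 1.0) < 1e-6
        # winding CCW from atrium orients the normal toward +z
        assert ring.plane_normal[2] > 0

    def test_portions_partition_curve_and_aortic_is_trigone_arc(self, make_saddle_landmarks):
        ring = resample_ring(make_saddle_landmarks(trigones=(1, 15)))
        assert ring.is_aortic.any() and (~ring.is_aortic).any()
        # the aortic portion is the short arc through θ=0 between the trigones
        aortic_angles = np.arctan2(ring.curve[ring.is_aortic, 1] / 6.5, ring.curve[ring.is_aortic, 0] / 6.0)
        assert np.max(np.abs(aortic_angles)) < 0.5

    def test_self_intersecting_projection_flagged_not_fatal(self):
        m = saddle_markers(10, 10, 1e-9)
        m[[3, 4]] = m[[4, 3]]  # swap two markers to force a crossing
        ring = resample_ring(AnnulusLandmarkSet("s", "pre", "ES", m, (1, 15)))
        assert ring.self_intersecting
        assert annulus_area(ring) > 0

    def test_smooth_ring_is_not_flagged(self, make_saddle_landmarks):
        assert not resample_ring(make_saddle_landmarks()).self_intersecting


class TestMetricPanel:
    def test_circle_area_matches_pi_r_squared(self, make_saddle_landmarks):
        ring = resample_ring(make_saddle_landmarks(a=10, b=10, h=1e-9))
        assert annulus_area(ring) == pytest.approx(np.pi * 100.0, rel=0.01)

    @pytest.mark.parametrize("a,b,h", [(12.5, 10, 1e-9), (12.5, 10, 3.0), (6, 6.5, 1.0), (5, 9, 2.0)])
    def test_area_matches_ellipse_and_dense_polygon_oracle(self, make_saddle_landmarks, a, b, h):
        maa = annulus_area(resample_ring(make_saddle_landmarks(a=a, b=b, h=h)))
        assert maa == pytest.approx(np.pi * a * b, rel=0.01)
        assert maa == pytest.approx(dense_polygon_area(a, b, h), rel=0.01)

    def test_projection_removes_saddle_height_from_area(self, make_saddle_landmarks):
        flat = annulus_area(resample_ring(make_saddle_landmarks(a=12.5, b=10, h=1e-9)))
        tall = annulus_area(resample_ring(make_saddle_landmarks(a=12.5, b=10, h=3.0)))
        assert tall == pytest.approx(flat, rel=0.01)

    def test_apd_is_horn_to_horn_in_plane_distance(self, make_saddle_landmarks):
        ring = resample_ring(make_saddle_landmarks(a=6, b=6.5, h=1))
        apd, (aortic, parietal) = aortoparietal_distance(ring)
        assert apd == pytest.approx(12.0, rel=0.01)
        assert aortic[0] > 0 > parietal[0]  # horns at θ=0 and θ=π

    def test_flat_ring_fallback_recovers_same_axis(self, make_saddle_landmarks):
        ring = resample_ring(make_saddle_landmarks(a=6, b=6.5, h=1e-9))
        apd, _ = aortoparietal_distance(ring)
        assert apd == pytest.approx(12.0, rel=0.01)

    def test_icd_is_caliper_width_orthogonal_to_apd(self, make_saddle_landmarks):
        ring = resample_ring(make_saddle_landmarks(a=6, b=6.5, h=1))
        assert intercommissural_distance(ring, np.array([1.0, 0, 0])) == pytest.approx(13.0, rel=0.01)

    def test_circle_icd_equals_apd(self, make_saddle_landmarks):
        m = annulus_metrics(make_saddle_landmarks(a=10, b=10, h=1e-9))
        assert m.icd == pytest.approx(20.0, rel=0.01)
        assert m.apd == pytest.approx(m.icd, rel=0.01)

    def test_trigone_distance_is_3d_chord(self):
        markers = saddle_markers(6, 6.5, 1)
        markers[0] = [0, 0, 0]
        markers[8] = [6, 0, 0]
        lm = AnnulusLandmarkSet("s", "pre", "ES", markers, (0, 8))
        assert trigone_distance(lm) == pytest.approx(6.0)

    def test_trigone_distance_matches_parametrization(self, make_saddle_landmarks):
        # markers 3 and 13 sit at θ=±3π/8; chord = 2·b·sin(3π/8) on this family
        lm = make_saddle_landmarks(a=6, b=6.5, h=1, trigones=(3, 13))
        assert trigone_distance(lm) == pytest.approx(2 * 6.5 * np.sin(3 * np.pi / 8), rel=1e-12)

    def test_sphericity_index_table_values(self):
        assert sphericity_index(10.0, 10.0) == pytest.approx(1.0)
        assert round(sphericity_index(10.96, 11.32), 2) == 0.97
        assert round(sphericity_index(9.75, 11.18), 2) == 0.87
        with pytest.raises(ValueError):
            sphericity_index(10.0, 0.0)

    def test_leaflet_annulus_index(self):
        leaf = LeafletMeasurement(8.0, 7.0)
        assert leaf.tll == pytest.approx(15.0)
        assert leaflet_annulus_index(leaf, 12.0) == pytest.approx(1.25)
        assert leaflet_annulus_index(LeafletMeasurement(6.0, 6.0), 12.0) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="late-systolic"):
            leaflet_annulus_index(LeafletMeasurement(8.0, 7.0, phase=PhaseLabel.ES), 12.0)
        with pytest.raises(ValueError):
            leaflet_annulus_index(leaf, 0.0)

    def test_monotone_in_semiaxis_a(self, make_saddle_landmarks):
        apds, maas = [], []
        for a in (5.0, 6.0, 7.0, 8.0):
            m = annulus_metrics(make_saddle_landmarks(a=a, b=6.5, h=1))
            apds.append(m.apd)
            maas.append(m.maa)
        assert np.all(np.diff(apds) > 0)
        assert np.all(np.diff(maas) > 0)


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), a=st.floats(4, 12), ratio=st.floats(0.7, 1.4), h=st.floats(0.2, 3))
    def test_rigid_motion_invariance(self, seed, a, ratio, h):
        b = a * ratio
        markers = saddle_markers(a, b, h)
        base = annulus_metrics(AnnulusLandmarkSet("s", "pre", "ES", markers, (1, 15)))
        rot, trans = random_rigid(np.random.default_rng(seed))
        moved = annulus_metrics(
            AnnulusLandmarkSet("s", "pre", "ES", markers @ rot.T + trans, (1, 15))
        )
        for attr in ("maa", "apd", "icd", "ttd", "si"):
            assert getattr(moved, attr) == pytest.approx(getattr(base, attr), rel=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(scale=st.floats(0.2, 5.0))
    def test_scale_equivariance(self, scale):
        markers = saddle_markers(6, 6.5, 1)
        base = annulus_metrics(AnnulusLandmarkSet("s", "pre", "ES", markers, (1, 15)))
        scaled = annulus_metrics(AnnulusLandmarkSet("s", "pre", "ES", markers * scale, (1, 15)))
        assert scaled.apd == pytest.approx(base.apd * scale, rel=1e-9)
        assert scaled.icd == pytest.approx(base.icd * scale, rel=1e-9)
        assert scaled.ttd == pytest.approx(base.ttd * scale, rel=1e-9)
        assert scaled.maa == pytest.approx(base.maa * scale**2, rel=1e-9)
        assert scaled.si == pytest.approx(base.si, rel=1e-9)

    def test_curve_transforms_with_the_markers(self, make_saddle_landmarks):
        lm = make_saddle_landmarks()
        ring = resample_ring(lm)
        rot, trans = random_rigid(np.random.default_rng(3))
        moved = resample_ring(
            AnnulusLandmarkSet("s", "pre", "ES", lm.markers @ rot.T + trans, (1, 15))
        )
        np.testing.assert_allclose(moved.curve, ring.curve @ rot.T + trans, atol=1e-9)
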