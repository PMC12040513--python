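import numpy as np
import pytest
from conftest import axis_angle_deg, digitize_ellipsoid

from lesiondir.direction_fields import FeatureAxes, orthogonal_vein_axis
from lesiondir.io_core import ImageVolume, VectorVolume
from lesiondir.longitudinal import (
    classify_change_direction,
    classify_dynamics,
    compute_mtr,
    expansion_axis,
    jacobian_determinant,
    lesion_mean_jacobian,
    lesion_mtr_change,
)


def world_grid(shape, affine=None):
    affine = np.eye(4) if affine is None else affine
    g = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
    return g @ affine[:3, :3].T + affine[:3, 3]


class TestComputeMTR:
    def test_forty_pu(self):
        off = ImageVolume(np.full((3, 3, 3), 1.0), np.eye(4))
        on = ImageVolume(np.full((3, 3, 3), 0.6), np.eye(4))
        np.testing.assert_allclose(compute_mtr(off, on).data, 40.0)

    def test_equal_images_give_zero(self):
        off = ImageVolume(np.full((3, 3, 3), 2.0), np.eye(4))
        np.testing.assert_allclose(compute_mtr(off, off).data, 0.0)

    def test_zero_off_is_undefined_not_an_exception(self):
        off = ImageVolume(np.zeros((3, 3, 3)), np.eye(4))
        on = ImageVolume(np.ones((3, 3, 3)), np.eye(4))
        out = compute_mtr(off, on)
        assert np.isnan(out.data).all()

    def test_grid_mismatch_raises(self):
        off = ImageVolume(np.ones((3, 3, 3)), np.eye(4))
        on = ImageVolume(np.ones((4, 3, 3)), np.eye(4))
        with pytest.raises(ValueError):
            compute_mtr(off, on)


class TestJacobianDeterminant:
    def test_zero_field_is_identity(self):
        fld = VectorVolume(np.zeros((5, 5, 5, 3)), np.eye(4), semantics="displacement")
        np.testing.assert_allclose(jacobian_determinant(fld).data, 1.0, atol=1e-12)

    @pytest.mark.parametrize("s", [1.08, 0.9, 1.3])
    def test_uniform_1d_stretch(self, s):
        pts = world_grid((9, 9, 9))
        u = np.zeros_like(pts)
        u[..., 0] = (s - 1.0) * pts[..., 0]
        fld = VectorVolume(u, np.eye(4), semantics="displacement")
        det = jacobian_determinant(fld).data
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], s, atol=1e-6)

    def test_isotropic_stretch_cubes(self):
        s = 1.05
        pts = world_grid((9, 9, 9))
        u = (s - 1.0) * pts
        fld = VectorVolume(u, np.eye(4), semantics="displacement")
        det = jacobian_determinant(fld).data
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], s**3, atol=1e-6)

    def test_anisotropic_grid_uses_world_spacing(self):
        s = 1.2
        affine = np.diag([1.0, 1.0, 2.5, 1.0])
        pts = world_grid((9, 9, 9), affine)
        u = np.zeros_like(pts)
        u[..., 2] = (s - 1.0) * pts[..., 2]
        fld = VectorVolume(u, affine, semantics="displacement")
        det = jacobian_determinant(fld).data
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], s, atol=1e-6)

    def test_global_translation_changes_nothing(self):
        rng = np.random.default_rng(0)
        u = rng.normal(scale=0.05, size=(7, 7, 7, 3))
        d1 = jacobian_determinant(VectorVolume(u, np.eye(4), semantics="displacement"))
        d2 = jacobian_determinant(
            VectorVolume(u + np.array([3.0, -2.0, 1.0]), np.eye(4), semantics="displacement")
        )
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)

    def test_too_small_grid_raises(self):
        fld = VectorVolume(np.zeros((2, 5, 5, 3)), np.eye(4), semantics="displacement")
        with pytest.raises(ValueError):
            jacobian_determinant(fld)


class TestClassifyDynamics:
    def test_one_sd_rule_isolates_outliers(self):
        vals = {i: 1.0 for i in range(98)}
        vals[98], vals[99] = 1.3, 0.7
        out = classify_dynamics(vals, k=1.0)
        assert out[98] == "expanding" and out[99] == "contracting"
        assert sum(c == "stable" for c in out.values()) == 98

    def test_all_equal_is_all_stable(self):
        out = classify_dynamics({i: 1.0 for i in range(10)})
        assert set(out.values()) == {"stable"}

    def test_k_zero_leaves_only_exact_mean_stable(self):
        out = classify_dynamics({0: 1.0, 1: 1.2, 2: 0.8}, k=0.0)
        assert out[0] == "stable" and out[1] == "expanding" and out[2] == "contracting"

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        vals = {i: v for i, v in enumerate(rng.normal(1.0, 0.05, 200))}
        out = classify_dynamics(vals)
        counts = {c: sum(v == c for v in out.values()) for c in ("expanding", "stable", "contracting")}
        assert sum(counts.values()) == 200

    def test_single_lesion_cohort_raises(self):
        with pytest.raises(ValueError):
            classify_dynamics({0: 1.0})


def stretch_field(shape, centre, axis, s):
    pts = world_grid(shape)
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    d = pts - np.asarray(centre, float)
    return (s - 1.0) * (d @ axis)[..., None] * axis


class TestExpansionAxis:
    def test_stretch_along_x_recovered(self):
        u = stretch_field((15, 15, 15), (7, 7, 7), [1, 0, 0], 1.1)
        fld = VectorVolume(u, np.eye(4), semantics="displacement")
        lesion = digitize_ellipsoid([4.0, 3.0, 3.0], centre=np.array([7.0, 7.0, 7.0]), pad=2)
        axis, flags = expansion_axis(lesion, fld)
        assert not flags and axis_angle_deg(axis, [1, 0, 0]) < 3.0

    def test_isotropic_expansion_is_undefined(self):
        pts = world_grid((15, 15, 15))
        u = 0.05 * (pts - np.array([7.0, 7.0, 7.0]))
        fld = VectorVolume(u, np.eye(4), semantics="displacement")
        lesion = digitize_ellipsoid([4.0, 4.0, 4.0], centre=np.array([7.0, 7.0, 7.0]), pad=2)
        axis, flags = expansion_axis(lesion, fld)
        assert axis is None and "no_dominant_expansion_direction" in flags

    def test_translation_invariance(self):
        u = stretch_field((15, 15, 15), (7, 7, 7), [1, 0, 0], 1.1)
        lesion = digitize_ellipsoid([4.0, 3.0, 3.0], centre=np.array([7.0, 7.0, 7.0]), pad=2)
        a1, _ = expansion_axis(lesion, VectorVolume(u, np.eye(4), semantics="displacement"))
        shifted = u + np.array([5.0, -1.0, 2.0])
        a2, _ = expansion_axis(lesion, VectorVolume(shifted, np.eye(4), semantics="displacement"))
        assert axis_angle_deg(a1, a2) < 1e-6

    def test_strain_mode_agrees_on_linear_stretch(self):
        u = stretch_field((15, 15, 15), (7, 7, 7), [0, 1, 0], 1.15)
        fld = VectorVolume(u, np.eye(4), semantics="displacement")
        lesion = digitize_ellipsoid([4.0, 3.0, 3.0], centre=np.array([7.0, 7.0, 7.0]), pad=2)
        a1, _ = expansion_axis(lesion, fld, mode="displacement")
        a2, _ = expansion_axis(lesion, fld, mode="strain")
        assert axis_angle_deg(a1, [0, 1, 0]) < 3.0
        assert axis_angle_deg(a1, a2) < 3.0

    def test_all_zero_displacement_raises(self):
        fld = VectorVolume(np.zeros((9, 9, 9, 3)), np.eye(4), semantics="displacement")
        with pytest.raises(ValueError):
            expansion_axis(np.array([[4, 4, 4], [4, 4, 5], [4, 5, 4]]), fld)


class TestChangeDirection:
    def test_axis_equal_to_vein_is_v(self):
        v = np.array([0.0, 1.0, 0.0])
        axes = FeatureAxes(lesion_id=1, v=v, v90=np.array([1.0, 0, 0]))
        label = classify_change_direction(v, axes)
        assert label.category == "V"

    def test_axis_orthogonal_to_vein_hits_v90(self):
        # v90 constructed from the baseline major axis, orthogonal to v
        v = np.array([0.0, 0.0, 1.0])
        eps1 = np.array([1.0, 0.0, 0.0])
        v90, _ = orthogonal_vein_axis(v, eps1)
        axes = FeatureAxes(lesion_id=1, v=v, v90=v90)
        label = classify_change_direction(eps1, axes)
        assert "V90" in label.aligned and "V" not in label.aligned

    def test_undefined_axis_gives_no_label(self):
        axes = FeatureAxes(lesion_id=1, v=np.array([0.0, 0, 1.0]))
        assert classify_change_direction(None, axes) is None


class TestLesionMTRChange:
    def test_identical_maps_zero_change(self):
        m = ImageVolume(np.full((4, 4, 4), 35.0), np.eye(4))
        assert lesion_mtr_change(m, m, np.array([[1, 1, 1], [2, 2, 2]])) == 0.0

    def test_uniform_offset_recovered(self):
        b = ImageVolume(np.full((4, 4, 4), 35.0), np.eye(4))
        f = ImageVolume(np.full((4, 4, 4), 35.3), np.eye(4))
        assert lesion_mtr_change(b, f, np.array([[0, 0, 0]])) == pytest.approx(0.3)

    def test_no_defined_voxels_raises(self):
        b = ImageVolume(np.full((4, 4, 4), np.nan), np.eye(4))
        with pytest.raises(ValueError):
            lesion_mtr_change(b, b, np.array([[0, 0, 0]]))


def test_jacobian_mean_over_lesion_matches_injected_volume_ratio():
    """A lesion given an 8% volume increase sits above a static cohort."""
    s = 1.08
    u = stretch_field((17, 17, 17), (8, 8, 8), [1, 0, 0], s)
    fld = VectorVolume(u, np.eye(4), semantics="displacement")
    lesion = digitize_ellipsoid([4.0, 2.0, 2.0], centre=np.array([8.0, 8.0, 8.0]), pad=2)
    det = jacobian_determinant(fld)
    mean_j = lesion_mean_jacobian(lesion, det)
    assert mean_j == pytest.approx(s, rel=0.01)
    cohort = {i: 1.0 for i in range(30)}
    cohort[99] = mean_j
    assert classify_dynamics(cohort)[99] == "expanding"
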