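"""Pose frames, plane angles, dihedrals and fiber descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleopack.geometry import (
    Fiber,
    NucleosomePose,
    _rodrigues,
    build_ideal_fiber,
    build_two_start_fiber,
    build_zigzag_fiber,
    fiber_step_table,
    plane_angle,
    radius_of_gyration,
    signed_dihedral,
)

from conftest import make_pose, random_pose


class TestPoseValidation:
    def test_rejects_non_unit_normal(self):
        with pytest.raises(ValueError, match="unit"):
            NucleosomePose(center=np.zeros(3), normal=[0, 0, 2.0], dyad=[1, 0, 0])

    def test_rejects_non_orthogonal_dyad(self):
        with pytest.raises(ValueError, match="perpendicular"):
            NucleosomePose(center=np.zeros(3), normal=[0, 0, 1.0],
                           dyad=[0, 0.2, 0.98])

    def test_frame_is_right_handed(self, rng):
        p = random_pose(rng)
        assert np.linalg.det(p.rotation_matrix) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(np.cross(p.normal, p.dyad), p.binormal)


class TestPlaneAngle:
    def test_identity_is_zero(self):
        p = make_pose([0, 0, 0], [0, 0, 1])
        assert plane_angle(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_is_ninety(self):
        a = make_pose([0, 0, 0], [0, 0, 1])
        b = make_pose([10, 0, 0], [1, 0, 0])
        assert plane_angle(a, b) == pytest.approx(90.0, abs=1e-9)

    def test_folds_beyond_ninety(self):
        # normals separated by 120 degrees fold to 60
        a = make_pose([0, 0, 0], [0, 0, 1])
        b = make_pose([10, 0, 0], [0, np.sin(np.radians(120)), np.cos(np.radians(120))])
        assert plane_angle(a, b) == pytest.approx(60.0, abs=1e-9)

    def test_flip_invariance_on_random_pairs(self, rng):
        for _ in range(1000):
            a, b = random_pose(rng, id=0), random_pose(rng, id=1)
            ref = plane_angle(a, b)
            flipped = NucleosomePose(center=b.center, normal=-b.normal,
                                     dyad=b.dyad, id=1)
            assert plane_angle(a, flipped) == pytest.approx(ref, abs=1e-9)
            assert plane_angle(b, a) == pytest.approx(ref, abs=1e-9)


class TestSignedDihedral:
    def test_parallel_normals_give_zero(self):
        a = make_pose([0, 0, 0], [0, 0, 1])
        b = make_pose([10, 0, 0], [0, 0, 1])
        assert signed_dihedral(a, b) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [10.0, 90.0, 230.0, 359.0])
    def test_rotation_about_axis_round_trips(self, theta):
        a = make_pose([0, 0, 0], [0, 0, 1])
        axis = np.array([1.0, 0.0, 0.0])
        rot = _rodrigues(axis, theta)
        b = NucleosomePose(center=a.center + 10 * axis, normal=rot @ a.normal,
                           dyad=rot @ a.dyad, id=1)
        assert signed_dihedral(a, b) == pytest.approx(theta, abs=1e-8)

    def test_round_trip_on_one_degree_grid(self):
        a = make_pose([0, 0, 0], [0, 0, 1])
        axis = np.array([1.0, 0.0, 0.0])
        for theta in range(0, 360):
            rot = _rodrigues(axis, float(theta))
            b = NucleosomePose(center=a.center + 10 * axis, normal=rot @ a.normal,
                               dyad=rot @ a.dyad, id=1)
            assert signed_dihedral(a, b) == pytest.approx(float(theta), abs=1e-7)

    def test_reversing_direction_negates_angle(self, rng):
        # brute-force check on 100 random pose pairs
        for _ in range(100):
            a, b = random_pose(rng, id=0), random_pose(rng, id=1)
            u = b.center - a.center
            if min(1 - abs(np.dot(a.normal, u / np.linalg.norm(u))),
                   1 - abs(np.dot(b.normal, u / np.linalg.norm(u)))) < 1e-4:
                continue
            fwd = signed_dihedral(a, b, u)
            rev = signed_dihedral(a, b, -u)
            assert (fwd + rev) % 360.0 == pytest.approx(0.0, abs=1e-7) or \
                (fwd + rev) % 360.0 == pytest.approx(360.0, abs=1e-7)

    def test_degenerate_axis_raises(self):
        a = make_pose([0, 0, 0], [0, 0, 1])
        b = make_pose([0, 0, 10], [0, 0, 1])
        with pytest.raises(ValueError, match="degenerate"):
            signed_dihedral(a, b)


class TestStepTable:
    def test_two_start_rise_gives_constant_D(self):
        f = build_two_start_fiber(12, rise=6.0, alpha=80.0)
        tab = fiber_step_table(f)
        D = tab["D_nm"].dropna()
        assert np.allclose(D, 6.0, atol=1e-9)

    def test_configured_alpha_recovered(self):
        f = build_two_start_fiber(12, rise=6.0, alpha=80.0)
        tab = fiber_step_table(f)
        assert tab.attrs["summary"]["alpha_deg"]["mean"] == pytest.approx(80.0, abs=1e-6)

    def test_collinear_parallel_fiber_is_flat(self):
        poses = [make_pose([10.0 * i, 0, 0], [0, 0, 1], id=i) for i in range(6)]
        tab = fiber_step_table(Fiber(nucleosomes=poses))
        assert np.allclose(tab["para_deg"].dropna(), 0.0, atol=1e-9)
        assert np.allclose(tab["alpha_deg"], 0.0, atol=1e-9)

    def test_short_fiber_raises(self):
        poses = [make_pose([0, 0, 0], [0, 0, 1], id=0),
                 make_pose([10, 0, 0], [0, 0, 1], id=1)]
        with pytest.raises(ValueError, match="length >= 3"):
            fiber_step_table(Fiber(nucleosomes=poses))


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_points_ten_apart(self):
        c = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert radius_of_gyration(c) == pytest.approx(5.0)

    def test_collinear_closed_form(self):
        # n equally spaced points: Rg^2 = s^2 (n^2 - 1) / 12
        s = 7.3
        c = np.column_stack([s * np.arange(12), np.zeros(12), np.zeros(12)])
        assert radius_of_gyration(c) == pytest.approx(s * np.sqrt(143.0 / 12.0))

    def test_matches_double_sum_formula(self, rng):
        for _ in range(20):
            c = rng.normal(scale=10, size=(15, 3))
            d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
            brute = np.sqrt(d2.sum() / (2 * len(c) ** 2))
            assert radius_of_gyration(c) == pytest.approx(brute, rel=1e-12)


class TestBuilders:
    def test_two_start_stacking_distances(self):
        f = build_ideal_fiber("two_start", 4, rise=6.0, alpha=50.0)
        c = f.centers
        assert np.linalg.norm(c[2] - c[0]) == pytest.approx(6.0, abs=1e-9)
        assert np.linalg.norm(c[3] - c[1]) == pytest.approx(6.0, abs=1e-9)

    @pytest.mark.parametrize("alpha,para", [(230.0, 45.0), (200.0, 30.0),
                                            (50.0, 45.0), (80.0, 20.0)])
    def test_zigzag_noiseless_identity(self, alpha, para):
        f = build_zigzag_fiber(10, d_adj=10.0, alpha=alpha, para=para)
        s = fiber_step_table(f).attrs["summary"]
        assert s["alpha_deg"]["mean"] == pytest.approx(alpha, abs=1e-6)
        assert s["para_deg"]["mean"] == pytest.approx(para, abs=1e-6)
        assert s["d_adj_nm"]["mean"] == pytest.approx(10.0, abs=1e-9)

    def test_opposite_phasing_differs_by_180(self):
        a = build_zigzag_fiber(12, d_adj=10.0, alpha=230.0, para=45.0)
        b = build_zigzag_fiber(12, d_adj=10.0, alpha=50.0, para=45.0)
        ma = fiber_step_table(a).attrs["summary"]["alpha_deg"]["mean"]
        mb = fiber_step_table(b).attrs["summary"]["alpha_deg"]["mean"]
        assert abs(ma - mb) == pytest.approx(180.0, abs=1e-6)

    def test_steric_overlap_raises_with_pair(self):
        with pytest.raises(ValueError, match="steric overlap"):
            build_zigzag_fiber(8, d_adj=1.0, alpha=0.0, para=0.0, min_sep=3.0)

    def test_noisy_build_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            build_zigzag_fiber(8, alpha_sd=20.0, seed=None)
        with pytest.raises(ValueError, match="seed"):
            build_two_start_fiber(8, tilt_sd=5.0, seed=None)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="mode"):
            build_ideal_fiber("solenoid", 6)


@settings(max_examples=50, derandomize=True)
@given(theta=st.floats(min_value=0.5, max_value=359.5),
       seed=st.integers(min_value=0, max_value=2**16))
def test_dihedral_rotation_roundtrip_property(theta, seed):
    """Constructing b by rotating a about the centre axis returns theta."""
    rng = np.random.default_rng(seed)
    a = random_pose(rng, id=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    if 1 - abs(np.dot(a.normal, axis)) < 1e-4:
        return
    rot = _rodrigues(axis, theta)
    b = NucleosomePose(center=a.center + 12 * axis, normal=rot @ a.normal,
                       dyad=rot @ a.dyad, id=1)
    assert signed_dihedral(a, b) == pytest.approx(theta, abs=1e-6)
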