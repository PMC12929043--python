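"""Radial distribution, nearest neighbours, contact classes and census."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import kstest

from nucleopack.geometry import Fiber, NucleosomePose, build_two_start_fiber
from nucleopack.packing import (
    CondensateModel,
    classify_contact,
    contact_census,
    first_rdf_peak,
    nearest_neighbor_pairs,
    orientation_distribution,
    pair_distance_histogram,
    radial_distribution,
    random_bath,
)
from nucleopack.masks import BoxMask

from conftest import make_pose, random_pose


class TestRadialDistribution:
    def test_random_bath_is_flat(self):
        m = random_bath(800, 6.0e5, seed=3)
        rdf = radial_distribution(m, r_max=30.0, bin_width=1.0,
                                  n_reference_draws=100, seed=5)
        sel = rdf["r_nm"] > 7.0
        assert np.nanmax(np.abs(rdf.loc[sel, "g_r"] - 1.0)) < 0.1

    def test_histogram_matches_brute_force(self, rng):
        centers = rng.uniform(0, 60, size=(200, 3))
        edges = np.arange(0.0, 25.5, 0.5)
        h = pair_distance_histogram(centers, edges)
        brute, _ = np.histogram(pdist(centers), bins=edges)
        assert np.array_equal(h, brute)

    def test_rmax_beyond_mask_raises(self):
        m = random_bath(200, 6.0e5, seed=1)
        with pytest.raises(ValueError, match="extent"):
            radial_distribution(m, r_max=1e4)

    def test_needs_mask_and_poses(self, rng):
        poses = [random_pose(rng, id=i) for i in range(150)]
        m = CondensateModel(poses=poses)
        with pytest.raises(ValueError, match="mask"):
            radial_distribution(m, r_max=10.0)


class TestNearestNeighbors:
    def test_three_collinear_poses(self):
        poses = [make_pose([0, 0, 0], [0, 0, 1], id=0),
                 make_pose([6, 0, 0], [0, 0, 1], id=1),
                 make_pose([20, 0, 0], [0, 0, 1], id=2)]
        m = CondensateModel(poses=poses)
        assert nearest_neighbor_pairs(m, k=1) == [(0, 1), (1, 2)]

    def test_matches_brute_force(self, rng):
        poses = [NucleosomePose(center=rng.uniform(0, 80, 3), normal=[0, 0, 1],
                                dyad=[1, 0, 0], id=i) for i in range(500)]
        m = CondensateModel(poses=poses)
        got = set(nearest_neighbor_pairs(m, k=1))
        centers = m.centers
        expected = set()
        for i in range(500):
            d = np.linalg.norm(centers - centers[i], axis=1)
            d[i] = np.inf
            j = int(np.argmin(d))
            expected.add((min(i, j), max(i, j)))
        assert got == expected

    def test_equidistant_tie_prefers_lower_id(self):
        poses = [make_pose([0, 0, 0], [0, 0, 1], id=0),
                 make_pose([-5, 0, 0], [0, 0, 1], id=1),
                 make_pose([5, 0, 0], [0, 0, 1], id=2)]
        m = CondensateModel(poses=poses)
        pairs = nearest_neighbor_pairs(m, k=1)
        assert (0, 1) in pairs  # pose 0 ties between 1 and 2 -> lower id

    def test_k_too_large_raises(self):
        poses = [make_pose([i * 10.0, 0, 0], [0, 0, 1], id=i) for i in range(3)]
        with pytest.raises(ValueError, match="k"):
            nearest_neighbor_pairs(CondensateModel(poses=poses), k=3)


class TestOrientationDistribution:
    def test_parallel_stack_in_first_bin(self):
        poses = [make_pose([0, 0, 7.0 * i], [0, 0, 1], id=i) for i in range(10)]
        m = CondensateModel(poses=poses)
        pairs = nearest_neighbor_pairs(m, k=1)
        hist = orientation_distribution(pairs, m, bin_width_deg=5.0)
        assert hist["count"].iloc[0] == hist["count"].sum()

    def test_uniform_orientations_have_one_radian_mean(self, rng):
        # folded plane angle of independent uniform discs ~ sin density:
        # mean = 1 radian = 57.2958 degrees
        from nucleopack.geometry import plane_angle

        angles = []
        for i in range(10_000):
            a = random_pose(rng, id=0)
            b = random_pose(rng, id=1)
            angles.append(plane_angle(a, b))
        assert np.mean(angles) == pytest.approx(57.2958, abs=1.0)

    def test_reference_integrates_to_sample_count(self):
        m = random_bath(300, 6.0e5, seed=9)
        pairs = nearest_neighbor_pairs(m, k=1)
        hist = orientation_distribution(pairs, m)
        assert hist["reference"].sum() == pytest.approx(len(pairs), rel=1e-9)


class TestClassifyContact:
    def test_coaxial_caps_face_to_face(self):
        a = make_pose([0, 0, 0], [0, 0, 1], id=0)
        b = make_pose([0, 0, 7.0], [0, 0, 1], id=1)
        assert classify_contact(a, b) == "face-to-face"

    def test_perpendicular_rim_on_cap(self):
        a = make_pose([0, 0, 0], [0, 0, 1], id=0)
        b = make_pose([0, 0, 9.5], [1, 0, 0], id=1)
        assert classify_contact(a, b) == "face-to-side"

    def test_lateral_walls_side_to_side(self):
        a = make_pose([0, 0, 0], [0, 0, 1], id=0)
        b = make_pose([12.0, 0, 0], [0, 0, 1], id=1)
        assert classify_contact(a, b) == "side-to-side"

    def test_beyond_gate_returns_none(self):
        a = make_pose([0, 0, 0], [0, 0, 1], id=0)
        b = make_pose([30, 0, 0], [0, 0, 1], id=1)
        assert classify_contact(a, b) is None

    def test_symmetric_in_arguments(self, rng):
        for _ in range(50):
            a, b = random_pose(rng, id=0), random_pose(rng, id=1)
            b = NucleosomePose(center=b.center / np.linalg.norm(b.center) * 11.0,
                               normal=b.normal, dyad=b.dyad, id=1)
            assert classify_contact(a, b) == classify_contact(b, a)

    def test_agreement_with_surface_sampling_oracle(self, rng):
        """>= 99% class agreement with a Monte-Carlo closest-point oracle."""
        from nucleopack._cylinder import CylinderSpec

        def sample_surface(pose, n):
            radius, hh = 5.5, 3.0
            a_lat = 2 * np.pi * radius * 2 * hh
            a_cap = np.pi * radius**2
            m_lat = int(n * a_lat / (a_lat + 2 * a_cap))
            m_cap = (n - m_lat) // 2
            phi = rng.uniform(0, 2 * np.pi, m_lat)
            pts = [np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                                    rng.uniform(-hh, hh, m_lat)])]
            for zs in (hh, -hh):
                phi = rng.uniform(0, 2 * np.pi, m_cap)
                r = radius * np.sqrt(rng.uniform(0, 1, m_cap))
                pts.append(np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                            np.full(m_cap, zs)]))
            local = np.vstack(pts)
            return local @ pose.rotation_matrix.T + pose.center, local

        def facet_of(local_pt):
            rho = np.hypot(local_pt[0], local_pt[1])
            if abs(abs(local_pt[2]) - 3.0) < 1e-9 and rho <= 0.9 * 5.5:
                return "face"
            return "side"

        n_checked = agree = 0
        for _ in range(220):
            a = make_pose([0, 0, 0], [0, 0, 1], id=0)
            b = random_pose(rng, id=1)
            c = rng.normal(size=3)
            c = c / np.linalg.norm(c) * rng.uniform(10.0, 14.5)
            b = NucleosomePose(center=c, normal=b.normal, dyad=b.dyad, id=1)
            got = classify_contact(a, b)
            wa, la = sample_surface(a, 6000)
            wb, lb = sample_surface(b, 6000)
            dist, idx = cKDTree(wb).query(wa)
            i = int(np.argmin(dist))
            mc_dist = float(dist[i])
            mc_class = "-to-".join(sorted([facet_of(la[i]), facet_of(lb[idx[i]])]))
            # the point-sampling oracle is only meaningful for separated
            # solids; skip overlaps and decision-boundary degeneracies
            if mc_dist < 0.1 or abs(mc_dist - 2.0) < 0.15:
                continue
            if any(abs(np.hypot(p[0], p[1]) - 0.9 * 5.5) < 0.25
                   for p in (la[i], lb[idx[i]])):
                continue
            n_checked += 1
            expected = mc_class if mc_dist <= 2.0 else None
            agree += got == expected
        assert n_checked >= 100
        assert agree / n_checked >= 0.99


class TestContactCensus:
    def test_constructed_inter_contacts(self):
        # two 4-mers stacked pairwise cap-to-cap: 4 inter face-to-face, 0 intra
        poses, array_of, seq_of = [], {}, {}
        for j in range(4):
            poses.append(make_pose([20.0 * j, 0, 0], [0, 0, 1], id=j))
            array_of[j], seq_of[j] = "A", j
        for j in range(4):
            poses.append(make_pose([20.0 * j, 0, 7.0], [0, 0, 1], id=4 + j))
            array_of[4 + j], seq_of[4 + j] = "B", j
        m = CondensateModel(poses=poses, array_of=array_of, seq_of=seq_of)
        census = contact_census(m)
        row_a = census.per_array.set_index("array_id").loc["A"]
        assert row_a["inter"] == 4
        assert row_a["intra"] == 0
        assert set(census.records["geometry_class"]) == {"face-to-face"}

    def test_isolated_two_start_twelve_mer(self):
        fiber = build_two_start_fiber(12, rise=6.0, alpha=80.0)
        m = CondensateModel(
            poses=fiber.nucleosomes,
            array_of={p.id: 0 for p in fiber.nucleosomes},
            seq_of={p.id: i for i, p in enumerate(fiber.nucleosomes)},
        )
        census = contact_census(m)
        f2f = census.records[census.records["geometry_class"] == "face-to-face"]
        # the 10 (N, N+2) stacking pairs of a 12-mer
        stack_pairs = {(i, i + 2) for i in range(10)}
        assert stack_pairs <= set(zip(f2f["pose_i"], f2f["pose_j"]))
        assert len(f2f) == 10
        assert (census.records["scope"] == "intra-array").all()

    def test_census_matches_brute_force(self, small_bp30_condensate):
        m = small_bp30_condensate
        fast = contact_census(m)
        brute = contact_census(m, brute_force=True)
        key = ["pose_i", "pose_j", "geometry_class", "scope"]
        assert fast.records[key].sort_values(key).reset_index(drop=True).equals(
            brute.records[key].sort_values(key).reset_index(drop=True)
        )

    def test_class_fractions_partition(self, small_bp30_condensate):
        census = contact_census(small_bp30_condensate)
        per = census.per_array
        with_contacts = per[per["total"] > 0]
        frac_cols = [c for c in per.columns if c.startswith("frac_")]
        assert np.allclose(with_contacts[frac_cols].sum(axis=1), 1.0)

    def test_requires_array_assignment(self, rng):
        poses = [random_pose(rng, id=i) for i in range(5)]
        with pytest.raises(ValueError, match="array"):
            contact_census(CondensateModel(poses=poses))


class TestRandomBath:
    def test_box_side_from_density(self):
        m = random_bath(600, 6.0e5, seed=0)
        assert m.meta["box_side_nm"] == pytest.approx(100.0)

    def test_normals_uniform_on_sphere(self):
        m = random_bath(10_000, 1.0e5, seed=8)
        z = np.array([p.normal[2] for p in m.poses])
        assert kstest(z, "uniform", args=(-1, 2)).pvalue > 0.01

    def test_determinism(self):
        a = random_bath(100, 6.0e5, seed=5)
        b = random_bath(100, 6.0e5, seed=5)
        assert np.array_equal(a.centers, b.centers)
        assert all(np.array_equal(p.normal, q.normal)
                   for p, q in zip(a.poses, b.poses))

    def test_overdense_bath_raises(self):
        with pytest.raises(ValueError, match="volume fraction"):
            random_bath(1000, 5.0e6, seed=0)


def test_first_peak_of_stacked_condensate(small_bp30_condensate):
    rdf = radial_distribution(small_bp30_condensate, r_max=20.0, bin_width=0.5,
                              n_reference_draws=50, seed=2)
    assert first_rdf_peak(rdf) == pytest.approx(6.0, abs=0.5)
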