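"""Ensemble geometry and contact quantification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import mc_circle_overlap
from laminafold import synth
from laminafold.metrics import (RegionSet, calibrate_length, calibrate_overlap,
                                circle_intersection_area, contact_map,
                                map_correlation, ne_distance,
                                pairwise_distance, projected_overlap,
                                radius_of_gyration, sphericity,
                                subtraction_map, three_body_overlap)


class TestContactMap:
    def test_hand_placed_three_beads(self):
        # distances (0,1)=5, (1,2)=8, (0,2)=12 (taxicab placement along x)
        frame = np.array([[[0.0, 0, 0], [5.0, 0, 0], [13.0, 0, 0]]])
        m = contact_map([frame], threshold=7.5)
        assert m[0, 1] == 1.0 and m[1, 0] == 1.0
        assert m[1, 2] == 0.0 and m[0, 2] == 0.0
        assert (np.diag(m) == 1.0).all()

    def test_symmetry_and_range(self, rng):
        frames = rng.normal(scale=3, size=(8, 20, 3))
        m = contact_map([frames])
        assert np.allclose(m, m.T)
        assert (m >= 0).all() and (m <= 1).all()

    def test_monotone_in_threshold(self, rng):
        frames = rng.normal(scale=3, size=(5, 15, 3))
        m1 = contact_map([frames], threshold=3.0)
        m2 = contact_map([frames], threshold=6.0)
        assert (m2 >= m1).all()

    def test_aggregates_over_simulations(self):
        near = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])
        far = np.array([[[0.0, 0, 0], [20.0, 0, 0]]])
        m = contact_map([near, far])
        assert m[0, 1] == 0.5

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contact_map([])


class TestSubtractionMap:
    def test_identical_maps_zero(self, rng):
        m = rng.random((6, 6))
        assert (subtraction_map(m, m) == 0).all()

    def test_antisymmetric_under_swap(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        assert np.allclose(subtraction_map(a, b), -subtraction_map(b, a))

    def test_single_entry_difference(self):
        a = np.zeros((5, 5))
        b = a.copy()
        b[1, 3] = b[3, 1] = 0.2
        d = subtraction_map(b, a)
        assert d[1, 3] == d[3, 1] == 0.2
        assert np.count_nonzero(d) == 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtraction_map(np.zeros((3, 3)), np.zeros((4, 4)))


class TestPairwiseDistance:
    def test_region_to_itself_zero(self, rng):
        frames = rng.normal(size=(25, 10, 3))
        mean, _ = pairwise_distance(frames, (0, 5), (0, 5))
        assert mean == 0.0

    def test_single_bead_euclidean(self):
        frames = np.tile(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]), (20, 1, 1))
        mean, d = pairwise_distance(frames, (0, 1), (1, 2))
        assert mean == pytest.approx(5.0)
        assert np.allclose(d, 5.0)

    def test_translation_invariance(self, rng):
        frames = rng.normal(size=(22, 12, 3))
        m1, _ = pairwise_distance(frames, (0, 6), (6, 12))
        m2, _ = pairwise_distance(frames + 100.0, (0, 6), (6, 12))
        assert m1 == pytest.approx(m2)

    def test_short_trajectory_rejected(self, rng):
        with pytest.raises(ValueError, match="frames"):
            pairwise_distance(rng.normal(size=(5, 4, 3)), (0, 2), (2, 4))


class TestNeDistance:
    def test_formula_cases(self):
        at_centre = np.zeros((3, 3))
        assert ne_distance(at_centre, (0, 3), 40.0) == pytest.approx(40.0)
        on_wall = np.tile([40.0, 0, 0], (2, 1))
        assert ne_distance(on_wall, (0, 2), 40.0) == pytest.approx(0.0)
        halfway = np.tile([0, 20.0, 0], (2, 1))
        assert ne_distance(halfway, (0, 2), 40.0) == pytest.approx(20.0)

    def test_complementarity_with_com_norm(self, rng):
        coords = rng.normal(scale=5, size=(8, 3))
        d = ne_distance(coords, (0, 8), 40.0)
        assert d + np.linalg.norm(coords.mean(axis=0)) == pytest.approx(40.0)


class TestCalibration:
    def test_identity(self):
        assert calibrate_length([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_factor_44(self):
        # model medians {2,4} sigma vs experimental {88,176} nm -> 44 nm/sigma
        assert calibrate_length([2.0, 4.0], [88.0, 176.0]) == pytest.approx(44.0)

    def test_overlap_factor(self):
        model = [0.1, 0.2, 0.3]
        exp = [0.12, 0.24, 0.36]
        assert calibrate_overlap(model, exp) == pytest.approx(1.2)

    def test_order_invariance(self):
        assert calibrate_overlap([1, 2], [2, 2.2]) == pytest.approx(
            calibrate_overlap([2, 1], [2.2, 2]))

    def test_zero_model_median_rejected(self):
        with pytest.raises(ValueError):
            calibrate_length([0.0], [1.0])


class TestCircleOverlap:
    def test_disjoint_zero(self):
        assert circle_intersection_area(1.0, 2.0, 3.0) == 0.0
        assert circle_intersection_area(1.0, 2.0, 3.5) == 0.0

    def test_containment_quarter(self):
        # R1=1 inside R2=2: A12=pi -> overlap = pi/(pi+4pi-pi) = 0.25
        a12 = circle_intersection_area(1.0, 2.0, 0.0)
        assert a12 == pytest.approx(np.pi, abs=1e-15)
        ov = a12 / (np.pi + 4 * np.pi - a12)
        assert ov == pytest.approx(0.25)

    def test_printed_partial_case(self):
        # R1=R2=1, d=1: A12 = 2pi/3 - sqrt(3)/2 = 1.2284
        a12 = circle_intersection_area(1.0, 1.0, 1.0)
        assert a12 == pytest.approx(2 * np.pi / 3 - np.sqrt(3) / 2, abs=1e-12)
        assert a12 / (2 * np.pi - a12) == pytest.approx(0.2430, abs=1e-4)

    def test_symmetric_in_radii(self):
        assert circle_intersection_area(0.7, 1.3, 1.1) == pytest.approx(
            circle_intersection_area(1.3, 0.7, 1.1), abs=1e-14)

    @pytest.mark.parametrize("seed", range(8))
    def test_against_mc_oracle(self, seed):
        r = np.random.default_rng(seed)
        r1, r2 = r.uniform(0.2, 2.0, 2)
        d = r.uniform(0.0, 1.2 * (r1 + r2))
        a12 = circle_intersection_area(r1, r2, d)
        ana = a12 / (np.pi * r1 ** 2 + np.pi * r2 ** 2 - a12)
        mc = mc_circle_overlap(r1, r2, d, 2_000_000, seed + 1)
        assert ana == pytest.approx(mc, abs=2e-3)


class TestProjectedOverlap:
    def test_far_apart_zero(self, rng):
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3)) + [100.0, 0, 0]
        assert projected_overlap(a, b) == 0.0

    def test_identical_regions_full_overlap(self, rng):
        a = rng.normal(size=(50, 3))
        assert projected_overlap(a, a) == pytest.approx(1.0)

    def test_axis_choice_changes_projection(self):
        # two rods along z: identical xy -> overlap 1 along z-projection,
        # separated along x when projecting on y
        t = np.linspace(-1, 1, 40)
        a = np.c_[np.zeros_like(t), np.zeros_like(t), t]
        b = a + [5.0, 0, 0]
        assert projected_overlap(a, b, axis="z") == 0.0
        assert projected_overlap(a, a, axis="y") == pytest.approx(1.0)

    def test_degenerate_point_regions(self):
        p = np.zeros((3, 3))
        q = np.tile([1.0, 0, 0], (3, 1))
        assert projected_overlap(p, q) == 0.0
        assert projected_overlap(p, p) == 1.0


class TestThreeBodyOverlap:
    def test_all_disjoint_zero(self, rng):
        a = rng.normal(size=(20, 3))
        assert three_body_overlap(a, a + [50, 0, 0], a + [0, 50, 0]) == 0.0

    def test_containment_cancellation(self, rng):
        # region1 tightly inside region2, region3 far: value = A1/(A2+A3)
        r = rng.normal(size=(500, 3))
        big = r * 3.0
        small = r[:100] * 0.3
        far = r + [200.0, 0, 0]
        v = three_body_overlap(small, big, far)

        def proj_area(pts):   # pi * (2D gyration radius)^2
            p = pts[:, :2]
            return np.pi * np.mean(np.sum((p - p.mean(0)) ** 2, axis=1))

        want = proj_area(small) / (proj_area(big) + proj_area(far))
        assert v == pytest.approx(want, rel=1e-9)

    def test_permutation_of_partners(self, rng):
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3)) + [1.0, 0, 0]
        c = rng.normal(size=(30, 3)) + [0, 1.5, 0]
        assert three_body_overlap(a, b, c) == pytest.approx(
            three_body_overlap(a, c, b), rel=1e-12)


class TestSphericity:
    def test_cube_closed_form(self):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                            for k in (0, 1)], dtype=float)
        assert sphericity(corners) == pytest.approx((np.pi / 6) ** (1 / 3),
                                                    abs=1e-9)

    def test_tetrahedron_closed_form(self):
        # regular tetrahedron: V = a^3/(6 sqrt2), A = sqrt3 a^2
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        a = np.sqrt(8.0)
        v = a ** 3 / (6 * np.sqrt(2))
        area = np.sqrt(3) * a ** 2
        want = np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / area
        assert sphericity(pts) == pytest.approx(want, abs=1e-9)

    def test_sampled_ball_near_one(self, rng):
        u = rng.normal(size=(10_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = u * rng.random(10_000)[:, None] ** (1 / 3)
        assert sphericity(pts) >= 0.97

    def test_elongation_decreases_sphericity(self, rng):
        pts = rng.normal(size=(200, 3))
        stretched = pts * [4.0, 1.0, 1.0]
        assert sphericity(stretched) < sphericity(pts)

    def test_coplanar_rejected(self):
        pts = np.c_[np.random.default_rng(0).normal(size=(10, 2)), np.zeros(10)]
        with pytest.raises(ValueError):
            sphericity(pts)

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_never_exceeds_one(self, seed):
        pts = np.random.default_rng(seed).normal(size=(30, 3))
        assert sphericity(pts) <= 1.0 + 1e-12


class TestMapCorrelation:
    def test_identical_maps_perfect(self):
        m = synth.make_block_contact_map(40, [20], noise_sd=0.1, seed=0)
        r, rp = map_correlation(m, m)
        assert r == pytest.approx(1.0)
        assert rp == pytest.approx(1.0)

    def test_distance_decay_offset_only_changes_r(self):
        m = synth.make_block_contact_map(40, [20], noise_sd=0.15, seed=1)
        n = m.shape[0]
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        offset = 0.5 / (1.0 + np.abs(i - j))
        r0, rp0 = map_correlation(m, m)
        r1, rp1 = map_correlation(m, m + offset)
        assert rp1 == pytest.approx(rp0, abs=1e-9)
        assert r1 != pytest.approx(r0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_copy_highly_correlated(self, seed):
        m = synth.make_block_contact_map(60, [20, 40])
        rng = np.random.default_rng(seed)
        noisy = np.abs(m * (1 + 0.1 * rng.normal(size=m.shape)))
        noisy = 0.5 * (noisy + noisy.T)
        r, _ = map_correlation(m, noisy)
        assert r >= 0.95

    def test_distance_cut_strictness(self):
        # bin size 20 kb: pairs at separation 5 bins = 100 kb are excluded
        m = synth.make_block_contact_map(30, [15], noise_sd=0.05, seed=2)
        with pytest.raises(ValueError):
            map_correlation(m[:7, :7], m[:7, :7])  # too few eligible entries

    def test_region_set_validation(self):
        with pytest.raises(ValueError, match="outside"):
            RegionSet({"desertA": (0, 50), "geneB": (40, 120)}, n_beads=100)
        rs = RegionSet({"desertA": (0, 50), "geneR": (50, 80)}, n_beads=100)
        assert rs.slice("desertA") == slice(0, 50)
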