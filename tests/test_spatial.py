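"""Density, radial neighbor profiles, conjugation, co-positivity, ROI draws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tme3d import (
    PopulationSpec,
    ROI,
    compute_density,
    conjugation_count,
    copositivity,
    radial_neighbor_profile,
    select_rois,
    simulate_point_pattern,
)
from tme3d.points import make_point_set, of_type

from conftest import brute_force_pair_count, brute_force_radial_bins

unit_roi = ROI.from_size((100.0, 100.0, 100.0), label="u")


def pts(array, marker="CD3"):
    return make_point_set(np.asarray(array, dtype=float).reshape(-1, 3), marker)


class TestROI:
    def test_membership_is_half_open(self):
        xyz = np.array([[0, 0, 0], [100, 50, 50], [99.999, 99.999, 99.999]])
        assert list(unit_roi.contains(xyz)) == [True, False, True]

    def test_volume_mm3(self):
        assert unit_roi.volume_mm3 == pytest.approx(1e-3)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            ROI(((0, 0), (0, 1), (0, 1)))


class TestDensity:
    def test_no_points_is_zero(self):
        assert compute_density(pts(np.empty((0, 3))), unit_roi, "CD3") == 0.0

    def test_hundred_cells_in_point_one_mm_cube(self):
        rng = np.random.default_rng(0)
        p = pts(rng.uniform(0, 100, (100, 3)))
        assert compute_density(p, unit_roi, "CD3") == pytest.approx(100_000.0)

    def test_poisson_density_recovery(self):
        lam = 1e-4  # cells/μm³ → 1e5 cells/mm³
        domain = ROI.from_size((500, 500, 400))
        truth = simulate_point_pattern(
            domain, [PopulationSpec(cell_type="CD3", intensity_per_um3=lam)], seed=8
        )
        est = compute_density(truth.points, domain, "CD3")
        v = domain.volume_um3
        assert abs(est - 1e5) < 3 * np.sqrt(lam * v) / domain.volume_mm3


class TestRadialProfile:
    def test_single_neighbor_lands_in_its_shell(self):
        prof = radial_neighbor_profile(
            pts([[50, 50, 50]]), pts([[57, 50, 50]], "CD20"),
            roi=unit_roi, edge_policy="none",
        )
        assert prof.n_centers == 1
        assert list(prof.total_count) == [0, 1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_neighbor_at_exactly_50um_excluded(self):
        prof = radial_neighbor_profile(
            pts([[0, 0, 0]]), pts([[50, 0, 0]], "CD20"),
            roi=unit_roi, edge_policy="none",
        )
        assert prof.total_count.sum() == 0

    def test_coincident_same_record_not_own_neighbor(self):
        same = pts([[10, 10, 10], [12, 10, 10]])
        prof = radial_neighbor_profile(same, same, roi=unit_roi, edge_policy="none")
        # each cell sees the other, not itself
        assert list(prof.total_count[:1]) == [2]
        assert prof.total_count.sum() == 2

    def test_oracle_parity_on_seeded_instances(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            ctr = rng.uniform(0, 200, (rng.integers(5, 60), 3))
            nbr = rng.uniform(0, 200, (rng.integers(5, 400), 3))
            prof = radial_neighbor_profile(
                pts(ctr), pts(nbr, "CD20"),
                roi=ROI.from_size((200, 200, 200)), edge_policy="none",
            )
            assert np.array_equal(
                prof.total_count, brute_force_radial_bins(ctr, nbr, 50.0, 5.0)
            )

    def test_integral_consistency(self):
        rng = np.random.default_rng(3)
        ctr, nbr = rng.uniform(0, 150, (40, 3)), rng.uniform(0, 150, (300, 3))
        prof = radial_neighbor_profile(
            pts(ctr), pts(nbr, "CD20"),
            roi=ROI.from_size((150, 150, 150)), edge_policy="none",
        )
        within = sum(
            1 for c in ctr for q in nbr if np.linalg.norm(c - q) < 50.0
        )
        assert prof.total_count.sum() == within

    def test_interior_only_drops_edge_centers(self):
        prof = radial_neighbor_profile(
            pts([[10, 50, 50], [50, 50, 50]]), pts([[55, 50, 50]], "CD20"),
            roi=unit_roi, edge_policy="interior_only",
        )
        assert prof.n_centers == 0  # 100³ ROI has no 50-μm interior

        roi2 = ROI.from_size((200, 200, 200))
        prof2 = radial_neighbor_profile(
            pts([[10, 100, 100], [100, 100, 100]]), pts([[105, 100, 100]], "CD20"),
            roi=roi2, edge_policy="interior_only",
        )
        assert prof2.n_centers == 1
        assert prof2.total_count.sum() == 1

    def test_no_centers_warns_and_reports_nan_means(self):
        with pytest.warns(UserWarning, match="no center"):
            prof = radial_neighbor_profile(
                pts(np.empty((0, 3))), pts([[5, 5, 5]], "CD20"),
                roi=unit_roi, edge_policy="none",
            )
        assert np.isnan(prof.mean_count_per_center).all()

    def test_bin_width_must_divide_range(self):
        with pytest.raises(ValueError, match="divide"):
            radial_neighbor_profile(
                pts([[1, 1, 1]]), pts([[2, 2, 2]], "CD20"),
                roi=unit_roi, r_max_um=50, bin_um=7, edge_policy="none",
            )


class TestConjugation:
    def test_threshold_is_strict(self):
        roi = ROI.from_size((200, 200, 200))
        at = lambda x: pts([[x, 0.1, 0.1]], "CD20")
        a = pts([[0.1, 0.1, 0.1]])
        assert conjugation_count(a, at(15.1), roi).pair_count == 0
        assert conjugation_count(a, at(15.0 + 0.1), roi).pair_count == 0
        assert conjugation_count(a, at(14.9 + 0.1), roi).pair_count == 1

    def test_oracle_parity_n300(self):
        rng = np.random.default_rng(17)
        a = rng.uniform(0, 300, (300, 3))
        b = rng.uniform(0, 300, (300, 3))
        roi = ROI.from_size((300, 300, 300))
        entry = conjugation_count(pts(a), pts(b, "CD20"), roi)
        assert entry.pair_count == brute_force_pair_count(a, b, 15.0)

    def test_symmetric_in_a_and_b(self):
        rng = np.random.default_rng(21)
        a, b = rng.uniform(0, 120, (80, 3)), rng.uniform(0, 120, (90, 3))
        roi = ROI.from_size((120, 120, 120))
        assert (
            conjugation_count(pts(a), pts(b, "CD20"), roi).pair_count
            == conjugation_count(pts(b, "CD20"), pts(a), roi).pair_count
        )

    def test_same_type_rejected(self):
        with pytest.raises(ValueError, match="different"):
            conjugation_count(pts([[1, 1, 1]]), pts([[2, 2, 2]]), unit_roi)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000), st.floats(0.5, 8.0))
    def test_scale_equivariance(self, seed, c):
        # scaling coordinates and the distance threshold together preserves counts
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 60, (40, 3)), rng.uniform(0, 60, (50, 3))
        roi = ROI.from_size((60, 60, 60))
        roi_c = ROI.from_size((60 * c, 60 * c, 60 * c))
        base = conjugation_count(pts(a), pts(b, "CD20"), roi, d_max_um=15.0)
        scaled = conjugation_count(
            pts(a * c), pts(b * c, "CD20"), roi_c, d_max_um=15.0 * c
        )
        assert base.pair_count == scaled.pair_count


class TestCopositivity:
    def test_coincident_lists_ratio_one(self):
        rng = np.random.default_rng(2)
        base = pts(rng.uniform(0, 100, (50, 3)), "CD8")
        marker = pts(base[["x_um", "y_um", "z_um"]].to_numpy(), "Ki67")
        assert copositivity(marker, base).ratio == 1.0

    def test_disjoint_sets_ratio_zero(self):
        base = pts([[0, 0, 0], [10, 0, 0]], "CD8")
        marker = pts([[50, 50, 50]], "Ki67")
        assert copositivity(marker, base).ratio == 0.0

    def test_marker_point_validates_at_most_one_base(self):
        base = pts([[0, 0, 0], [1, 0, 0]], "CD8")
        marker = pts([[0.4, 0, 0]], "Ki67")
        res = copositivity(marker, base, match_radius_um=5)
        assert res.n_double == 1

    def test_synthetic_copositive_fraction_recovered(self):
        from tme3d import CopositiveSpec

        domain = ROI.from_size((215, 215, 215))  # ≈ 1000 base cells at 1e-4
        spec = [
            PopulationSpec(
                cell_type="CD8", intensity_per_um3=1e-4,
                copositive_with=CopositiveSpec(marker="Ki67", fraction=0.3),
            )
        ]
        truth = simulate_point_pattern(domain, spec, seed=4)
        res = copositivity(
            of_type(truth.points, "Ki67"), of_type(truth.points, "CD8")
        )
        n = res.n_base
        assert abs(res.ratio - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_empty_base_warns_nan(self):
        with pytest.warns(UserWarning, match="empty base"):
            res = copositivity(pts([[1, 1, 1]], "Ki67"), pts(np.empty((0, 3)), "CD8"))
        assert np.isnan(res.ratio)


class TestSelectROIs:
    def test_single_roi_can_fill_domain(self):
        domain = ROI.from_size((100, 100, 100))
        rois = select_rois(domain, n=1, roi_shape_um=(100, 100, 100), seed=0)
        assert rois[0].bounds_um == domain.bounds_um

    def test_ten_disjoint_rois_inside_domain(self):
        domain = ROI.from_size((1000, 1000, 500))
        rois = select_rois(domain, n=10, roi_shape_um=(200, 200, 200), seed=1)
        assert len(rois) == 10
        for r in rois:
            for (lo, hi), (dlo, dhi) in zip(r.bounds_um, domain.bounds_um):
                assert lo >= dlo and hi <= dhi
        for i, a in enumerate(rois):
            for b in rois[i + 1 :]:
                disjoint = any(
                    a.bounds_um[k][0] >= b.bounds_um[k][1]
                    or b.bounds_um[k][0] >= a.bounds_um[k][1]
                    for k in range(3)
                )
                assert disjoint

    def test_same_seed_identical(self):
        domain = ROI.from_size((600, 600, 300))
        a = select_rois(domain, n=5, roi_shape_um=(120, 120, 120), seed=9)
        b = select_rois(domain, n=5, roi_shape_um=(120, 120, 120), seed=9)
        assert [r.bounds_um for r in a] == [r.bounds_um for r in b]

    def test_infeasible_packing_raises(self):
        domain = ROI.from_size((200, 200, 200))
        with pytest.raises((RuntimeError, ValueError)):
            select_rois(domain, n=10, roi_shape_um=(150, 150, 150), seed=0,
                        max_attempts=500)
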