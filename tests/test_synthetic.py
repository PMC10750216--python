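"""Point-pattern generation, rendering and z-tiling of synthetic blocks."""

import numpy as np
import pandas as pd
import pytest

from tme3d import (
    AttractionParams,
    CopositiveSpec,
    PopulationSpec,
    ROI,
    disease_preset,
    render_volume,
    simulate_point_pattern,
    tile_volume,
)
from tme3d.points import coords, of_type


def box(x, y, z):
    return ROI.from_size((x, y, z), label="domain")


class TestSimulatePointPattern:
    def test_zero_intensity_gives_empty_pattern(self):
        truth = simulate_point_pattern(
            box(100, 100, 100),
            [PopulationSpec(cell_type="CD3", intensity_per_um3=0.0)],
            seed=0,
        )
        assert len(truth.points) == 0

    def test_poisson_count_near_expectation(self):
        lam, vol = 1e-4, 1000 * 1000 * 500
        truth = simulate_point_pattern(
            box(1000, 1000, 500),
            [PopulationSpec(cell_type="CD3", intensity_per_um3=lam)],
            seed=42,
        )
        assert abs(len(truth.points) - lam * vol) < 4 * np.sqrt(lam * vol)

    def test_poisson_dispersion(self):
        # variance/mean of the count over replicates ≈ 1 for a Poisson
        # process; 2000 replicates put the estimator's SD near 0.03, well
        # inside the [0.9, 1.1] acceptance band
        domain = box(100, 100, 100)  # λV = 1000
        spec = [PopulationSpec(cell_type="CD3", intensity_per_um3=1e-3)]
        counts = [
            len(simulate_point_pattern(domain, spec, seed=s).points)
            for s in range(2000)
        ]
        counts = np.array(counts)
        assert 0.9 < counts.var() / counts.mean() < 1.1

    def test_all_points_inside_domain(self):
        domain = ROI(((10, 210), (20, 170), (5, 105)))
        truth = simulate_point_pattern(domain, disease_preset("AITL"), seed=3)
        assert domain.contains(coords(truth.points)).all()

    def test_attached_cells_sit_within_conjugation_distance_of_an_anchor(self):
        domain = box(300, 300, 300)
        specs = [
            PopulationSpec(cell_type="CD3", intensity_per_um3=200 / domain.volume_um3),
            PopulationSpec(
                cell_type="CD20",
                intensity_per_um3=150 / domain.volume_um3,
                pattern="paired_attraction",
                attraction_params=AttractionParams(
                    anchor_type="CD3", attached_fraction=1.0
                ),
            ),
        ]
        truth = simulate_point_pattern(domain, specs, seed=5)
        anchors = coords(of_type(truth.points, "CD3"))
        attached = coords(of_type(truth.points, "CD20"))
        assert len(anchors) > 100
        for p in attached:
            assert np.linalg.norm(anchors - p, axis=1).min() < 15.0

    def test_copositive_duplicates_share_coordinates(self):
        domain = box(200, 200, 200)
        specs = [
            PopulationSpec(
                cell_type="CD8",
                intensity_per_um3=2e-4,
                copositive_with=CopositiveSpec(marker="Ki67", fraction=0.3),
            )
        ]
        truth = simulate_point_pattern(domain, specs, seed=6)
        cd8 = coords(of_type(truth.points, "CD8"))
        ki67 = coords(of_type(truth.points, "Ki67"))
        n = len(cd8)
        frac = len(ki67) / n
        assert abs(frac - 0.3) < 4 * np.sqrt(0.3 * 0.7 / n)
        # every Ki67 point is an exact duplicate of a CD8 coordinate
        cd8_set = {tuple(row) for row in cd8}
        assert all(tuple(row) in cd8_set for row in ki67)

    def test_thomas_cluster_is_overdispersed(self):
        from tme3d.synthetic import ClusterParams

        domain = box(400, 400, 400)
        spec = [
            PopulationSpec(
                cell_type="CD20",
                intensity_per_um3=4e-5,
                pattern="thomas_cluster",
                cluster_params=ClusterParams(
                    parent_intensity_per_um3=2e-6,
                    mean_offspring=20,
                    offspring_sigma_um=10,
                ),
            )
        ]
        truth = simulate_point_pattern(domain, spec, seed=7)
        xyz = coords(truth.points)
        # quadrat counts on a 4×4×4 grid: clustered ⇒ variance ≫ mean
        idx = np.floor(xyz / 100.0).astype(int)
        counts = np.zeros((4, 4, 4))
        for i in idx:
            counts[tuple(i)] += 1
        assert counts.var() / counts.mean() > 2.0

    def test_same_seed_is_bit_identical(self):
        domain = box(300, 300, 150)
        specs = disease_preset("DLBCL")
        a = simulate_point_pattern(domain, specs, seed=11).points
        b = simulate_point_pattern(domain, specs, seed=11).points
        pd.testing.assert_frame_equal(a, b)

    def test_cyclic_anchor_dependency_rejected(self):
        mk = lambda name, anchor: PopulationSpec(
            cell_type=name,
            intensity_per_um3=1e-5,
            pattern="paired_attraction",
            attraction_params=AttractionParams(anchor_type=anchor),
        )
        with pytest.raises(ValueError, match="cycl"):
            simulate_point_pattern(
                box(100, 100, 100), [mk("CD3", "CD20"), mk("CD20", "CD3")], seed=0
            )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(cell_type="CD3", intensity_per_um3=-1.0)
        with pytest.raises(ValueError, match="conjugation"):
            AttractionParams(anchor_type="CD3", distance_range_um=(2.0, 15.0))


class TestRenderVolume:
    def _truth(self, xyz, size=(60, 60, 120)):
        domain = box(*size)
        from tme3d.points import make_point_set

        from tme3d.synthetic import GroundTruth

        pts = make_point_set(np.asarray(xyz, dtype=float).reshape(-1, 3), "CD3")
        return GroundTruth(pts, [], 0, domain)

    def test_empty_pattern_renders_background_plus_noise(self, acq):
        truth = self._truth(np.empty((0, 3)))
        vol = render_volume(truth, acq, "CD3", seed=1, background=100.0)
        mean = vol.intensities.mean()
        se = np.sqrt(100.0 / vol.intensities.size)
        assert abs(mean - 100.0) < 3 * se

    def test_depth_attenuation_ratio_is_e(self, acq):
        att = acq.channel("CD3").attenuation_length_um
        truth = self._truth([[30, 30, 0.0], [30, 30, att]], size=(60, 60, att + 60))
        vol = render_volume(truth, acq, "CD3", noise=False, background=0.0)
        img = vol.intensities.astype(float)
        nz = img.shape[0]
        peak_shallow = img[: nz // 2].max()
        peak_deep = img[nz // 2 :].max()
        assert peak_shallow / peak_deep == pytest.approx(np.e, rel=0.02)

    def test_noise_free_centroid_within_quarter_voxel(self, acq):
        pos = np.array([31.7, 28.3, 61.2])  # (x, y, z) μm
        truth = self._truth([pos])
        vol = render_volume(truth, acq, "CD3", noise=False, background=0.0)
        img = vol.intensities.astype(float)
        zyx = np.indices(img.shape).reshape(3, -1)
        w = img.ravel()
        com_idx = (zyx * w).sum(axis=1) / w.sum()
        com_um = com_idx * np.array(vol.voxel_size_um) + np.array(vol.origin_um)
        err_vox = np.abs(com_um - pos[::-1]) / np.array(vol.voxel_size_um)
        assert (err_vox < 0.25).all()

    def test_voxel_cap_guards_memory(self, acq):
        truth = self._truth(np.empty((0, 3)), size=(5000, 5000, 5000))
        with pytest.raises(MemoryError, match="cap"):
            render_volume(truth, acq, "CD3", voxel_cap=10_000_000)

    def test_same_seed_is_bit_identical(self, acq):
        truth = self._truth([[30, 30, 60]])
        a = render_volume(truth, acq, "CD3", seed=9)
        b = render_volume(truth, acq, "CD3", seed=9)
        assert np.array_equal(a.intensities, b.intensities)


class TestTileVolume:
    def _volume(self, depth_um, acq):
        nz = int(round(depth_um / acq.plane_step_um))
        rng = np.random.default_rng(0)
        from tme3d import ImageVolume

        data = rng.integers(0, 1000, size=(nz, 8, 8), dtype=np.uint16)
        return ImageVolume(data, voxel_size_um=acq.voxel_size_um, channel="CD3")

    def test_single_section_depth_gives_one_tile(self, acq):
        pairs = tile_volume(self._volume(300, acq), acq, jitter_vox=0)
        assert len(pairs) == 1
        assert pairs[0][1] == 0.0

    def test_tile_count_follows_tiling_arithmetic(self, acq):
        # ceil((1000 − 300)/250) + 1 = 4 overlapping sections
        pairs = tile_volume(self._volume(1000, acq), acq, jitter_vox=0)
        assert len(pairs) == 4

    def test_jitter_disabled_offsets_are_stage_step_multiples(self, acq):
        # depth chosen so the last section lands exactly on the stage grid
        pairs = tile_volume(self._volume(800, acq), acq, jitter_vox=0)
        for _, true_off in pairs:
            assert true_off % acq.z_stage_step_um == 0.0

    def test_jitter_bounded_and_recorded(self, acq):
        dz = acq.plane_step_um
        pairs = tile_volume(self._volume(1000, acq), acq, seed=3, jitter_vox=2)
        for tile, true_off in pairs:
            assert abs(true_off - tile.nominal_offset_um[0]) <= 2 * dz

    def test_too_shallow_volume_rejected(self, acq):
        with pytest.raises(ValueError, match="shallower"):
            tile_volume(self._volume(200, acq), acq)
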