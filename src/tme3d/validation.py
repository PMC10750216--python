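"""Self-validation benchmarks: closed-form, oracle and calibration checks.

Each function here recomputes a package-level guarantee from scratch —
acquisition arithmetic from the optical parameters, KD-tree statistics
against brute-force distance-matrix references, stochastic estimates
against closed-form Poisson/binomial expectations, detector quality on
rendered ground truth, stitching round trips, the type-I error of the rank
test, and recovery of the packaged disease-condition structure.  They are
used by the test suite and by ``scripts/acceptance.py``; all randomness
flows from the seed argument.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .config import (
    AcquisitionConfig,
    ChannelSpec,
    SHEET_THICKNESS_UM,
    magnification_from_optics,
)
from .detection import DetectionParams, detect_spots, match_detections
from .groupstats import kruskal_wallis
from .pipeline import AnalysisParams, analyze_block, compare_groups
from .points import coords, make_point_set, of_type
from .spatial import ROI, conjugation_count, radial_neighbor_profile
from .stitching import stitch
from .synthetic import (
    GroundTruth,
    PopulationSpec,
    disease_preset,
    render_volume,
    simulate_point_pattern,
    tile_volume,
)


def default_acq() -> AcquisitionConfig:
    return AcquisitionConfig(
        channels=[
            ChannelSpec(name="CD3", excitation_nm=488),
            ChannelSpec(name="CD20", excitation_nm=532),
            ChannelSpec(name="FOXP3", excitation_nm=637),
        ]
    )


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


# ------------------------------------------------------------------ optics

def acquisition_arithmetic() -> dict:
    """Derived acquisition quantities from the configured optics.

    Object-space pixel from camera pitch over magnification; z-tiling
    overlap from section depth and stage step; overall magnification from
    the 10× detection objective behind a 200 mm tube lens; and the ratio of
    the ~1 mm imaged sample depth to the 3.5 μm light-sheet thickness.
    """
    acq = AcquisitionConfig()
    return {
        "object_pixel_um": acq.object_pixel_um,
        "z_overlap_percent": 100.0 * acq.overlap_fraction,
        "overall_magnification": magnification_from_optics(
            objective_mag=10.0, tube_lens_mm=200.0, reference_tube_lens_mm=180.0
        ),
        "imaged_depth_to_sheet_ratio": 1000.0 / SHEET_THICKNESS_UM,
    }


# -------------------------------------------------------- oracle parity

def oracle_parity(seed: int, n_instances: int = 50, n_max: int = 500) -> dict:
    """KD-tree conjugation and radial counts vs brute-force distance matrices."""
    rng = _rng(seed, 101)
    conj_ok = radial_ok = 0
    for _ in range(n_instances):
        n_a = int(rng.integers(5, n_max + 1))
        n_b = int(rng.integers(5, n_max + 1))
        side = float(rng.uniform(150, 400))
        a = rng.uniform(0, side, (n_a, 3))
        b = rng.uniform(0, side, (n_b, 3))
        roi = ROI.from_size((side, side, side))
        d = cdist(a, b)

        entry = conjugation_count(
            make_point_set(a, "CD3"), make_point_set(b, "CD20"), roi
        )
        conj_ok += int(entry.pair_count == int((d < 15.0).sum()))

        prof = radial_neighbor_profile(
            make_point_set(a, "CD3"), make_point_set(b, "CD20"),
            roi=roi, edge_policy="none",
        )
        ref = np.histogram(d[d < 50.0], bins=np.arange(0.0, 55.0, 5.0))[0]
        radial_ok += int(np.array_equal(prof.total_count, ref))
    return {
        "conjugation_agreement": conj_ok / n_instances,
        "radial_agreement": radial_ok / n_instances,
        "n_instances": n_instances,
    }


# ------------------------------------------------- closed-form recovery

def radial_poisson_recovery(seed: int, lam: float = 1e-4) -> dict:
    """Radial shell means under homogeneous Poisson vs λ·(4/3)π(r₂³−r₁³).

    Centers are sparse (so their 50-μm shells rarely overlap and per-center
    counts are effectively independent) and interior-only; the worst
    per-bin deviation is reported in units of the empirical standard error
    of the shell mean.
    """
    side = 1000.0
    domain = ROI.from_size((side, side, side))
    specs = [
        PopulationSpec(cell_type="CD3", intensity_per_um3=8.5e-7),  # ≈ 620 interior
        PopulationSpec(cell_type="CD20", intensity_per_um3=lam),
    ]
    truth = simulate_point_pattern(domain, specs, seed=int(_rng(seed, 201).integers(2**31)))
    centers = of_type(truth.points, "CD3")
    neighbors = of_type(truth.points, "CD20")
    prof = radial_neighbor_profile(
        centers, neighbors, roi=domain, edge_policy="interior_only"
    )
    edges = prof.bin_edges_um
    expected = lam * (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    # per-center histograms for the empirical SE of each shell mean
    interior = domain.shrink(prof.bin_edges_um[-1])
    ctr = coords(centers)
    ctr = ctr[interior.contains(ctr)]
    nbr = coords(neighbors)
    tree = cKDTree(nbr)
    per_center = np.zeros((len(ctr), len(expected)))
    for i, hit in enumerate(tree.query_ball_point(ctr, edges[-1])):
        if hit:
            dist = np.linalg.norm(nbr[hit] - ctr[i], axis=1)
            dist = dist[dist < edges[-1]]
            per_center[i] = np.bincount(
                (dist // 5.0).astype(int), minlength=len(expected)
            )[: len(expected)]
    se = per_center.std(axis=0, ddof=1) / np.sqrt(len(ctr))
    z = (prof.mean_count_per_center - expected) / se
    return {
        "n_centers": int(prof.n_centers),
        "max_abs_z": float(np.abs(z).max()),
        "mean_counts": prof.mean_count_per_center.tolist(),
        "expected_counts": expected.tolist(),
    }


def csr_conjugation_calibration(
    seed: int, n_reps: int = 1000, n_a: int = 200, n_b: int = 200, side: float = 500.0
) -> dict:
    """Mean CSR conjugation count vs n_a·n_b·(4/3)π·15³/V.

    The a-points (centers) are drawn from the 15-μm interior of the box so
    every conjugation ball lies fully inside and the closed form is exact;
    b-points fill the whole box of volume V.
    """
    rng = _rng(seed, 301)
    roi = ROI.from_size((side, side, side))
    expected = n_a * n_b * (4.0 / 3.0) * np.pi * 15.0**3 / side**3
    counts = np.empty(n_reps)
    for r in range(n_reps):
        a = rng.uniform(15.0, side - 15.0, (n_a, 3))
        b = rng.uniform(0.0, side, (n_b, 3))
        counts[r] = conjugation_count(
            make_point_set(a, "CD3"), make_point_set(b, "CD20"), roi
        ).pair_count
    return {
        "expected": expected,
        "observed_mean": float(counts.mean()),
        "rel_error_percent": float(100.0 * abs(counts.mean() - expected) / expected),
        "n_reps": n_reps,
    }


# ------------------------------------------------------ detection quality

def detection_benchmark(seed: int, n_fields: int = 2, n_cells: int = 60) -> dict:
    """Detector F1 on rendered fields with spaced cells at high peak SNR.

    Fields are 256×256 px laterally and 150 planes deep (the desk-scale
    stand-in for a full camera tile); cells are pairwise ≥ 2 diameters
    apart and matched at tolerance = diameter/2.
    """
    acq = default_acq()
    dx = acq.lateral_pixel_um
    size = (256 * dx, 256 * dx, 150 * acq.plane_step_um)
    diameter = 10.0
    f1s = []
    for k in range(n_fields):
        rng = _rng(seed, 401, k)
        xyz = _spaced(rng, np.full(3, 8.0), np.array(size) - 8.0, n_cells, 2 * diameter)
        truth = GroundTruth(make_point_set(xyz, "CD3"), [], 0, ROI.from_size(size))
        vol = render_volume(
            truth, acq, "CD3", seed=int(rng.integers(2**31)),
            peak_amplitude=1000.0, background=100.0,
        )
        det = detect_spots(vol, DetectionParams(expected_diameter_um=diameter))
        rep = match_detections(det, truth.points, tol_um=diameter / 2.0)
        f1s.append(rep.f1)
    return {"f1": float(np.mean(f1s)), "n_fields": n_fields, "n_cells": n_cells}


def attenuation_recovery(seed: int = 0) -> dict:
    """Log-peak vs depth on a noise-free render: slope −1/attenuation, R²."""
    acq = default_acq()
    ch = acq.channel("CD3")
    depths = np.arange(20.0, 560.1, 30.0)
    lateral = 36.0
    xy = np.tile([[lateral / 2, lateral / 2]], (len(depths), 1))
    xyz = np.column_stack([xy, depths])
    truth = GroundTruth(
        make_point_set(xyz, "CD3"), [], 0,
        ROI.from_size((lateral, lateral, depths[-1] + 20.0)),
    )
    vol = render_volume(truth, acq, "CD3", noise=False, background=0.0,
                        peak_amplitude=10000.0)
    img = vol.intensities.astype(float)
    dz = acq.plane_step_um
    peaks = []
    for d in depths:
        z0 = int(d / dz)
        peaks.append(img[max(z0 - 4, 0) : z0 + 5].max())
    logp = np.log(np.array(peaks))
    slope, intercept = np.polyfit(depths, logp, 1)
    resid = logp - (slope * depths + intercept)
    r2 = 1.0 - resid.var() / logp.var()
    return {
        "fitted_attenuation_um": -1.0 / slope,
        "true_attenuation_um": ch.attenuation_length_um,
        "r_squared": float(r2),
    }


# ----------------------------------------------------- stitching round trip

def stitching_roundtrip(seed: int) -> dict:
    """Jittered z-tiling → registration → fusion vs the source volume."""
    acq = default_acq()
    rng = _rng(seed, 501)
    depth = 1000.0
    xyz = rng.uniform([5, 5, 5], [55, 55, depth - 5], size=(120, 3))
    truth = GroundTruth(
        make_point_set(xyz, "CD3"), [], 0, ROI.from_size((60, 60, depth))
    )
    vol = render_volume(truth, acq, "CD3", noise=False)
    pairs = tile_volume(vol, acq, seed=int(rng.integers(2**31)), jitter_vox=2)
    result = stitch([t for t, _ in pairs], search_radius_um=10.0)
    dz = acq.plane_step_um
    offset_err_vox = max(
        abs(ref[0] - true) / dz
        for (_, true), ref in zip(pairs, result.refined_offsets_um)
    )
    nz = min(result.fused.shape[0], vol.shape[0])
    mae = float(
        np.abs(
            result.fused.intensities[:nz].astype(float)
            - vol.intensities[:nz].astype(float)
        ).mean()
    )
    return {"max_offset_error_vox": float(offset_err_vox), "fused_mae": mae,
            "n_tiles": len(pairs)}


# ------------------------------------------------- statistical calibration

def kw_type1_error(seed: int, n_reps: int = 2000, group_size: int = 10) -> dict:
    """Null rejection rate of the rank test at α = 0.05, 3 equal groups."""
    rng = _rng(seed, 601)
    rejections = 0
    for _ in range(n_reps):
        groups = [rng.normal(size=group_size) for _ in range(3)]
        rejections += int(kruskal_wallis(groups).significant)
    return {"type1_rate": rejections / n_reps, "n_reps": n_reps}


# --------------------------------------- disease-structure recovery

_RECOVERY_ANALYSIS = AnalysisParams(
    neighbor_markers=("CD20", "FOXP3"),
    conjugation_pairs=(("CD3", "CD163"),),
    copositivity_pairs=(),
    density_markers=(),
)
_RECOVERY_TYPES = ("CD3", "CD20", "FOXP3", "CD163")


def structure_recovery(seed: int, n_runs: int = 50) -> dict:
    """Directional recovery of the packaged disease conditions.

    For each seeded run, one tissue block per condition (RLN-, DLBCL- and
    AITL-like) is simulated and analyzed over 10 ROIs; the run scores a
    success for a statistic when the rank test across conditions is
    significant at 0.05 *and* the expected condition has the highest
    median: B-near-T radial counts highest in DLBCL, Treg-near-T radial
    counts and TAM–T conjugations highest in AITL.  Populations not
    involved in these three statistics are skipped for speed.
    """
    domain = ROI.from_size((800.0, 800.0, 400.0), label="block")
    presets = {
        g: [s for s in disease_preset(g) if s.cell_type in _RECOVERY_TYPES]
        for g in ("RLN", "DLBCL", "AITL")
    }
    hits = {"b_near_t_dlbcl": 0, "treg_near_t_aitl": 0, "tam_t_conj_aitl": 0}
    for run in range(n_runs):
        rng = _rng(seed, 701, run)
        tables = {}
        for g, specs in presets.items():
            truth = simulate_point_pattern(domain, specs, int(rng.integers(2**31)))
            res = analyze_block(
                truth.points, domain, _RECOVERY_ANALYSIS,
                seed=int(rng.integers(2**31)), group=g,
            )
            for name, df in res.items():
                tables.setdefault(name, []).append(df)
        import pandas as pd

        tables = {k: pd.concat(v, ignore_index=True) for k, v in tables.items()}
        tests = compare_groups(tables)

        def hit(metric, key, expect_group):
            row = tests[(tests["metric"] == metric) & (tests["key"] == key)]
            return bool(
                len(row)
                and row["significant"].iloc[0]
                and row["highest_median_group"].iloc[0] == expect_group
            )

        hits["b_near_t_dlbcl"] += hit("radial_neighbors_50um", "CD20", "DLBCL")
        hits["treg_near_t_aitl"] += hit("radial_neighbors_50um", "FOXP3", "AITL")
        hits["tam_t_conj_aitl"] += hit("conjugation", "CD3/CD163", "AITL")
    return {k: v / n_runs for k, v in hits.items()} | {"n_runs": n_runs}


def _spaced(rng, lo, hi, n, min_dist, max_tries=100_000):
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = lo + rng.uniform(size=3) * (hi - lo)
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise RuntimeError("could not place spaced cells")
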