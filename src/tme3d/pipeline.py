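"""Reproducible end-to-end runs: simulate → (render/stitch/detect) → analyze → compare.

A pipeline run takes one JSON-serializable config and one output directory
and produces, per disease group and tissue block, ground-truth point CSVs
(and rendered/stitched volumes plus detections when rendering is enabled),
then the four tidy statistics tables — ``densities.csv``, ``radial.csv``,
``conjugation.csv``, ``copositivity.csv`` — and the group-comparison table
``tests.csv``.  Every artifact is recorded in ``manifest.json`` with its
SHA-256; reruns with the same config are bit-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as tio
from .config import AcquisitionConfig, ChannelSpec
from .detection import DetectionParams, detect_spots
from .groupstats import kruskal_wallis
from .points import concat_point_sets, of_type
from .spatial import (
    ROI,
    compute_density,
    conjugation_count,
    copositivity,
    radial_neighbor_profile,
    select_rois,
)
from .stitching import stitch
from .synthetic import (
    GroundTruth,
    PopulationSpec,
    disease_preset,
    render_volume,
    simulate_point_pattern,
    tile_volume,
)

log = logging.getLogger("tme3d")

DEFAULT_CONJUGATION_PAIRS = (
    ("CD8", "CD20"), ("CD8", "FOXP3"), ("CD3", "CD68"),
    ("CD3", "CD163"), ("CD3", "CD14"), ("CD3", "CD15"),
)
DEFAULT_COPOSITIVITY_PAIRS = (("Ki67", "CD8"), ("Ki67", "CD20"))
DEFAULT_DENSITY_MARKERS = (
    "CD3", "CD8", "CD20", "CD68", "CD163", "CD14", "CD15", "FOXP3",
)
DEFAULT_NEIGHBOR_MARKERS = ("CD20", "FOXP3", "CD163", "CD14", "CD15", "CD68", "CD8")


class AnalysisParams(BaseModel):
    n_rois: int = 10
    roi_shape_um: tuple[float, float, float] = (150.0, 150.0, 150.0)
    min_gap_um: float = 0.0
    r_max_um: float = 50.0
    bin_um: float = 5.0
    edge_policy: str = "interior_only"
    conjugation_distance_um: float = 15.0
    copositivity_radius_um: float = 5.0
    center_marker: str = "CD3"  # the profile anchor; CD8 for CD8-anchored panels
    neighbor_markers: tuple[str, ...] = DEFAULT_NEIGHBOR_MARKERS
    conjugation_pairs: tuple[tuple[str, str], ...] = DEFAULT_CONJUGATION_PAIRS
    copositivity_pairs: tuple[tuple[str, str], ...] = DEFAULT_COPOSITIVITY_PAIRS
    density_markers: tuple[str, ...] = DEFAULT_DENSITY_MARKERS


class PipelineConfig(BaseModel):
    acquisition: AcquisitionConfig = Field(
        default_factory=lambda: AcquisitionConfig(
            channels=[
                ChannelSpec(name="CD3", excitation_nm=488),
                ChannelSpec(name="CD20", excitation_nm=532),
                ChannelSpec(name="FOXP3", excitation_nm=637),
            ]
        )
    )
    groups: dict[str, list[PopulationSpec]] = Field(
        default_factory=lambda: {g: disease_preset(g) for g in ("RLN", "DLBCL", "AITL")}
    )
    blocks_per_group: int = 1
    domain_size_um: tuple[float, float, float] = (800.0, 800.0, 400.0)
    render: bool = False  # rendering is for small fields; point-pattern path otherwise
    detection: DetectionParams = Field(default_factory=DetectionParams)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)
    seed: int = 0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial_manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_manifest = partial_manifest


def block_seed(master_seed: int, group_index: int, block: int) -> int:
    """Stable per-block seed below 2³¹ derived from the master seed."""
    child = np.random.SeedSequence([master_seed, group_index, block])
    return int(child.generate_state(1)[0] % (2**31))


def analyze_block(
    points: pd.DataFrame,
    domain: ROI,
    params: AnalysisParams,
    seed: int,
    group: str = "",
    block: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-ROI densities, radial profiles, conjugation and co-positivity."""
    rois = select_rois(
        domain,
        n=params.n_rois,
        roi_shape_um=params.roi_shape_um,
        seed=seed,
        min_gap_um=params.min_gap_um,
    )
    meta = {"group": group, "block": block}
    dens_rows, radial_rows, conj_rows, copos_rows = [], [], [], []
    centers_all = of_type(points, params.center_marker)
    for roi in rois:
        for marker in params.density_markers:
            dens_rows.append(
                meta | {
                    "roi": roi.label,
                    "marker": marker,
                    "density_per_mm3": compute_density(points, roi, marker),
                }
            )
        for marker in params.neighbor_markers:
            prof = radial_neighbor_profile(
                centers_all,
                of_type(points, marker),
                roi=roi,
                r_max_um=params.r_max_um,
                bin_um=params.bin_um,
                edge_policy=params.edge_policy,
            )
            frame = prof.to_frame()
            frame.insert(0, "roi", roi.label)
            for k, v in meta.items():
                frame.insert(0, k, v)
            radial_rows.append(frame)
        for a, b in params.conjugation_pairs:
            entry = conjugation_count(
                of_type(points, a), of_type(points, b), roi,
                d_max_um=params.conjugation_distance_um,
            )
            conj_rows.append(
                meta | {
                    "roi": roi.label, "type_a": a, "type_b": b,
                    "pair_count": entry.pair_count,
                    "n_a": entry.n_a, "n_b": entry.n_b,
                }
            )
        for marker, base in params.copositivity_pairs:
            res = copositivity(
                roi.clip(of_type(points, marker)),
                roi.clip(of_type(points, base)),
                match_radius_um=params.copositivity_radius_um,
            )
            copos_rows.append(
                meta | {
                    "roi": roi.label, "marker": marker, "base": base,
                    "n_double": res.n_double, "n_base": res.n_base,
                    "ratio": res.ratio,
                }
            )
    return {
        "densities": pd.DataFrame(dens_rows),
        "radial": pd.concat(radial_rows, ignore_index=True),
        "conjugation": pd.DataFrame(conj_rows),
        "copositivity": pd.DataFrame(copos_rows),
    }


def compare_groups(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Kruskal–Wallis across disease groups for every per-ROI statistic.

    The unit of analysis is the ROI (the configurable default); for each
    marker / pair the per-ROI values of each group form one sample.
    """
    rows = []

    def run(df, key_cols, value_col, metric):
        if df.empty:
            return
        for key, sub in df.groupby(list(key_cols)):
            groups = {g: s[value_col].dropna().to_numpy()
                      for g, s in sub.groupby("group")}
            groups = {g: v for g, v in groups.items() if len(v)}
            if len(groups) < 2:
                continue
            res = kruskal_wallis(groups)
            medians = {g: float(np.median(v)) for g, v in groups.items()}
            top = max(medians, key=medians.get)
            rows.append({
                "metric": metric,
                "key": key if isinstance(key, str) else "/".join(map(str, key)),
                "H": res.statistic, "df": res.df, "pvalue": res.pvalue,
                "significant": res.significant,
                "highest_median_group": top,
            })

    run(tables["densities"], ["marker"], "density_per_mm3", "density")
    radial = tables["radial"]
    # per-ROI radial summary: mean neighbors per center within the full range
    summary = (
        radial.groupby(["group", "block", "roi", "neighbor_type"], as_index=False)
        ["mean_per_center"].sum()
    )
    run(summary, ["neighbor_type"], "mean_per_center", "radial_neighbors_50um")
    run(tables["conjugation"], ["type_a", "type_b"], "pair_count", "conjugation")
    run(tables["copositivity"], ["marker", "base"], "ratio", "copositivity")
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(mode="json"),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    stage = "configure"
    try:
        domain = ROI.from_size(config.domain_size_um, label="block")
        truths: list[tuple[str, int, GroundTruth]] = []

        stage = "simulate"
        t0 = time.time()
        for gi, (group, specs) in enumerate(sorted(config.groups.items())):
            for block in range(config.blocks_per_group):
                seed = block_seed(config.seed, gi, block)
                truth = simulate_point_pattern(domain, specs, seed)
                truth.points["block"] = block
                truth.points["seed"] = seed
                path = out / f"truth_{group}_b{block}.csv"
                tio.write_points(path, truth.points)
                _record(manifest, path)
                truths.append((group, block, truth))
        manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 3)}

        block_points: list[tuple[str, int, pd.DataFrame]] = []
        if config.render:
            stage = "render+stitch+detect"
            t0 = time.time()
            markers = [ch.name for ch in config.acquisition.channels]
            for group, block, truth in truths:
                detected = []
                for ci, marker in enumerate(markers):
                    seed = block_seed(config.seed, 1000 + ci, block)
                    vol = render_volume(truth, config.acquisition, marker, seed=seed)
                    try:
                        pairs = tile_volume(vol, config.acquisition, seed=seed)
                        fused = stitch([t for t, _ in pairs]).fused
                    except ValueError:
                        fused = vol  # shallower than one section: nothing to tile
                    vpath = out / f"vol_{group}_b{block}_{marker}.tif"
                    tio.write_volume(vpath, fused)
                    _record(manifest, vpath)
                    detected.append(detect_spots(fused, config.detection))
                pts = concat_point_sets(detected)
                ppath = out / f"points_{group}_b{block}.csv"
                tio.write_points(ppath, pts)
                _record(manifest, ppath)
                block_points.append((group, block, pts))
            manifest["stages"]["render+stitch+detect"] = {
                "seconds": round(time.time() - t0, 3)
            }
        else:
            # truth path: ground-truth coordinates flow directly to analysis
            block_points = [(g, b, t.points) for g, b, t in truths]

        stage = "analyze"
        t0 = time.time()
        collected: dict[str, list[pd.DataFrame]] = {}
        for gi, (group, block, pts) in enumerate(block_points):
            res = analyze_block(
                pts, domain, config.analysis,
                seed=block_seed(config.seed, 2000, gi),
                group=group, block=block,
            )
            for name, df in res.items():
                collected.setdefault(name, []).append(df)
        tables = {k: pd.concat(v, ignore_index=True) for k, v in collected.items()}
        for name, df in tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.6g")
            _record(manifest, path)
        manifest["stages"]["analyze"] = {"seconds": round(time.time() - t0, 3)}

        stage = "compare"
        t0 = time.time()
        tests = compare_groups(tables)
        tpath = out / "tests.csv"
        tests.to_csv(tpath, index=False, float_format="%.6g")
        _record(manifest, tpath)
        manifest["stages"]["compare"] = {"seconds": round(time.time() - t0, 3)}
    except Exception as exc:  # noqa: BLE001 — abort with stage name + partial manifest
        manifest["failed_stage"] = stage
        tio.write_json(out / "manifest.json", manifest)
        raise PipelineError(stage, exc, manifest) from exc

    tio.write_json(out / "manifest.json", manifest)
    return manifest


def _record(manifest: dict, path: Path) -> None:
    manifest["artifacts"][path.name] = tio.sha256_file(path)
    log.info("wrote %s", path)
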