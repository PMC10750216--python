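"""Ground-truthed synthetic tissue blocks and light-sheet renders.

The generator produces what the downstream pipeline expects from a cleared,
multiplex-immunolabeled lymphoma tissue block imaged on a light-sheet
microscope:

* typed 3D point patterns per immune marker (homogeneous Poisson, Thomas
  parent–offspring clusters, or attraction of one type to an anchor type,
  which is how disease-specific neighborhood enrichment — e.g. B cells
  crowding T cells — is encoded);
* rendered single-channel volumes: each cell becomes an anisotropic Gaussian
  blob whose peak decays exponentially with imaging depth, on a constant
  background, with Poisson shot noise, quantized to the camera bit depth;
* overlapping z-sections cut from a rendered volume at the z-stage step,
  with optional seeded jitter, to exercise registration and fusion.

All randomness flows from one explicit integer seed per call through
``numpy.random.SeedSequence`` spawning; no global RNG state is touched, and
regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import AcquisitionConfig
from .points import concat_point_sets, make_point_set
from .spatial import ROI
from .stitching import ImageTile
from .volume import ImageVolume, default_origin

#: Hard bound on attachment distances: attached cells must remain within the
#: conjugation distance of their anchor by construction.
CONJUGATION_DISTANCE_UM = 15.0


class ClusterParams(BaseModel):
    """Thomas-process parameters: Poisson parents, Gaussian offspring."""

    parent_intensity_per_um3: float = 1e-6
    mean_offspring: float = 20.0
    offspring_sigma_um: float = 15.0


class AttractionParams(BaseModel):
    """Attachment of a fraction of a population to cells of an anchor type."""

    anchor_type: str
    attached_fraction: float = 0.3
    distance_range_um: tuple[float, float] = (2.0, 10.0)

    @model_validator(mode="after")
    def _check(self) -> "AttractionParams":
        if not 0.0 <= self.attached_fraction <= 1.0:
            raise ValueError("attached_fraction must be in [0, 1]")
        lo, hi = self.distance_range_um
        if not 0.0 <= lo < hi:
            raise ValueError("distance range must satisfy 0 <= lo < hi")
        if hi >= CONJUGATION_DISTANCE_UM:
            raise ValueError(
                f"attachment distances must stay below the conjugation "
                f"distance ({CONJUGATION_DISTANCE_UM} μm); got upper bound {hi}"
            )
        return self


class CopositiveSpec(BaseModel):
    """Emit a duplicate point with a second marker for a fraction of cells."""

    marker: str
    fraction: float = 0.3

    @model_validator(mode="after")
    def _check(self) -> "CopositiveSpec":
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("co-positive fraction must be in [0, 1]")
        return self


class PopulationSpec(BaseModel):
    """One cell type's abundance and spatial pattern in a tissue block."""

    cell_type: str
    intensity_per_um3: float = 5e-5
    pattern: str = "poisson"  # poisson | thomas_cluster | paired_attraction
    cluster_params: ClusterParams | None = None
    attraction_params: AttractionParams | None = None
    copositive_with: CopositiveSpec | None = None

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        if self.intensity_per_um3 < 0:
            raise ValueError("intensity_per_um3 must be >= 0")
        if self.pattern not in ("poisson", "thomas_cluster", "paired_attraction"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "paired_attraction" and self.attraction_params is None:
            raise ValueError("paired_attraction requires attraction_params")
        if self.pattern == "thomas_cluster" and self.cluster_params is None:
            raise ValueError("thomas_cluster requires cluster_params")
        return self


@dataclass
class GroundTruth:
    """A generated point pattern with everything needed to regenerate it."""

    points: pd.DataFrame
    specs: list[PopulationSpec]
    rng_seed: int
    domain: ROI


def _topological_order(specs: list[PopulationSpec]) -> list[PopulationSpec]:
    """Anchors before the populations attached to them; cycles are an error."""
    by_type = {s.cell_type: s for s in specs}
    order: list[PopulationSpec] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(s: PopulationSpec) -> None:
        st = state.get(s.cell_type)
        if st == 1:
            return
        if st == 0:
            raise ValueError(
                f"cyclic anchor dependency involving {s.cell_type!r}"
            )
        state[s.cell_type] = 0
        if s.pattern == "paired_attraction":
            anchor = s.attraction_params.anchor_type
            if anchor not in by_type:
                raise ValueError(
                    f"{s.cell_type!r} is attached to {anchor!r}, which has no spec"
                )
            visit(by_type[anchor])
        state[s.cell_type] = 1
        order.append(s)

    for s in specs:
        visit(s)
    return order


def _uniform_in_box(rng: np.random.Generator, domain: ROI, n: int) -> np.ndarray:
    lo = np.array([b[0] for b in domain.bounds_um])
    hi = np.array([b[1] for b in domain.bounds_um])
    return lo + rng.uniform(0.0, 1.0, size=(n, 3)) * (hi - lo)


def _attached_positions(
    rng: np.random.Generator,
    anchors: np.ndarray,
    n: int,
    dist_range: tuple[float, float],
    domain: ROI,
) -> np.ndarray:
    """Points on random spherical shells around anchors chosen with replacement.

    Anchors are drawn with replacement — a T cell may host several
    conjugates.  Positions falling outside the domain are redrawn (anchor
    included) so the inside-domain invariant holds.
    """
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        todo = n - filled
        anchor = anchors[rng.integers(0, len(anchors), size=todo)]
        direction = rng.normal(size=(todo, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = rng.uniform(dist_range[0], dist_range[1], size=(todo, 1))
        cand = anchor + direction * radius
        ok = np.ones(todo, dtype=bool)
        for axis, (lo, hi) in enumerate(domain.bounds_um):
            ok &= (cand[:, axis] >= lo) & (cand[:, axis] < hi)
        keep = cand[ok]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def simulate_point_pattern(
    domain: ROI, specs: list[PopulationSpec], seed: int
) -> GroundTruth:
    """Generate typed cell coordinates for every population spec.

    Populations with ``paired_attraction`` are generated after their anchor
    type (topological ordering; a cycle raises).  Counts follow
    ``Poisson(intensity × volume)``; attached cells sit on spherical shells
    around anchors at distances below the conjugation threshold; co-positive
    markers are emitted as duplicate coordinates under the second label.
    """
    if domain.volume_um3 <= 0:
        raise ValueError("domain volume must be > 0")
    order = _topological_order(list(specs))
    seq = np.random.SeedSequence(seed)
    streams = {s.cell_type: np.random.default_rng(child)
               for s, child in zip(order, seq.spawn(len(order)))}
    volume = domain.volume_um3
    parts: list[pd.DataFrame] = []
    generated: dict[str, np.ndarray] = {}

    for spec in order:
        rng = streams[spec.cell_type]
        n_total = rng.poisson(spec.intensity_per_um3 * volume)
        if spec.pattern == "poisson":
            xyz = _uniform_in_box(rng, domain, n_total)
        elif spec.pattern == "thomas_cluster":
            cp = spec.cluster_params
            n_parents = rng.poisson(cp.parent_intensity_per_um3 * volume)
            parents = _uniform_in_box(rng, domain, n_parents)
            chunks = []
            for p in parents:
                k = rng.poisson(cp.mean_offspring)
                off = p + rng.normal(0.0, cp.offspring_sigma_um, size=(k, 3))
                inside = np.ones(len(off), dtype=bool)
                for axis, (lo, hi) in enumerate(domain.bounds_um):
                    inside &= (off[:, axis] >= lo) & (off[:, axis] < hi)
                chunks.append(off[inside])
            xyz = np.concatenate(chunks) if chunks else np.empty((0, 3))
        else:  # paired_attraction
            ap = spec.attraction_params
            anchors = generated.get(ap.anchor_type, np.empty((0, 3)))
            n_attached = int(round(ap.attached_fraction * n_total))
            if len(anchors) == 0 and n_attached > 0:
                warnings.warn(
                    f"{spec.cell_type}: anchor type {ap.anchor_type!r} produced "
                    "no cells; attached cells fall back to uniform background"
                )
                n_attached = 0
            background = _uniform_in_box(rng, domain, n_total - n_attached)
            attached = (
                _attached_positions(rng, anchors, n_attached, ap.distance_range_um, domain)
                if n_attached
                else np.empty((0, 3))
            )
            xyz = np.concatenate([attached, background])
        generated[spec.cell_type] = xyz
        parts.append(make_point_set(xyz, spec.cell_type))
        if spec.copositive_with is not None and len(xyz):
            co = spec.copositive_with
            mask = rng.uniform(size=len(xyz)) < co.fraction
            parts.append(make_point_set(xyz[mask], co.marker))

    return GroundTruth(concat_point_sets(parts), list(specs), seed, domain)


def render_volume(
    truth: GroundTruth,
    acq: AcquisitionConfig,
    channel: str,
    seed: int = 0,
    peak_amplitude: float = 1000.0,
    background: float = 100.0,
    noise: bool = True,
    voxel_cap: int = 150_000_000,
) -> ImageVolume:
    """Render one marker channel of a ground-truth block as a z-stack.

    Each cell of the channel's marker becomes an anisotropic Gaussian blob
    (σ_xy, σ_z from the channel spec) with peak amplitude scaled by
    ``exp(−depth / attenuation_length)``, where depth is distance from the
    illuminated (z-low) face.  A constant background offset is added,
    Poisson shot noise applied if ``noise``, and the result quantized to the
    configured bit depth with saturation clipping.  Voxel (0,0,0) is
    centered half a voxel inside the field corner.
    """
    ch = acq.channel(channel)
    dz, dy, dx = acq.voxel_size_um
    size_x, size_y, size_z = truth.domain.size_um
    shape = (
        int(np.ceil(size_z / dz)),
        int(np.ceil(size_y / dy)),
        int(np.ceil(size_x / dx)),
    )
    n_vox = int(np.prod(shape))
    if n_vox > voxel_cap:
        raise MemoryError(
            f"render field {shape} = {n_vox} voxels exceeds the cap "
            f"({voxel_cap}); reduce the domain or raise voxel_cap explicitly"
        )
    field = np.zeros(shape, dtype=np.float64)
    lo = np.array([b[0] for b in truth.domain.bounds_um])  # (x, y, z) lower corner

    pts = truth.points
    pts = pts[pts["marker"] == channel]
    if len(pts):
        xyz = pts[["x_um", "y_um", "z_um"]].to_numpy(dtype=float) - lo
        sigma = np.array([ch.psf_sigma_z_um, ch.psf_sigma_xy_um, ch.psf_sigma_xy_um])
        voxel = np.array([dz, dy, dx])
        half = np.ceil(4.0 * sigma / voxel).astype(int)
        zyx = xyz[:, ::-1]  # physical (z, y, x)
        depth = xyz[:, 2]
        amps = peak_amplitude * np.exp(-depth / ch.attenuation_length_um)
        center_idx = zyx / voxel - 0.5  # voxel i center sits at (i + 0.5)·Δ
        for pos, idx, amp in zip(zyx, center_idx, amps):
            i0 = np.maximum(np.round(idx).astype(int) - half, 0)
            i1 = np.minimum(np.round(idx).astype(int) + half + 1, shape)
            if (i0 >= i1).any():
                continue
            grids = np.ogrid[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
            blob = amp
            for axis, g in enumerate(grids):
                centers_um = (g + 0.5) * voxel[axis]
                blob = blob * np.exp(
                    -((centers_um - pos[axis]) ** 2) / (2.0 * sigma[axis] ** 2)
                )
            field[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += blob

    field += background
    if noise:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        field = rng.poisson(field).astype(np.float64)
    top = 2 ** acq.bit_depth - 1
    field = np.clip(np.round(field), 0, top)
    dtype = np.uint16 if acq.bit_depth <= 16 else np.uint32
    corner = default_origin((dz, dy, dx))
    return ImageVolume(
        field.astype(dtype),
        voxel_size_um=(dz, dy, dx),
        channel=channel,
        # voxel (0,0,0) center half a voxel inside the domain's lower corner
        origin_um=(lo[2] + corner[0], lo[1] + corner[1], lo[0] + corner[2]),
    )


def tile_volume(
    volume: ImageVolume,
    acq: AcquisitionConfig,
    seed: int = 0,
    jitter_vox: int = 2,
) -> list[tuple[ImageTile, float]]:
    """Cut overlapping z-sections as the z stage would acquire them.

    Sections of ``section_depth_um`` are taken at nominal spacing
    ``z_stage_step_um``; the last section is shifted back so it ends at the
    volume bottom.  Each section start (except the first) gets a seeded
    integer jitter of at most ``jitter_vox`` voxels to exercise
    registration.  Returns ``(tile, true_offset_um)`` pairs: the tile
    carries the nominal offset, the true (jittered) offset is what
    registration should recover.
    """
    dz = volume.voxel_size_um[0]
    nz = volume.shape[0]
    n_section = int(round(acq.section_depth_um / dz))
    n_step = int(round(acq.z_stage_step_um / dz))
    if nz < n_section:
        raise ValueError(
            f"volume depth {nz * dz} μm is shallower than one optical "
            f"section ({acq.section_depth_um} μm)"
        )
    n_tiles = 1 if nz == n_section else int(np.ceil((nz - n_section) / n_step)) + 1
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[tuple[ImageTile, float]] = []
    for i in range(n_tiles):
        nominal = min(i * n_step, nz - n_section)
        jitter = 0
        if jitter_vox > 0 and i > 0:
            jitter = int(rng.integers(-jitter_vox, jitter_vox + 1))
        start = int(np.clip(nominal + jitter, 0, nz - n_section))
        section = ImageVolume(
            volume.intensities[start : start + n_section].copy(),
            voxel_size_um=volume.voxel_size_um,
            channel=volume.channel,
            origin_um=volume.origin_um,
        )
        tile = ImageTile(
            volume=section,
            nominal_offset_um=(nominal * dz, 0.0, 0.0),
            tile_index=i,
        )
        out.append((tile, start * dz))
    return out


# --------------------------------------------------------------------------
# Disease-group presets
# --------------------------------------------------------------------------

def disease_preset(group: str) -> list[PopulationSpec]:
    """Population specs emulating one disease condition's TME structure.

    Three conditions are packaged, mirroring the qualitative structure of
    reactive lymph node (RLN), diffuse large B-cell lymphoma (DLBCL) and
    angioimmunoblastic T-cell lymphoma (AITL) tissue: T cells are the most
    abundant type everywhere; B cells are enriched near T cells in the
    DLBCL-like condition; Treg and tumor-associated-macrophage neighborhoods
    around T cells are enriched (and neutrophils depleted) in the AITL-like
    condition; CD8 T-cell proliferation (Ki67 co-positivity) is highest in
    the RLN-like condition while B-cell proliferation is flat across groups.
    Absolute densities are order-of-magnitude choices in the
    10⁻⁵–10⁻⁴ cells/μm³ range, not claims about patient data.
    """
    group = group.upper()
    if group not in ("RLN", "DLBCL", "AITL"):
        raise ValueError(f"unknown disease group {group!r}; use RLN, DLBCL or AITL")

    def attracted(cell_type, intensity, fraction, ki67=None):
        return PopulationSpec(
            cell_type=cell_type,
            intensity_per_um3=intensity,
            pattern="paired_attraction",
            attraction_params=AttractionParams(
                anchor_type="CD3", attached_fraction=fraction
            ),
            copositive_with=(
                CopositiveSpec(marker="Ki67", fraction=ki67) if ki67 else None
            ),
        )

    t_cells = PopulationSpec(cell_type="CD3", intensity_per_um3=1e-4)
    if group == "RLN":
        return [
            t_cells,
            PopulationSpec(
                cell_type="CD8", intensity_per_um3=4e-5,
                copositive_with=CopositiveSpec(marker="Ki67", fraction=0.5),
            ),
            attracted("CD20", 5e-5, 0.10, ki67=0.30),
            attracted("FOXP3", 1.5e-5, 0.10),
            attracted("CD163", 2e-5, 0.10),
            attracted("CD15", 2e-5, 0.20),
            PopulationSpec(cell_type="CD68", intensity_per_um3=2e-5),
            PopulationSpec(cell_type="CD14", intensity_per_um3=2e-5),
        ]
    if group == "DLBCL":
        return [
            t_cells,
            PopulationSpec(
                cell_type="CD8", intensity_per_um3=4e-5,
                copositive_with=CopositiveSpec(marker="Ki67", fraction=0.3),
            ),
            attracted("CD20", 1e-4, 0.45, ki67=0.30),  # B-cell-dominated disease
            attracted("FOXP3", 1.5e-5, 0.10),
            attracted("CD163", 2e-5, 0.10),
            attracted("CD15", 2e-5, 0.20),
            PopulationSpec(cell_type="CD68", intensity_per_um3=2e-5),
            PopulationSpec(cell_type="CD14", intensity_per_um3=2e-5),
        ]
    # AITL: immunosuppressive neighborhoods around T cells
    return [
        t_cells,
        PopulationSpec(
            cell_type="CD8", intensity_per_um3=4e-5,
            copositive_with=CopositiveSpec(marker="Ki67", fraction=0.2),
        ),
        attracted("CD20", 5e-5, 0.10, ki67=0.30),
        attracted("FOXP3", 4e-5, 0.45),
        attracted("CD163", 4.5e-5, 0.45),
        attracted("CD15", 1e-5, 0.05),
        PopulationSpec(cell_type="CD68", intensity_per_um3=2e-5),
        PopulationSpec(cell_type="CD14", intensity_per_um3=2e-5),
    ]
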