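"""Registration and fusion of overlapping z-sections into one volume.

The acquisition tiles a sample in depth: ~300 μm optical sections taken at
250 μm z-stage steps, so consecutive sections share ~16.7% of their planes.
Registration here is a 1D search: the stage moves only in z between
sections, so each adjacent pair is aligned by the integer-voxel z shift that
maximizes normalized cross-correlation over the shared planes.  Fusion
feathers each tile linearly across the overlaps (blend weights sum to 1
everywhere), and copies voxels verbatim where only one tile contributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume


@dataclass
class ImageTile:
    """One optical z-section with its nominal stage position."""

    volume: ImageVolume
    nominal_offset_um: tuple[float, float, float]  # (z, y, x); z-dominant
    tile_index: int = 0


@dataclass
class StitchResult:
    fused: ImageVolume
    refined_offsets_um: list[tuple[float, float, float]]
    scores: list[float]  # peak normalized cross-correlation per adjacent pair


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape arrays."""
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def estimate_offset(
    tile_a: ImageTile,
    tile_b: ImageTile,
    search_radius_um: float = 10.0,
) -> tuple[tuple[float, float, float], float]:
    """Refine tile_b's z offset relative to tile_a by cross-correlation.

    Searches integer-voxel z shifts within ``search_radius_um`` of the
    nominal offset and returns the shift maximizing normalized
    cross-correlation over the overlapping planes, with ties broken toward
    the nominal.  A structureless (zero-variance) overlap returns the
    nominal offset with score 0 and a warning.
    """
    dz = tile_a.volume.voxel_size_um[0]
    nz_a = tile_a.volume.shape[0]
    nz_b = tile_b.volume.shape[0]
    nominal_vox = int(round((tile_b.nominal_offset_um[0] - tile_a.nominal_offset_um[0]) / dz))
    radius_vox = int(np.floor(search_radius_um / dz))
    if nz_a - nominal_vox < 10:
        raise ValueError(
            f"nominal overlap is {max(nz_a - nominal_vox, 0)} planes; "
            "need at least 10 for registration"
        )

    best_shift = nominal_vox
    best_score = -np.inf
    flat = True
    # candidates ordered by distance from nominal => ties resolve toward nominal
    for delta in sorted(range(-radius_vox, radius_vox + 1), key=abs):
        shift = nominal_vox + delta
        if shift < 0 or shift >= nz_a:
            continue
        n_overlap = min(nz_a - shift, nz_b)
        if n_overlap < 1:
            continue
        a = tile_a.volume.intensities[shift : shift + n_overlap]
        b = tile_b.volume.intensities[:n_overlap]
        if a.std() == 0 or b.std() == 0:
            continue
        flat = False
        score = _ncc(a, b)
        if score > best_score:
            best_score = score
            best_shift = shift
    if flat:
        warnings.warn("overlap has no structure; returning nominal offset, score 0")
        return (
            (
                tile_a.nominal_offset_um[0] + nominal_vox * dz,
                tile_b.nominal_offset_um[1],
                tile_b.nominal_offset_um[2],
            ),
            0.0,
        )
    z_um = tile_a.nominal_offset_um[0] + best_shift * dz
    return ((z_um, tile_b.nominal_offset_um[1], tile_b.nominal_offset_um[2]), best_score)


def fuse_tiles(
    tiles: list[ImageTile],
    offsets_um: list[tuple[float, float, float]],
) -> ImageVolume:
    """Blend z-tiles placed at the given offsets into one volume.

    Tiles are feathered along z (weight rises linearly from each tile edge),
    and the weighted contributions are normalized per voxel, so constants
    are preserved and blend weights sum to 1.  Offsets must form a
    connected chain in z: each tile must start inside or immediately after
    the extent covered so far.
    """
    if len(tiles) != len(offsets_um):
        raise ValueError("one offset per tile required")
    if not tiles:
        raise ValueError("no tiles to fuse")
    dz = tiles[0].volume.voxel_size_um[0]
    order = np.argsort([o[0] for o in offsets_um])
    tiles = [tiles[i] for i in order]
    offsets_um = [offsets_um[i] for i in order]
    z0 = offsets_um[0][0]
    starts = [int(round((o[0] - z0) / dz)) for o in offsets_um]
    ends = [s + t.volume.shape[0] for s, t in zip(starts, tiles)]
    covered = ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s > covered:
            raise ValueError(
                f"disconnected tile chain: gap of {s - covered} planes before "
                f"plane {s}"
            )
        covered = max(covered, e)
    nz = max(ends)
    ny, nx = tiles[0].volume.shape[1:]

    acc = np.zeros((nz, ny, nx), dtype=np.float64)
    wsum = np.zeros((nz, 1, 1), dtype=np.float64)
    for tile, start in zip(tiles, starts):
        data = tile.volume.intensities.astype(np.float64)
        n = data.shape[0]
        i = np.arange(n)
        w = np.minimum(i + 1, n - i).astype(np.float64)  # linear feather
        acc[start : start + n] += data * w[:, None, None]
        wsum[start : start + n, 0, 0] += w
    fused = acc / wsum
    ref = tiles[0].volume
    top = np.iinfo(ref.intensities.dtype).max if np.issubdtype(
        ref.intensities.dtype, np.integer
    ) else None
    if top is not None:
        fused = np.clip(np.round(fused), 0, top).astype(ref.intensities.dtype)
    return ImageVolume(
        fused,
        voxel_size_um=ref.voxel_size_um,
        channel=ref.channel,
        origin_um=ref.origin_um,
    )


def stitch(
    tiles: list[ImageTile],
    search_radius_um: float = 10.0,
) -> StitchResult:
    """Chain-register adjacent tiles and fuse them.

    Tile 0 anchors the frame; each subsequent tile's offset is refined
    against its predecessor and accumulated along the chain.
    """
    if not tiles:
        raise ValueError("no tiles")
    offsets: list[tuple[float, float, float]] = [tiles[0].nominal_offset_um]
    scores: list[float] = []
    for prev, cur in zip(tiles, tiles[1:]):
        # registration is pairwise; re-anchor the predecessor at its refined z
        anchored_prev = ImageTile(
            volume=prev.volume,
            nominal_offset_um=offsets[-1],
            tile_index=prev.tile_index,
        )
        shifted_cur = ImageTile(
            volume=cur.volume,
            nominal_offset_um=(
                offsets[-1][0]
                + (cur.nominal_offset_um[0] - prev.nominal_offset_um[0]),
                cur.nominal_offset_um[1],
                cur.nominal_offset_um[2],
            ),
            tile_index=cur.tile_index,
        )
        offset, score = estimate_offset(anchored_prev, shifted_cur, search_radius_um)
        offsets.append(offset)
        scores.append(score)
    fused = fuse_tiles(list(tiles), offsets)
    return StitchResult(fused, offsets, scores)
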