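"""Spatial statistics on typed 3D cell coordinates within ROIs.

Implements the four quantities used to characterize the lymphoma tumor
microenvironment from cell centroids:

* **density** — cells of a type per ROI volume (cells/mm³);
* **radial neighbor profile** — counts of neighbor-type cells in concentric
  5-μm shells out to 50 μm around each center T cell;
* **conjugation** — unordered pairs of cells of two different types whose
  centroids lie strictly closer than 15 μm, treated as interacting;
* **co-positivity** — the fraction of base-marker cells validated by a
  second-marker detection within a small matching radius (e.g. Ki67⁺CD8⁺).

All distances are Euclidean in physical μm.  ROI membership uses half-open
bounds: a point on the upper face is outside.  Radial bins are half-open
``[r, r+5)`` so the shells partition ``[0, 50)``; the conjugation threshold
is strict (``< 15 μm``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .points import coords, of_type


@dataclass(frozen=True)
class ROI:
    """Axis-aligned physical box ``[x0,x1) × [y0,y1) × [z0,z1)`` in μm."""

    bounds_um: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    label: str = "roi"

    def __post_init__(self) -> None:
        b = tuple((float(lo), float(hi)) for lo, hi in self.bounds_um)
        object.__setattr__(self, "bounds_um", b)
        for lo, hi in b:
            if not hi > lo:
                raise ValueError(f"degenerate ROI bounds {self.bounds_um}")

    @classmethod
    def from_size(cls, size_um, origin_um=(0.0, 0.0, 0.0), label="roi") -> "ROI":
        return cls(
            tuple((o, o + s) for o, s in zip(origin_um, size_um)), label=label
        )

    @property
    def size_um(self) -> tuple[float, float, float]:
        return tuple(hi - lo for lo, hi in self.bounds_um)

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.size_um))

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 * 1e-9

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Half-open membership mask for an (n, 3) array of (x, y, z) μm."""
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        mask = np.ones(len(xyz), dtype=bool)
        for axis, (lo, hi) in enumerate(self.bounds_um):
            mask &= (xyz[:, axis] >= lo) & (xyz[:, axis] < hi)
        return mask

    def clip(self, points: pd.DataFrame) -> pd.DataFrame:
        return points[self.contains(coords(points))]

    def shrink(self, margin_um: float) -> "ROI":
        """The ROI with every face moved inward by ``margin_um``."""
        b = tuple((lo + margin_um, hi - margin_um) for lo, hi in self.bounds_um)
        return ROI(b, label=self.label)


@dataclass
class RadialNeighborProfile:
    """Binned neighbor counts around center cells (5-μm shells, 0–50 μm)."""

    center_type: str
    neighbor_type: str
    bin_edges_um: np.ndarray
    total_count: np.ndarray
    n_centers: int

    @property
    def mean_count_per_center(self) -> np.ndarray:
        if self.n_centers == 0:
            return np.full(len(self.total_count), np.nan)
        return self.total_count / self.n_centers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_type": self.center_type,
                "neighbor_type": self.neighbor_type,
                "bin_lo_um": self.bin_edges_um[:-1],
                "bin_hi_um": self.bin_edges_um[1:],
                "total": self.total_count,
                "mean_per_center": self.mean_count_per_center,
                "n_centers": self.n_centers,
            }
        )


@dataclass
class ConjugationEntry:
    """Inter-type pair count within one ROI at the conjugation distance."""

    type_a: str
    type_b: str
    roi_label: str
    pair_count: int
    n_a: int
    n_b: int
    d_max_um: float


@dataclass
class CopositivityResult:
    numerator_type: str
    base_type: str
    match_radius_um: float
    n_double: int
    n_base: int

    @property
    def ratio(self) -> float:
        if self.n_base == 0:
            return float("nan")
        return self.n_double / self.n_base


def compute_density(points: pd.DataFrame, roi: ROI, cell_type: str) -> float:
    """Cells of ``cell_type`` inside ``roi`` divided by the ROI volume (mm³)."""
    if roi.volume_mm3 <= 0:
        raise ValueError("zero-volume ROI")
    typed = of_type(points, cell_type)
    n = int(roi.contains(coords(typed)).sum())
    return n / roi.volume_mm3


def radial_neighbor_profile(
    centers: pd.DataFrame,
    neighbors: pd.DataFrame,
    roi: ROI | None = None,
    r_max_um: float = 50.0,
    bin_um: float = 5.0,
    edge_policy: str = "interior_only",
) -> RadialNeighborProfile:
    """Count neighbor-type cells in concentric shells around each center cell.

    ``edge_policy="interior_only"`` (the default) drops centers closer than
    ``r_max_um`` to any ROI face so that every shell lies fully inside the
    ROI; this is what makes the homogeneous-Poisson expectation
    ``λ·(4/3)π(r₂³−r₁³)`` per shell hold without edge correction.
    ``"none"`` keeps every center.  A coincident record counted as both
    center and neighbor (same row of the same table) never counts as its own
    neighbor.
    """
    nbins = r_max_um / bin_um
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError(f"bin width {bin_um} must divide r_max {r_max_um} exactly")
    nbins = int(round(nbins))
    edges = np.arange(nbins + 1) * bin_um
    if edge_policy not in ("interior_only", "none"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")

    center_type = centers["marker"].iloc[0] if len(centers) else ""
    neighbor_type = neighbors["marker"].iloc[0] if len(neighbors) else ""
    same_table = centers is neighbors

    if roi is not None:
        centers = roi.clip(centers)
        neighbors = roi.clip(neighbors)
    if edge_policy == "interior_only":
        if roi is None:
            raise ValueError("edge_policy='interior_only' requires an ROI")
        if min(roi.size_um) <= 2 * r_max_um:
            centers = centers.iloc[0:0]  # the ROI has no r_max interior
        else:
            interior = roi.shrink(r_max_um)
            centers = centers[interior.contains(coords(centers))]

    n_centers = len(centers)
    total = np.zeros(nbins, dtype=np.int64)
    if n_centers == 0:
        warnings.warn("radial profile with no center cells; means are NaN")
        return RadialNeighborProfile(center_type, neighbor_type, edges, total, 0)
    if len(neighbors) == 0:
        return RadialNeighborProfile(center_type, neighbor_type, edges, total, n_centers)

    ctr = coords(centers)
    nbr = coords(neighbors)
    tree = cKDTree(nbr)
    hits = tree.query_ball_point(ctr, r_max_um)
    nbr_index = neighbors.index.to_numpy()
    ctr_index = centers.index.to_numpy()
    for i, hit in enumerate(hits):
        if not hit:
            continue
        hit = np.asarray(hit)
        d = np.linalg.norm(nbr[hit] - ctr[i], axis=1)
        if same_table:
            keep = nbr_index[hit] != ctr_index[i]  # a record is not its own neighbor
            d = d[keep]
        d = d[d < r_max_um]  # half-open outer edge
        total += np.bincount((d // bin_um).astype(int), minlength=nbins)[:nbins]
    return RadialNeighborProfile(center_type, neighbor_type, edges, total, n_centers)


def conjugation_count(
    points_a: pd.DataFrame,
    points_b: pd.DataFrame,
    roi: ROI,
    d_max_um: float = 15.0,
) -> ConjugationEntry:
    """Unordered inter-type pairs strictly closer than ``d_max_um`` in the ROI.

    Contractually equal to the O(n²) double loop; implemented with a KD-tree.
    """
    type_a = points_a["marker"].iloc[0] if len(points_a) else "a"
    type_b = points_b["marker"].iloc[0] if len(points_b) else "b"
    if len(points_a) and len(points_b) and type_a == type_b:
        raise ValueError("conjugation is defined between two different cell types")
    a = coords(roi.clip(points_a))
    b = coords(roi.clip(points_b))
    n_pairs = 0
    if len(a) and len(b):
        tree_b = cKDTree(b)
        hits = cKDTree(a).query_ball_tree(tree_b, d_max_um)
        for i, hit in enumerate(hits):
            if hit:
                d = np.linalg.norm(b[hit] - a[i], axis=1)
                n_pairs += int((d < d_max_um).sum())  # strict threshold
    return ConjugationEntry(type_a, type_b, roi.label, n_pairs, len(a), len(b), d_max_um)


def copositivity(
    points_marker: pd.DataFrame,
    points_base: pd.DataFrame,
    match_radius_um: float = 5.0,
) -> CopositivityResult:
    """Fraction of base cells with a marker detection within the match radius.

    Each marker point may validate at most one base cell; assignment is
    greedy nearest-first so coincident detections pair up exactly.
    """
    if match_radius_um <= 0:
        raise ValueError("match_radius_um must be > 0")
    numerator_type = points_marker["marker"].iloc[0] if len(points_marker) else "marker"
    base_type = points_base["marker"].iloc[0] if len(points_base) else "base"
    n_base = len(points_base)
    if n_base == 0:
        warnings.warn("co-positivity with empty base set; ratio is NaN")
        return CopositivityResult(numerator_type, base_type, match_radius_um, 0, 0)
    if len(points_marker) == 0:
        return CopositivityResult(numerator_type, base_type, match_radius_um, 0, n_base)

    m = coords(points_marker)
    b = coords(points_base)
    pairs = _pairs_within(m, b, match_radius_um)
    marker_used = np.zeros(len(m), dtype=bool)
    base_hit = np.zeros(len(b), dtype=bool)
    for d, i, j in pairs:
        if not marker_used[i] and not base_hit[j]:
            marker_used[i] = True
            base_hit[j] = True
    return CopositivityResult(
        numerator_type, base_type, match_radius_um, int(base_hit.sum()), n_base
    )


def _pairs_within(a: np.ndarray, b: np.ndarray, r: float) -> list[tuple[float, int, int]]:
    """All (distance, i, j) with |a_i − b_j| ≤ r, ascending by distance."""
    hits = cKDTree(a).query_ball_tree(cKDTree(b), r)
    out: list[tuple[float, int, int]] = []
    for i, hit in enumerate(hits):
        for j in hit:
            out.append((float(np.linalg.norm(a[i] - b[j])), i, j))
    out.sort()
    return out


def select_rois(
    domain: ROI,
    n: int = 10,
    roi_shape_um: tuple[float, float, float] = (100.0, 100.0, 100.0),
    seed: int = 0,
    min_gap_um: float = 0.0,
    max_attempts: int = 20000,
) -> list[ROI]:
    """Seeded rejection sampling of ``n`` non-overlapping ROIs inside a domain.

    ROIs are axis-aligned boxes of ``roi_shape_um`` fully inside ``domain``,
    pairwise separated by at least ``min_gap_um`` (box faces).  Raises if the
    packing cannot be achieved within ``max_attempts`` draws.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in domain.bounds_um])
    hi = np.array([b[1] for b in domain.bounds_um])
    shape = np.asarray(roi_shape_um, dtype=float)
    slack = hi - lo - shape
    if (slack < 0).any():
        raise ValueError(
            f"ROI shape {tuple(shape)} does not fit in domain {domain.bounds_um}"
        )
    placed: list[np.ndarray] = []
    attempts = 0
    stuck = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} ROIs of shape {tuple(shape)} with gap "
                f"{min_gap_um} μm in {domain.bounds_um} after {max_attempts} "
                f"attempts ({len(placed)} placed); shrink the ROIs or the gap"
            )
        attempts += 1
        corner = lo + rng.uniform(0.0, 1.0, size=3) * slack
        ok = True
        for other in placed:
            # disjoint (with gap) iff separated along at least one axis
            sep = (corner >= other + shape + min_gap_um) | (
                other >= corner + shape + min_gap_um
            )
            if not sep.any():
                ok = False
                break
        if ok:
            placed.append(corner)
            stuck = 0
        else:
            stuck += 1
            if stuck >= 500:  # jammed partial packing: restart the draw
                placed.clear()
                stuck = 0
    return [
        ROI.from_size(tuple(shape), origin_um=tuple(c), label=f"roi{i:02d}")
        for i, c in enumerate(placed)
    ]
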