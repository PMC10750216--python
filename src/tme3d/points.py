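"""Typed 3D cell coordinates — the unit analysis object.

A cell point set is a pandas DataFrame with columns ``x_um, y_um, z_um,
marker`` and optionally ``quality``.  Coordinates are physical micrometers in
a right-handed frame with 0 at the volume origin.  Markers come from the
immune panel used for lymphoma tissue blocks.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Immune-cell / proliferation marker panel.
MARKER_PANEL: tuple[str, ...] = (
    "CD3", "CD8", "CD20", "CD68", "CD163", "CD14", "CD15", "FOXP3", "Ki67",
)

REQUIRED_COLUMNS = ("x_um", "y_um", "z_um", "marker")


def make_point_set(
    coords_um: np.ndarray,
    marker: str | Sequence[str],
    quality: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build a point-set DataFrame from an ``(n, 3)`` array of (x, y, z) μm."""
    coords_um = np.asarray(coords_um, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(coords_um, columns=["x_um", "y_um", "z_um"])
    df["marker"] = marker if not isinstance(marker, str) else marker
    df["quality"] = 1.0 if quality is None else np.asarray(quality, dtype=float)
    return df


def coords(points: pd.DataFrame) -> np.ndarray:
    """Extract the ``(n, 3)`` (x, y, z) coordinate array."""
    return points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def of_type(points: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Rows of one marker."""
    return points[points["marker"] == marker]


def validate_point_set(
    points: pd.DataFrame,
    panel: Iterable[str] = MARKER_PANEL,
    require_panel: bool = True,
) -> pd.DataFrame:
    """Validate schema, coordinate finiteness and marker membership.

    Raises ``ValueError`` naming the first offending row, per the I/O
    contract: an unknown marker must never pass silently.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"point set missing required columns: {missing}")
    xyz = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xyz).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite coordinate at row {row}")
    if "quality" in points.columns:
        q = points["quality"].to_numpy(dtype=float)
        if (q < 0).any():
            row = int(np.flatnonzero(q < 0)[0])
            raise ValueError(f"negative quality at row {row}")
    if require_panel:
        panel = set(panel)
        unknown = ~points["marker"].isin(panel)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValueError(
                f"unknown marker {points['marker'].iloc[row]!r} at row {row}; "
                f"panel is {sorted(panel)}"
            )
    return points


def concat_point_sets(parts: Sequence[pd.DataFrame]) -> pd.DataFrame:
    parts = [p for p in parts if len(p)]
    if not parts:
        return make_point_set(np.empty((0, 3)), marker="CD3").iloc[0:0]
    return pd.concat(parts, ignore_index=True)
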