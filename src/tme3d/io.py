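"""Reading and writing the pipeline's interchange formats.

Volumes travel as multi-page TIFF with ImageJ-style metadata (plane spacing,
lateral resolution, unit); point sets as CSV with an ``x_um, y_um, z_um,
marker`` schema (coordinates written to 0.001 μm); configs and manifests as
JSON.  A volume without voxel-size metadata is an error unless an explicit
override is given — isotropy is never assumed silently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .points import validate_point_set
from .volume import ImageVolume


def write_volume(path, volume: ImageVolume) -> None:
    dz, dy, dx = volume.voxel_size_um
    tifffile.imwrite(
        str(path),
        volume.intensities,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "um",
            "channel": volume.channel,
            "origin_zyx_um": json.dumps(list(volume.origin_um)),
        },
    )


def read_volume(path, voxel_size_um=None, channel: str | None = None) -> ImageVolume:
    """Read a multi-page TIFF as an ImageVolume.

    ``voxel_size_um`` (dz, dy, dx) overrides file metadata; if the file has
    no voxel-size metadata and no override is given, this is an error.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        page = tif.pages[0]
        if voxel_size_um is None:
            spacing = meta.get("spacing")
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if spacing is None or xres is None or yres is None:
                raise ValueError(
                    f"{path}: no voxel-size metadata; pass voxel_size_um "
                    "explicitly (isotropy is never assumed)"
                )
            dx = xres.value[1] / xres.value[0]
            dy = yres.value[1] / yres.value[0]
            voxel_size_um = (float(spacing), float(dy), float(dx))
        origin = (0.0, 0.0, 0.0)
        if "origin_zyx_um" in meta:
            origin = tuple(json.loads(meta["origin_zyx_um"]))
        if channel is None:
            channel = str(meta.get("channel", ""))
    if data.ndim == 2:
        data = data[None]
    return ImageVolume(data, voxel_size_um=voxel_size_um, channel=channel,
                       origin_um=origin)


def write_points(path, points: pd.DataFrame) -> None:
    df = points.copy()
    for c in ("x_um", "y_um", "z_um"):
        df[c] = df[c].round(3)  # interchange precision: 0.001 μm
    df.to_csv(path, index=False, float_format="%.3f")


def read_points(path, require_panel: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_point_set(df, require_panel=require_panel)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
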