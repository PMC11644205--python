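"""TIFF / CSV interchange for scenes, FUI maps and profiles.

Scenes travel as plain multiband TIFFs (tifffile): five float32 bands in
order 443, 482, 561, 655 nm, QA (1 = clear sky), with the water mask as a
uint8 sidecar `<stem>_water.tif`.  Acquisition dates come from a manifest
CSV (`scene,date`) or from a trailing `_YYYYMMDD` in the file name.
FUI maps are written as uint8 with 0 = nodata.
"""

from __future__ import annotations

import datetime as dt
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .raster import FuiScene, Scene

__all__ = [
    "write_scene",
    "read_scene",
    "write_fui_map",
    "read_fui_map",
    "date_from_filename",
    "write_manifest",
    "read_manifest",
]

_DATE_RE = re.compile(r"(\d{8})(?:\D[^/\\]*)?$")


def water_sidecar(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_water.tif")


def write_scene(path, scene: Scene) -> Path:
    """Write a Scene as a 5-band TIFF plus the water-mask sidecar."""
    path = Path(path)
    stack = np.concatenate(
        [
            np.moveaxis(scene.rrs, -1, 0).astype(np.float32),
            scene.clear[None].astype(np.float32),
        ]
    )
    tifffile.imwrite(path, stack)
    tifffile.imwrite(water_sidecar(path), scene.water.astype(np.uint8))
    return path


def date_from_filename(path) -> dt.date:
    """Parse a trailing _YYYYMMDD date out of a scene file name."""
    m = _DATE_RE.search(Path(path).stem)
    if not m:
        raise ValueError(f"no YYYYMMDD date in file name {Path(path).name!r}")
    return dt.datetime.strptime(m.group(1), "%Y%m%d").date()


def read_scene(path, water_path=None, date=None) -> Scene:
    """Read a 5-band scene TIFF (+ water sidecar) back into a Scene."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] < 5:
        raise ValueError(
            f"{path.name}: expected 5 bands (443/482/561/655/QA), "
            f"got shape {stack.shape}"
        )
    water_path = water_sidecar(path) if water_path is None else Path(water_path)
    water = tifffile.imread(water_path).astype(bool)
    if date is None:
        date = date_from_filename(path)
    return Scene(
        rrs=np.moveaxis(stack[:4], 0, -1).astype(float),
        water=water,
        clear=stack[4] > 0.5,
        date=date,
    )


def write_fui_map(path, fscene: FuiScene) -> Path:
    """FUI raster as uint8, 0 = nodata (invalid or off-water)."""
    path = Path(path)
    out = np.where(fscene.valid, fscene.fui, 0).astype(np.uint8)
    tifffile.imwrite(path, out)
    return path


def read_fui_map(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_manifest(path, entries) -> Path:
    """Manifest CSV: columns scene (file name) and date (ISO)."""
    path = Path(path)
    pd.DataFrame(entries, columns=["scene", "date"]).to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"scene", "date"} <= set(df.columns):
        raise ValueError("manifest needs columns 'scene' and 'date'")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df
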