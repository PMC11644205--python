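"""Scene-level FUI retrieval and latitudinal reduction.

A Scene is a small multiband raster of a river channel: four reflectance
bands on a shared grid, a clear-sky QA mask (cloud masking is consumed,
never computed here), and a water mask.  Row 0 is the northernmost
latitude; "latitudinal blocking" averages FUI within contiguous bands of
rows to build an along-river profile, the standard reduction for narrow
north-south tributary channels.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromaticity import (
    DEFAULT_CORRECTION_PRESET,
    FuiLookupTable,
    classify_fui,
    classify_scheme,
    correct_hue_angle,
    hue_angle,
    rrs_to_xyz,
    xyz_to_xy,
)

__all__ = [
    "Scene",
    "FuiScene",
    "retrieve_fui_scene",
    "latitudinal_profile",
    "scene_mean_fui",
    "scheme_area_fractions",
]


@dataclass
class Scene:
    """One acquisition: reflectance cube plus masks.

    rrs   : float array (rows, cols, 4), bands 443/482/561/655 nm
    water : bool array (rows, cols), True on the water extent
    clear : bool array (rows, cols), True where the QA band is cloud-free
    date  : acquisition date
    """

    rrs: np.ndarray
    water: np.ndarray
    clear: np.ndarray
    date: dt.date

    def __post_init__(self) -> None:
        self.rrs = np.asarray(self.rrs, dtype=float)
        self.water = np.asarray(self.water, dtype=bool)
        self.clear = np.asarray(self.clear, dtype=bool)
        if self.rrs.ndim != 3 or self.rrs.shape[-1] != 4:
            raise ValueError("rrs must have shape (rows, cols, 4)")
        if self.water.shape != self.rrs.shape[:2]:
            raise ValueError("water mask shape does not match the band grid")
        if self.clear.shape != self.rrs.shape[:2]:
            raise ValueError("QA mask shape does not match the band grid")
        if isinstance(self.date, str):
            self.date = dt.date.fromisoformat(self.date)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rrs.shape[:2]


@dataclass
class FuiScene:
    """Per-pixel FUI map with validity bookkeeping.

    fui    : int16 (rows, cols), level 1..21 on valid water, 0 elsewhere
    scheme : int8 (rows, cols), Scheme code on valid water, -1 elsewhere
    valid  : bool (rows, cols), True where a FUI level was retrieved
    water  : bool (rows, cols), the scene's water extent
    date   : acquisition date
    """

    fui: np.ndarray
    scheme: np.ndarray
    valid: np.ndarray
    water: np.ndarray
    date: dt.date
    alpha_t: np.ndarray | None = field(default=None, repr=False)

    @property
    def valid_fraction(self) -> float:
        """Fraction of water pixels with a retrieved FUI level."""
        n_water = int(self.water.sum())
        if n_water == 0:
            return float("nan")
        return float(self.valid.sum() / n_water)


def retrieve_fui_scene(
    scene: Scene,
    table: FuiLookupTable | None = None,
    preset=DEFAULT_CORRECTION_PRESET,
    scale: float = 1.0,
    offset: float = 0.0,
) -> FuiScene:
    """Run the chromaticity chain over every valid water pixel of a scene.

    `scale`/`offset` convert integer surface-reflectance digital numbers to
    Rrs (rrs = dn * scale + offset).  Pixels that are cloudy, off-water,
    non-finite, negative after scaling, or chromatically degenerate are
    masked invalid — never clipped or zero-filled.
    """
    rrs = scene.rrs * scale + offset
    finite = np.all(np.isfinite(rrs), axis=-1)
    nonneg = np.all(np.where(np.isfinite(rrs), rrs, -1.0) >= 0.0, axis=-1)
    candidate = scene.water & scene.clear & finite & nonneg

    fui = np.zeros(scene.shape, dtype=np.int16)
    scheme = np.full(scene.shape, -1, dtype=np.int8)
    alpha_t_map = np.full(scene.shape, np.nan)

    if candidate.any():
        xyz = rrs_to_xyz(rrs[candidate])
        x, y = xyz_to_xy(xyz)
        alpha = hue_angle(x, y)
        _, alpha_t = correct_hue_angle(alpha, preset)
        levels = classify_fui(alpha_t, table)
        ok = levels > 0  # degenerate chromaticities drop out here
        idx = np.flatnonzero(candidate.ravel())[ok]
        fui.ravel()[idx] = levels[ok]
        alpha_t_map.ravel()[idx] = alpha_t[ok]
        scheme.ravel()[idx] = classify_scheme(levels[ok])

    valid = fui > 0
    return FuiScene(
        fui=fui,
        scheme=scheme,
        valid=valid,
        water=scene.water.copy(),
        date=scene.date,
        alpha_t=alpha_t_map,
    )


def latitudinal_profile(fscene: FuiScene, block_size_px: int) -> pd.DataFrame:
    """Mean FUI per contiguous band of `block_size_px` raster rows.

    Blocks are indexed north -> south (row 0 = northernmost).  A trailing
    partial block is kept and flagged.  Block means are reported only where
    the block holds at least one valid pixel (NaN otherwise, mirroring the
    blank-when-cloudy convention of archive composites).

    Returns a DataFrame with columns block, mean_fui, n_valid, partial.
    """
    if block_size_px < 1:
        raise ValueError("block_size_px must be >= 1")
    n_rows = fscene.fui.shape[0]
    if block_size_px > n_rows:
        warnings.warn(
            f"block size {block_size_px} exceeds raster height {n_rows}; "
            "using a single block",
            stacklevel=2,
        )
    edges = np.arange(0, n_rows, block_size_px)
    records = []
    for b, start in enumerate(edges):
        stop = min(start + block_size_px, n_rows)
        vals = fscene.fui[start:stop][fscene.valid[start:stop]]
        n = int(vals.size)
        records.append(
            {
                "block": b,
                "mean_fui": float(vals.mean()) if n else np.nan,
                "n_valid": n,
                "partial": stop - start < block_size_px,
            }
        )
    return pd.DataFrame.from_records(records)


def scene_mean_fui(fscene: FuiScene) -> float:
    """Mean FUI over valid pixels; NaN (missing) when no pixel is valid."""
    vals = fscene.fui[fscene.valid]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def scheme_area_fractions(fscene: FuiScene) -> np.ndarray:
    """Fractions of valid pixels in each colour scheme (blueish..yellowish).

    Sums to 1; all-NaN when the scene has no valid pixel.
    """
    codes = fscene.scheme[fscene.valid]
    if codes.size == 0:
        return np.full(4, np.nan)
    counts = np.bincount(codes, minlength=4)[:4]
    return counts / codes.size
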