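"""CIE chromaticity core: 4-band reflectance -> hue angle -> Forel-Ule index.

The Forel-Ule index (FUI) is a 21-level ordinal water-colour scale running
from deep blue (1) to brown-yellow (21).  For a multispectral sensor the
retrieval chain is

    Rrs(443, 482, 561, 561, 655)  --linear interpolation model-->  CIE XYZ
    XYZ  --normalisation-->  chromaticity (x, y)
    (x, y)  --angle about the white point-->  hue angle alpha
    alpha  --quintic deviation correction-->  alpha_t
    alpha_t  --21-level lookup table-->  FUI  -->  4-class colour scheme

Every step exists in a scalar form (the reference path used by tests and by
the synthetic-data generator for truth records) and a vectorised form used
by the raster pipeline.  Hue angles are expressed in degrees on [0, 360),
measured counterclockwise from the +x' axis about the white point
(0.3333, 0.3333); under this convention the published 21-level lookup
table is strictly decreasing from blue (~230 deg) to yellow (~21 deg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "XYZ_FROM_RRS",
    "WHITE_POINT",
    "Scheme",
    "SpectralSample",
    "TristimulusTriple",
    "ChromaticityPoint",
    "HueAngleResult",
    "FuiLookupTable",
    "LookupTableError",
    "InvalidPixelError",
    "load_correction_presets",
    "resolve_correction",
    "DEFAULT_CORRECTION_PRESET",
    "rrs_to_xyz",
    "xyz_to_xy",
    "hue_angle",
    "correct_hue_angle",
    "classify_fui",
    "classify_scheme",
    "scheme_name",
    "describe_sample",
    "rgb_model_fui",
]

# Interpolation-model matrix: rows X, Y, Z; columns Rrs443, Rrs482, Rrs561, Rrs655.
XYZ_FROM_RRS = np.array(
    [
        [11.053, 6.950, 51.135, 34.457],
        [1.320, 21.053, 66.023, 18.034],
        [58.083, 34.931, 2.606, 0.016],
    ]
)

# White point used for the hue-angle offsets; the literal 0.3333, not 1/3.
WHITE_POINT = 0.3333

DEFAULT_CORRECTION_PRESET = "published-oli"

# Linear sRGB -> XYZ (D65) applied to the 655/561/482 bands treated as R/G/B.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)


class InvalidPixelError(ValueError):
    """A scalar conversion hit a degenerate input (zero tristimulus sum,
    exact white point, non-finite band)."""


class LookupTableError(ValueError):
    """Malformed FUI lookup table (wrong length, non-monotonic boundaries)."""


class Scheme(IntEnum):
    """Four-class water-colour scheme grouping the 21 FUI levels.

    blueish   1 <= FUI < 6   low suspended sediment and algae density
    cyanish   6 <= FUI < 9   moderate dissolved organics and algae density
    greenish  9 <= FUI < 13  high algae density
    yellowish FUI >= 13      high suspended sediment and dissolved organics
    """

    BLUEISH = 0
    CYANISH = 1
    GREENISH = 2
    YELLOWISH = 3


SCHEME_NAMES = ("blueish", "cyanish", "greenish", "yellowish")


class SpectralSample(NamedTuple):
    """One pixel's remote-sensing reflectance at 443/482/561/655 nm (sr^-1)."""

    rrs443: float
    rrs482: float
    rrs561: float
    rrs655: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


class TristimulusTriple(NamedTuple):
    X: float
    Y: float
    Z: float


class ChromaticityPoint(NamedTuple):
    """CIE-xy coordinates plus white-point-centred offsets x' = x - 0.3333."""

    x: float
    y: float
    x_prime: float
    y_prime: float


@dataclass(frozen=True)
class HueAngleResult:
    """Full scalar retrieval record for one spectrum."""

    xyz: TristimulusTriple
    chromaticity: ChromaticityPoint
    alpha: float          # raw hue angle, degrees
    b: float              # alpha / 100
    delta_alpha: float    # quintic correction, degrees
    alpha_t: float        # corrected hue angle, degrees
    fui: int              # 1..21
    scheme: Scheme


def load_correction_presets() -> dict[str, np.ndarray]:
    """Shipped quintic deviation-coefficient presets, degree 5 down to constant."""
    text = resources.files("forelule.data").joinpath(
        "hue_angle_correction_presets.json"
    ).read_text()
    raw = json.loads(text)
    return {
        name: np.asarray(coeffs, dtype=float)
        for name, coeffs in raw.items()
        if not name.startswith("_")
    }


def resolve_correction(preset: str | Sequence[float]) -> np.ndarray:
    """Resolve a preset name or explicit 6-vector into polynomial coefficients."""
    if isinstance(preset, str):
        presets = load_correction_presets()
        try:
            return presets[preset]
        except KeyError:
            raise KeyError(
                f"unknown correction preset {preset!r}; "
                f"shipped presets: {sorted(presets)}"
            ) from None
    coeffs = np.asarray(preset, dtype=float)
    if coeffs.shape != (6,):
        raise ValueError("correction coefficients must be 6 values, degree 5..0")
    return coeffs


@dataclass(frozen=True)
class FuiLookupTable:
    """21-level FUI lookup: upper hue-angle boundary per level, degrees.

    Boundaries decrease strictly with increasing FUI level (blue water has
    large hue angles).  Level k occupies [boundary(k+1), boundary(k));
    an angle exactly on a boundary is assigned the bluer (lower) level.
    Angles above the level-1 boundary clamp to 1, below the level-21
    boundary clamp to 21.
    """

    levels: np.ndarray       # 1..21
    alpha_upper: np.ndarray  # degrees, strictly decreasing

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=int)
        upper = np.asarray(self.alpha_upper, dtype=float)
        if levels.shape != (21,) or upper.shape != (21,):
            raise LookupTableError("lookup table must have exactly 21 levels")
        if not np.array_equal(levels, np.arange(1, 22)):
            raise LookupTableError("lookup levels must be 1..21 in order")
        if not np.all(np.isfinite(upper)):
            raise LookupTableError("lookup boundaries must be finite")
        if not np.all(np.diff(upper) < 0):
            raise LookupTableError(
                "lookup boundaries must decrease strictly with FUI level"
            )
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "alpha_upper", upper)
        # Ascending internal boundaries b(21)..b(2) for searchsorted.
        object.__setattr__(self, "_asc", upper[1:][::-1].copy())

    @classmethod
    def from_csv(cls, path) -> "FuiLookupTable":
        df = pd.read_csv(path, comment="#")
        if not {"fui", "alpha_upper_deg"} <= set(df.columns):
            raise LookupTableError(
                "lookup CSV needs columns 'fui' and 'alpha_upper_deg'"
            )
        df = df.sort_values("fui")
        return cls(df["fui"].to_numpy(), df["alpha_upper_deg"].to_numpy())

    @classmethod
    def default(cls) -> "FuiLookupTable":
        with resources.as_file(
            resources.files("forelule.data").joinpath("fui_hue_angle_table.csv")
        ) as p:
            return cls.from_csv(p)

    def classify(self, alpha_t):
        """Vectorised hue angle -> FUI level; NaN angles map to 0 (invalid)."""
        at = np.asarray(alpha_t, dtype=float)
        # count of internal boundaries <= alpha (ties go to the bluer level)
        counts = np.searchsorted(self._asc, at, side="right")
        fui = (21 - counts).astype(np.int16)
        fui = np.where(np.isnan(at), np.int16(0), fui)
        return fui if fui.ndim else int(fui)


def _default_table_cache() -> FuiLookupTable:
    global _TABLE_CACHE
    try:
        return _TABLE_CACHE
    except NameError:
        _TABLE_CACHE = FuiLookupTable.default()
        return _TABLE_CACHE


def rrs_to_xyz(rrs) -> np.ndarray:
    """Interpolation model: reflectance (..., 4) -> CIE tristimulus (..., 3).

    A fixed linear map; non-finite inputs propagate as NaN rather than
    being zeroed.
    """
    rrs = np.asarray(rrs, dtype=float)
    if rrs.shape[-1] != 4:
        raise ValueError("expected 4 reflectance bands in the last axis")
    return rrs @ XYZ_FROM_RRS.T


def xyz_to_xy(xyz) -> tuple[np.ndarray, np.ndarray]:
    """Normalise tristimulus values to chromaticity coordinates.

    x = X / (X+Y+Z), y = Y / (X+Y+Z); a non-positive sum yields NaN
    (the invalid-pixel signal in the vectorised path).
    """
    xyz = np.asarray(xyz, dtype=float)
    total = xyz.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(total > 0, total, np.nan)
        x = xyz[..., 0] / safe
        y = xyz[..., 1] / safe
    return x, y


def hue_angle(x, y) -> np.ndarray:
    """Hue angle about the white point, degrees on [0, 360).

    alpha = atan2(y - 0.3333, x - 0.3333), counterclockwise from the +x'
    axis; the exact white point yields NaN.
    """
    xp = np.asarray(x, dtype=float) - WHITE_POINT
    yp = np.asarray(y, dtype=float) - WHITE_POINT
    alpha = np.degrees(np.arctan2(yp, xp)) % 360.0
    alpha = np.where((xp == 0) & (yp == 0), np.nan, alpha)
    return alpha if alpha.ndim else float(alpha)


def correct_hue_angle(alpha, preset=DEFAULT_CORRECTION_PRESET):
    """Quintic multiband deviation correction.

    b = alpha/100; delta_alpha = poly(b) with the preset's coefficients;
    returns (delta_alpha, alpha_t = alpha + delta_alpha).  The correction
    compensates the bias of reconstructing a continuous spectrum from four
    discrete bands.
    """
    coeffs = resolve_correction(preset)
    alpha = np.asarray(alpha, dtype=float)
    delta = np.polyval(coeffs, alpha / 100.0)
    out = delta, alpha + delta
    if alpha.ndim:
        return out
    return float(out[0]), float(out[1])


def classify_fui(alpha_t, table: FuiLookupTable | None = None):
    """Corrected hue angle -> FUI level 1..21 via the lookup table."""
    table = table if table is not None else _default_table_cache()
    return table.classify(alpha_t)


def classify_scheme(fui):
    """FUI level(s) -> colour-scheme code(s) (Scheme IntEnum values).

    Raises on levels outside 1..21; vectorised input returns int8 codes.
    """
    arr = np.asarray(fui)
    if arr.ndim == 0:
        level = int(arr)
        if not 1 <= level <= 21:
            raise ValueError(f"FUI level {level} outside 1..21")
        if level < 6:
            return Scheme.BLUEISH
        if level < 9:
            return Scheme.CYANISH
        if level < 13:
            return Scheme.GREENISH
        return Scheme.YELLOWISH
    if arr.size and (arr.min() < 1 or arr.max() > 21):
        raise ValueError("FUI levels outside 1..21")
    codes = np.full(arr.shape, Scheme.YELLOWISH, dtype=np.int8)
    codes[arr < 13] = Scheme.GREENISH
    codes[arr < 9] = Scheme.CYANISH
    codes[arr < 6] = Scheme.BLUEISH
    return codes


def scheme_name(scheme) -> str:
    return SCHEME_NAMES[int(scheme)]


def describe_sample(
    sample: SpectralSample,
    table: FuiLookupTable | None = None,
    preset=DEFAULT_CORRECTION_PRESET,
) -> HueAngleResult:
    """Scalar reference path: one spectrum through the full retrieval chain.

    Raises :class:`InvalidPixelError` on non-finite bands, a non-positive
    tristimulus sum, or a chromaticity exactly at the white point.
    """
    rrs = np.asarray(sample, dtype=float)
    if not np.all(np.isfinite(rrs)):
        raise InvalidPixelError("non-finite reflectance")
    X, Y, Z = rrs_to_xyz(rrs)
    total = X + Y + Z
    if not total > 0:
        raise InvalidPixelError("non-positive tristimulus sum")
    x, y = X / total, Y / total
    alpha = hue_angle(x, y)
    if np.isnan(alpha):
        raise InvalidPixelError("chromaticity at the white point")
    delta, alpha_t = correct_hue_angle(alpha, preset)
    fui = classify_fui(alpha_t, table)
    return HueAngleResult(
        xyz=TristimulusTriple(float(X), float(Y), float(Z)),
        chromaticity=ChromaticityPoint(
            float(x), float(y), float(x - WHITE_POINT), float(y - WHITE_POINT)
        ),
        alpha=float(alpha),
        b=float(alpha) / 100.0,
        delta_alpha=float(delta),
        alpha_t=float(alpha_t),
        fui=int(fui),
        scheme=classify_scheme(int(fui)),
    )


def rgb_model_fui(sample, table: FuiLookupTable | None = None):
    """Alternative FUI retrieval from the three primary-colour bands only.

    The 655/561/482 nm bands are treated as linear R/G/B and mapped to XYZ
    with the sRGB/D65 matrix, then classified through the shared
    xy -> alpha -> FUI path.  No deviation correction is applied: the
    quintic is calibrated for the 4-band interpolation reconstruction.
    Provided for model comparison only; the main pipeline never uses it.
    Accepts a SpectralSample or an (..., 4) band array; vectorised input
    returns levels with 0 marking invalid pixels.
    """
    rrs = np.asarray(sample, dtype=float)
    scalar = rrs.ndim == 1
    rgb = rrs[..., [3, 2, 1]]  # 655 -> R, 561 -> G, 482 -> B
    xyz = rgb @ _SRGB_TO_XYZ.T
    x, y = xyz_to_xy(xyz)
    alpha = hue_angle(x, y)
    fui = classify_fui(alpha, table)
    if scalar:
        if int(fui) == 0:
            raise InvalidPixelError("degenerate RGB input")
        return int(fui)
    return fui
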