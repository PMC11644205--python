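"""Synthetic tributary scenes and driver series with known ground truth.

The generator emulates the structure of a narrow, north-south oriented
river channel observed by a 4-band multispectral sensor: an
upstream-to-downstream water-colour gradient built by convex mixing of
four reference ("endmember") Rrs spectra, one per colour scheme; a
seasonal colour cycle with a linear interannual drift; a sediment plume
near the estuary; optional bloom patches; additive per-band Gaussian
noise; and contiguous rectangular cloud gaps.  Every scene carries a
truth record (per-pixel FUI and scheme, per-block mean FUI) computed at
generation time by pushing the noiseless spectra through the scalar
chromaticity chain, so pipeline output can be checked against designed
truth rather than against itself.

Driver series are built constructively: a driver with target correlation
r is an exact unit-norm combination r*z + sqrt(1-r^2)*e of the
standardized FUI series z and residualized independent noise e, then
rescaled to physical units; a target of exactly 0 yields pure independent
noise (so null drivers keep the honest sampling distribution of r).
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromaticity import (
    DEFAULT_CORRECTION_PRESET,
    FuiLookupTable,
    SpectralSample,
    classify_scheme,
    describe_sample,
    scheme_name,
)
from .raster import FuiScene, Scene, latitudinal_profile

__all__ = [
    "ENDMEMBER_RRS",
    "EndmemberValidationError",
    "ScenarioConfig",
    "DriverScenario",
    "SceneTruth",
    "make_endmember_spectra",
    "mix_endmembers",
    "make_scene",
    "make_fui_series",
    "make_monthly_fui_series",
    "make_driver_series",
    "acquisition_dates",
    "simulate_decade",
]

# Reference Rrs spectra (443/482/561/655 nm, sr^-1), one per colour scheme.
# Chosen to sit mid-interval (FUI ~3/7/11/15) so band noise at the default
# sigma rarely crosses a scheme boundary; re-validated through the scalar
# chain every time make_endmember_spectra runs.
ENDMEMBER_RRS = {
    "blueish": (0.0105, 0.0083, 0.0038, 0.0007),
    "cyanish": (0.0060, 0.0090, 0.0120, 0.0030),
    "greenish": (0.0038, 0.0075, 0.0158, 0.0060),
    "yellowish": (0.0030, 0.0060, 0.0180, 0.0125),
}

_SCHEME_ORDER = ("blueish", "cyanish", "greenish", "yellowish")


class EndmemberValidationError(RuntimeError):
    """An endmember's pipeline FUI missed its target scheme interval."""


def make_endmember_spectra(
    table: FuiLookupTable | None = None,
    preset=DEFAULT_CORRECTION_PRESET,
) -> dict[str, SpectralSample]:
    """Return the four scheme endmembers, validated through the pipeline.

    Each spectrum is run through the scalar chromaticity chain under the
    given lookup table and correction preset; generation fails loudly if
    any endmember's FUI lands outside its named scheme.
    """
    out = {}
    for name, rrs in ENDMEMBER_RRS.items():
        sample = SpectralSample(*rrs)
        result = describe_sample(sample, table=table, preset=preset)
        got = scheme_name(result.scheme)
        if got != name:
            raise EndmemberValidationError(
                f"endmember {name!r} classifies as {got!r} (FUI {result.fui}) "
                "under the current lookup table / correction preset"
            )
        out[name] = sample
    return out


def mix_endmembers(t, endmembers=None) -> np.ndarray:
    """Convex mixing along the blueish -> yellowish chain.

    t in [0, 1] (scalar or array) moves piecewise-linearly through the
    four endmembers (t = 0, 1/3, 2/3, 1 are the pure spectra).  Returns
    spectra with shape t.shape + (4,).
    """
    if endmembers is None:
        ems = np.array([ENDMEMBER_RRS[k] for k in _SCHEME_ORDER])
    else:
        ems = np.array([np.asarray(endmembers[k], float) for k in _SCHEME_ORDER])
    t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
    s = t * 3.0
    i = np.minimum(s.astype(int), 2)
    w = s - i
    return (1.0 - w)[..., None] * ems[i] + w[..., None] * ems[i + 1]


@dataclass(frozen=True)
class ScenarioConfig:
    """Geometry, optics and dynamics of a synthetic tributary.

    Colour state is a chain position in [0, 1] (0 = blueish endmember,
    1 = yellowish endmember); the latitudinal gradient runs from
    `color_north` (upstream, row 0) to `color_south` (downstream), with a
    sediment plume pushing the last `plume_rows` rows toward yellow, a
    seasonal sinusoid of amplitude `seasonal_amplitude` peaking at
    `seasonal_peak_doy`, and a linear interannual drift of
    `interannual_slope` chain units per year from `start_year`.
    """

    n_rows: int = 240
    n_cols: int = 40
    width_north_px: int = 8
    width_south_px: int = 28
    color_north: float = 0.15
    color_south: float = 0.70
    plume_rows: int = 30
    plume_strength: float = 0.15
    bloom: tuple | None = None  # (row0, row1, col0, col1, delta_t)
    seasonal_amplitude: float = 0.10
    seasonal_peak_doy: int = 185
    interannual_slope: float = 0.0
    start_year: int = 2013
    noise_sigma: float = 0.0003
    cloud_fraction: float = 0.0
    block_size_px: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must be at least 1x1")
        if min(self.width_north_px, self.width_south_px) < 1:
            raise ValueError("channel width must be >= 1 px (zero-width channel)")
        if max(self.width_north_px, self.width_south_px) > self.n_cols:
            raise ValueError("channel wider than the grid")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud_fraction must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class SceneTruth:
    """Designed truth for one generated scene (noiseless, cloud-free)."""

    fui: np.ndarray      # int16, 0 off-water
    scheme: np.ndarray   # int8, -1 off-water
    block_mean_fui: pd.DataFrame
    scene_mean_fui: float
    scheme_fractions: np.ndarray
    chain_offset: float  # seasonal + trend colour-state offset applied


def _channel_mask(cfg: ScenarioConfig) -> np.ndarray:
    rows = np.arange(cfg.n_rows)
    frac = rows / max(cfg.n_rows - 1, 1)
    width = np.rint(
        cfg.width_north_px + (cfg.width_south_px - cfg.width_north_px) * frac
    ).astype(int)
    half_lo = width // 2
    half_hi = width - half_lo
    center = cfg.n_cols // 2
    cols = np.arange(cfg.n_cols)
    return (cols >= (center - half_lo)[:, None]) & (cols < (center + half_hi)[:, None])


def _chain_field(cfg: ScenarioConfig, date: dt.date) -> tuple[np.ndarray, float]:
    """Per-pixel chain position for the given date, plus the scalar offset."""
    rows = np.arange(cfg.n_rows)
    frac = rows / max(cfg.n_rows - 1, 1)
    t_row = cfg.color_north + (cfg.color_south - cfg.color_north) * frac
    if cfg.plume_rows > 0 and cfg.plume_strength != 0:
        ramp = np.clip(
            (rows - (cfg.n_rows - cfg.plume_rows)) / max(cfg.plume_rows, 1), 0, None
        )
        t_row = t_row + cfg.plume_strength * ramp
    doy = date.timetuple().tm_yday
    seasonal = cfg.seasonal_amplitude * math.cos(
        2.0 * math.pi * (doy - cfg.seasonal_peak_doy) / 365.25
    )
    years = (date - dt.date(cfg.start_year, 1, 1)).days / 365.25
    offset = seasonal + cfg.interannual_slope * years
    t = np.repeat((t_row + offset)[:, None], cfg.n_cols, axis=1)
    if cfg.bloom is not None:
        r0, r1, c0, c1, delta = cfg.bloom
        t[r0:r1, c0:c1] += delta
    return np.clip(t, 0.0, 1.0), offset


def _paint_clouds(
    shape: tuple[int, int], water: np.ndarray, fraction: float, rng
) -> np.ndarray:
    """Contiguous rectangular cloud gaps until >= `fraction` of the water
    pixels are covered.  Returns the clear-sky mask."""
    clear = np.ones(shape, dtype=bool)
    if fraction <= 0:
        return clear
    if fraction >= 1.0:
        return np.zeros(shape, dtype=bool)
    n_water = max(int(water.sum()), 1)
    n_rows, n_cols = shape
    for _ in range(1000):
        covered = (~clear & water).sum() / n_water
        if covered >= fraction:
            break
        h = int(rng.integers(max(n_rows // 10, 1), max(n_rows // 3, 2)))
        w = int(rng.integers(max(n_cols // 4, 1), n_cols + 1))
        r = int(rng.integers(0, max(n_rows - h, 1)))
        c = int(rng.integers(0, max(n_cols - w, 1)))
        clear[r : r + h, c : c + w] = False
    return clear


def _scene_rng(cfg: ScenarioConfig, date: dt.date):
    # independent stream per (seed, date): same scene regardless of call order
    return np.random.default_rng([cfg.seed, date.toordinal()])


def make_scene(
    cfg: ScenarioConfig,
    date,
    rng=None,
    table: FuiLookupTable | None = None,
    preset=DEFAULT_CORRECTION_PRESET,
) -> tuple[Scene, SceneTruth]:
    """Generate one dated scene plus its truth record.

    Truth is computed by running every distinct noiseless spectrum through
    the scalar chromaticity chain under the same lookup table and
    correction preset the consumer will use.
    """
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    if rng is None:
        rng = _scene_rng(cfg, date)
    water = _channel_mask(cfg)
    t_field, offset = _chain_field(cfg, date)
    spectra = mix_endmembers(t_field)

    # truth from the noiseless spectra, one scalar evaluation per distinct state
    fui_truth = np.zeros(water.shape, dtype=np.int16)
    uniq, inverse = np.unique(np.round(t_field, 12), return_inverse=True)
    levels = np.empty(uniq.shape, dtype=np.int16)
    for k, tv in enumerate(uniq):
        sample = SpectralSample(*mix_endmembers(tv))
        levels[k] = describe_sample(sample, table=table, preset=preset).fui
    fui_truth[water] = levels[inverse.reshape(water.shape)][water]
    scheme_truth = np.full(water.shape, -1, dtype=np.int8)
    scheme_truth[water] = classify_scheme(fui_truth[water])

    truth_scene = FuiScene(
        fui=fui_truth,
        scheme=scheme_truth,
        valid=water.copy(),
        water=water.copy(),
        date=date,
    )
    blocks = latitudinal_profile(truth_scene, cfg.block_size_px)
    counts = np.bincount(scheme_truth[water], minlength=4)[:4]
    truth = SceneTruth(
        fui=fui_truth,
        scheme=scheme_truth,
        block_mean_fui=blocks,
        scene_mean_fui=float(fui_truth[water].mean()),
        scheme_fractions=counts / max(int(water.sum()), 1),
        chain_offset=offset,
    )

    if cfg.noise_sigma > 0:
        spectra = spectra + rng.normal(0.0, cfg.noise_sigma, spectra.shape)
    clear = _paint_clouds(water.shape, water, cfg.cloud_fraction, rng)
    scene = Scene(rrs=spectra, water=water, clear=clear, date=date)
    return scene, truth


def make_fui_series(
    n_periods: int = 11,
    start_period: int = 2013,
    base: float = 9.0,
    slope: float = 0.0,
    sigma: float = 0.0,
    rng=None,
) -> pd.DataFrame:
    """Synthetic yearly FUI series: base + slope * index + N(0, sigma)."""
    rng = np.random.default_rng(rng)
    idx = np.arange(n_periods)
    y = base + slope * idx + (rng.normal(0.0, sigma, n_periods) if sigma > 0 else 0.0)
    return pd.DataFrame(
        {"period": start_period + idx, "mean_fui": y, "n_scenes": 1}
    )


def make_monthly_fui_series(
    base: float = 9.5,
    amplitude: float = 2.0,
    peak_month: int = 7,
    sigma: float = 0.0,
    rng=None,
) -> pd.DataFrame:
    """12-point month-of-year composite with a single seasonal peak."""
    rng = np.random.default_rng(rng)
    months = np.arange(1, 13)
    y = base + amplitude * np.cos(2.0 * np.pi * (months - peak_month) / 12.0)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, 12)
    return pd.DataFrame({"period": months, "mean_fui": y, "n_scenes": 1})


@dataclass(frozen=True)
class DriverScenario:
    """Target Pearson correlations (driver -> FUI series) and output units.

    A target of exactly 0 produces pure independent noise; any other
    target is hit exactly in-sample by construction.  `units` maps driver
    name to (mean, sd) in physical units.
    """

    target_r: dict = field(
        default_factory=lambda: {
            "precipitation": 0.0,
            "sunshine": 0.0,
            "air_temperature": 0.0,
            "ndvi": 0.0,
            "water_level": 0.0,
        }
    )
    units: dict = field(
        default_factory=lambda: {
            "precipitation": (1100.0, 180.0),   # mm / yr
            "sunshine": (1300.0, 120.0),        # h / yr
            "air_temperature": (18.0, 0.6),     # deg C
            "ndvi": (0.55, 0.05),               # dimensionless
            "water_level": (160.0, 8.0),        # m
        }
    )
    seed: int = 0


def make_driver_series(
    scenario: DriverScenario, fui_series: pd.DataFrame, rng=None
) -> pd.DataFrame:
    """Driver series with designed correlation to a FUI series.

    For target r != 0 the realized in-sample Pearson correlation equals
    the target exactly (unit-vector construction); |r| may only drift from
    the target through later missing-data alignment.  Targets outside
    [-1, 1] are rejected; n < 3 is refused.
    """
    if rng is None:
        # keyed stream so a shared integer seed never collides with the
        # stream that generated the FUI series itself
        rng = np.random.default_rng([scenario.seed, 0x0D21])
    else:
        rng = np.random.default_rng(rng)
    f = fui_series["mean_fui"].to_numpy(float)
    n = f.size
    if n < 3:
        raise ValueError("need at least 3 periods to build driver series")
    fc = f - f.mean()
    norm = np.linalg.norm(fc)
    if norm == 0:
        raise ValueError("FUI series has zero variance; correlations undefined")
    z0 = fc / norm

    out = {"period": fui_series["period"].to_numpy()}
    for name, target in scenario.target_r.items():
        if not -1.0 <= target <= 1.0:
            raise ValueError(f"target correlation for {name!r} outside [-1, 1]")
        mean, sd = scenario.units.get(name, (0.0, 1.0))
        eps = rng.normal(size=n)
        if target == 0.0:
            d = eps - eps.mean()
            d = d / (np.linalg.norm(d) or 1.0)
        else:
            e = eps - eps.mean()
            e = e - (e @ z0) * z0
            e_norm = np.linalg.norm(e)
            if e_norm == 0:
                warnings.warn(
                    f"driver {name!r}: no independent noise direction at n={n}; "
                    "correlation will be +-1",
                    stacklevel=2,
                )
                e = np.zeros(n)
            else:
                e = e / e_norm
            d = target * z0 + math.sqrt(max(1.0 - target**2, 0.0)) * e
        out[name] = mean + sd * d * math.sqrt(max(n - 1, 1))
    return pd.DataFrame(out)


def acquisition_dates(
    start_year: int = 2013, n_years: int = 11, scenes_per_month: int = 2
) -> list[dt.date]:
    """Regular acquisition calendar: `scenes_per_month` dates per month."""
    days = {1: (15,), 2: (8, 23)}.get(scenes_per_month)
    if days is None:
        days = tuple(
            int(d) for d in np.linspace(5, 25, scenes_per_month).round()
        )
    return [
        dt.date(year, month, day)
        for year in range(start_year, start_year + n_years)
        for month in range(1, 13)
        for day in days
    ]


def simulate_decade(
    cfg: ScenarioConfig,
    n_years: int = 11,
    scenes_per_month: int = 2,
    table: FuiLookupTable | None = None,
    preset=DEFAULT_CORRECTION_PRESET,
    keep_profiles: bool = False,
):
    """Generate and retrieve a full multi-year scene archive.

    Returns (scene_means, profiles) where scene_means is a DataFrame with
    one row per acquisition (date, mean_fui, truth_mean_fui,
    valid_fraction) and profiles (when requested) is the concatenated
    per-scene latitudinal profile table.  Retrieval runs through
    raster.retrieve_fui_scene, never through the truth record.
    """
    from .raster import retrieve_fui_scene, scene_mean_fui

    rows = []
    profiles = []
    for date in acquisition_dates(cfg.start_year, n_years, scenes_per_month):
        scene, truth = make_scene(cfg, date, table=table, preset=preset)
        fscene = retrieve_fui_scene(scene, table=table, preset=preset)
        rows.append(
            {
                "date": date,
                "mean_fui": scene_mean_fui(fscene),
                "truth_mean_fui": truth.scene_mean_fui,
                "valid_fraction": fscene.valid_fraction,
            }
        )
        if keep_profiles:
            prof = latitudinal_profile(fscene, cfg.block_size_px)
            prof.insert(0, "date", date)
            profiles.append(prof)
    scene_means = pd.DataFrame(rows)
    prof_df = pd.concat(profiles, ignore_index=True) if profiles else None
    return scene_means, prof_df
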