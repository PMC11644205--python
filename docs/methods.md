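# Methods

## The retrieval model

`forelule` estimates the Forel–Ule index (FUI) — the classical 21-level
ordinal water-colour scale, deep blue (1) to brown-yellow (21) — from
four-band remote-sensing reflectance at 443, 482, 561 and 655 nm (the
coastal/blue/green/red bands of a Landsat-8-class sensor).

**Tristimulus interpolation.** Because a multispectral sensor samples the
visible spectrum at a few discrete bands, the CIE tristimulus integrals are
approximated by a fixed linear combination of the bands (the *interpolation
model*):

```
X = 11.053·Rrs443 +  6.950·Rrs482 + 51.135·Rrs561 + 34.457·Rrs655
Y =  1.320·Rrs443 + 21.053·Rrs482 + 66.023·Rrs561 + 18.034·Rrs655
Z = 58.083·Rrs443 + 34.931·Rrs482 +  2.606·Rrs561 +  0.016·Rrs655
```

All coefficients are non-negative, so non-negative reflectance yields
non-negative XYZ. Chromaticity coordinates are the normalisation
x = X/(X+Y+Z), y = Y/(X+Y+Z).

**Hue angle.** The hue angle is the polar angle of the chromaticity point
about the white point, α = atan2(y − 0.3333, x − 0.3333), expressed in
degrees on **[0, 360)**, counterclockwise with 0° on the +x′ axis. The
literal constant 0.3333 is used throughout, not 1/3. The [0, 360)
branch was chosen (over a (−180, 180] mapping of the same angle) because
the published 21-level hue-angle table spans ≈21°–230°: with the seam at
0°/360° the table is strictly monotonic, and the seam sits on the purple
line that natural water colours never cross.

**Deviation correction.** Reconstructing a continuous spectrum from four
bands biases the hue angle; the standard remedy is a quintic in
b = α/100, Δα = c₅b⁵ + … + c₀, applied as α_t = α + Δα. Three
coefficient presets are shipped because the final terms of this
polynomial are frequently mangled in print:

| preset | final terms | note |
|---|---|---|
| `published-oli` | −533.61·b + 76.72 | complete published polynomial; **default** |
| `linear-final-term` | −533.61·b (no constant) | truncated reading |
| `as-printed` | bare constant −533.61 | as sometimes typeset |

The default was chosen on a reachability argument: under either truncated
reading Δα ≈ −60…−80° across the entire natural hue-angle range, which
makes FUI levels 1–5 (blueish water) unreachable for *any* chromaticity —
a correction that can never classify clear blue water as blue is not
usable as a default. Every CLI run logs the preset in effect, and any
6-coefficient vector can be supplied instead.

**Lookup table.** FUI levels come from a versioned CSV
(`forelule/data/fui_hue_angle_table.csv`) giving each level's upper
hue-angle boundary; boundaries are midpoints between the hue angles of
adjacent Forel–Ule comparator classes (CIE 1931 2° observer) and decrease
strictly from ~232° (level 1 ceiling) to ~22.6°. Intervals are half-open
with ties assigned to the bluer (lower) level; angles beyond either end
clamp to levels 1 and 21. The table is user-overridable (`--lookup`).

**Colour schemes.** Levels group into four schemes: blueish (1–5),
cyanish (6–8), greenish (9–12), yellowish (13–21) — low sediment/algae,
moderate organics, algal-bloom dominated, and sediment/organics dominated
water respectively.

**RGB comparison model.** An alternative retrieval maps the 655/561/482
bands through the linear sRGB→XYZ (D65) matrix and then the shared
xy → α → FUI path, with no deviation correction (the quintic is calibrated
for the 4-band interpolation, not for a 3-primary superposition). It
exists only for model comparison; on synthetic eutrophic spectra it reads
systematically bluer (lower FUI) than the interpolation model, the known
failure mode that motivates the interpolation model for inland waters.

## Raster pipeline

Scenes are small multiband rasters with a water mask and a clear-sky QA
mask; cloud masking and atmospheric correction are *consumed*, never
computed. Pixels that are off-water, cloudy, non-finite, negative after
DN scaling, or chromatically degenerate are masked invalid and propagate
as missing — never clipped or zero-filled. Row 0 is the northernmost
latitude; the latitudinal profile averages valid-pixel FUI in contiguous
bands of N rows (N = 30 for wide tributaries, 5 for short ones, in the
motivating application), keeping and flagging a trailing partial block.
Block means are simple valid-pixel means (not width-weighted across the
variable channel); a block with no valid pixel is reported missing, not
zero.

## Trends and attribution

Scene means aggregate to calendar-year means or to month-of-year
composites (12 values pooling all years; monthly driver correlations are
therefore computed at n = 12). Change rates are OLS slopes on (period,
mean FUI), requiring ≥ 3 points, skipping — never interpolating — missing
periods. Pearson r uses two-sided t-distribution p-values (n − 2 df),
pairwise deletion, and no multiple-testing correction. The cloud-gap
sensitivity analysis refits the trend after excluding years with fewer
than `min_scenes` scenes (default 1) and counts points outside the 95%
OLS prediction interval.

The joint attribution z-scores all five drivers (precipitation, sunshine
duration, air temperature, NDVI, water level) and the FUI series,
fits them together by least squares (listwise deletion), and splits the
explained variance by absolute standardized coefficient:

```
contribution_i = |β_i| / Σ_j |β_j| · R² · 100 %,   residual = (1 − R²) · 100 %
```

This rule was chosen because it is order-independent, scale-invariant,
and conserves 100% exactly; the LMG averaging-over-orderings
decomposition is a noted alternative, not implemented. Note the usual
caveat of any |β|-based split: with strongly collinear drivers and short
series the weight concentrates on the driver closest to the response and
co-varying drivers' shares shrink — the per-driver Pearson r is reported
alongside for exactly this reason. Rank-deficient designs drop the
offending driver with a warning rather than failing.

**Dominance rule.** A driver is flagged dominant when its contribution
exceeds 35%, or when it reaches 10–35% with |r| ≥ 0.6 and p < 0.05.

## Synthetic data

The generator emulates a narrow north–south river channel: a channel mask
whose width grows downstream, per-pixel spectra mixed convexly along a
blueish→cyanish→greenish→yellowish endmember chain (upstream blue-green,
downstream yellower, with a sediment plume near the "estuary" and
optional bloom patches), a seasonal colour cycle peaking around day 185
with a linear interannual drift, additive Gaussian band noise (default
σ = 3×10⁻⁴ sr⁻¹; negatives are left for the pipeline to mask), and
contiguous rectangular cloud gaps painted until a target coverage
fraction is reached. The default archive is 11 years × 2 scenes/month on
a 240 × 40 grid.

Endmember spectra are defined in Rrs space and validated *through the
pipeline itself* every time they are requested — generation fails loudly
if any endmember's FUI leaves its scheme under the active lookup table
and preset — so a change of table or preset cannot silently invalidate
the ground truth. Truth records (per-pixel FUI/scheme, per-block mean)
are computed at generation time by the scalar reference chain on the
noiseless spectra.

Driver series are constructive: for a target correlation r ≠ 0 the driver
is r·ẑ + √(1−r²)·ê with ẑ the unit-norm centred FUI series and ê
unit-norm residualized noise, so the in-sample Pearson correlation equals
the target exactly before unit scaling; a target of exactly 0 yields pure
independent noise so null drivers keep the honest sampling distribution
of r. Driver randomness is keyed off the seed on a separate stream so a
shared integer seed cannot collide with the series' own noise stream.

**What the generator does not emulate:** radiative transfer or bio-optical
inversion (endmembers are plausible but not physically derived),
sensor-geometry effects, adjacency or sun-glint, spatially correlated
noise, realistic revisit gaps (acquisitions are on a fixed calendar), or
lagged driver–colour causality. Passing tests therefore demonstrate that
the *pipeline machinery* is correct and that the statistics recover
designed signals at realistic noise — not that any specific real-world
water body behaves this way.

## Numerical choices and degenerate inputs

- Invalid pixels signal as masked values (vector path) or
  `InvalidPixelError` (scalar path); an all-invalid scene yields a missing
  (NaN) mean, never zero.
- Lookup ties go to the bluer level; clamping handles angles outside the
  table.
- Standardization uses the population std (ddof = 0); contributions are
  invariant to this choice.
- Problem sizes in the test-suite and acceptance script (e.g. a 512×128
  oracle-equivalence scene, 200–500 seed replicates, an 11-year ×
  2 scenes/month noiseless archive on a 180×32 grid) were chosen as the
  smallest sizes at which the statistical properties under test are
  stable.

## Known limitations

- No geo-referencing: rasters are plain TIFF grids; reprojection,
  mosaicking and shapefile handling are out of scope.
- The embedded lookup boundaries are a documented reconstruction
  (class-angle midpoints); any application with its own calibrated table
  should supply it via `--lookup`.
- The attribution is correlational; no causal or lagged analysis is
  attempted.
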