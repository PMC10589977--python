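# Methods

## Model and conventions

All analysis operates on a 2-D non-negative `float64` raster in *signal-high*
polarity (bands bright). Rows are the migration direction; coordinates are
0-based, row-major, with half-open integer ranges. Polarity conversion
(`invert`: `max − pixels`) happens exactly once, at read time, so no later
stage needs to reason about sign. RGB input is reduced to Rec.709 luminance
(0.2126 R + 0.7152 G + 0.0722 B).

## Background subtraction

The default method is rolling-ball subtraction realized as grayscale
morphological opening with a **flat disk** structuring element (erosion then
dilation, `scipy.ndimage` grey morphology with a `skimage` disk footprint).
A flat element rather than a true hemisphere was chosen deliberately:

* min/max filtering commutes with positive scaling, so background
  subtraction — and hence every normalized value — is exactly invariant
  under global exposure changes;
* opening is anti-extensive and idempotent, which gives testable guarantees
  (residual `0 ≤ out ≤ in`; the background estimate is a fixed point);
* it removes any bright feature that cannot contain the disk, which is the
  practical purpose of the rolling ball on blots.

The radius must exceed the band footprint; the package default is 50 px,
and the synthetic-panel analyses use 20 px for their ≈15 px bands. A second
method, `flat_percentile`, subtracts a single global intensity percentile —
a deliberately simple alternative that is useful as a contrast in tests
and for images with genuinely flat background.

On a noisy image, opening tracks a low envelope of the noise, so the
residual retains a roughly uniform positive offset (≈2–3 σ of the noise)
with slow spatial variation on the scale of the disk. This is expected and
is what the per-lane baseline absorbs.

## Lane profiles

A lane is a polyline of nodes `(row y, center x, half-width w)`, linearly
interpolated in both `x` and `w`. Node rows must strictly increase — the
testable form of forbidding horizontal lane segments, which the per-row
profile representation cannot express. The profile integrates horizontally:
for each integer row, `p[y]` sums the pixels whose integer column center
lies within `|x − x_c(y)| ≤ w(y)`, clipped at the image edges (clipping is
permitted and logged, since tight crops routinely truncate outer lanes).

Two design choices keep the profile an exact pixel sum, checkable against a
brute-force loop to 1e-9:

* integration is along the row, not perpendicular to the path — no
  resampling, and band selections survive lateral lane adjustments;
* a column either contributes fully or not at all (no fractional edge
  weighting), making the sum order-independent and exactly linear in the
  raster.

Units: `p[y]` is intensity·px; the measurement `v = Σ (p[y] − b(y))` over a
half-open row region is intensity·px², a plain discrete sum (no trapezoid
correction — the profile is a per-row aggregate, not samples of a smooth
function).

## Baselines

The per-lane baseline is piecewise-linear through anchors `(y, b ≥ 0)` with
constant extrapolation beyond the ends; the default is identically zero. In
scripted analyses the anchors may be given as `auto_rows`: the engine pins
each anchor to the mean profile value over ±4 rows (configurable) around a
stated band-free row, emulating the interactive gesture of resting the
baseline on the profile between bands. The resolved numeric anchors — not
the rule — are what the analysis log records, so replay is independent of
the resolution procedure. Negative measurement values are allowed (baseline
above signal) but logged as warnings.

## Normalization

Per image and measurement type, the reference value is
`r = (1/R) Σ v_i/m_i` over reference lanes with successful measurements
(`R ≥ 1`), and every successful lane reports `w = (v/m)/r`. Consequences
used as test invariants: the mean of `w` over successful reference lanes is
1 to machine precision; `w` is invariant under rescaling all intensities by
`k > 0` (exactly, because the flat-disk background is scale-equivariant)
and under rescaling all protein amounts. Normalization is strictly
per-image; comparability across gels comes from physically sharing
reference samples, not from any statistical coupling. Lanes with no
protein amount are excluded from both the reference average and the
normalized output, with a warning; an image whose reference lanes all
failed raises an error for normalization while raw values remain
exportable.

## Datastore and replay

A single-file SQLite store holds the project hierarchy (adjacency list,
acyclic by construction from path-based creation), gels and their lane
sample records, measurement types, images (path + SHA-256 content hash
fixed at ingest), measurements, and the analysis log. All tables and views
carry a `gelquant_` namespace prefix so the layout ports to a schema in a
shared server database unchanged. Three SQL views expose finished results —
project full paths (recursive CTE), per-image reference values `(r, R)`,
and normalized values `w` computed directly in SQL — so R or any SQL client
can fetch results without running Python. The spreadsheet export (XLSX
workbook or CSV pair; raw sheet: gel, image, measurement type, lane,
sample, m, v, success; normalized sheet adds r and w) is generated from the
same queries, and round-trips against the views in tests.

The analysis log stores each operation (`read_image`, `crop`,
`subtract_background`, `measure_lane`) with its complete parameters in
canonical JSON: sorted keys, minimal separators, shortest exact round-trip
float representation. Replay re-executes the log against the source image
(refusing if the content hash changed) and asserts bit-identical equality
with every stored value; SQLite REAL is IEEE double, so storage is
lossless. A failed analysis run never touches the log: parameters are
validated by executing them first, then logged.

Viewing versus editing is a property of the store handle
(`open_store(path, readonly=True)`), not a UI state: read-only handles
serve all queries, views and replay, and raise on any mutation.

## Synthetic gels and what they do (not) show

The generator renders lanes along parabolic center lines
`x(y) = x0 + c (y − H/2)²` with 2-D Gaussian bands whose horizontal center
follows the curve, normalized so the pixel sum of a band equals its
injected amount within 0.5 % discretization for σ ≥ 1 px. Background is a
planar gradient plus an optional broad blob; noise is seeded i.i.d.
Gaussian, default σ = 1 % of the peak band intensity — a realistic level
for a well-exposed 16-bit acquisition; the image clamps at zero. The same
spec and seed reproduce the raster bit-identically. Validation rules:
bands inside the image at 3σ, lane centers separated by more than 3σ of
both lanes' widest bands.

The standard self-validation panel is 20 gels of 5 curved lanes × 3 bands
(170×160 px, band σ 2.5 px, amounts drawn from [5000, 50000], curvature up
to ≈4 px of bow) — sizes chosen so the whole experiment, including
morphological opening, runs in seconds. Recovery uses regions of ±4σ
around each band and baselines auto-anchored on band-free rows; typical
results are Pearson r ≈ 0.998 against injected amounts with ≈2.5 % median
relative error, the residual error being dominated by the noisy background
envelope described above.

What the generator does **not** emulate: membrane texture, saturation and
blooming, ladder bleed-through into adjacent lanes, dust and scratches, or
nonlinear stain response. Passing tests therefore demonstrate that the
geometry and arithmetic of the pipeline are correct and self-consistent —
not that any particular stain or detector behaves linearly.

## Numerical notes

* Exact additivity of measurements over adjacent regions holds when the
  summands are exactly representable (e.g. integer intensities with dyadic
  baseline slopes); with arbitrary floats it holds to rounding.
* `np.interp` provides both the path interpolation and baseline evaluation,
  giving constant extrapolation beyond baseline anchors for free.
* The `flat_percentile` level uses `np.percentile` (linear interpolation
  midpoint convention).
* Crop rectangles compose exactly (`outer.compose(inner)`), and cropping
  copies — operations never alias or mutate their input raster.

## Known limitations

* No automatic lane or band detection: geometry is always declared.
* Rolling-ball radius is a user responsibility; a radius smaller than a
  band's footprint silently eats signal (the synthetic tests would catch a
  regression in the opening itself, not a bad user choice).
* Multi-page TIFFs require explicit page selection; no multi-channel
  fluorescence support.
* The store targets single-user embedded use; no concurrency control
  beyond SQLite's.
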