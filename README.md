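# gelquant

Headless, replayable densitometry for gel electrophoresis and blot images.

Quantifying a Western blot (or Southern/Northern blot, or isoelectric
focusing gel) means turning band intensities on an image into numbers that
can be compared across lanes, images and gels. Doing that reproducibly is
hard with interactive tools: the background subtraction, lane placement,
baseline and integration bounds live in clicks that nobody records.
`gelquant` is a library (plus a thin CLI) for doing the same analysis as
scripted, recorded steps: every operation and its full parameters are logged
in an embedded SQLite store, so any stored result can be re-derived
bit-for-bit from the original image, and the raw/normalized result tables
are plain SQL views any statistics environment can read.

It is aimed at wet-lab groups and analysts who want blot quantification to
live in version-controllable scripts and a queryable database rather than
in a GUI session.

## The analysis

1. **Ingest** — the image (TIFF/PNG/JPEG, 8/16-bit, RGB reduced to
   luminance) is converted to a signal-high raster; dark-bands-on-light
   images (e.g. Ponceau) are inverted once at read time.
2. **Crop and background** — an optional crop, then whole-image background
   subtraction. The default is rolling-ball subtraction implemented as
   grayscale morphological opening with a flat disk (anti-extensive, so the
   residual is never negative, and exactly scale-equivariant).
3. **Lane profiles** — each lane is a polyline of `(row, center, half-width)`
   nodes, linearly interpolated, so lanes may curve but never run
   horizontally. For every image row the lane's pixels are summed across its
   width, giving the lane intensity profile *p(y)* along the migration axis.
4. **Baseline and measurement** — a per-lane piecewise-linear baseline
   *b(y)* absorbs residual background under the profile; the raw value of a
   band is the bounded sum

   $$v = \sum_{y=y_0}^{y_1-1}\bigl(p(y) - b(y)\bigr).$$

5. **Normalization** — with reference lanes loaded at protein amounts
   $m_i$, the per-image reference value and the normalized value of lane
   $j$ are

   $$r = \frac{1}{R}\sum_{i=1}^{R}\frac{v_i}{m_i}, \qquad
     w_j = \frac{1}{r}\,\frac{v_j}{m_j},$$

   where $R$ counts only reference lanes whose measurement is flagged
   successful. By construction the mean of $w$ over successful reference
   lanes is exactly 1, and $w$ is invariant under rescaling all intensities
   or all protein amounts.

A deterministic synthetic-gel generator (`gelquant.synthgel`) renders
curved-lane images with known injected band amounts, so the entire pipeline
is validated against ground truth — see `docs/methods.md`.

## Worked example

`examples/02_measure_and_normalize.py` builds a noisy 3-lane panel in which
every lane carries the same signal per µg loaded (lane 0 is the reference,
loaded at 1 µg; lane 1 has twice the band amount but is loaded at 2 µg), and
runs the full pipeline:

```
lane 0 (ref): raw v = 19,972 (injected 20,000, m = 1.0 ug)
lane 1 (a): raw v = 40,251 (injected 40,000, m = 2.0 ug)
lane 2 (b): raw v = 19,893 (injected 20,000, m = 1.0 ug)
reference value r = 19,971.5 from R = 1 reference lane(s)
lane 0: w = 1.0000 (truth 1.0000)
lane 1: w = 1.0077 (truth 1.0000)
lane 2: w = 0.9961 (truth 1.0000)
```

The raw values recover the injected band amounts to well under 2 % here,
and the normalized values sit at their true value 1: equal expression per
µg loaded. The other examples show profile extraction
(`01_synthetic_gel_and_profiles.py`), the store/replay/export cycle
(`03_store_replay_export.py`) and the same workflow from the shell
(`04_cli_workflow.sh`).

### CLI in one breath

```sh
gelquant synth fx --seed 17                 # synthetic fixture + parameter files
gelquant --store gel.db init
gelquant --store gel.db gel "demo" --project "Lab/Blots"
gelquant --store gel.db lanes 1 fx/lanes.json
gelquant --store gel.db image 1 fx/image.tif
gelquant --store gel.db analyze 1 fx/analysis.json
gelquant --store gel.db replay 1            # "OK, 3 measurements verified"
gelquant --store gel.db export results.csv
```

The analysis parameter file is declarative JSON (crop, background spec,
lane paths, baselines, integration regions — schema in
`gelquant/engine.py`); `replay` re-executes the logged steps and confirms
every stored value bit-for-bit.

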