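# Methods

This note documents the models, algorithms and numerical choices behind
`gelquant`, and what its synthetic validation does and does not show.

## Image model and conventions

A gel scan is treated as a non-negative intensity matrix with wells at
the top: row index = migration distance, column index = lateral
position. Orientation is an input contract (with a `--rotate` flag for
other scans), not auto-detected — auto-rotation heuristics fail on
sparse STELA gels more often than they help. Polarity is normalized on
load so that higher value = more band signal; `invert="auto"` flips a
scan when its median sits above the midrange of the pixel values, which
identifies light-background (dark-band) scans as long as bands occupy a
minority of pixels. RGB scans are collapsed by unweighted channel mean;
gel scanners emit near-gray RGB and any spectral weighting would be
arbitrary. Images smaller than 16×16 are rejected as degenerate. All
coordinates are 0-based, positions are sub-pixel floats, intervals are
half-open.

## Preprocessing

Order is fixed: polarity → unsharp masking → background subtraction.

* **Unsharp masking**: `out = in + amount·(in − G_σ(in))`, clipped at 0.
  Defaults σ = 2 px, amount = 1.0. `amount = 0` is the exact identity
  and constants are fixed points.
* **Background**: per-column 1-D grey opening with a vertical line of
  `2·radius + 1` pixels (default radius 50 rows), subtracted and clipped
  at 0 (white top-hat). A 1-D per-column model was chosen over a 2-D
  rolling ball because gel background varies chiefly along the migration
  axis and smear must not bleed between lanes. Any feature narrower than
  the structuring element (a band) is preserved — an isolated band's
  prominence survives within 1% — while flat backgrounds map exactly to
  zero. The top-hat is idempotent on the band-plus-smooth-background
  images it is designed for (and on flat images exactly); it is not an
  algebraic identity for arbitrary signals, which is why the tests
  assert it on gel-like inputs.

Both stages are independently switchable
(`preprocess.sharpen_enabled`, `preprocess.background_enabled`).

## Lane and band detection

Both detections operate on 1-D projections. The **lateral profile**
(column sums over all rows) peaks at lane centers; the **migration
profile** of a lane (row sums over the lane window, smoothed by a
truncated-window moving average, default window 5) peaks at bands.

Peaks are selected by **prominence** — height above the higher of the
two minima separating the peak from any higher sample — rather than raw
height, so bands riding on residual smear are kept while smear
shoulders are not. Candidate maxima and prominences come from
`scipy.signal`; distance thinning is our own greedy pass (keep the
highest remaining peak, drop anything closer than the minimum spacing)
so the tie rule is guaranteed: **equal peaks → smaller index wins**.
Deterministic output is a hard requirement; identical inputs give
byte-identical reports (no timestamps).

* Lane threshold: prominence ≥ `lane_prominence_frac` (default 0.2) of
  the profile maximum; minimum separation default 20 columns. Lane
  half-width is half the median inter-center gap, capped at half the
  *minimum* gap so adjacent lane windows never overlap (the cap only
  binds on unevenly spaced gels); a single lane falls back to the
  minimum separation.
* Band threshold: absolute (a.u.) or the default adaptive rule
  `5 · MAD(profile) · 1.4826` — about 5σ under Gaussian noise, robust to
  the bands themselves, and transferable across scanners since it scales
  with the lane's own noise. Minimum band spacing default 4 rows.
* Sub-pixel refinement: parabola through the peak sample and its
  neighbors, vertex offset `(y₋ − y₊)/(2(y₋ − 2y₀ + y₊))` clamped to
  ±0.5; a zero second difference (plateau) yields offset 0, and
  boundary samples are left at integer positions.
* Band area: profile sum over a fixed ±`band_min_distance_rows` window
  around the peak. On a background-subtracted profile this approximates
  the integrated band signal; a fixed window keeps areas comparable
  across bands, which is what the intensity-weighted statistics need.

Manual **edits** are declarative add/remove rows applied after automatic
calling: `remove` deletes every band within a stated tolerance (an edit
matching nothing is an error, so silently double-applying a removal is
impossible); `add` inserts a band with `origin="manual"` and intensity
measured from the profile, refusing to collide with an existing call.

## Ladder calibration

Migration is log-linear in fragment size to first order
(log10 L = a + b·d). The calibration pairs ladder band calls with the
known sizes strictly by position (i-th band by migration ↔ i-th size
descending — a count mismatch is surfaced for manual editing, never
guessed away) and interpolates log10(size) piecewise-linearly between
knots. Piecewise interpolation was preferred to a single global line
because real gels deviate from log-linearity at the size extremes; the
global line's R² is retained as a QC diagnostic with a warning below
0.98. Beyond the terminal knots the terminal slope is extended up to
10% of the knot span, after which positions are out of domain.
Out-of-domain bands are flagged and left unsized, not dropped.

## Per-lane statistics

For sized bands of one lane: band count, unweighted mean size,
area-weighted mean size, and the short-telomere fraction below a
threshold (default **1.6 kb**, the conventional cut-off for critically
short Uni-STELA products). "Short vs the rest" is reported **both** as a
count fraction (primary — STELA bands are discrete molecules) and as an
intensity fraction (secondary — the densitometric reading); the
definitions genuinely differ and reporting both avoids committing the
tool to one. The threshold comparison is strict (`< 1.6`): a band at
exactly the threshold is not short. Empty lanes report NaN means and
ratios — undefined, never zero. The TRF-style smear estimator
`ΣOD_i / Σ(OD_i/L_i)` is provided as a standard optional add-on for
continuous-smear lanes; it always lies within the size range it
integrates.

## Synthetic gels

The simulator renders `background(base + gradient·row)` plus separable
Gaussian bands (`amplitude·exp(−Δr²/2σ_r²)·exp(−Δc²/2σ_c²)`) plus
additive Gaussian noise clipped at 0, with exact truth tables
(`true_position_row = (log10 L − a)/b` identically). Gaussian rather
than Poisson noise: scanned film/CCD gels at working intensities are
well within the Gaussian regime and it keeps SNR = amplitude/σ simple.
Migration is drawn from the same log-linear family the calibrator fits,
deliberately, so calibration error is separable from detection error.

Preset conditions (fixed, seed-deterministic):

* `clean`: 600×400 px, log10(kb) = 1.0 − 0.0025·row, one ladder lane
  (8, 6, 4, 3, 2, 1.5, 1, 0.5 kb at amplitude 300) and three sample
  lanes of 5–12 bands log-uniform in [0.4, 8] kb with minimum log10
  spacing 0.03 (≈12 rows, i.e. well separated at band σ_r = 2.5 rows),
  amplitudes U(180, 280), background 20 + 0.02·row, noise σ = 11.5
  (SNR ≈ 20).
* `noisy`: σ = 57.5 (SNR ≈ 4). `crowded`: minimum spacing halved.
  `ladder-only`: the ladder lane alone, noise-free.

Band sizes are placed by the stick-breaking construction (uniform draws
on the spacing-shrunk interval plus fixed offsets), which gives the
exact minimum-gap distribution without rejection loops.

What the simulator does **not** emulate — lane smiling/frowning, lane
leakage, saturation/blooming, spatially correlated film grain, partial
digestion smear under the bands — bounds what synthetic validation
shows: passing tests demonstrate the algorithm recovers truth under the
stated geometric/noise model, not that it handles every pathology of
real scans; the manual-edit path exists precisely for those cases.

Validation under these conditions (20 clean gels): band recall and
precision 1.0 at a 3-row match tolerance, calibrated sizes within 0.25%
of truth, short counts exact whenever no true size lies within 5% of
the 1.6 kb threshold.

## Pedigree anticipation

`initial = measured + age·rate/1000` (kb; rate in bp/year, age in
years) projects each measurement to birth; per-generation means and
earlier-minus-later consecutive deltas (bp) summarize anticipation, with
an optional per-year normalization by the mean parent–child age gap when
links are supplied. The correction rate is **required, with no
default**: published longitudinal adult rates vary by cohort and
childhood attrition is substantially faster than the adult rate, so a
linear correction applied to children understates their initial length
— users must choose a rate they can defend, and the linear model is the
only one implemented (the config reserves room for a piecewise rate but
deliberately does not provide one). The construction is self-inverse:
pedigrees generated with an injected per-generation drop D and rate r
are recovered exactly (deltas = D to 1e-9) when analyzed with the same
r, and ∂initial/∂rate = age/1000 exactly.

## Problem sizes and tolerances

Default validation sizes — 20 simulated gels of 600×400 px, 1,000
random profiles (length ≤ 512) for the peak-calling oracle, 8-knot
ladders, 12-member pedigrees — were chosen so the full suite exercises
every path in seconds while keeping per-gel band counts (15–36) typical
of real Uni-STELA lanes. Floating-point comparisons use 1e-9 relative
tolerance where the computation is exact (calibration knots, pedigree
inversion) and the stated empirical bounds (5% size error, 1%
prominence preservation) where detection noise enters.
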