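# Methods

## Scope and data model

The package analyzes printing-substrate characterization panels: one row
per substrate with uniformity (weight mg/cm², thickness µm), porosity (%),
drug load (µg), printed-pattern marks, disintegration times (s) and
mechanical parameters (EB %, TS MPa, YM MPa, G* MPa). Missing
measurements are explicit absent values (`None` in memory, empty cells in
CSV); a substrate that disintegrated during printing simply has no
after-printing data and drops out of each statistic on its own, rather
than being imputed. Standard deviations are stored alongside the means
but are not propagated through the scoring pipeline, which operates on
per-substrate means only.

The bundled ten-substrate reference panel covers three structurally
distinct classes: dense single-polymer orodispersible films (subset I),
structured orodispersible film templates with an open-pore top layer over
a closed base (subset II), and commercial starch-based wafer edible
sheets, porous with both faces open (subset III). One value in it is
flagged rather than trusted: S2's after-printing disintegration time is
stored verbatim as 2.2 s but carries a `dt_after_suspect` flag, because it
is inconsistent with its 32.5 s before-printing value and with the
panel-level conclusion that printing does not change disintegration. The
documented corrected variant (32.2 s, `reference_panel(corrected_dt=True)`)
restores that consistency; the paired test emits a warning whenever the
suspect value enters it. The verbatim value is never silently rewritten.

## Tensile analysis

Engineering stress/strain throughout: σ = F/A₀ and ε = ΔL/L₀ with initial
geometry, the convention standard for thin-film tensile tests.

* **TS** = max(F)/A₀.
* **Break point**: first sample after the force maximum where force falls
  below a configurable fraction (default 0.5) of the maximum; if the force
  never drops that far, the last point. **EB** = 100·ΔL(break)/L₀.
* **YM**: least-squares slope of σ on ε restricted to a strain window,
  default ε ∈ [0.0005, 0.0025] — the conventional initial linear region —
  falling back to the first 10% of points when the window holds fewer
  samples (coarse traces). Fewer than two usable points is an error, not
  a guess.

The defaults are package decisions: single reported TS/EB/YM values do
not pin down a fit region or break criterion, so both are explicit,
configurable parameters with standard-practice defaults.

## Complex modulus

|G*| = √(G′² + G″²) element-wise over the 0.1–10 Hz sweep. A sweep is
reduced to one G* per substrate by the mean over frequencies (default) or
the interpolated value at 1 Hz — the reduction is explicit configuration
because a single reported G* per substrate leaves it ambiguous, and for
strongly frequency-dependent materials the two differ.

## Porosity

* **Oil method**: 100·(W_wet − W_dry)/W_wet on the default wet basis. The
  wet basis is chosen because it bounds the value below 100% like a volume
  fraction; the dry basis is selectable (`basis="dry"`) since "relative
  weight difference" admits both readings.
* **Image method**: 8-bit grayscale micrographs thresholded at a fixed
  gray level or by Otsu's method ("otsu"), the reproducible stand-in for a
  manually adjusted threshold. Bright pixels count as pores by default
  (transmitted light passes through empty space); polarity is invertible
  for reflected-light images. Porosity is the pore-pixel percentage.
* **Cross-method regression**: OLS of image porosity (y) on oil porosity
  (x) — this direction matches the observed scale relation (image values
  about five times the oil values). On the reference panel (all ten
  pairs) the fit is y = 4.88x − 3.45 with R = 0.98; the nine-pair fit
  without S4 gives the same slope and R with intercept −3.39, so the
  ten-pair fit is the shipped default.

## Disintegration and dissolution

The before/after-printing comparison is a two-sided paired Student t-test
on per-substrate mean disintegration times (two-sided because the claim
being tested is "no influence", directionless; per-sample means because
that is the reported granularity). Records lacking an after value are
excluded upstream. Zero-variance differences make t degenerate; the
result is flagged, with p = 1 for identically zero differences and p = 0
for a constant nonzero shift. Compliance flags compare each substrate
with a disintegration limit, default 180 s (the compendial orodispersible
disintegration requirement; the limit is a parameter, not a constant).

Dissolution profiles are cumulative %-released vs. time; t_level is the
earliest time the profile reaches a level, linearly interpolated between
the bracketing sampling points, absent if never reached. Slightly
decreasing points (sampling noise) can optionally be repaired by isotonic
regression before interpolation (off by default — it alters data).

## Printability transform

Eight axes, all scored 0–100% with 100% favorable:

| axis | transform | default parameter |
|------|-----------|-------------------|
| POR, TH, G\*, DL | 100·x/max(x) over the scope | scope = whole panel |
| EB | 100·min(EB/target, 1) | target 10% |
| TS | 100·min(TS/target, 1) | target 2 MPa |
| YM | 100·max(0, (bound − YM)/bound) | bound 430 MPa |
| PPA | ordinal 0/5/10 → 0/50/100% | linear ×10 map |

Choices made where the design was genuinely open:

* **YM penalty**: the recommended stiffness boundary appears both as
  430 MPa and as "above 400 MPa unfavorable"; the default is a continuous
  linear penalty to a 430 MPa bound (400 selectable), consistent with
  "lower is better", rather than a step function. An alternative
  `min_over` inversion (100·min(bound/YM, 1)) is available for the
  convention search.
* **Normalization scope**: global across the panel by default, because
  relative areas are compared across subsets; per-subset is selectable
  since the charts are drawn per subset.
* **Axis order**: the methods-listing order (POR, TH, EB, TS, YM, G\*,
  DL, PPA). The area statistic depends on neighbor products, so the
  order is configuration, never hard-coded; a variant grouping the
  figure-label axes is provided.
* **PPA map**: 0/5/10 → 0/50/100% (linear ×10) is assumed as the intended
  0–100% mapping of the ordinal score, and flagged as an assumption.
* **Exclusions** are flag-driven rules (drug recrystallization, excessive
  brittleness, disintegration during printing), not hard-coded sample IDs.

**Relative radar area.** With n = 8 equally spaced axes and radii rᵢ, the
polygon area is A = ½·sin(2π/n)·Σ rᵢ·rᵢ₊₁ (cyclic); relative area is
100·A/A_max with A_max the all-100 polygon, so the sine factor cancels.
Consequences worth knowing: the statistic is invariant under cyclic
rotation and reversal of the axis order but *not* under arbitrary
permutations; a single non-zero axis scores exactly 0% (both neighbor
products vanish); and it is monotone non-decreasing in every coordinate.

**Convention search.** The exact convention behind externally reported
relative areas (axis order, normalization scope, YM inversion, bound) is
under-determined, and no documented variant reproduces them exactly — the
best of the 16 enumerated variants still leaves a maximum absolute
residual above 11 percentage points on the reference panel.
`convention_search` therefore reports per-sample residuals for every
variant and never adopts the best fit as a default; the shipped default
is the documented convention above, which does reproduce all reported
*within-subset orderings* (S2 > S1; S5 > S7 > S6; S9 first among the
wafer sheets). Reported areas are calibration references, not acceptance
values.

## Synthetic data generator

The generator emulates each raw input with exact, recoverable ground
truth; all randomness flows through NumPy's seeded PCG64 generator, so
output is reproducible across platforms.

* **Tensile curves**: linear elastic rise at slope YM to a yield knee at
  0.9·TS (the knee fraction is a parameter), then the quadratic blend
  s(u) = u(2 − u) — value- and peak-slope-matched, zero slope at the peak
  — reaching TS exactly at ε = EB/100, then a near-vertical drop to 30%
  of peak force. The generator enforces YM·EB/100 ≥ TS (otherwise the
  elastic line cannot reach the peak stress and the targets are
  inconsistent). Recovery of YM by the default window fit additionally
  requires the knee strain 0.9·TS/YM to exceed the window's upper edge
  (0.0025); all bundled reference-range targets satisfy this. Noise is
  Gaussian on force, sd expressed relative to peak force.
* **Sweeps**: constant phase angle (default 15°, predominantly elastic),
  so |G*| equals the target at every frequency and any reduction recovers
  it exactly at zero noise.
* **Pore images**: bright ellipses (semi-axes 2–8% of the smaller
  dimension) painted on a dark background until the bright-pixel fraction
  first meets the target; the realized fraction is returned exactly, and
  a mid-gray threshold recovers it to the pixel.
* **Dissolution**: first-order release Q(t) = 100(1 − e^(−kt)) — chosen
  as the generative model because it matches the fast-release plateau
  shape of orodispersible substrates — with truncated-Gaussian replicate
  noise and per-timepoint sds.

What the generator does *not* emulate: real tensile curves' toe regions,
serrated yielding and grip slippage; frequency-dependent moduli;
non-elliptical, overlapping pore morphologies and uneven illumination;
multi-phase dissolution. Passing recovery tests therefore demonstrates
the analysis code is correct for idealized signals of the right shape and
scale, not that it is robust to every instrument artifact.

## Numerical choices and problem sizes

Default synthetic tensile curves use ~400 points, a 50 mm gauge length
and 1 mm² cross-section; pore images are 256×256; recovery tests run a
grid of nine observed-range (TS, EB, YM) triples plus corner
combinations, and the property suite checks the radar-area statistic
against an independent shoelace-polygon oracle on 1,000 random vectors at
1e-9. Exact-arithmetic identities are asserted at 1e-9–1e-12; recovery
assertions at 1% relative (noiseless) or a 2% median (1% noise), and
image-fraction recovery at 0.5 percentage points. The t-test p-value is
cross-checked against a numerically integrated Student-t tail at 1e-6.

## Known limitations

* The radar-area composite weights parameters implicitly through axis
  adjacency; it is not a calibrated multi-criteria decision method.
* Max-normalized axes (POR, TH, G\*, DL) make scores panel-relative:
  adding a new maximal substrate rescales everyone else's axis.
* The oil-method porosity is a bulk proxy; closed pores are invisible to
  the image method, and the two measure different pore populations.
* Uncertainty (the stored sds) is not propagated into scores or areas.
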