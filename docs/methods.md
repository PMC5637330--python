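# Methods

## Gradient temperature model

A gradient thermocycler program `center ± span` over `n` block columns is
reproduced with an *edge-weighted* spacing rule: the interior
column-to-column interval is `2·span/(n−1)` rounded to 0.1 °C, and the two
edge intervals each absorb half of the rounding remainder, so the first
and last columns land exactly on `center − span` and `center + span`. All
outputs are reported to 0.1 °C, the instrument's display resolution. This
rule was reverse-engineered from the two series a Primus96-class cycler
displays for 60.1 ± 19.9 °C and 55.0 ± 19.9 °C programs and reproduces all
24 printed values; naive linear interpolation does not (it gives 43.8 °C
where the instrument shows 43.9). Because the rule is inferred from one
instrument family, a `linear` mode is kept for cyclers that interpolate
evenly; the two modes agree exactly whenever `2·span/(n−1)` is a multiple
of 0.1. Gradient programs are assumed to be entered at 0.1 °C resolution
(the instrument's input granularity); sub-0.1° spans are accepted but the
endpoint rounding then dominates the interval budget.

Layouts are configurable (any row count and pH series); the default is
8 rows × 12 columns with the citrate–phosphate series pH 4.0, 4.6, 5.2,
5.8, 6.4, 7.0, 7.6, 8.0 (rows A–H). Rows run A→H top to bottom, columns
1→12 left to right; indices are zero-based internally, letter+number
labels external.

## Activity pipeline

Inputs are replicate absorbance plates (one CSV per plate, grid or long
format) plus a substrate blank. The transformation is: blank subtraction →
clip negatives to zero → per-plate relative activity (plate max = 100 %) →
per-well mean and sample standard deviation across plates → final rescale
so the maximum *mean* is exactly 100 %.

Decisions where the procedure itself is silent:

- **SD denominator** — sample SD (n−1). With triplicates the difference
  from the population form is a constant factor √(3/2); the sample form is
  the standard choice for an estimate from few replicates.
- **SD scale** — SD is computed on the per-plate relative activities and
  multiplied by the same final `100/max` factor as the mean, so mean and
  SD share one scale and SD reads as ± percentage points of the plotted
  landscape.
- **Blank** — default is a single scalar (the average substrate
  background); a per-well blank matrix is supported for substrates with
  positional background structure. Blank subtraction may produce
  negatives; they are preserved until the clipping step.
- **Replicate count** — 3 is the designed-for count; 1 or 2 plates are
  processed with a logged warning (SD is absent for n = 1).
- **Reader overflows** — non-finite cells are masked (excluded from the
  plate maximum and the replicate mean, NaN in the output) by default;
  `on_nonfinite="raise"` fails hard naming the well.
- **Linearity** — absorbance is treated as proportional to activity. A
  user-supplied monotone calibration hook (absorbance → activity units)
  can be applied after blank subtraction; it is off by default.
- **Degenerate inputs** — a plate or mean landscape whose maximum is zero
  raises a dedicated error rather than dividing by zero: it means no
  detectable activity anywhere, which no normalisation can fix.

The pipeline is scale-invariant (multiplying all raw values and the blank
by one positive constant changes nothing) and is tested for well-by-well
agreement with an explicit loop-based reference implementation at 1e−10
relative error.

## Buffer pH temperature model

Each buffer row carries a linear temperature coefficient
(`pH(T) = pH_ref + coeff·(T − T_ref)`, `T_ref` = 25 °C). Components of the
citrate–phosphate system: phosphate ≈ −0.0028 pH/°C, citrate ≈ 0. The
per-row effective coefficient depends on the citrate:phosphate mixing
fraction of that pH step, which is preparation-specific and must be
supplied by the user; `effective_coefficient(phosphate_fraction)` combines
the component values linearly. Alternatively a measured (T, pH) table per
row is interpolated linearly, with no extrapolation outside the measured
range.

Axis correction is **opt-in**: for this buffer system the worst-case
drift across 35–80 °C is 0.0028 × 45 = 0.126 ≤ 0.13 pH units, below the
grid's pH resolution (0.4–0.6 units), so the default landscape keeps the
nominal per-row pH axis. When applied, correction only replaces the pH
axis with a per-(row, column) grid; activities are untouched.
Coefficient-based correction is additive in the current axis, so applying
it twice equals applying doubled coefficients once; table-based
correction is absolute.

## Landscape analytics and plotting

- Contour plots: pH on x, temperature on y, activity as colour on a
  *fixed* 0–100 % purple-to-red scale (so different enzymes' plots are
  comparable), filled levels every 10 % by default.
- Grid refinement for smooth level curves is bilinear by default — it
  cannot overshoot the measured [min, max] and is honest to the 8 × 12
  resolution; bicubic smoothing is available behind a flag and clipped
  back to [0, 100].
- Threshold regions (">90 % activity between …") and optimum cells are
  always computed on the measured grid cells, never on interpolated
  pixels; interpolation is cosmetic only.
- Slices (conventional 1-D pH or temperature curves) are exact rows or
  columns of the landscape. A requested value within half a grid step of
  a measured line snaps with a warning; farther values are rejected
  instead of silently interpolated.

## Synthetic data

The simulator generates the kind of data the method assumes, not a model
of any particular enzyme:

- pH response: diprotic active-site ionisation,
  `f(pH) = 1/(1 + 10^(pKa1−pH) + 10^(pH−pKa2))`, a bell peaking at
  `(pKa1 + pKa2)/2`.
- Temperature response: Arrhenius-like activation times two-state
  denaturation, `g(T) = e^{aT}/(1 + e^{k(T−Tm)})`, normalised to max 1
  over the plate's temperature range; unimodal for `a < k`. Evaluated in
  log-space to avoid overflow.
- Coupling: `pKa2(T) = pKa2_ref + pka2_slope·(T − T_ref)`; a negative
  slope makes the high-activity pH window shrink toward acid as
  temperature rises — the qualitative behaviour that motivates measuring
  both axes at once. Slope 0 gives a separable surface.
- Plates: `absorbance = blank + amplitude·surface/100 + N(0, σ)` per
  well, independent across wells and plates. Homoscedastic Gaussian noise
  by default (plate-reader noise dominates at these absorbances); an
  optional heteroscedastic mode scales σ with the signal. One global seed
  spawns an independent substream per plate, so raising the plate count
  extends, never reshuffles, the existing plates.

Presets (illustrative shapes, hand-picked, not fitted to measurements):
`cel8a-like` — thermostable endoglucanase-style separable surface, pKa
4.2/7.6, activation slope 0.06 /°C, Tm 79 °C, steepness 0.5 /°C, optimum
near 75 °C and pH 5.5–6.5; `celluclast-like` — mesophilic
cellulase-mixture-style coupled surface, pKa1 3.5, pKa2_ref 7.1 with
−0.02 pH/°C slope, activation 0.05 /°C, Tm 60 °C, steepness 0.4 /°C,
optimum near 55 °C and pH 5. Default noise σ = 0.02 absorbance units
(≈ 2 % of the default amplitude 1.0, typical plate-reader repeatability),
blank 0.1, three plates.

What passing synthetic tests do and do not show: they validate the
transformation, normalisation, axis bookkeeping and noise propagation
end-to-end against a known ground truth; they do not validate assay
chemistry — substrate background drift, non-linear calibration, pipetting
error structure, or evaporation gradients across the plate are not
emulated (noise is i.i.d. per well).

## Problem sizes

Validation experiments are sized for a laptop-class run: 50 random
triplicate sets for the reference-equivalence check, 100 seeded
simulations for argmax recovery under 2 % noise (each a full 3 × 96-well
simulate-and-process cycle), dense 801–2001-point grids for closed-form
argmax oracles. The whole suite runs in a few seconds.

## Known limitations

- The edge-weighted spacing rule is inferred from one cycler family's
  display output; other instruments may quantise differently (use
  `linear` mode or measure).
- Relative activity only: absolute units (U/mg) are out of scope beyond
  the calibration hook, as is replicate outlier rejection.
- Region/optimum claims inherit the grid resolution (0.4–0.6 pH units,
  ~3.6 °C); the simulator's continuous argmax can sit between grid
  lines, and the reported optimum is then the best measured cell, not
  the true continuous one.
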