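# gradplate

Enzyme pH and temperature optima are usually measured one axis at a time —
a temperature curve at a fixed pH, a pH curve at a fixed temperature. That
treats the two as independent, which they often are not: for cellulase
mixtures the pH window for high activity narrows toward acid as the
temperature rises, so a "pH optimum" depends entirely on which temperature
you happened to fix. A full-factorial alternative measures all
combinations at once: a 96-well PCR plate in a *gradient* thermocycler
gets a different temperature in each of its 12 block columns, while a
citrate–phosphate buffer series sets a different pH (4.0–8.0) in each of
its 8 rows — 96 distinct (pH, T) reaction conditions per plate, read in
triplicate on a plate reader, and rendered as a filled contour
"activity landscape".

`gradplate` is the informatics half of that workflow, for assay developers
and enzymologists: the plate/gradient geometry model, the defined
transformation from raw absorbances to a normalised landscape, buffer pH
temperature correction, contour plots and conventional 1-D slices, reagent
arithmetic checks, and a mechanistic simulator that replaces the wet-lab
step for validation.

## The model

**Gradient temperatures.** A program `center ± span` over `n` columns is
not spaced by naive linear interpolation: the cycler quantises the
interior step to 0.1 °C,

```
interior = round(2·span/(n−1), 0.1)    edge = (2·span − (n−3)·interior)/2
```

so a 60.1 ± 19.9 °C program gives 40.2, 43.9, 47.5, …, 76.3, 80.0 °C
(interior 3.6 °C, edges 3.7 °C) — matching the instrument display digit
for digit where linear spacing would not (43.8 vs 43.9 at column 2).

**Activity landscape.** For replicate plates *A⁽ᵏ⁾* and substrate blank
*b*:

1. blank subtraction: *C⁽ᵏ⁾ = A⁽ᵏ⁾ − b*
2. clipping: negatives → 0
3. per-plate relative activity: *R⁽ᵏ⁾ = 100·C⁽ᵏ⁾ / max C⁽ᵏ⁾*
4. per-well mean and sample SD (n−1) across plates
5. final rescale so the highest mean is exactly 100 %

**Buffer correction (optional).** Buffer pH drifts with temperature
(phosphate ≈ −0.0028 pH/°C, citrate ≈ 0); each row can be assigned an
individual pH at each column temperature from coefficients or a measured
table. For citrate–phosphate the worst-case shift over 35–80 °C is
≤ 0.13 pH units, so correction is off by default.

**Simulator.** Noiseless truth = diprotic ionisation bell
`1/(1 + 10^(pKa1−pH) + 10^(pH−pKa2))` × activation/denaturation profile
`e^{aT}/(1 + e^{k(T−Tm)})`; letting pKa2 fall with temperature couples the
axes. Plates are `blank + amplitude·surface + N(0, σ)` per well.

## Worked example

```python
import numpy as np
from gradplate import (default_layout, find_optimum, preset,
                       process_plates, simulate_plates)

layout = default_layout(center=55.0, span=19.9)
params = preset("celluclast-like", noise_sd=0.02, seed=42)
readings, blank = simulate_plates(params, layout)
landscape = process_plates(readings, blank, layout)
ph, t, act = find_optimum(landscape)[0]
print(f"optimum: pH {ph}, {t} °C ({act:.0f}%)")
print(f"mean replicate SD: {np.nanmean(landscape.sd):.2f} percentage points")
```

prints

```
optimum: pH 5.2, 53.2 °C (100%)
mean replicate SD: 1.68 percentage points
```

— the landscape's best cell is pH 5.2 at 53.2 °C (the cell set to 100 %
by normalisation), and triplicate scatter averages ±1.7 percentage points
per well. `examples/` holds one short script per capability (geometry,
simulate/process, contours and slices, buffer correction).

The same workflow from a shell:

```
gradplate simulate --preset celluclast-like --seed 42 --out-dir sim/
gradplate process --plates sim/plate_sim-1.csv --plates sim/plate_sim-2.csv \
    --plates sim/plate_sim-3.csv --blank 0.1 --out landscape.csv --xyz xyz.csv
gradplate plot --landscape landscape.csv --out landscape.png
gradplate report --landscape landscape.csv --thresholds 60,90
```

Other subcommands: `slice`, `layout show`, `recipe check`.

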