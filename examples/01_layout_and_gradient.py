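"""Plate geometry: which (pH, temperature) condition sits in each well.

Builds the standard 8 x 12 layout (citrate-phosphate rows pH 4.0-8.0,
gradient 60.1 ± 19.9 °C) and prints the column temperatures and a few
well conditions. Note the edge-weighted spacing: interior steps of 3.6 °C
with 3.7 °C at both edges, exactly as a gradient cycler displays them.
"""

from gradplate import column_temperatures, condition_of_well, default_layout

layout = default_layout(center=60.1, span=19.9)
temps = column_temperatures(layout.gradient)
print("column temperatures [°C]:", temps)
print("steps [°C]:", [round(b - a, 1) for a, b in zip(temps, temps[1:])])

for well in ("A1", "D6", "H12"):
    i, j = layout.parse_well_label(well)
    ph, t = condition_of_well(layout, i, j)
    print(f"well {well}: pH {ph}, {t} °C")
print(f"total distinct conditions: {layout.n_wells}")
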