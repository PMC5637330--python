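"""Optional per-temperature pH axis correction.

Citrate-phosphate buffers drift slightly acidic as they heat (phosphate
contributes about -0.0028 pH/°C, citrate about 0), so each buffer row has
a slightly different true pH at each column temperature. The correction
replaces the per-row pH axis with a per-well grid; activities are
untouched. For this buffer system the worst-case shift over 35-80 °C is
~0.13 pH units — small enough that correction is off by default.
"""

import dataclasses

from gradplate import (
    BufferRow, correct_axis, default_layout, ph_at_temperature, preset,
    process_plates, simulate_plates,
)

row = BufferRow("H", 8.0, temp_coefficient=-0.0028, t_ref=25.0)
print(f"pure-phosphate pH 8.0 buffer at 75 °C: pH {ph_at_temperature(row, 75.0)}")

layout = default_layout(center=55.0, span=19.9)
readings, blank = simulate_plates(preset("celluclast-like", noise_sd=0.0), layout)
landscape = process_plates(readings, blank, layout)

corrected_layout = dataclasses.replace(layout, rows=tuple(
    dataclasses.replace(r, temp_coefficient=-0.0028) for r in layout.rows
))
corrected = correct_axis(landscape, corrected_layout)
print("pH of row A across the gradient after correction:")
print([round(float(p), 3) for p in corrected.ph_axis[0]])
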