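"""Contour plot, threshold regions and conventional 1-D slices.

Renders the filled contour figure (pH on x, temperature on y, activity as
colour 0-100%), reports where activity stays above 60% and 90%, and cuts
three conventional pH profiles to show the temperature-dependent pH
ceiling: the highest pH still giving >= 60% of the slice's own maximum
drops as temperature rises.
"""

from gradplate import (
    default_layout, extract_region, preset, process_plates, render_contour,
    simulate_plates, slice_profile,
)

layout = default_layout(center=55.0, span=19.9)
params = preset("celluclast-like", noise_sd=0.0)
readings, blank = simulate_plates(params, layout)
landscape = process_plates(readings, blank, layout)

render_contour(landscape, "landscape.png", title="celluclast-like (synthetic)")
print("wrote landscape.png")

for thr in (60.0, 90.0):
    region = extract_region(landscape, thr)
    print(
        f">= {thr:.0f}%: {region.n_cells} cells, "
        f"pH {region.ph_range[0]}-{region.ph_range[1]}, "
        f"{region.temp_range[0]}-{region.temp_range[1]} °C"
    )

for t in (46.0, 56.8, 64.0):
    prof = slice_profile(landscape, "temperature", t)
    own_max = max(m for _, m, _ in prof.points)
    ceiling = max(ph for ph, m, _ in prof.points if m >= 0.6 * own_max)
    print(f"slice at {prof.fixed_value} °C: pH ceiling for >=60% is {ceiling}")
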