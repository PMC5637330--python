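"""Temperature dependence of buffer pH.

The pKa of a buffer shifts with temperature, dragging the actual in-well
pH away from its room-temperature value. For the citrate-phosphate system
the effect is small — the phosphate component carries a coefficient of
about -0.0028 pH/°C and citrate essentially 0 — so over a 35-80 °C assay
the shift stays below ~0.13 pH units and correction is off by default.
For buffers with larger coefficients (Tris is the classic offender) the
landscape's pH axis can be corrected per (row, column): each buffer row is
assigned an individual pH at each column temperature, from either a linear
coefficient model or a measured pH-vs-temperature table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .plate import (
    BufferRow,
    CITRATE_TEMP_COEFFICIENT,
    PHOSPHATE_TEMP_COEFFICIENT,
    PlateLayout,
)
from .pipeline import ActivityLandscape

__all__ = [
    "PhTemperatureTable",
    "RangeError",
    "ph_at_temperature",
    "ph_from_table",
    "correct_axis",
    "effective_coefficient",
]


class RangeError(ValueError):
    """Temperature outside the measured table range (no extrapolation)."""


def ph_at_temperature(row: BufferRow, t: float) -> float:
    """Linear coefficient model: ph_ref + coeff * (t - t_ref)."""
    return row.ph_ref + row.temp_coefficient * (t - row.t_ref)


def effective_coefficient(phosphate_fraction: float) -> float:
    """Effective dpH/d°C of a citrate-phosphate mix from its phosphate fraction.

    Mixing ratios per pH step are preparation-specific, so the per-row
    fraction must come from the user; this helper just combines the two
    component coefficients linearly.
    """
    if not 0.0 <= phosphate_fraction <= 1.0:
        raise ValueError(
            f"phosphate fraction must be in [0, 1]: {phosphate_fraction}"
        )
    return (
        phosphate_fraction * PHOSPHATE_TEMP_COEFFICIENT
        + (1.0 - phosphate_fraction) * CITRATE_TEMP_COEFFICIENT
    )


@dataclass(frozen=True)
class PhTemperatureTable:
    """Measured pH vs temperature, one series per buffer row label.

    ``series`` maps a row label to ``[(temperature °C, pH), ...]`` with
    strictly increasing temperatures; at least two points per row.
    """

    series: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for label, pts in self.series.items():
            if len(pts) < 2:
                raise ValueError(
                    f"buffer {label!r}: need >= 2 (T, pH) points, "
                    f"got {len(pts)}"
                )
            temps = [t for t, _ in pts]
            if any(b <= a for a, b in zip(temps, temps[1:])):
                raise ValueError(
                    f"buffer {label!r}: temperatures not strictly increasing"
                )


def ph_from_table(table: PhTemperatureTable, row_label: str, t: float) -> float:
    """pH by linear interpolation in the measured table; no extrapolation."""
    if row_label not in table.series:
        raise KeyError(f"no pH-temperature series for buffer {row_label!r}")
    pts = table.series[row_label]
    temps = np.array([p[0] for p in pts])
    phs = np.array([p[1] for p in pts])
    if t < temps[0] or t > temps[-1]:
        raise RangeError(
            f"temperature {t} °C outside measured range "
            f"{temps[0]}-{temps[-1]} °C for buffer {row_label!r}"
        )
    return float(np.interp(t, temps, phs))


def correct_axis(
    landscape: ActivityLandscape,
    layout: PlateLayout,
    source: PhTemperatureTable | None = None,
) -> ActivityLandscape:
    """Replace the per-row pH axis with a per-(row, column) corrected one.

    Each well's pH becomes the pH of its row's buffer at its column's
    temperature — from the measured ``source`` table when given (absolute
    replacement), else from each row's linear temperature coefficient
    (an additive shift ``coeff * (T - t_ref)`` on the current axis, so
    corrections compose linearly). Activity values and SDs are untouched;
    only the axis changes. With all-zero coefficients the landscape is
    returned unchanged.
    """
    temps = landscape.temperature_axis
    n_rows = landscape.shape[0]
    if len(layout.rows) != n_rows:
        raise ValueError(
            f"layout has {len(layout.rows)} rows, landscape {n_rows}"
        )
    if source is not None:
        ph_grid = np.empty(landscape.shape)
        for i, row in enumerate(layout.rows):
            for j, t in enumerate(temps):
                ph_grid[i, j] = ph_from_table(source, row.label, float(t))
        return dataclasses.replace(landscape, ph_axis=ph_grid)
    if all(row.temp_coefficient == 0.0 for row in layout.rows):
        return landscape
    current = landscape.ph_axis
    if current.ndim == 1:
        current = np.repeat(current[:, None], len(temps), axis=1)
    shift = np.array(
        [
            [row.temp_coefficient * (float(t) - row.t_ref) for t in temps]
            for row in layout.rows
        ]
    )
    return dataclasses.replace(landscape, ph_axis=current + shift)
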