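"""96-well gradient-assay geometry.

A gradient PCR cycler imposes a different temperature on each of its 12
block columns while a citrate-phosphate buffer series sets a different pH
in each of the 8 plate rows, so a single plate samples 96 distinct
(pH, temperature) reaction conditions.

The cycler does not space the column temperatures by naive linear
interpolation: the instrument quantises the interior column-to-column step
to 0.1 °C and pushes the rounding remainder into the two edge intervals.
``column_temperatures`` implements that edge-weighted rule (the default)
alongside a plain linear rule for instruments that interpolate evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GradientSpec",
    "BufferRow",
    "PlateLayout",
    "AssayConfig",
    "InvalidSpecError",
    "column_temperatures",
    "condition_of_well",
    "default_buffer_rows",
    "default_layout",
    "ROW_LETTERS",
]

ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: pH of the standard citrate-phosphate buffer series, rows A-H.
DEFAULT_ROW_PH = (4.0, 4.6, 5.2, 5.8, 6.4, 7.0, 7.6, 8.0)

#: Temperature coefficients (delta pH per °C) of the buffer components.
PHOSPHATE_TEMP_COEFFICIENT = -0.0028
CITRATE_TEMP_COEFFICIENT = 0.0


class InvalidSpecError(ValueError):
    """Raised when a gradient or layout specification is not physical."""


@dataclass(frozen=True)
class GradientSpec:
    """Temperature program of a gradient cycler: ``center ± span`` over columns.

    Parameters
    ----------
    center : float
        Midpoint of the gradient in °C.
    span : float
        Half-range in °C; column 1 sits at ``center - span`` and the last
        column at ``center + span``.
    n_columns : int
        Number of block columns (12 on a standard 96-well cycler).
    mode : {"edge_weighted", "linear"}
        Spacing rule. ``edge_weighted`` reproduces the quantised spacing of
        gradient cyclers (interior step rounded to 0.1 °C, remainder split
        between the two edge intervals); ``linear`` interpolates evenly.
    """

    center: float
    span: float
    n_columns: int = 12
    mode: str = "edge_weighted"

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise InvalidSpecError(f"span must be positive, got {self.span}")
        if self.n_columns < 2:
            raise InvalidSpecError(
                f"n_columns must be at least 2, got {self.n_columns}"
            )
        if self.mode not in ("edge_weighted", "linear"):
            raise InvalidSpecError(f"unknown gradient mode {self.mode!r}")
        lo, hi = self.center - self.span, self.center + self.span
        if lo < 0.0 or hi > 105.0:
            raise InvalidSpecError(
                f"gradient range {lo:.1f}-{hi:.1f} °C outside instrument "
                "range 0-105 °C"
            )


def column_temperatures(spec: GradientSpec) -> list[float]:
    """Temperatures assigned to each block column, in °C to one decimal.

    In ``edge_weighted`` mode the interior interval is ``2*span/(n-1)``
    rounded to 0.1 °C and the two edge intervals each absorb half of the
    rounding remainder, so the endpoints land exactly on ``center ± span``.
    For a 60.1 ± 19.9 °C program this yields
    40.2, 43.9, 47.5, ..., 76.3, 80.0 °C (interior step 3.6, edges 3.7).

    When ``2*span/(n-1)`` is already a multiple of 0.1 the two modes agree.
    """
    n = spec.n_columns
    lo = spec.center - spec.span
    hi = spec.center + spec.span
    if spec.mode == "linear" or n == 2:
        step = 2.0 * spec.span / (n - 1)
        temps = [lo + i * step for i in range(n)]
    else:
        interior = round(2.0 * spec.span / (n - 1), 1)
        edge = (2.0 * spec.span - (n - 3) * interior) / 2.0
        temps = [lo, lo + edge]
        for _ in range(n - 3):
            temps.append(temps[-1] + interior)
        temps.append(hi)
    temps = [round(t, 1) for t in temps]
    # endpoint contract: never let accumulated float error leak into the ends
    temps[0], temps[-1] = round(lo, 1), round(hi, 1)
    if any(b <= a for a, b in zip(temps, temps[1:])):
        raise InvalidSpecError(
            "column temperatures not strictly increasing; span too small "
            f"for {n} columns at 0.1 °C resolution"
        )
    return temps


@dataclass(frozen=True)
class BufferRow:
    """One buffer of the plate's pH series.

    ``ph_ref`` is the pH at the reference temperature ``t_ref`` (room
    temperature by default); ``temp_coefficient`` is the linear pH change
    per °C of the mixed buffer (0 disables any temperature correction for
    this row).
    """

    label: str
    ph_ref: float
    temp_coefficient: float = 0.0
    t_ref: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph_ref <= 14.0:
            raise InvalidSpecError(f"pH {self.ph_ref} outside 0-14")
        if abs(self.temp_coefficient) > 0.05:
            raise InvalidSpecError(
                f"temperature coefficient {self.temp_coefficient} "
                "implausibly large (|coeff| must be <= 0.05 pH/°C)"
            )


def default_buffer_rows() -> list[BufferRow]:
    """The standard citrate-phosphate series, rows A-H, pH 4.0-8.0."""
    return [
        BufferRow(label=ROW_LETTERS[i], ph_ref=ph)
        for i, ph in enumerate(DEFAULT_ROW_PH)
    ]


@dataclass(frozen=True)
class PlateLayout:
    """Maps plate rows (buffer pH) x columns (gradient °C) to conditions."""

    rows: tuple[BufferRow, ...]
    gradient: GradientSpec

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise InvalidSpecError("layout needs at least one buffer row")
        labels = [r.label for r in self.rows]
        if len(set(labels)) != len(labels):
            raise InvalidSpecError(f"duplicate row labels in {labels}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return self.gradient.n_columns

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_columns

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_columns)

    @property
    def column_temperatures(self) -> list[float]:
        return column_temperatures(self.gradient)

    @property
    def row_phs(self) -> list[float]:
        return [r.ph_ref for r in self.rows]

    def well_label(self, row_index: int, col_index: int) -> str:
        """External well address, e.g. ``A1`` for (0, 0)."""
        self._check_indices(row_index, col_index)
        return f"{self.rows[row_index].label}{col_index + 1}"

    def parse_well_label(self, label: str) -> tuple[int, int]:
        """Inverse of :meth:`well_label`; raises ``KeyError`` if unknown."""
        label = label.strip().upper()
        for i, row in enumerate(self.rows):
            if label.startswith(row.label.upper()):
                try:
                    col = int(label[len(row.label):]) - 1
                except ValueError:
                    continue
                if 0 <= col < self.n_columns:
                    return (i, col)
        raise KeyError(f"well label {label!r} not on this layout")

    def _check_indices(self, row_index: int, col_index: int) -> None:
        if not (0 <= row_index < self.n_rows):
            raise IndexError(
                f"row index {row_index} outside 0-{self.n_rows - 1}"
            )
        if not (0 <= col_index < self.n_columns):
            raise IndexError(
                f"column index {col_index} outside 0-{self.n_columns - 1}"
            )


def default_layout(
    center: float = 60.1, span: float = 19.9, mode: str = "edge_weighted"
) -> PlateLayout:
    """Standard 8 x 12 layout: pH 4.0-8.0 rows, ``center ± span`` gradient."""
    return PlateLayout(
        rows=tuple(default_buffer_rows()),
        gradient=GradientSpec(center=center, span=span, n_columns=12, mode=mode),
    )


def condition_of_well(
    layout: PlateLayout, row_index: int, col_index: int
) -> tuple[float, float]:
    """(pH, temperature) of one well; no buffer temperature correction.

    Returns the row buffer's reference pH and the column's programmed
    temperature. Per-temperature pH correction, when wanted, is applied to
    a finished landscape by :func:`gradplate.buffers.correct_axis`.
    """
    layout._check_indices(row_index, col_index)
    return (layout.rows[row_index].ph_ref, layout.column_temperatures[col_index])


@dataclass(frozen=True)
class AssayConfig:
    """Assay metadata attached to a landscape for provenance."""

    assay_name: str = "other"
    substrate: str = ""
    enzyme_conc: float | None = None  # µg/ml
    substrate_final_conc: float | None = None  # mg/ml or mM per conc_unit
    conc_unit: str = "mg/ml"
    duration: float | None = None  # minutes
    wavelength: float | None = None  # nm
    layout: PlateLayout = field(default_factory=default_layout)

    KNOWN_ASSAYS = ("DNSA", "AzoCMC", "pNP", "GlucoseHK", "other")

    def __post_init__(self) -> None:
        if self.duration is not None and self.duration <= 0:
            raise InvalidSpecError(f"duration must be positive: {self.duration}")
        for name, v in (
            ("enzyme_conc", self.enzyme_conc),
            ("substrate_final_conc", self.substrate_final_conc),
        ):
            if v is not None and v <= 0:
                raise InvalidSpecError(f"{name} must be positive: {v}")
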