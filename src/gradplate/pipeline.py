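"""Raw replicate absorbance plates -> relative-activity landscape.

The transformation is a fixed composition:

1. subtract the substrate blank (scalar or per-well) from each plate;
2. clip negatives to zero (they would only distort a colour scale);
3. express each plate relative to its own maximum (100% = plate max);
4. average the replicate plates per well and take the sample standard
   deviation (n-1) across plates;
5. rescale so the highest *mean* value is exactly 100%.

Absorbance is taken as proportional to activity (valid on the linear part
of the calibration curve); an optional monotone ``calibration`` hook maps
blank-corrected absorbance to activity units before normalisation for
assays where that assumption fails.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .plate import AssayConfig, PlateLayout, default_layout

__all__ = [
    "PlateReading",
    "BlankModel",
    "ActivityLandscape",
    "DegeneratePlateError",
    "ShapeError",
    "subtract_blank",
    "clip_negative",
    "per_plate_relative",
    "aggregate_plates",
    "rescale_to_max",
    "process_plates",
]

logger = logging.getLogger(__name__)


class DegeneratePlateError(ValueError):
    """No detectable activity anywhere on a plate or landscape."""


class ShapeError(ValueError):
    """Matrix shape does not match the plate layout."""


@dataclass(frozen=True)
class PlateReading:
    """One replicate plate's absorbance grid at a stated wavelength."""

    values: np.ndarray
    plate_id: str = ""
    wavelength: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.values.ndim != 2:
            raise ShapeError(
                f"plate values must be 2-D, got shape {self.values.shape}"
            )


@dataclass(frozen=True)
class BlankModel:
    """Substrate background to subtract: one scalar or a per-well matrix.

    The scalar form is the average background of the substrate-only
    control; the per-well form serves substrates with positional
    background structure.
    """

    value: float | np.ndarray
    kind: str = "scalar"

    def __post_init__(self) -> None:
        if self.kind not in ("scalar", "per_well"):
            raise ValueError(f"unknown blank kind {self.kind!r}")
        if self.kind == "per_well":
            object.__setattr__(
                self, "value", np.asarray(self.value, dtype=float)
            )
            if not np.all(np.isfinite(self.value)):
                raise ValueError("per-well blank contains non-finite values")
        elif not np.isfinite(self.value):
            raise ValueError(f"blank value not finite: {self.value}")

    def as_matrix(self, shape: tuple[int, int]) -> np.ndarray:
        if self.kind == "scalar":
            return np.full(shape, float(self.value))
        if self.value.shape != shape:
            raise ShapeError(
                f"per-well blank shape {self.value.shape} != plate {shape}"
            )
        return self.value


@dataclass(frozen=True)
class ActivityLandscape:
    """Mean relative activity (%) per well, with replicate SD and axes.

    ``ph_axis`` is per-row by construction; after buffer temperature
    correction it becomes a per-(row, column) matrix. ``sd`` is None when
    only one plate was processed.
    """

    mean_relative_activity: np.ndarray
    sd: np.ndarray | None
    ph_axis: np.ndarray
    temperature_axis: np.ndarray
    n_plates: int
    provenance: AssayConfig | None = field(default=None, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_relative_activity.shape

    def ph_of(self, row: int, col: int) -> float:
        """pH of a well, honouring a per-(row, column) corrected axis."""
        if self.ph_axis.ndim == 2:
            return float(self.ph_axis[row, col])
        return float(self.ph_axis[row])

    @property
    def ph_corrected(self) -> bool:
        return self.ph_axis.ndim == 2


def _check_shapes(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"{what}: shape {a.shape} != {b.shape}")


def subtract_blank(
    reading: PlateReading | np.ndarray, blank: BlankModel | float
) -> np.ndarray:
    """Raw minus substrate background; negatives are preserved here."""
    raw = reading.values if isinstance(reading, PlateReading) else np.asarray(
        reading, dtype=float
    )
    if not isinstance(blank, BlankModel):
        blank = BlankModel(value=float(blank))
    return raw - blank.as_matrix(raw.shape)


def clip_negative(matrix: np.ndarray) -> np.ndarray:
    """Set sub-blank wells to zero activity. Idempotent."""
    return np.maximum(np.asarray(matrix, dtype=float), 0.0)


def per_plate_relative(matrix: np.ndarray) -> np.ndarray:
    """Percent of the plate's own maximum; NaN wells ignored for the max."""
    m = np.asarray(matrix, dtype=float)
    if np.all(np.isnan(m)):
        raise DegeneratePlateError("all wells are masked")
    peak = np.nanmax(m)
    if peak <= 0:
        raise DegeneratePlateError(
            "plate maximum is zero: no detectable activity on this plate"
        )
    return 100.0 * m / peak


def aggregate_plates(
    relatives: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-well mean and sample SD (n-1) across replicate plates.

    SD is None for a single plate. NaN wells (masked reader overflows)
    are excluded per well.
    """
    if len(relatives) == 0:
        raise ValueError("no plates to aggregate")
    mats = [np.asarray(r, dtype=float) for r in relatives]
    for m in mats[1:]:
        _check_shapes(mats[0], m, "replicate plates")
    stack = np.stack(mats)
    # fully-masked wells legitimately yield NaN mean/SD; keep that quiet
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if len(mats) >= 2 else None
    return mean, sd


def rescale_to_max(matrix: np.ndarray) -> np.ndarray:
    """Scale so the maximum is exactly 100; argmax is unchanged."""
    m = np.asarray(matrix, dtype=float)
    peak = np.nanmax(m)
    if not np.isfinite(peak) or peak <= 0:
        raise DegeneratePlateError("landscape maximum is zero")
    return m * (100.0 / peak)


def process_plates(
    readings: Sequence[PlateReading],
    blank: BlankModel | float,
    layout: PlateLayout | None = None,
    *,
    calibration: Callable[[np.ndarray], np.ndarray] | None = None,
    on_nonfinite: str = "mask",
    provenance: AssayConfig | None = None,
) -> ActivityLandscape:
    """Full pipeline: replicate readings + blank -> ActivityLandscape.

    Parameters
    ----------
    readings : sequence of PlateReading
        Replicate plates; three is the designed-for count, one or two are
        accepted with a warning.
    blank : BlankModel or float
        Substrate background (scalar average blank, or per-well).
    layout : PlateLayout, optional
        Supplies the pH and temperature axes; defaults to the standard
        8 x 12 layout.
    calibration : callable, optional
        Monotone map from blank-corrected absorbance to activity units,
        applied before normalisation. Off by default (linear assumption).
    on_nonfinite : {"mask", "raise"}
        Reader overflows (non-finite cells): mask them out of the plate
        maximum and the replicate mean, or fail hard.

    Notes
    -----
    The replicate SD is computed on the per-plate relative activities and
    multiplied by the same final 100/max factor as the mean, so mean and
    SD share one scale (percentage points of the plotted landscape).
    """
    if len(readings) == 0:
        raise ValueError("at least one plate reading is required")
    layout = layout or default_layout()
    shape = layout.shape
    if len(readings) < 3:
        logger.warning(
            "processing %d plate(s); the protocol is designed for 3 "
            "replicates", len(readings)
        )
    if on_nonfinite not in ("mask", "raise"):
        raise ValueError(f"unknown on_nonfinite mode {on_nonfinite!r}")

    relatives = []
    n_clipped_total = 0
    for reading in readings:
        if reading.values.shape != shape:
            raise ShapeError(
                f"plate {reading.plate_id!r} shape {reading.values.shape} "
                f"does not match layout {shape}"
            )
        raw = reading.values
        bad = ~np.isfinite(raw)
        if bad.any():
            if on_nonfinite == "raise":
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-finite absorbance in plate {reading.plate_id!r} "
                    f"at well {layout.well_label(int(r), int(c))}"
                )
            logger.warning(
                "plate %r: masking %d non-finite well(s)",
                reading.plate_id, int(bad.sum()),
            )
            raw = np.where(bad, np.nan, raw)
        corrected = subtract_blank(raw, blank)
        if calibration is not None:
            corrected = np.asarray(calibration(corrected), dtype=float)
        clipped = clip_negative(corrected)
        n_clipped = int(np.sum(corrected < 0))
        n_clipped_total += n_clipped
        relatives.append(per_plate_relative(clipped))
    logger.info(
        "processed %d plate(s): %d well(s) clipped negative "
        "(heavy clipping suggests a bad blank)",
        len(readings), n_clipped_total,
    )

    mean, sd = aggregate_plates(relatives)
    peak = np.nanmax(mean)
    if not np.isfinite(peak) or peak <= 0:
        raise DegeneratePlateError("mean landscape has no positive values")
    factor = 100.0 / peak
    return ActivityLandscape(
        mean_relative_activity=mean * factor,
        sd=None if sd is None else sd * factor,
        ph_axis=np.asarray(layout.row_phs, dtype=float),
        temperature_axis=np.asarray(layout.column_temperatures, dtype=float),
        n_plates=len(readings),
        provenance=provenance,
    )
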