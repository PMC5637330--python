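"""Readers, writers and configuration.

Canonical dialect is plain CSV (comma separator, UTF-8, '.' decimal); a
``dialect="semicolon"`` option accepts the semicolon-separated,
comma-decimal exports common from plate readers in German-locale labs.
All writes are atomic (write to a temp file, then rename) so an
interrupted run never leaves a truncated output behind.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import ActivityLandscape, PlateReading, ShapeError
from .plate import (
    AssayConfig,
    BufferRow,
    GradientSpec,
    PlateLayout,
    default_layout,
)

__all__ = [
    "FormatError",
    "read_plate_csv",
    "write_plate_csv",
    "write_landscape_csv",
    "read_landscape_csv",
    "write_xyz_triplets",
    "read_xyz_triplets",
    "load_config",
    "atomic_write",
]


class FormatError(ValueError):
    """Input file does not match any recognised plate format."""


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write-then-rename: the target only ever appears fully written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent, prefix=f".{path.name}.", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, mode, encoding="utf-8", newline="") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def _read_csv(path, dialect: str) -> pd.DataFrame:
    kwargs = {"header": None, "dtype": str, "comment": "#"}
    if dialect == "semicolon":
        kwargs.update(sep=";", decimal=",")
    else:
        kwargs.update(sep=",")
    return pd.read_csv(path, **kwargs)


def _parse_cell(text: str, where: str, dialect: str) -> float:
    s = str(text).strip()
    if dialect == "semicolon":
        s = s.replace(",", ".")
    try:
        return float(s)
    except ValueError:
        raise FormatError(
            f"non-numeric value {text!r} at {where}"
        ) from None


def read_plate_csv(
    path,
    layout: PlateLayout | None = None,
    *,
    dialect: str = "comma",
    plate_id: str | None = None,
    wavelength: float | None = None,
) -> PlateReading:
    """Read one replicate plate from CSV, grid or long format.

    Grid form: a rows x columns block of absorbances, with optional A-H
    row labels in the first column and optional 1-12 header row. Long
    form: a ``well,value`` table (header required, any row order). The
    format is auto-detected; malformed cells are reported with their well
    address.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plate file not found: {path}")
    layout = layout or default_layout()
    raw = _read_csv(path, dialect)
    df = raw.dropna(axis=0, how="all").dropna(axis=1, how="all")
    pid = plate_id if plate_id is not None else path.stem

    first_cell = str(df.iloc[0, 0]).strip().lower()
    if first_cell in ("well", "well_id", "position"):
        return _read_long(df, layout, pid, wavelength, dialect)
    return _read_grid(df, layout, pid, wavelength, dialect)


def _read_grid(df, layout, plate_id, wavelength, dialect) -> PlateReading:
    n_rows, n_cols = layout.shape
    # strip an optional 1..12 header row and A..H label column
    first_col = df.iloc[:, 0].astype(str).str.strip()
    row_labels = [r.label for r in layout.rows]
    if first_col.iloc[-n_rows:].tolist() == row_labels:
        header_rows = len(df) - n_rows
        df = df.iloc[header_rows:, 1:]
    elif len(df) == n_rows + 1:
        df = df.iloc[1:, :]
    if df.shape != (n_rows, n_cols):
        raise FormatError(
            f"expected a {n_rows}x{n_cols} grid (plus optional headers), "
            f"got {df.shape[0]}x{df.shape[1]} in plate {plate_id!r}"
        )
    values = np.empty((n_rows, n_cols))
    for i in range(n_rows):
        for j in range(n_cols):
            values[i, j] = _parse_cell(
                df.iat[i, j], f"well {layout.well_label(i, j)}", dialect
            )
    return PlateReading(values=values, plate_id=plate_id, wavelength=wavelength)


def _read_long(df, layout, plate_id, wavelength, dialect) -> PlateReading:
    header = [str(x).strip().lower() for x in df.iloc[0]]
    body = df.iloc[1:]
    try:
        w_idx = header.index("well") if "well" in header else 0
        v_idx = header.index("value")
    except ValueError:
        raise FormatError(
            f"long-format plate {plate_id!r} needs a 'value' column"
        ) from None
    values = np.full(layout.shape, np.nan)
    seen = set()
    for _, rec in body.iterrows():
        label = str(rec.iloc[w_idx]).strip()
        r, c = layout.parse_well_label(label)
        if (r, c) in seen:
            raise FormatError(f"duplicate well {label!r} in {plate_id!r}")
        seen.add((r, c))
        values[r, c] = _parse_cell(rec.iloc[v_idx], f"well {label}", dialect)
    missing = layout.n_wells - len(seen)
    if missing:
        raise FormatError(
            f"long-format plate {plate_id!r} missing {missing} well(s)"
        )
    return PlateReading(values=values, plate_id=plate_id, wavelength=wavelength)


def write_plate_csv(
    reading: PlateReading, path, layout: PlateLayout | None = None
) -> None:
    """Write a plate as a labelled grid CSV (header 1-12, labels A-H)."""
    layout = layout or default_layout()
    if reading.values.shape != layout.shape:
        raise ShapeError(
            f"plate shape {reading.values.shape} != layout {layout.shape}"
        )
    with atomic_write(path) as fh:
        fh.write("," + ",".join(str(j + 1) for j in range(layout.n_columns)))
        fh.write("\n")
        for i, row in enumerate(layout.rows):
            cells = ",".join(f"{v:.6g}" for v in reading.values[i])
            fh.write(f"{row.label},{cells}\n")


def write_landscape_csv(landscape: ActivityLandscape, path,
                        layout: PlateLayout | None = None) -> None:
    """Landscape as long CSV: well, pH, temperature, mean %, sd %."""
    layout = layout or default_layout()
    nr, nc = landscape.shape
    with atomic_write(path) as fh:
        fh.write("well,ph,temperature,mean_activity,sd_activity\n")
        for i in range(nr):
            for j in range(nc):
                ph = landscape.ph_of(i, j)
                ph_s = f"{ph:.2f}" if landscape.ph_corrected else f"{ph:.1f}"
                sd = (
                    "" if landscape.sd is None
                    else f"{landscape.sd[i, j]:.4f}"
                )
                fh.write(
                    f"{layout.well_label(i, j)},{ph_s},"
                    f"{landscape.temperature_axis[j]:.1f},"
                    f"{landscape.mean_relative_activity[i, j]:.4f},{sd}\n"
                )


def read_landscape_csv(path, layout: PlateLayout | None = None
                       ) -> ActivityLandscape:
    """Reload a landscape written by :func:`write_landscape_csv`."""
    layout = layout or default_layout()
    df = pd.read_csv(path)
    nr, nc = layout.shape
    mean = np.full((nr, nc), np.nan)
    sd = np.full((nr, nc), np.nan)
    ph = np.full((nr, nc), np.nan)
    has_sd = "sd_activity" in df and df["sd_activity"].notna().any()
    for _, rec in df.iterrows():
        r, c = layout.parse_well_label(str(rec["well"]))
        mean[r, c] = rec["mean_activity"]
        ph[r, c] = rec["ph"]
        if has_sd:
            sd[r, c] = rec["sd_activity"]
    corrected = any(
        len(set(np.round(ph[i], 6))) > 1 for i in range(nr)
    )
    return ActivityLandscape(
        mean_relative_activity=mean,
        sd=sd if has_sd else None,
        ph_axis=ph if corrected else ph[:, 0],
        temperature_axis=np.asarray(layout.column_temperatures),
        n_plates=0,
    )


def write_xyz_triplets(landscape: ActivityLandscape, path) -> None:
    """Vertical XYZ-triplet CSV for contour-plotting packages.

    One row per well with columns (pH, temperature, activity), ordered
    column-major: all pH values for the first temperature, then the
    second, and so on. pH is printed to 1 decimal (2 when the axis was
    temperature-corrected), temperature to 1 decimal, activity to 2.
    """
    nr, nc = landscape.shape
    ph_dec = 2 if landscape.ph_corrected else 1
    with atomic_write(path) as fh:
        fh.write("ph,temperature,activity\n")
        for j in range(nc):
            for i in range(nr):
                fh.write(
                    f"{landscape.ph_of(i, j):.{ph_dec}f},"
                    f"{landscape.temperature_axis[j]:.1f},"
                    f"{landscape.mean_relative_activity[i, j]:.2f}\n"
                )


def read_xyz_triplets(path) -> pd.DataFrame:
    """XYZ triplet CSV back as a DataFrame (ph, temperature, activity)."""
    return pd.read_csv(path)


def _build_layout(cfg: dict) -> PlateLayout:
    rows_cfg = cfg.get("rows")
    if rows_cfg:
        rows = tuple(
            BufferRow(
                label=str(r["label"]),
                ph_ref=float(r["ph"]),
                temp_coefficient=float(r.get("temp_coefficient", 0.0)),
                t_ref=float(r.get("t_ref", 25.0)),
            )
            for r in rows_cfg
        )
    else:
        rows = tuple(default_layout().rows)
    g = cfg.get("gradient", {})
    gradient = GradientSpec(
        center=float(g.get("center", 60.1)),
        span=float(g.get("span", 19.9)),
        n_columns=int(g.get("n_columns", 12)),
        mode=str(g.get("mode", "edge_weighted")),
    )
    return PlateLayout(rows=rows, gradient=gradient)


def load_config(path) -> AssayConfig:
    """Load a YAML assay configuration into an :class:`AssayConfig`.

    Recognised keys: ``rows`` (list of label/ph/temp_coefficient/t_ref),
    ``gradient`` (center/span/n_columns/mode) and assay metadata
    (``assay``, ``substrate``, ``enzyme_conc``, ``substrate_final_conc``,
    ``conc_unit``, ``duration``, ``wavelength``). Missing keys fall back
    to the standard layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    layout = _build_layout(cfg)
    return AssayConfig(
        assay_name=str(cfg.get("assay", "other")),
        substrate=str(cfg.get("substrate", "")),
        enzyme_conc=cfg.get("enzyme_conc"),
        substrate_final_conc=cfg.get("substrate_final_conc"),
        conc_unit=str(cfg.get("conc_unit", "mg/ml")),
        duration=cfg.get("duration"),
        wavelength=cfg.get("wavelength"),
        layout=layout,
    )
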