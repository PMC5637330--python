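"""Landscape analytics: interpolation, regions, optima, slices, rendering."""

import numpy as np
import pytest

from gradplate import (
    ActivityLandscape,
    extract_region,
    find_optimum,
    interpolate_grid,
    render_contour,
    slice_profile,
)
from gradplate.contour import AxisValueError
from gradplate.pipeline import DegeneratePlateError


def _landscape(mean, sd=None):
    nr, nc = mean.shape
    return ActivityLandscape(
        mean_relative_activity=np.asarray(mean, dtype=float),
        sd=None if sd is None else np.asarray(sd, dtype=float),
        ph_axis=np.linspace(4.0, 8.0, nr),
        temperature_axis=np.linspace(40.0, 80.0, nc),
        n_plates=3,
    )


def test_interpolate_identity_and_midpoint():
    grid = np.array([[0.0, 10.0], [20.0, 50.0]])
    assert np.array_equal(interpolate_grid(grid, 1), grid)
    fine = interpolate_grid(grid, 2)
    assert fine.shape == (3, 3)
    assert fine[1, 1] == pytest.approx(grid.mean())  # bilinear cell centre
    # measured nodes reproduced exactly
    assert np.array_equal(fine[::2, ::2], grid)
    with pytest.raises(ValueError):
        interpolate_grid(grid, 0)


def test_interpolation_never_overshoots(rng):
    grid = rng.uniform(0, 100, (8, 12))
    fine = interpolate_grid(grid, 7)
    assert fine.max() <= grid.max() + 1e-9
    assert fine.min() >= grid.min() - 1e-9


def test_extract_region_matches_brute_force(noiseless_landscape, rng):
    for threshold in (30.0, 60.0, 90.0):
        region = extract_region(noiseless_landscape, threshold)
        mean = noiseless_landscape.mean_relative_activity
        expected = {
            (i, j)
            for i in range(mean.shape[0])
            for j in range(mean.shape[1])
            if mean[i, j] >= threshold
        }
        assert region.cells == expected
        phs = [noiseless_landscape.ph_of(i, j) for i, j in expected]
        temps = [noiseless_landscape.temperature_axis[j] for _, j in expected]
        assert region.ph_range == (min(phs), max(phs))
        assert region.temp_range == (min(temps), max(temps))


def test_extract_region_edges(noiseless_landscape):
    with pytest.raises(ValueError):
        extract_region(noiseless_landscape, 100.5)
    with pytest.raises(ValueError):
        extract_region(noiseless_landscape, 0.0)
    at_max = extract_region(noiseless_landscape, 100.0)
    mean = noiseless_landscape.mean_relative_activity
    assert at_max.cells == {
        tuple(map(int, rc)) for rc in np.argwhere(mean == mean.max())
    }


def test_region_monotone_in_threshold(noiseless_landscape):
    r60 = extract_region(noiseless_landscape, 60.0)
    r90 = extract_region(noiseless_landscape, 90.0)
    assert r90.cells <= r60.cells
    # the optimum cell sits inside every region up to 100%
    opt = find_optimum(noiseless_landscape)[0]
    r100 = extract_region(noiseless_landscape, 100.0)
    assert any(
        noiseless_landscape.ph_of(i, j) == opt[0]
        and noiseless_landscape.temperature_axis[j] == opt[1]
        for i, j in r100.cells
    )


def test_find_optimum_unique_and_ties():
    mean = np.zeros((3, 4))
    mean[1, 2] = 100.0
    hits = find_optimum(_landscape(mean))
    assert len(hits) == 1
    assert hits[0][0] == 6.0 and hits[0][2] == 100.0
    mean[2, 1] = 100.0
    hits = find_optimum(_landscape(mean))
    assert len(hits) == 2
    temps = [t for _, t, _ in hits]
    assert temps == sorted(temps)  # deterministic order
    with pytest.raises(DegeneratePlateError):
        find_optimum(_landscape(np.zeros((3, 4))))


def test_optimum_against_closed_form(noiseless_landscape, layout_55):
    """An independent closed-form loop over the grid nodes must agree with
    the reported optimum cell, and that cell must lie within one grid step
    of the continuous analytic maximiser (dense brute-force search)."""
    import math

    from gradplate import preset

    p = preset("celluclast-like")

    def surface_value(ph, t):
        pka2 = p.pka2_ref + p.pka2_slope * (t - p.t_ref)
        bell = 1.0 / (1.0 + 10 ** (p.pka1 - ph) + 10 ** (ph - pka2))
        therm = math.exp(p.a * t) / (1.0 + math.exp(p.k * (t - p.tm)))
        return bell * therm

    row_phs = layout_55.row_phs
    col_ts = layout_55.column_temperatures
    best = max(
        ((surface_value(ph, t), ph, t) for ph in row_phs for t in col_ts),
        key=lambda x: x[0],
    )
    (ph_opt, t_opt, act) = find_optimum(noiseless_landscape)[0]
    assert act == pytest.approx(100.0)
    assert (ph_opt, t_opt) == (best[1], best[2])
    # continuous maximiser by dense search; grid optimum within one step
    phs = np.linspace(4.0, 8.0, 801)
    temps = np.linspace(35.1, 74.9, 801)
    vals = np.array([[surface_value(ph, t) for t in temps] for ph in phs])
    i, j = np.unravel_index(vals.argmax(), vals.shape)
    ph_star, t_star = phs[i], temps[j]
    ph_step = max(np.diff(row_phs))
    t_step = max(np.diff(col_ts))
    assert abs(ph_opt - ph_star) <= ph_step
    assert abs(t_opt - t_star) <= t_step


def test_slices_are_exact_projections(noiseless_landscape):
    mean = noiseless_landscape.mean_relative_activity
    for i, ph in enumerate(noiseless_landscape.ph_axis):
        prof = slice_profile(noiseless_landscape, "ph", float(ph))
        assert [m for _, m, _ in prof.points] == list(mean[i])
    for j, t in enumerate(noiseless_landscape.temperature_axis):
        prof = slice_profile(noiseless_landscape, "temperature", float(t))
        assert [m for _, m, _ in prof.points] == list(mean[:, j])
    # the slice through the optimum contains 100
    opt = find_optimum(noiseless_landscape)[0]
    prof = slice_profile(noiseless_landscape, "ph", opt[0])
    assert max(m for _, m, _ in prof.points) == pytest.approx(100.0)


def test_slice_snapping_and_rejection(noiseless_landscape):
    prof = slice_profile(noiseless_landscape, "temperature", 46.5)
    assert prof.fixed_value == 46.0  # within half a step: snaps
    with pytest.raises(AxisValueError):
        slice_profile(noiseless_landscape, "ph", 9.5)
    with pytest.raises(ValueError):
        slice_profile(noiseless_landscape, "depth", 5.0)


def test_ph_window_narrows_with_temperature(noiseless_landscape):
    """On a surface whose base-side pKa falls with temperature, the pH at
    which each temperature slice drops below 60% of its own maximum must
    not increase from 46 to 64 °C (the conventional three-pH-curve view)."""
    ceilings = []
    for t in (46.0, 53.2, 64.0):
        prof = slice_profile(noiseless_landscape, "temperature", t)
        own_max = max(m for _, m, _ in prof.points)
        ceilings.append(max(
            ph for ph, m, _ in prof.points if m >= 0.6 * own_max
        ))
    assert ceilings[0] >= ceilings[1] >= ceilings[2]
    assert ceilings[2] < ceilings[0] or ceilings[1] < ceilings[0] or \
        ceilings[2] < ceilings[1]


def test_render_contour_writes_figures(noiseless_landscape, tmp_path):
    for name, kwargs in [
        ("plain.png", {}),
        ("smooth.svg", {"method": "bicubic", "interp": 4}),
        ("flat.png", {"interp": 1}),
    ]:
        out = tmp_path / name
        render_contour(noiseless_landscape, out, **kwargs)
        assert out.exists() and out.stat().st_size > 0


def test_render_constant_landscape(tmp_path):
    flat = _landscape(np.full((8, 12), 100.0))
    out = tmp_path / "const.png"
    render_contour(flat, out)
    assert out.exists() and out.stat().st_size > 0


def test_innermost_contour_ring_encloses_argmax(noiseless_landscape):
    """The highest filled level set (computed numerically on the refined
    grid, not from pixels) must contain the coarse-grid argmax."""
    mean = noiseless_landscape.mean_relative_activity
    fine = interpolate_grid(noiseless_landscape, 10)
    top = fine >= 90.0
    r, c = np.unravel_index(mean.argmax(), mean.shape)
    assert top[r * 10, c * 10]
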