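"""Mechanistic synthetic surface and plate simulator."""

import numpy as np
import pytest

from gradplate import (
    SyntheticModelParams,
    default_layout,
    ph_response,
    preset,
    process_plates,
    simulate_plates,
    temp_response,
    true_surface,
)


def test_ph_response_closed_form_and_symmetry():
    # midpoint value of the diprotic bell with pKa 4 and 8
    assert ph_response(6.0, 4.0, 8.0) == pytest.approx(
        1.0 / (1.0 + 2.0 * 10.0 ** -2)
    )
    # at pH = pKa1 the acid term equals 1
    assert ph_response(4.0, 4.0, 8.0) == pytest.approx(
        1.0 / (2.0 + 10.0 ** (4.0 - 8.0))
    )
    for d in (0.3, 1.0, 2.5):
        assert ph_response(6.0 + d, 4.0, 8.0) == pytest.approx(
            ph_response(6.0 - d, 4.0, 8.0)
        )
    with pytest.raises(ValueError):
        ph_response(5.0, 8.0, 4.0)


def test_temp_response_shape():
    t = np.linspace(20, 90, 701)
    # pure sigmoid decay when activation is off
    decay = temp_response(t, 0.0, 60.0, 0.5)
    assert (np.diff(decay) < 0).all()
    # before normalisation g(tm) is half the low-T plateau; the ratio
    # survives normalisation
    g = temp_response(np.array([20.0, 60.0]), 0.0, 60.0, 0.5, t_range=t)
    assert g[1] / g[0] == pytest.approx(0.5, rel=1e-3)
    # unimodal for a < k: rises then falls
    vals = temp_response(t, 0.05, 60.0, 0.4)
    peak = int(np.argmax(vals))
    assert 0 < peak < len(t) - 1
    assert (np.diff(vals[:peak]) > 0).all()
    assert (np.diff(vals[peak:]) < 0).all()


def test_temp_response_argmax_matches_grid_search():
    """Analytic argmax Tm + ln(a/(k-a))/k against a 0.01 °C brute force."""
    a, tm, k = 0.05, 60.0, 0.4
    t = np.arange(20.0, 90.0, 0.01)
    vals = temp_response(t, a, tm, k)
    t_star = t[int(np.argmax(vals))]
    analytic = tm + np.log(a / (k - a)) / k
    assert t_star == pytest.approx(analytic, abs=0.01)


def test_separable_surface_has_fixed_ph_optimum(layout):
    surf = true_surface(preset("cel8a-like"), layout)
    assert surf.max() == pytest.approx(100.0)
    argmax_rows = surf.argmax(axis=0)
    assert len(set(argmax_rows.tolist())) == 1


def test_coupled_surface_shifts_acidic(layout_55):
    """With pKa2 falling in temperature, the pH where each temperature
    column crosses 50% of its own maximum is non-increasing in T."""
    surf = true_surface(preset("celluclast-like"), layout_55)
    phs = np.asarray(default_layout().row_phs)
    crossings = []
    for j in range(surf.shape[1]):
        col = surf[:, j]
        above = phs[col >= 0.5 * col.max()]
        crossings.append(above.max())
    assert all(b <= a for a, b in zip(crossings, crossings[1:]))
    assert crossings[-1] < crossings[0]


def test_simulation_determinism_and_substreams(layout_55):
    p = preset("celluclast-like", seed=7)
    r1, b1 = simulate_plates(p, layout_55)
    r2, b2 = simulate_plates(p, layout_55)
    for a, b in zip(r1, r2):
        assert np.array_equal(a.values, b.values)
    assert b1.value == b2.value
    # adding a plate must not reshuffle the existing ones
    r4, _ = simulate_plates(
        preset("celluclast-like", seed=7, n_plates=4), layout_55
    )
    for a, b in zip(r1, r4[:3]):
        assert np.array_equal(a.values, b.values)
    # a different seed gives different noise
    r_other, _ = simulate_plates(
        preset("celluclast-like", seed=8), layout_55
    )
    assert not np.array_equal(r1[0].values, r_other[0].values)


def test_noiseless_round_trip(layout_55):
    p = preset("celluclast-like", noise_sd=0.0)
    readings, blank = simulate_plates(p, layout_55)
    landscape = process_plates(readings, blank, layout_55)
    surf = true_surface(p, layout_55)
    assert np.allclose(
        landscape.mean_relative_activity, surf, rtol=0, atol=1e-9
    )
    assert np.allclose(landscape.sd, 0.0)


def test_more_noise_more_reported_sd(layout_55):
    """Mean per-well SD reported by the pipeline must not shrink when the
    simulated reader noise grows (averaged over seeds)."""
    def mean_sd(noise, seed):
        p = preset("celluclast-like", noise_sd=noise, seed=seed)
        readings, blank = simulate_plates(p, layout_55)
        return float(np.nanmean(
            process_plates(readings, blank, layout_55).sd
        ))

    seeds = range(5)
    low = np.mean([mean_sd(0.005, s) for s in seeds])
    mid = np.mean([mean_sd(0.02, s) for s in seeds])
    high = np.mean([mean_sd(0.08, s) for s in seeds])
    assert low < mid < high


def test_heteroscedastic_noise_concentrates_where_signal_is(layout_55):
    p = preset("celluclast-like", heteroscedastic=True, noise_sd=0.05,
               seed=3, n_plates=20)
    readings, _ = simulate_plates(p, layout_55)
    surf = true_surface(p, layout_55)
    stack = np.stack([r.values for r in readings])
    per_well_sd = stack.std(axis=0, ddof=1)
    hot = surf >= 80.0
    cold = surf <= 5.0
    assert per_well_sd[hot].mean() > 5 * per_well_sd[cold].mean()


def test_parameter_validation():
    with pytest.raises(ValueError):
        SyntheticModelParams(pka1=8.0, pka2_ref=4.0)
    with pytest.raises(ValueError):
        SyntheticModelParams(noise_sd=-0.1)
    with pytest.raises(ValueError):
        SyntheticModelParams(amplitude=0.0)
    with pytest.raises(KeyError):
        preset("no-such-preset")
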