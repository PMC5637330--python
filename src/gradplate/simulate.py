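"""Synthetic gradient-plate assays from a mechanistic activity surface.

Stands in for the wet-lab step so the whole pipeline can be exercised and
validated in silico. The noiseless surface is the product of two standard
enzymology models:

* **pH response** — a diprotic active-site model: the catalytically
  competent fraction is ``1 / (1 + 10^(pKa1 - pH) + 10^(pH - pKa2))``,
  a bell peaking midway between the two apparent pKa values.
* **temperature response** — Arrhenius-like activation multiplied by
  two-state thermal denaturation: ``e^(a·T) / (1 + e^(k·(T - Tm)))``,
  normalised to its maximum over the plate's temperature range; unimodal
  whenever ``a < k``.

Letting the base-side pKa drift downward with temperature
(``pka2_slope < 0``) couples the two axes: the pH ceiling for high
activity moves to more acidic values as temperature rises, the behaviour
real cellulase mixtures show. ``pka2_slope = 0`` gives a separable
surface.

Simulated plates are ``blank + amplitude * surface + Gaussian noise`` per
well. A single seed spawns one independent substream per plate, so adding
a fourth replicate never reshuffles the first three.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pipeline import BlankModel, PlateReading
from .plate import PlateLayout, default_layout

__all__ = [
    "SyntheticModelParams",
    "ph_response",
    "temp_response",
    "true_surface",
    "simulate_plates",
    "preset",
    "PRESETS",
]


def ph_response(ph, pka1: float, pka2: float):
    """Active fraction of a diprotic enzyme at a given pH, in (0, 1].

    Maximised at ``(pKa1 + pKa2) / 2`` and symmetric about it.
    """
    if pka1 >= pka2:
        raise ValueError(f"pKa1 ({pka1}) must be below pKa2 ({pka2})")
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (pka1 - ph) + 10.0 ** (ph - pka2))
    return float(out) if out.ndim == 0 else out


def temp_response(t, a: float, tm: float, k: float, *, t_range=None):
    """Activation x denaturation temperature profile, normalised to max 1.

    ``g(T) = exp(a*T) / (1 + exp(k*(T - Tm)))`` rescaled so its maximum
    over ``t_range`` (default: the evaluation points themselves) is 1.
    ``a`` is the activation slope per °C, ``Tm`` the denaturation midpoint
    and ``k`` the unfolding steepness; unimodal for ``a < k``.
    """
    if k <= 0:
        raise ValueError(f"denaturation steepness k must be > 0, got {k}")
    t = np.asarray(t, dtype=float)

    def g(x):
        # log-space evaluation keeps exp(a*T) from overflowing
        x = np.asarray(x, dtype=float)
        return np.exp(a * x - np.logaddexp(0.0, k * (x - tm)))

    ref = g(t if t_range is None else np.asarray(t_range, dtype=float))
    out = g(t) / np.max(ref)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticModelParams:
    """Parameters of the coupled pH x temperature surface and noise model.

    Attributes
    ----------
    pka1 : float
        Acid-side apparent pKa (temperature-independent here).
    pka2_ref : float
        Base-side apparent pKa at ``t_ref``.
    pka2_slope : float
        d(pKa2)/d°C; negative values shift the usable pH window toward
        acid as temperature rises.
    a, tm, k : float
        Temperature-response parameters: activation slope (per °C),
        denaturation midpoint (°C), unfolding steepness (per °C).
    amplitude : float
        Absorbance above blank at 100% activity.
    blank : float
        Substrate background absorbance.
    noise_sd : float
        Per-well Gaussian reader noise SD (absorbance units). With
        ``heteroscedastic=True`` the SD scales with the signal instead:
        ``noise_sd * (signal / amplitude)``.
    """

    pka1: float = 4.2
    pka2_ref: float = 7.6
    pka2_slope: float = 0.0
    a: float = 0.06
    tm: float = 79.0
    k: float = 0.5
    t_ref: float = 25.0
    amplitude: float = 1.0
    blank: float = 0.1
    noise_sd: float = 0.02
    heteroscedastic: bool = False
    n_plates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pka1 >= self.pka2_ref:
            raise ValueError(
                f"pKa1 ({self.pka1}) must be below pKa2_ref ({self.pka2_ref})"
            )
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0: {self.amplitude}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0: {self.noise_sd}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0: {self.k}")
        if self.n_plates < 1:
            raise ValueError(f"n_plates must be >= 1: {self.n_plates}")


#: Illustrative presets mirroring two real activity-landscape shapes:
#: a thermostable endoglucanase with a separable surface peaking near
#: 75 °C / pH 5.5-6.5, and a mesophilic cellulase mixture whose pH window
#: narrows toward acid with rising temperature (optimum near 55 °C, pH 5).
#: Values are hand-picked for shape, not fitted to any measurement.
PRESETS: dict[str, SyntheticModelParams] = {
    "cel8a-like": SyntheticModelParams(
        pka1=4.2, pka2_ref=7.6, pka2_slope=0.0, a=0.06, tm=79.0, k=0.5
    ),
    "celluclast-like": SyntheticModelParams(
        pka1=3.5, pka2_ref=7.1, pka2_slope=-0.02, a=0.05, tm=60.0, k=0.4
    ),
}


def preset(name: str, **overrides) -> SyntheticModelParams:
    """Fetch a named preset, optionally overriding fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


def true_surface(
    params: SyntheticModelParams, layout: PlateLayout | None = None
) -> np.ndarray:
    """Noiseless activity grid (% of its own grid maximum, max = 100)."""
    layout = layout or default_layout()
    temps = np.asarray(layout.column_temperatures)
    phs = np.asarray(layout.row_phs)
    pka2 = params.pka2_ref + params.pka2_slope * (temps - params.t_ref)
    if np.any(pka2 <= params.pka1):
        raise ValueError(
            "pka2 drifts below pka1 within the plate's temperature range"
        )
    surf = np.empty((len(phs), len(temps)))
    trow = temp_response(temps, params.a, params.tm, params.k)
    for j in range(len(temps)):
        surf[:, j] = ph_response(phs, params.pka1, float(pka2[j])) * trow[j]
    return 100.0 * surf / surf.max()


def simulate_plates(
    params: SyntheticModelParams, layout: PlateLayout | None = None
) -> tuple[list[PlateReading], BlankModel]:
    """Noisy replicate absorbance plates plus the blank used to build them.

    ``absorbance = blank + amplitude * surface/100 + N(0, noise_sd)`` per
    well, independent across wells and plates; deterministic for a fixed
    seed, with one spawned substream per plate.
    """
    layout = layout or default_layout()
    surface = true_surface(params, layout)
    signal = params.blank + params.amplitude * surface / 100.0
    streams = np.random.SeedSequence(params.seed).spawn(params.n_plates)
    readings = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if params.noise_sd > 0:
            if params.heteroscedastic:
                sd = params.noise_sd * (
                    params.amplitude * surface / 100.0
                ) / params.amplitude
                noise = rng.normal(0.0, 1.0, size=surface.shape) * sd
            else:
                noise = rng.normal(0.0, params.noise_sd, size=surface.shape)
        else:
            noise = 0.0
        readings.append(
            PlateReading(values=signal + noise, plate_id=f"sim-{i + 1}")
        )
    return readings, BlankModel(value=params.blank)
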