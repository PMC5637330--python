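"""Reagent arithmetic for plate assays.

Final in-well concentrations follow from the pipetted volumes alone
(c_final = c_stock * V_added / V_total), so a configured assay table can be
validated against the protocol volumes that supposedly produced it.
Concentrations are displayed to two significant figures, matching the way
assay tables are usually printed; internal arithmetic is never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Component",
    "ReactionRecipe",
    "VolumeError",
    "DilutionError",
    "final_concentration",
    "dilution",
    "parse_concentration",
    "round_sig",
    "check_recipe",
]


class VolumeError(ValueError):
    """Volume added exceeds the total reaction volume."""


class DilutionError(ValueError):
    """Dilution factor below 1 (a 'dilution' may not concentrate)."""


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def final_concentration(
    stock_conc: float, volume_added: float, total_volume: float
) -> float:
    """In-well concentration after mixing, in the stock's own unit.

    Full precision; use :func:`round_sig` for report display.
    """
    if volume_added <= 0:
        raise VolumeError(f"volume added must be positive: {volume_added}")
    if volume_added > total_volume:
        raise VolumeError(
            f"volume added ({volume_added} µl) exceeds total "
            f"volume ({total_volume} µl)"
        )
    return stock_conc * volume_added / total_volume


def dilution(stock_conc: float, fold: float) -> float:
    """Concentration after an n-fold dilution. ``fold`` must be >= 1."""
    if fold < 1:
        raise DilutionError(f"dilution fold must be >= 1, got {fold}")
    return stock_conc / fold


# unit string -> multiplier into (mg/ml | mM), e.g. "1%" w/v == 10 mg/ml
_UNIT_SCALE = {
    "mg/ml": ("mg/ml", 1.0),
    "g/l": ("mg/ml", 1.0),
    "%": ("mg/ml", 10.0),  # percent w/v
    "% w/v": ("mg/ml", 10.0),
    "mm": ("mM", 1.0),
    "m": ("mM", 1000.0),
}


def parse_concentration(text: str) -> tuple[float, str]:
    """Parse '1% w/v', '25 mg/ml', '0.1 M', '6.7 mM' -> (value, unit).

    Percent is w/v (1% == 10 mg/ml); molar units are normalised to mM.
    """
    s = text.strip()
    i = 0
    while i < len(s) and (s[i].isdigit() or s[i] in ".+-eE"):
        i += 1
    if i == 0:
        raise ValueError(f"cannot parse concentration {text!r}")
    value = float(s[:i])
    unit_key = s[i:].strip().lower() or "mg/ml"
    if unit_key not in _UNIT_SCALE:
        raise ValueError(f"unknown concentration unit {s[i:].strip()!r}")
    unit, scale = _UNIT_SCALE[unit_key]
    return value * scale, unit


@dataclass(frozen=True)
class Component:
    """One pipetted component of a reaction: stock concentration + volume."""

    name: str
    stock_conc: float
    unit: str
    volume_ul: float

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise VolumeError(
                f"component {self.name!r}: volume must be positive, "
                f"got {self.volume_ul}"
            )


@dataclass(frozen=True)
class ReactionRecipe:
    """A full reaction mix; total volume is the sum of component volumes."""

    components: tuple[Component, ...]

    @property
    def total_volume(self) -> float:
        return sum(c.volume_ul for c in self.components)

    def final_concentration_of(self, name: str) -> float:
        for c in self.components:
            if c.name == name:
                return final_concentration(
                    c.stock_conc, c.volume_ul, self.total_volume
                )
        raise KeyError(f"no component named {name!r}")


@dataclass(frozen=True)
class RecipeCheck:
    """Result of comparing a configured final concentration to the volumes."""

    component: str
    configured: float
    recomputed: float
    unit: str

    @property
    def matches(self) -> bool:
        # agreement at display precision (2 significant figures)
        return round_sig(self.recomputed) == round_sig(self.configured)


def check_recipe(
    recipe: ReactionRecipe, configured: dict[str, float]
) -> list[RecipeCheck]:
    """Recompute final concentrations from volumes and flag mismatches.

    ``configured`` maps component name to the final concentration a config
    or published table claims. Mismatches are reported, never silently
    corrected: an inconsistent table entry is a finding, not an error.
    """
    out = []
    for name, conf in configured.items():
        comp = next(c for c in recipe.components if c.name == name)
        out.append(
            RecipeCheck(
                component=name,
                configured=conf,
                recomputed=recipe.final_concentration_of(name),
                unit=comp.unit,
            )
        )
    return out
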