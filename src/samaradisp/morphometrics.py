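"""Wing-area, inverse-wing-loading and wing-loading computations for winged fruit.

Inverse wing loading (IWL) is the ratio of a fruit's "long" wing area (cm^2)
to its air-dried mass (g).  Higher IWL means more lift per unit weight and,
empirically, longer wind dispersal.  Using the inverse of the traditional
wing loading keeps wingless fruit well defined (IWL = 0) instead of dividing
by a zero wing area.

Wing-area rules differ by genus:

* ``two_winged`` (e.g. *Dipterocarpus*, *Hopea*): area is the sum of
  length x width over the two long wings.
* ``shorea_five_winged`` (*Shorea*): three long wings and two short wings;
  only the longest and shortest long wings are measured, their summed
  rectangular area is multiplied by 1.5 to stand in for the unmeasured
  middle long wing.  Short wings contribute negligible lift and are ignored.
* ``wingless``: area is 0 by definition.

Wing loading proper is fruit *weight* (force) per wing area.  Mass in grams
converts to weight in millidynes through standard gravity
(g = 980.665 cm/s^2, so 1 g of mass weighs 980665 mdyn); descent rate of
gyrating samaras scales with the square root of this wing loading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GENUS_RULES",
    "STANDARD_GRAVITY_MDYN_PER_G",
    "FruitMorphology",
    "WingLoadingValue",
    "MeasurementError",
    "compute_wing_area",
    "compute_iwl",
    "iwl_to_sqrt_wing_loading",
    "read_fruit_csv",
    "write_fruit_csv",
]

GENUS_RULES = ("two_winged", "shorea_five_winged", "wingless")

#: weight (millidynes) of one gram of mass under standard gravity 980.665 cm/s^2
STANDARD_GRAVITY_MDYN_PER_G = 980665.0


class MeasurementError(ValueError):
    """Raised for physically impossible or inconsistent fruit measurements."""


@dataclass
class FruitMorphology:
    """One fruit: identity, wing measurements, mass and derived quantities."""

    fruit_id: str
    species: str
    genus_rule: str
    long_wing_lengths: tuple[float, ...]
    long_wing_widths: tuple[float, ...]
    mass: float  # g, air-dried
    wing_area: float = field(init=False)  # cm^2
    iwl: float = field(init=False)  # cm^2 / g

    def __post_init__(self) -> None:
        self.long_wing_lengths = tuple(float(x) for x in self.long_wing_lengths)
        self.long_wing_widths = tuple(float(x) for x in self.long_wing_widths)
        self.wing_area = compute_wing_area(
            self.genus_rule, self.long_wing_lengths, self.long_wing_widths
        )
        self.iwl = compute_iwl(self.wing_area, self.mass)


@dataclass(frozen=True)
class WingLoadingValue:
    """Wing loading (mdyn/cm^2) and its square root; NaN when undefined."""

    wing_loading: float
    sqrt_wing_loading: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.wing_loading)


def compute_wing_area(
    genus_rule: str,
    long_wing_lengths: Sequence[float],
    long_wing_widths: Sequence[float],
) -> float:
    """Long-wing area (cm^2) from lengths and widths (cm) under a genus rule.

    ``two_winged`` sums the two rectangles; ``shorea_five_winged`` expects
    the longest and shortest of the three long wings and scales their summed
    area by 1.5; ``wingless`` requires empty lists and returns 0.
    """
    if genus_rule not in GENUS_RULES:
        raise MeasurementError(f"unknown genus_rule {genus_rule!r}")
    lengths = [float(x) for x in long_wing_lengths]
    widths = [float(x) for x in long_wing_widths]
    if len(lengths) != len(widths):
        raise MeasurementError(
            f"{len(lengths)} lengths vs {len(widths)} widths: lists must pair up"
        )
    if any(not math.isfinite(x) or x < 0 for x in lengths + widths):
        raise MeasurementError("wing dimensions must be finite and non-negative")

    if genus_rule == "wingless":
        if lengths:
            raise MeasurementError("wingless fruit must have no wing measurements")
        return 0.0
    if len(lengths) != 2:
        raise MeasurementError(
            f"{genus_rule} expects exactly 2 measured long wings, got {len(lengths)}"
        )
    area = lengths[0] * widths[0] + lengths[1] * widths[1]
    if genus_rule == "shorea_five_winged":
        # longest + shortest measured; x1.5 accounts for the unmeasured middle long wing
        area *= 1.5
    return area


def compute_iwl(wing_area: float, mass: float) -> float:
    """Inverse wing loading (cm^2/g) = long-wing area / mass; 0 for wingless."""
    if not math.isfinite(mass) or mass <= 0:
        raise MeasurementError(f"mass must be positive, got {mass}")
    if not math.isfinite(wing_area) or wing_area < 0:
        raise MeasurementError(f"wing area must be non-negative, got {wing_area}")
    return wing_area / mass


def iwl_to_sqrt_wing_loading(iwl: float) -> WingLoadingValue:
    """Convert IWL (cm^2/g) to wing loading (mdyn/cm^2) and its square root.

    wing_loading = 980665 / iwl, i.e. the fruit's weight in millidynes per
    square centimetre of wing.  For a wingless fruit (iwl = 0) wing loading
    diverges; the value is returned as NaN (flagged undefined), never 0.
    """
    if not math.isfinite(iwl) or iwl < 0:
        raise MeasurementError(f"iwl must be finite and non-negative, got {iwl}")
    if iwl == 0:
        return WingLoadingValue(math.nan, math.nan)
    wl = STANDARD_GRAVITY_MDYN_PER_G / iwl
    return WingLoadingValue(wl, math.sqrt(wl))


# -- fruit.csv round trip -----------------------------------------------------

_FRUIT_COLUMNS = [
    "fruit_id",
    "species",
    "genus_rule",
    "wing_lengths_cm",
    "wing_widths_cm",
    "mass_g",
]


def _join(values: Iterable[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


def _split(cell: str) -> tuple[float, ...]:
    cell = "" if cell is None else str(cell).strip()
    if not cell or cell == "nan":
        return ()
    return tuple(float(tok) for tok in cell.split(";"))


def write_fruit_csv(fruits: Sequence[FruitMorphology], path) -> None:
    """Write fruit records with derived wing_area_cm2 and iwl_cm2_per_g columns."""
    rows = [
        {
            "fruit_id": f.fruit_id,
            "species": f.species,
            "genus_rule": f.genus_rule,
            "wing_lengths_cm": _join(f.long_wing_lengths),
            "wing_widths_cm": _join(f.long_wing_widths),
            "mass_g": f.mass,
            "wing_area_cm2": f.wing_area,
            "iwl_cm2_per_g": f.iwl,
        }
        for f in fruits
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fruit_csv(path) -> list[FruitMorphology]:
    """Read ``fruit.csv``; derived columns are recomputed, not trusted."""
    df = pd.read_csv(path, dtype={"wing_lengths_cm": str, "wing_widths_cm": str})
    missing = [c for c in _FRUIT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementError(f"fruit csv missing columns: {missing}")
    return [
        FruitMorphology(
            fruit_id=str(row.fruit_id),
            species=str(row.species),
            genus_rule=str(row.genus_rule),
            long_wing_lengths=_split(row.wing_lengths_cm),
            long_wing_widths=_split(row.wing_widths_cm),
            mass=float(row.mass_g),
        )
        for row in df.itertuples()
    ]
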