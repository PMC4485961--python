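"""Synthetic release-experiment generator.

Emulates a canopy-tower fruit-release experiment: a panel of winged (and
one wingless) tree species with known mean inverse wing loading (IWL),
per-release wind-speed records with a heavy right tail, and horizontal
dispersal distances generated from the log-log random-intercept model.
Every stage downstream of data collection can therefore be exercised and
validated without access to the original field measurements.

Generating process, per fruit:

* IWL ~ Normal(mean_iwl, iwl_sd) truncated at zero by redraw (wingless
  species are fixed at exactly 0);
* mass ~ log-normal with median ``mean_mass`` and coefficient of variation
  ``mass_cv``;
* wing dimensions are back-solved so the genus wing-area rule reproduces
  the drawn IWL exactly;
* maximum wind during the release ~ Gamma(shape, scale) scaled to mean
  ``wind_mean_max`` and truncated at ``wind_max_cap`` by redraw; the mean
  wind is a Uniform(0.3, 1) fraction of the maximum;
* ln(distance) = b0 + b1 ln(IWL+1) + b2 ln(U+1) + b3 ln(IWL+1) ln(U+1)
  + a_species + e, with a_species ~ N(0, sigma_species^2) drawn once per
  species and e ~ N(0, sigma_resid^2) per fruit.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical configurations give
byte-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dispersal_lmm import ModelParameters, RELEASE_COLUMNS
from .morphometrics import FruitMorphology, GENUS_RULES

__all__ = [
    "SpeciesProfile",
    "GeneratorConfig",
    "InvalidConfigError",
    "generate_fruit",
    "generate_winds",
    "generate_releases",
    "releases_frame",
    "write_releases",
]


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Morphological summary of one species in the release panel.

    ``iwl_sd`` is the per-fruit SD (a published standard error of a species
    mean converts via SE * sqrt(n)).  ``mass_cv`` is the coefficient of
    variation of fruit mass.  Wingless species must have zero IWL and spread.
    """

    name: str
    genus_rule: str
    mean_iwl: float  # cm^2/g
    iwl_sd: float  # cm^2/g, per-fruit SD
    mean_mass: float  # g (median of the log-normal mass distribution)
    mass_cv: float
    n_fruit: int

    def __post_init__(self) -> None:
        vals = (self.mean_iwl, self.iwl_sd, self.mean_mass, self.mass_cv)
        if any(not math.isfinite(v) for v in vals):
            raise InvalidConfigError(f"non-finite profile parameters for {self.name}")
        if self.genus_rule not in GENUS_RULES:
            raise InvalidConfigError(f"unknown genus_rule {self.genus_rule!r}")
        if self.mean_iwl < 0 or self.iwl_sd < 0 or self.mass_cv < 0:
            raise InvalidConfigError(f"negative spread/mean parameters for {self.name}")
        if self.mean_mass <= 0:
            raise InvalidConfigError(f"mean_mass must be > 0 for {self.name}")
        if self.n_fruit < 1:
            raise InvalidConfigError(f"n_fruit must be >= 1 for {self.name}")
        if self.genus_rule == "wingless" and (self.mean_iwl != 0 or self.iwl_sd != 0):
            raise InvalidConfigError(
                f"wingless species {self.name} must have mean_iwl = iwl_sd = 0"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic release experiment."""

    species_profiles: tuple[SpeciesProfile, ...]
    truth: ModelParameters
    wind_mean_max: float = 1.72  # m/s, mean of per-release maximum wind
    wind_max_cap: float = 10.5  # m/s, truncation of the wind distribution
    wind_shape: float = 1.0  # gamma shape; 1 gives the heavy right tail seen in calm tropical conditions
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_profiles", tuple(self.species_profiles))
        if not self.species_profiles:
            raise InvalidConfigError("species_profiles must be non-empty")
        if not (self.wind_mean_max > 0 and math.isfinite(self.wind_mean_max)):
            raise InvalidConfigError("wind_mean_max must be positive")
        if self.wind_max_cap <= self.wind_mean_max:
            raise InvalidConfigError("wind_max_cap must exceed wind_mean_max")
        if not (self.wind_shape > 0):
            raise InvalidConfigError("wind_shape must be positive")


# -- fruit -------------------------------------------------------------------


def _dims_for_area(genus_rule: str, area: float):
    """Back-solve wing lengths/widths (aspect ratio 3) matching a target area."""
    if genus_rule == "wingless":
        return (), ()
    if genus_rule == "two_winged":
        per_wing = area / 2.0
        L = math.sqrt(3.0 * per_wing)
        return (L, L), (L / 3.0, L / 3.0)
    # shorea: (L1 W1 + L2 W2) * 1.5 = area; longest carries 55% of the pair area
    pair = area / 1.5
    a1, a2 = 0.55 * pair, 0.45 * pair
    L1, L2 = math.sqrt(3.0 * a1), math.sqrt(3.0 * a2)
    return (L1, L2), (L1 / 3.0, L2 / 3.0)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf) by redraw; exact at sd = 0."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_fruit(profile: SpeciesProfile, rng_seed) -> list[FruitMorphology]:
    """Draw ``profile.n_fruit`` fruit with IWL, mass and consistent wing dims.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(rng_seed)
    n = profile.n_fruit
    sigma = math.sqrt(math.log1p(profile.mass_cv**2))
    mass = np.exp(rng.normal(math.log(profile.mean_mass), sigma, size=n))
    if profile.genus_rule == "wingless":
        iwl = np.zeros(n)
    else:
        iwl = _truncated_normal(rng, profile.mean_iwl, profile.iwl_sd, n)
    fruits = []
    for k in range(n):
        area = iwl[k] * mass[k]
        lengths, widths = _dims_for_area(profile.genus_rule, area)
        fruits.append(
            FruitMorphology(
                fruit_id=f"{profile.name}_{k:03d}",
                species=profile.name,
                genus_rule=profile.genus_rule,
                long_wing_lengths=lengths,
                long_wing_widths=widths,
                mass=float(mass[k]),
            )
        )
    return fruits


# -- wind --------------------------------------------------------------------


def generate_winds(
    n: int,
    wind_mean_max: float = 1.72,
    wind_shape: float = 1.0,
    wind_max_cap: float = 10.5,
    rng_seed=0,
) -> np.ndarray:
    """Per-release (max_wind, mean_wind) pairs, shape (n, 2), all positive.

    Maximum winds are Gamma(wind_shape) scaled to mean ``wind_mean_max`` and
    truncated at ``wind_max_cap`` by redraw; mean wind is a Uniform(0.3, 1)
    fraction of the maximum, so mean <= max always holds.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    if wind_max_cap <= wind_mean_max:
        raise InvalidConfigError("wind_max_cap must exceed wind_mean_max")
    rng = np.random.default_rng(rng_seed)
    scale = wind_mean_max / wind_shape
    vmax = rng.gamma(wind_shape, scale, size=n)
    bad = (vmax > wind_max_cap) | (vmax <= 0)
    while np.any(bad):
        vmax[bad] = rng.gamma(wind_shape, scale, size=int(bad.sum()))
        bad = (vmax > wind_max_cap) | (vmax <= 0)
    vmean = vmax * rng.uniform(0.3, 1.0, size=n)
    return np.column_stack([vmax, vmean])


# -- releases ----------------------------------------------------------------


def generate_releases(config: GeneratorConfig) -> tuple[pd.DataFrame, ModelParameters]:
    """Simulate the full experiment; returns (releases table, generating truth).

    The table follows the ``releases.csv`` schema (one row per recovered
    fruit) and is fully reproducible from ``config.rng_seed``.
    """
    root = np.random.SeedSequence(config.rng_seed)
    ss_fruit, ss_wind, ss_species, ss_resid = root.spawn(4)
    fruit_seeds = ss_fruit.spawn(len(config.species_profiles))

    truth = config.truth
    rng_species = np.random.default_rng(ss_species)
    intercepts = rng_species.normal(0.0, truth.sigma_species, size=len(config.species_profiles))

    all_fruit: list[FruitMorphology] = []
    species_of: list[int] = []
    for i, (profile, seed) in enumerate(zip(config.species_profiles, fruit_seeds)):
        batch = generate_fruit(profile, np.random.default_rng(seed))
        all_fruit.extend(batch)
        species_of.extend([i] * len(batch))

    n = len(all_fruit)
    winds = generate_winds(
        n,
        wind_mean_max=config.wind_mean_max,
        wind_shape=config.wind_shape,
        wind_max_cap=config.wind_max_cap,
        rng_seed=np.random.default_rng(ss_wind),
    )
    rng_resid = np.random.default_rng(ss_resid)
    resid = rng_resid.normal(0.0, truth.sigma_resid, size=n)

    iwl = np.array([f.iwl for f in all_fruit])
    li = np.log1p(iwl)
    lw = np.log1p(winds[:, 0])
    mu = truth.beta0 + truth.beta1 * li + truth.beta2 * lw + truth.beta3 * li * lw
    log_d = mu + intercepts[np.array(species_of)] + resid
    distance = np.exp(log_d)

    df = pd.DataFrame(
        {
            "fruit_id": [f.fruit_id for f in all_fruit],
            "species": [f.species for f in all_fruit],
            "genus": [f.genus_rule for f in all_fruit],
            "mass_g": [f.mass for f in all_fruit],
            "wing_area_cm2": [f.wing_area for f in all_fruit],
            "iwl_cm2_per_g": iwl,
            "max_wind_ms": winds[:, 0],
            "mean_wind_ms": winds[:, 1],
            "distance_m": distance,
        },
        columns=RELEASE_COLUMNS,
    )
    return df, truth


def releases_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Convenience: the dataset only."""
    return generate_releases(config)[0]


def write_releases(config: GeneratorConfig, out_dir) -> tuple[Path, Path]:
    """Write ``releases.csv`` and ``truth.json`` to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df, truth = generate_releases(config)
    csv_path = out / "releases.csv"
    df.to_csv(csv_path, index=False)
    truth_path = out / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return csv_path, truth_path
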