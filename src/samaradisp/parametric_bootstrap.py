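"""Parametric bootstrap for the dispersal mixed model.

Each replicate simulates a fresh response from the fitted model — new
species intercepts from N(0, sigma_species^2), new residuals from
N(0, sigma_resid^2), the fixed-effect surface kept at its estimate — and
refits the model.  The resulting table of refitted parameter vectors feeds
percentile confidence intervals, approximate p-values (two-sided tail
counts with a 1/B floor, after Gelman & Hill's recipe for simulation-based
inference) and, downstream, pointwise confidence bands on dispersal kernels.

Per-replicate seeds are spawned deterministically from one base seed, so a
``BootstrapDraws`` is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dispersal_lmm import FitError, FittedLMM, ModelParameters, PARAMETER_NAMES, fit_lmm

__all__ = [
    "BootstrapDraws",
    "IntervalEstimate",
    "BootstrapError",
    "simulate_response",
    "bootstrap",
    "percentile_interval",
    "approx_p_value",
]


class BootstrapError(RuntimeError):
    """Raised when the bootstrap cannot produce usable draws."""


@dataclass
class BootstrapDraws:
    """Refitted parameter vectors from B parametric-bootstrap replicates."""

    B: int
    draws: np.ndarray  # (B - refit_failures) x 6, columns in PARAMETER_NAMES order
    refit_failures: int
    base_seed: int

    def column(self, parameter: str) -> np.ndarray:
        try:
            j = PARAMETER_NAMES.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}") from None
        return self.draws[:, j]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]


@dataclass(frozen=True)
class IntervalEstimate:
    """Percentile interval and approximate p-value for one parameter."""

    parameter: str
    point: float
    lower: float
    upper: float
    level: float
    approx_p: float
    degenerate: bool = False  # all draws identical: zero-width interval


def simulate_response(
    fit: FittedLMM,
    X: np.ndarray,
    groups: np.ndarray,
    rng_seed,
) -> np.ndarray:
    """One simulated response vector X b + Z a* + e* from the fitted model."""
    rng = np.random.default_rng(rng_seed)
    p = fit.params
    groups = np.asarray(groups)
    n_groups = int(groups.max()) + 1
    a = rng.normal(0.0, p.sigma_species, size=n_groups)
    e = rng.normal(0.0, p.sigma_resid, size=groups.size)
    return np.asarray(X, float) @ p.betas + a[groups] + e


def bootstrap(
    fit: FittedLMM,
    X: np.ndarray,
    groups: np.ndarray,
    B: int = 1000,
    base_seed: int = 0,
    method: str = "REML",
) -> BootstrapDraws:
    """B simulate-then-refit cycles; failed refits are dropped and counted."""
    if B < 1:
        raise BootstrapError("B must be >= 1")
    seeds = np.random.SeedSequence(base_seed).spawn(B)
    rows, failures = [], 0
    for seed in seeds:
        y_star = simulate_response(fit, X, groups, np.random.default_rng(seed))
        try:
            refit = fit_lmm(y_star, X, groups, method=method)
        except (FitError, np.linalg.LinAlgError):
            failures += 1
            continue
        if not refit.converged:
            failures += 1
            continue
        q = refit.params
        rows.append([q.beta0, q.beta1, q.beta2, q.beta3, q.sigma_species, q.sigma_resid])
    if not rows:
        raise BootstrapError("all bootstrap replicates failed to refit")
    return BootstrapDraws(
        B=B,
        draws=np.asarray(rows, dtype=float),
        refit_failures=failures,
        base_seed=int(base_seed),
    )


def percentile_interval(
    draws: BootstrapDraws,
    parameter: str,
    level: float = 0.95,
    point: float | None = None,
) -> IntervalEstimate:
    """Equal-tailed percentile interval (type-7 quantile interpolation)."""
    if not 0.0 < level < 1.0:
        raise BootstrapError(f"level must be in (0, 1), got {level}")
    col = draws.column(parameter)
    if col.size < 2:
        raise BootstrapError("need >= 2 retained draws for an interval")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(col, [alpha, 1.0 - alpha])  # linear = type 7
    degenerate = math.isclose(lower, upper, rel_tol=0.0, abs_tol=0.0) or lower == upper
    return IntervalEstimate(
        parameter=parameter,
        point=float(np.median(col) if point is None else point),
        lower=float(lower),
        upper=float(upper),
        level=level,
        approx_p=approx_p_value(draws, parameter),
        degenerate=bool(degenerate),
    )


def approx_p_value(draws: BootstrapDraws, parameter: str) -> float:
    """Two-sided tail-count p-value with floor 1/B_retained, capped at 1.

    p = max(2 * min(#{draws <= 0}, #{draws >= 0}) / B_retained, 1/B_retained)
    """
    col = draws.column(parameter)
    if col.size < 1:
        raise BootstrapError("need >= 1 retained draw")
    b = col.size
    n_le = int(np.sum(col <= 0.0))
    n_ge = int(np.sum(col >= 0.0))
    p = 2.0 * min(n_le, n_ge) / b
    return float(min(max(p, 1.0 / b), 1.0))
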