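"""Random-intercept linear mixed model of log dispersal distance.

The model for fruit *j* of species *i* released at wind speed U is

    ln d_ij = b0 + b1 ln(IWL_ij + 1) + b2 ln(U_ij + 1)
              + b3 ln(IWL_ij + 1) ln(U_ij + 1) + a_i + e_ij

with a_i ~ N(0, sigma_species^2) a per-species random intercept and
e_ij ~ N(0, sigma_resid^2) homoscedastic residual noise.  The +1 offsets
keep the logs finite for wingless fruit (IWL = 0) and calm releases (U = 0);
natural logs are used throughout.

Fitting is by REML (or ML) with the variance structure profiled out: for a
fixed variance ratio lambda = sigma_species^2 / sigma_resid^2 the GLS
estimates of the fixed effects and of sigma_resid^2 are closed form, so the
fit reduces to a one-dimensional bounded search over ln(lambda).  Because the
random effect is a per-group intercept, all lambda-dependent quantities are
O(#groups) once per-group sufficient statistics are cached, which makes
bootstrap refits cheap.

``fit_lmm_direct`` maximizes the same (restricted) likelihood by dense
linear algebra over arbitrarily many random-intercept terms; it is slower
but independent of the profiling shortcut, and is the route used for
multi-term fits (e.g. mother tree nested within species, nested in genus)
whose minor components are screened with ``variance_decomposition``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelParameters",
    "FittedLMM",
    "VarianceDecomposition",
    "DataError",
    "FitError",
    "build_design",
    "design_from_frame",
    "fit_lmm",
    "fit_lmm_direct",
    "variance_decomposition",
    "compare_wind_covariates",
    "predict_median_distance",
    "read_releases_csv",
    "write_fit_json",
    "read_fit_json",
]

_LN2PI = math.log(2.0 * math.pi)

RELEASE_COLUMNS = [
    "fruit_id",
    "species",
    "genus",
    "mass_g",
    "wing_area_cm2",
    "iwl_cm2_per_g",
    "max_wind_ms",
    "mean_wind_ms",
    "distance_m",
]


class DataError(ValueError):
    """Raised for invalid input data (non-positive distances, bad columns)."""


class FitError(RuntimeError):
    """Raised when a model cannot be fitted (rank deficiency, no data)."""


@dataclass(frozen=True)
class ModelParameters:
    """Fixed effects and variance components of the dispersal model."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    sigma_species: float
    sigma_resid: float

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(not math.isfinite(v) for v in vals.values()):
            raise ValueError(f"non-finite model parameters: {vals}")
        if self.sigma_species < 0 or self.sigma_resid < 0:
            raise ValueError("variance parameters must be non-negative")

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        return cls(**{k: float(d[k]) for k in (
            "beta0", "beta1", "beta2", "beta3", "sigma_species", "sigma_resid")})


PARAMETER_NAMES = ("beta0", "beta1", "beta2", "beta3", "sigma_species", "sigma_resid")


@dataclass
class FittedLMM:
    """A fitted random-intercept model with criteria and fixed-effect covariance."""

    params: ModelParameters
    fixed_cov: np.ndarray  # 4x4 covariance of beta-hat from the GLS information
    reml_criterion: float  # restricted log-likelihood at the optimum
    loglik_ml: float  # ML log-likelihood at the (re-optimized) ML estimates
    aic_ml: float  # -2 loglik_ml + 2k, k = 6
    n_obs: int
    n_species: int
    converged: bool
    method: str = "REML"


@dataclass(frozen=True)
class VarianceDecomposition:
    """Proportion of total variance per random term (residual included)."""

    shares: dict[str, float]
    droppable: tuple[str, ...]  # terms whose share falls below the threshold
    threshold: float = 0.001


# -- design ------------------------------------------------------------------


def build_design(
    distance: Sequence[float],
    iwl: Sequence[float],
    wind: Sequence[float],
    species: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Log-transformed response, fixed design and species grouping.

    Returns ``(y, X, groups, levels)`` with y = ln(distance),
    X columns [1, ln(iwl+1), ln(wind+1), ln(iwl+1) * ln(wind+1)], and
    ``groups`` integer codes into ``levels`` (first-appearance order).
    """
    d = np.asarray(distance, dtype=float)
    w = np.asarray(wind, dtype=float)
    a = np.asarray(iwl, dtype=float)
    if d.size == 0:
        raise DataError("empty dataset")
    if not (d.size == w.size == a.size == len(species)):
        raise DataError("distance, iwl, wind and species must have equal length")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise DataError("all distances must be finite and > 0")
    if np.any(a < 0) or np.any(w < 0):
        raise DataError("iwl and wind must be non-negative")
    y = np.log(d)
    li = np.log1p(a)
    lw = np.log1p(w)
    X = np.column_stack([np.ones_like(y), li, lw, li * lw])
    levels: list[str] = []
    index: dict[str, int] = {}
    codes = np.empty(d.size, dtype=np.int64)
    for k, s in enumerate(species):
        s = str(s)
        if s not in index:
            index[s] = len(levels)
            levels.append(s)
        codes[k] = index[s]
    return y, X, codes, levels


def design_from_frame(df: pd.DataFrame, wind_choice: str = "max"):
    """Design matrices from a releases table, selecting the wind covariate."""
    if wind_choice not in ("max", "mean"):
        raise DataError(f"wind_choice must be 'max' or 'mean', got {wind_choice!r}")
    col = "max_wind_ms" if wind_choice == "max" else "mean_wind_ms"
    for c in ("distance_m", "iwl_cm2_per_g", col, "species"):
        if c not in df.columns:
            raise DataError(f"releases table missing column {c!r}")
    return build_design(
        df["distance_m"].to_numpy(),
        df["iwl_cm2_per_g"].to_numpy(),
        df[col].to_numpy(),
        df["species"].tolist(),
    )


# -- profiled REML/ML fit ----------------------------------------------------


class _Profile:
    """Cached per-group sufficient statistics; criterion evaluations are O(G).

    With V(lambda) = I + lambda * Z Z' block diagonal over groups,
    (I + lambda J)^-1 = I - lambda/(1 + lambda n_i) J per group, so every
    lambda-dependent inner product is a lambda-weighted correction of the
    ordinary cross-products by per-group sums.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        order = np.argsort(groups, kind="stable")
        Xs, ys, gs = X[order], y[order], groups[order]
        starts = np.flatnonzero(np.r_[True, np.diff(gs) != 0])
        self.n_i = np.diff(np.r_[starts, gs.size]).astype(float)
        self.G = starts.size
        self.Sx = np.add.reduceat(Xs, starts, axis=0)  # G x p group sums
        self.Sy = np.add.reduceat(ys, starts)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def gls(self, lam: float):
        """GLS pieces at variance ratio lam: (XtVinvX, XtVinvy, ytVinvy, log|V|)."""
        w = lam / (1.0 + lam * self.n_i)
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (w * self.Sy)
        q = self.yty - float(w @ (self.Sy**2))
        logdetV = float(np.sum(np.log1p(lam * self.n_i)))
        return A, b, q, logdetV

    def criterion(self, lam: float, method: str) -> float:
        """Profiled restricted (REML) or full (ML) log-likelihood at lam."""
        A, b, q, logdetV = self.gls(lam)
        beta = np.linalg.solve(A, b)
        rss = max(q - float(beta @ b), 1e-300)  # r' V^-1 r at GLS beta
        n, p = self.n, self.p
        if method == "REML":
            dof = n - p
            sigma2 = rss / dof
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                raise FitError("fixed-effect design is rank deficient")
            return -0.5 * (dof * (_LN2PI + math.log(sigma2) + 1.0) + logdetV + logdetA)
        sigma2 = rss / n
        return -0.5 * (n * (_LN2PI + math.log(sigma2) + 1.0) + logdetV)

    def solution(self, lam: float, method: str):
        A, b, q, _ = self.gls(lam)
        beta = np.linalg.solve(A, b)
        rss = max(q - float(beta @ b), 0.0)
        dof = self.n - self.p if method == "REML" else self.n
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(A)
        return beta, sigma2, cov


_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    method: str = "REML",
) -> FittedLMM:
    """Fit the Gaussian random-intercept model by profiled REML or ML.

    A bounded Brent search over ln(lambda), lambda the ratio of species to
    residual variance, locates the optimum; the lambda = 0 boundary (no
    species variance) is checked explicitly and wins ties.
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise FitError(f"method must be REML or ML, got {method!r}")
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    if y.size < 2:
        raise FitError("need at least 2 observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("fixed-effect design is rank deficient")

    prof = _Profile(y, X, groups)

    if prof.G == 1:
        # a single group: the random intercept is confounded with the fixed
        # intercept, so the variance ratio is pinned at the identifiable 0
        lam = 0.0
        crit = prof.criterion(0.0, method)
        beta, sigma2, cov = prof.solution(0.0, method)
        params = ModelParameters(
            beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
            beta3=float(beta[3]), sigma_species=0.0, sigma_resid=math.sqrt(sigma2),
        )
        reml = prof.criterion(0.0, "REML")
        loglik_ml = prof.criterion(0.0, "ML")
        k = X.shape[1] + 2
        return FittedLMM(
            params=params, fixed_cov=cov, reml_criterion=reml, loglik_ml=loglik_ml,
            aic_ml=-2.0 * loglik_ml + 2.0 * k, n_obs=int(y.size), n_species=1,
            converged=True, method=method,
        )

    def neg(loglam: float) -> float:
        return -prof.criterion(math.exp(loglam), method)

    res = optimize.minimize_scalar(
        neg, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": 1e-10},
    )
    lam = math.exp(float(res.x))
    crit = -float(res.fun)
    crit0 = prof.criterion(0.0, method)
    if crit0 >= crit - 1e-12:  # boundary: no species variance
        lam, crit = 0.0, crit0
    converged = bool(res.success) or lam == 0.0

    beta, sigma2, cov = prof.solution(lam, method)
    params = ModelParameters(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        beta3=float(beta[3]),
        sigma_species=math.sqrt(lam * sigma2),
        sigma_resid=math.sqrt(sigma2),
    )

    if method == "ML":
        loglik_ml = crit
        reml = prof.criterion(lam, "REML")
    else:
        reml = crit
        res_ml = optimize.minimize_scalar(
            lambda ll: -prof.criterion(math.exp(ll), "ML"),
            bounds=_LOG_LAMBDA_BOUNDS, method="bounded", options={"xatol": 1e-10},
        )
        loglik_ml = max(-float(res_ml.fun), prof.criterion(0.0, "ML"))

    k = X.shape[1] + 2  # fixed effects + two variance parameters
    return FittedLMM(
        params=params,
        fixed_cov=cov,
        reml_criterion=reml,
        loglik_ml=loglik_ml,
        aic_ml=-2.0 * loglik_ml + 2.0 * k,
        n_obs=int(y.size),
        n_species=int(prof.G),
        converged=converged,
        method=method,
    )


# -- dense-likelihood fit for arbitrary random-intercept terms ---------------


def _dense_loglik(
    y: np.ndarray,
    X: np.ndarray,
    Zs: Sequence[np.ndarray],
    variances: Sequence[float],
    sigma2_resid: float,
    method: str,
) -> float:
    """Gaussian (restricted) log-likelihood with dense covariance.

    Sigma = sigma2_resid I + sum_k variances[k] Z_k Z_k'; beta is profiled
    at its GLS value.  REML uses the Harville form with the
    log|X' Sigma^-1 X| correction.
    """
    n, p = X.shape
    Sigma = sigma2_resid * np.eye(n)
    for Z, v in zip(Zs, variances):
        Sigma += v * (Z @ Z.T)
    L = np.linalg.cholesky(Sigma)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Li_y = np.linalg.solve(L, y)
    Li_X = np.linalg.solve(L, X)
    A = Li_X.T @ Li_X
    beta = np.linalg.solve(A, Li_X.T @ Li_y)
    r = Li_y - Li_X @ beta
    quad = float(r @ r)
    if method == "REML":
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise FitError("rank-deficient design in dense likelihood")
        return -0.5 * ((n - p) * _LN2PI + logdet + logdetA + quad)
    return -0.5 * (n * _LN2PI + logdet + quad)


def fit_lmm_direct(
    y: np.ndarray,
    X: np.ndarray,
    groupings: Mapping[str, np.ndarray],
    method: str = "REML",
    n_starts: int = 4,
) -> dict:
    """Direct numerical maximization over all variance components.

    Supports any number of random-intercept terms (``groupings`` maps a term
    name to integer group codes).  Intended for small n: builds the dense
    covariance each evaluation.  Returns a dict with ``betas``, per-term
    ``sigmas`` (SDs), ``sigma_resid``, ``criterion`` and ``method``.
    """
    method = method.upper()
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    names = list(groupings)
    Zs = []
    for name in names:
        codes = np.asarray(groupings[name])
        Z = np.zeros((y.size, int(codes.max()) + 1))
        Z[np.arange(y.size), codes] = 1.0
        Zs.append(Z)

    resid0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s2_ols = float(resid0 @ resid0) / max(y.size - X.shape[1], 1)

    def neg(theta: np.ndarray) -> float:
        vs = np.exp(theta[:-1])
        s2 = math.exp(theta[-1])
        try:
            return -_dense_loglik(y, X, Zs, vs, s2, method)
        except np.linalg.LinAlgError:
            return 1e12

    best = None
    # multistart over the ratio of group to residual variance
    for frac in np.linspace(0.02, 0.8, n_starts):
        x0 = np.r_[
            np.full(len(names), math.log(max(frac * s2_ols, 1e-10))),
            math.log(max((1 - frac) * s2_ols, 1e-10)),
        ]
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    vs = np.exp(best.x[:-1])
    s2 = math.exp(best.x[-1])
    # variances pinned to ~0 by the optimizer are boundary solutions
    vs = np.where(vs < 1e-12, 0.0, vs)
    return {
        "betas": _gls_betas(y, X, Zs, vs, s2),
        "sigmas": {name: float(math.sqrt(v)) for name, v in zip(names, vs)},
        "sigma_resid": float(math.sqrt(s2)),
        "criterion": -float(best.fun),
        "method": method,
        "converged": bool(best.success),
    }


def _whiten(y, X, Zs, vs, s2):
    n = y.size
    Sigma = s2 * np.eye(n)
    for Z, v in zip(Zs, vs):
        Sigma += v * (Z @ Z.T)
    L = np.linalg.cholesky(Sigma)
    return np.linalg.solve(L, y), np.linalg.solve(L, X)


def _gls_betas(y, X, Zs, vs, s2) -> np.ndarray:
    Li_y, Li_X = _whiten(y, X, Zs, vs, s2)
    beta, _, _, _ = np.linalg.lstsq(Li_X, Li_y, rcond=None)
    return beta


# -- variance decomposition and model comparison -----------------------------


def variance_decomposition(
    components: Mapping[str, float] | FittedLMM,
    threshold: float = 0.001,
) -> VarianceDecomposition:
    """Share of total variance per random term, flagging negligible terms.

    ``components`` maps term name to SD (a ``FittedLMM`` contributes its
    species and residual SDs).  A term whose share of the summed variances
    falls below ``threshold`` (default 0.1%) is flagged droppable, mirroring
    the screening rule used to simplify nested random-effect structures.
    """
    if isinstance(components, FittedLMM):
        components = {
            "species": components.params.sigma_species,
            "residual": components.params.sigma_resid,
        }
    sds = {k: float(v) for k, v in components.items()}
    if any(v < 0 for v in sds.values()):
        raise ValueError("SDs must be non-negative")
    total = sum(v * v for v in sds.values())
    if total <= 0:
        raise ValueError("total variance is zero")
    shares = {k: v * v / total for k, v in sds.items()}
    droppable = tuple(
        k for k, s in shares.items() if k != "residual" and s < threshold
    )
    return VarianceDecomposition(shares=shares, droppable=droppable, threshold=threshold)


def compare_wind_covariates(df: pd.DataFrame) -> tuple[float, float, str]:
    """AICs of the max-wind vs mean-wind model (both by ML) and the winner.

    ML rather than REML because the two models differ in their fixed-effect
    design, for which REML criteria are not comparable.
    """
    fits = {}
    for choice in ("max", "mean"):
        y, X, g, _ = design_from_frame(df, wind_choice=choice)
        fits[choice] = fit_lmm(y, X, g, method="ML")
    aic_max, aic_mean = fits["max"].aic_ml, fits["mean"].aic_ml
    return aic_max, aic_mean, ("max" if aic_max <= aic_mean else "mean")


def predict_median_distance(params: ModelParameters, iwl: float, wind: float) -> float:
    """Median dispersal distance (m): exp of the linear predictor.

    This is the conditional median for a species at random-effect 0 and,
    because the random effect is symmetric on the log scale, also the median
    of the marginal log-normal mixture.
    """
    iwl = np.asarray(iwl, dtype=float)
    wind = np.asarray(wind, dtype=float)
    if np.any(iwl < 0) or np.any(wind < 0):
        raise DataError("iwl and wind must be non-negative")
    li, lw = np.log1p(iwl), np.log1p(wind)
    mu = params.beta0 + params.beta1 * li + params.beta2 * lw + params.beta3 * li * lw
    out = np.exp(mu)
    return float(out) if out.ndim == 0 else out


# -- i/o ---------------------------------------------------------------------


def read_releases_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RELEASE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"releases csv missing columns: {missing}")
    return df


def write_fit_json(fit: FittedLMM, path) -> None:
    payload = {
        "params": fit.params.to_dict(),
        "fixed_cov": np.asarray(fit.fixed_cov).tolist(),
        "reml_criterion": fit.reml_criterion,
        "loglik_ml": fit.loglik_ml,
        "aic_ml": fit.aic_ml,
        "n_obs": fit.n_obs,
        "n_species": fit.n_species,
        "converged": fit.converged,
        "method": fit.method,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_fit_json(path) -> FittedLMM:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return FittedLMM(
        params=ModelParameters.from_dict(d["params"]),
        fixed_cov=np.asarray(d["fixed_cov"], dtype=float),
        reml_criterion=float(d["reml_criterion"]),
        loglik_ml=float(d["loglik_ml"]),
        aic_ml=float(d["aic_ml"]),
        n_obs=int(d["n_obs"]),
        n_species=int(d["n_species"]),
        converged=bool(d["converged"]),
        method=d.get("method", "REML"),
    )
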