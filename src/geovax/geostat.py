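"""Bayesian continuation-ratio geostatistical model.

Each stage (first dose; third dose given first) is a binomial-logit model

    k_i ~ Binomial(n_i, sigmoid(eta_i))
    eta_i = beta0 + sum_j alpha_j * logit(stacker_ji) + gamma_group(i)
            + u(pixel_i, year_i) + eps_i

with stacked-generalization predictors entering through simplex-constrained
weights alpha, a group (level-1 admin) random effect gamma, an
observation-level nugget eps, and a separable space-time Gaussian process u
whose covariance is the Kronecker product of an AR1 kernel in time and an
isotropic Matern kernel in space.

Inference is an INLA-style nested Laplace scheme written for this package:
for fixed hyperparameters the latent field at the observations is Gaussian
(all Gaussian terms collapse into one covariance), so the binomial
likelihood admits a standard Gaussian (Laplace) approximation with an
analytic approximate marginal likelihood; hyperparameters get a Laplace
approximation on transformed scales, sampled hyperparameter points form a
Monte-Carlo mixture, and structured parameters (beta0, gamma, u) are
recovered draw-by-draw through exact linear-Gaussian conditioning.
Prediction uses Matheron's rule for conditional GP draws on the full grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import cdist
from scipy.special import expit, logit as sp_logit

from .geo_io import DataError, PixelGrid

logger = logging.getLogger("geovax")

__all__ = [
    "GpSpec",
    "GeoModel",
    "PosteriorFit",
    "PosteriorDrawCube",
    "SizeError",
    "ar1_correlation",
    "matern_covariance",
    "st_covariance",
    "build_model",
    "fit_posterior",
    "predict_surface",
    "combine_stages",
]

_PROB_CLIP = 1e-4  # probabilities clipped into [clip, 1-clip] before logit


class SizeError(ValueError):
    """Joint covariance dimension too large for dense Kronecker algebra."""


# ---------------------------------------------------------------------------
# covariance kernels


def ar1_correlation(rho: float, years: list[int] | np.ndarray) -> np.ndarray:
    """AR1 correlation matrix: entry (t, t') = rho^|year_t - year_t'|."""
    if not -1 < rho < 1:
        raise DataError(f"AR1 coefficient must satisfy |rho| < 1, got {rho}")
    years = np.asarray(years, dtype=float)
    lag = np.abs(years[:, None] - years[None, :])
    return rho**lag


def matern_covariance(
    coords: np.ndarray,
    spatial_range: float,
    variance: float,
    nu: float = 1.5,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Isotropic stationary Matern covariance over point coordinates.

    Supported smoothness nu in {1/2, 3/2, 5/2}, with the usual closed forms
    (nu = 3/2: variance * (1 + sqrt(3) d / range) * exp(-sqrt(3) d / range)).
    ``distances`` may be supplied to reuse a precomputed distance matrix.
    """
    if not spatial_range > 0:
        raise DataError("spatial_range must be > 0")
    if variance < 0:
        raise DataError("variance must be >= 0")
    if distances is None:
        coords = np.asarray(coords, dtype=float)
        distances = cdist(coords, coords)
    d = distances / spatial_range
    if nu == 0.5:
        k = np.exp(-d)
    elif nu == 1.5:
        s = np.sqrt(3.0) * d
        k = (1.0 + s) * np.exp(-s)
    elif nu == 2.5:
        s = np.sqrt(5.0) * d
        k = (1.0 + s + s**2 / 3.0) * np.exp(-s)
    else:
        raise DataError(f"unsupported Matern smoothness nu={nu}")
    return variance * k


def st_covariance(spatial: np.ndarray, temporal: np.ndarray) -> np.ndarray:
    """Separable space-time covariance: Kronecker product, time-major layout.

    Joint index (t, s) maps to t * n_pixels + s.  Guards against joint
    dimensions beyond dense-linear-algebra reach.
    """
    spatial = np.asarray(spatial)
    temporal = np.asarray(temporal)
    joint = spatial.shape[0] * temporal.shape[0]
    if joint > 20_000:
        raise SizeError(
            f"joint space-time dimension {joint} > 20000; use a coarser grid"
        )
    for name, m in (("spatial", spatial), ("temporal", temporal)):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DataError(f"{name} covariance must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise DataError(f"{name} covariance must be symmetric")
    return np.kron(temporal, spatial)


# ---------------------------------------------------------------------------
# model specification and container types


@dataclass
class GpSpec:
    """Hyperparameters, priors and constraints for one model stage.

    The supplied values double as prior centers and optimizer starting
    points.  ``fixed`` freezes any of {"spatial_range", "spatial_variance",
    "rho", "nugget_variance", "group_effect_variance", "weights"} at the
    supplied value; a variance fixed at zero removes that term entirely.
    """

    spatial_range: float
    spatial_variance: float = 1.0
    nu: float = 1.5
    rho: float = 0.7
    nugget_variance: float = 0.1
    group_effect_variance: float = 0.1
    beta0_prior_sd: float = 3.0
    sd_prior_scale: float = 1.0           # half-Normal scale for all sds
    rho_bounds: tuple[float, float] = (-0.99, 0.99)
    range_prior_log_sd: float = 0.75      # log-Normal sd around log(spatial_range)
    weight_logit_prior_sd: float = 1.5
    constrain_weights_simplex: bool = True
    fixed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.spatial_variance < 0 or self.nugget_variance < 0:
            raise DataError("variances must be >= 0")
        if self.group_effect_variance < 0:
            raise DataError("group_effect_variance must be >= 0")
        if not -1 < self.rho < 1:
            raise DataError("|rho| must be < 1")
        if self.nu not in (0.5, 1.5, 2.5):
            raise DataError("nu must be one of 1/2, 3/2, 5/2")


@dataclass
class PosteriorDrawCube:
    """Posterior draws of a coverage surface: (n_draws, n_years, n_pixels)."""

    grid: PixelGrid
    years: list[int]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (
            len(self.years),
            self.grid.n_pixels,
        ):
            raise DataError(
                f"cube shape {self.values.shape} inconsistent with "
                f"{len(self.years)} years x {self.grid.n_pixels} pixels"
            )
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise DataError("cube values must lie in [0, 1]")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def posterior_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class GeoModel:
    """One stage's assembled model: data, design structure, precomputations."""

    spec: GpSpec
    grid: PixelGrid
    years: list[int]
    trials: np.ndarray          # (n,)
    successes: np.ndarray       # (n,)
    stacker_logits: np.ndarray  # (n, J)
    group_code: np.ndarray      # (n,) int codes into groups
    groups: list                # group ids in code order
    obs_sup: np.ndarray         # (n,) index into support sites
    sup_pixel: np.ndarray       # (S,) pixel index of each support site
    sup_year_idx: np.ndarray    # (S,) year index of each support site
    pixel_group: np.ndarray     # (n_pixels,) group code per pixel (for prediction)
    d_sup: np.ndarray = field(repr=False, default=None)    # (S, S) distances km
    lag_sup: np.ndarray = field(repr=False, default=None)  # (S, S) |year lags|

    @property
    def n_obs(self) -> int:
        return len(self.trials)

    @property
    def n_children(self) -> int:
        return self.stacker_logits.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_support(self) -> int:
        return len(self.sup_pixel)

    # -- structural pieces ---------------------------------------------------

    def latent_dim(self) -> int:
        """beta0 + group effects + GP at support (terms with zero variance drop)."""
        n = 1
        if self.spec.group_effect_variance > 0:
            n += self.n_groups
        if self.spec.spatial_variance > 0:
            n += self.n_support
        return n

    def k_support(self, spatial_range: float, spatial_variance: float, rho: float) -> np.ndarray:
        """GP covariance among support sites (AR1 x Matern evaluated pairwise)."""
        m = matern_covariance(
            None, spatial_range, spatial_variance, nu=self.spec.nu, distances=self.d_sup
        )
        return m * (rho**self.lag_sup)

    def prior_mean(self, alpha: np.ndarray) -> np.ndarray:
        return self.stacker_logits @ alpha

    def marginal_cov(
        self,
        spatial_range: float,
        spatial_variance: float,
        rho: float,
        nugget_variance: float,
        group_variance: float,
    ) -> np.ndarray:
        """Prior covariance of eta at the observations (all Gaussian terms)."""
        n = self.n_obs
        c = np.full((n, n), self.spec.beta0_prior_sd**2)
        if group_variance > 0:
            same = self.group_code[:, None] == self.group_code[None, :]
            c = c + group_variance * same
        if spatial_variance > 0:
            k_sup = self.k_support(spatial_range, spatial_variance, rho)
            c = c + k_sup[np.ix_(self.obs_sup, self.obs_sup)]
        c[np.diag_indices_from(c)] += max(nugget_variance, 0.0) + 1e-8
        return c

    def eta_at_obs(
        self,
        beta0: float,
        alpha: np.ndarray,
        gamma: np.ndarray | None = None,
        u_support: np.ndarray | None = None,
        eps: np.ndarray | None = None,
    ) -> np.ndarray:
        """Linear predictor at the observations for explicit parameter values."""
        eta = beta0 + self.prior_mean(np.asarray(alpha, dtype=float))
        if gamma is not None:
            eta = eta + np.asarray(gamma)[self.group_code]
        if u_support is not None:
            eta = eta + np.asarray(u_support)[self.obs_sup]
        if eps is not None:
            eta = eta + np.asarray(eps)
        return eta

    def log_density(
        self,
        beta0: float,
        alpha: np.ndarray,
        gamma: np.ndarray | None = None,
        u_support: np.ndarray | None = None,
        eps: np.ndarray | None = None,
        hyper: dict | None = None,
    ) -> float:
        """Joint log density (likelihood + latent Gaussian priors + beta0 prior)
        at an explicit parameter point.  Hyperparameter priors and the weight
        prior are excluded: this is the fixed-hyperparameter joint density
        used by the Laplace step, exposed for independent verification.
        """
        from scipy.stats import binom, multivariate_normal, norm

        h = dict(
            spatial_range=self.spec.spatial_range,
            spatial_variance=self.spec.spatial_variance,
            rho=self.spec.rho,
            nugget_variance=self.spec.nugget_variance,
            group_effect_variance=self.spec.group_effect_variance,
        )
        h.update(hyper or {})
        eta = self.eta_at_obs(beta0, alpha, gamma, u_support, eps)
        p = expit(eta)
        ld = float(binom.logpmf(self.successes, self.trials, p).sum())
        ld += float(norm.logpdf(beta0, 0.0, self.spec.beta0_prior_sd))
        if gamma is not None:
            ld += float(
                norm.logpdf(gamma, 0.0, np.sqrt(h["group_effect_variance"])).sum()
            )
        if u_support is not None:
            k = self.k_support(h["spatial_range"], h["spatial_variance"], h["rho"])
            k[np.diag_indices_from(k)] += 1e-10
            ld += float(
                multivariate_normal.logpdf(u_support, mean=np.zeros(len(k)), cov=k)
            )
        if eps is not None:
            ld += float(norm.logpdf(eps, 0.0, np.sqrt(h["nugget_variance"])).sum())
        return ld


@dataclass
class PosteriorFit:
    """Joint posterior draws for one stage, plus sampler diagnostics."""

    model: GeoModel
    beta0: np.ndarray          # (D,)
    alpha: np.ndarray          # (D, J)
    gamma: np.ndarray          # (D, G) zeros when the term is off
    u_support: np.ndarray      # (D, S) zeros when the GP is off
    eta_obs: np.ndarray        # (D, n) latent field draws at the observations
    hyper: pd.DataFrame        # per-draw hyperparameter values
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return len(self.beta0)


# ---------------------------------------------------------------------------
# model assembly


def clipped_logit(p: np.ndarray) -> np.ndarray:
    return sp_logit(np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP))


def build_model(
    spec: GpSpec,
    obs: pd.DataFrame,
    stackers: pd.DataFrame,
    grid: PixelGrid,
    years: list[int],
    pixel_group: np.ndarray | None = None,
) -> GeoModel:
    """Assemble one stage's model from aligned observation and stacker tables.

    ``obs`` needs columns observation_id, pixel_id, year, trials, successes,
    group_id; ``stackers`` needs observation_id plus one probability column
    per child model.  Rows are aligned on observation_id; misalignment is an
    error.  ``pixel_group`` assigns each pixel to a group for prediction
    (defaults to a single shared group).
    """
    required = {"observation_id", "pixel_id", "year", "trials", "successes", "group_id"}
    if not required <= set(obs.columns):
        raise DataError(f"observation table needs columns {sorted(required)}")
    if "observation_id" not in stackers.columns:
        raise DataError("stacker table needs an observation_id column")
    if len(obs) != len(stackers) or not np.array_equal(
        np.sort(obs["observation_id"].to_numpy()),
        np.sort(stackers["observation_id"].to_numpy()),
    ):
        raise DataError("observation and stacker tables are misaligned")
    merged = obs.merge(stackers, on="observation_id", validate="one_to_one")
    if (merged["trials"] <= 0).any():
        raise DataError("all observations must have trials > 0")
    if ((merged["successes"] < 0) | (merged["successes"] > merged["trials"])).any():
        raise DataError("successes must lie in [0, trials]")

    child_cols = [c for c in stackers.columns if c != "observation_id"]
    stacker_logits = clipped_logit(merged[child_cols].to_numpy(dtype=float))

    groups = sorted(pd.unique(merged["group_id"]))
    gcode = merged["group_id"].map({g: i for i, g in enumerate(groups)}).to_numpy()

    year_index = {int(y): t for t, y in enumerate(years)}
    try:
        t_idx = merged["year"].map(lambda y: year_index[int(y)]).to_numpy()
    except KeyError as exc:
        raise DataError(f"observation year {exc} outside model years {years}") from exc
    pix = merged["pixel_id"].to_numpy(dtype=int)
    if (pix < 0).any() or (pix >= grid.n_pixels).any():
        raise DataError("pixel_id out of range")

    site = t_idx * grid.n_pixels + pix
    sup_sites, obs_sup = np.unique(site, return_inverse=True)
    sup_year_idx = sup_sites // grid.n_pixels
    sup_pixel = sup_sites % grid.n_pixels

    centers = grid.cell_centers()
    sup_xy = centers[sup_pixel]
    d_sup = cdist(sup_xy, sup_xy)
    yrs = np.asarray(years, dtype=float)
    lag_sup = np.abs(yrs[sup_year_idx][:, None] - yrs[sup_year_idx][None, :])

    if pixel_group is None:
        pg = np.zeros(grid.n_pixels, dtype=int)
    else:
        pg_raw = np.asarray(pixel_group)
        mapping = {g: i for i, g in enumerate(groups)}
        pg = np.array([mapping.get(g, 0) for g in pg_raw], dtype=int)

    return GeoModel(
        spec=spec,
        grid=grid,
        years=list(years),
        trials=merged["trials"].to_numpy(dtype=float),
        successes=merged["successes"].to_numpy(dtype=float),
        stacker_logits=stacker_logits,
        group_code=gcode,
        groups=groups,
        obs_sup=obs_sup,
        sup_pixel=sup_pixel,
        sup_year_idx=sup_year_idx,
        pixel_group=pg,
        d_sup=d_sup,
        lag_sup=lag_sup,
    )


# ---------------------------------------------------------------------------
# hyperparameter transform


class _Theta:
    """Transformed hyperparameter vector with priors and Jacobians.

    Components (only those not fixed): log spatial_range, log spatial_sd,
    atanh rho, log nugget_sd, log group_sd, and J-1 free weight logits
    (softmax with the last weight pinned at 0) or J unconstrained weights.
    """

    def __init__(self, model: GeoModel):
        spec = model.spec
        self.spec = spec
        self.model = model
        self.names: list[str] = []
        self.x0: list[float] = []
        gp_on = spec.spatial_variance > 0
        if gp_on and "spatial_range" not in spec.fixed:
            self.names.append("log_range")
            self.x0.append(np.log(spec.spatial_range))
        if gp_on and "spatial_variance" not in spec.fixed:
            self.names.append("log_spatial_sd")
            self.x0.append(0.5 * np.log(spec.spatial_variance))
        if gp_on and "rho" not in spec.fixed:
            self.names.append("atanh_rho")
            self.x0.append(np.arctanh(np.clip(spec.rho, -0.98, 0.98)))
        if spec.nugget_variance > 0 and "nugget_variance" not in spec.fixed:
            self.names.append("log_nugget_sd")
            self.x0.append(0.5 * np.log(spec.nugget_variance))
        if spec.group_effect_variance > 0 and "group_effect_variance" not in spec.fixed:
            self.names.append("log_group_sd")
            self.x0.append(0.5 * np.log(spec.group_effect_variance))
        self.n_weights = 0
        if "weights" not in spec.fixed and model.n_children > 1:
            self.n_weights = (
                model.n_children - 1
                if spec.constrain_weights_simplex
                else model.n_children
            )
            for j in range(self.n_weights):
                self.names.append(f"w{j}")
                self.x0.append(0.0)
        self.x0 = np.array(self.x0)

    @property
    def dim(self) -> int:
        return len(self.names)

    def unpack(self, x: np.ndarray) -> dict:
        spec = self.spec
        vals = dict(zip(self.names, np.atleast_1d(x)))
        out = {
            "spatial_range": float(np.exp(vals["log_range"]))
            if "log_range" in vals
            else spec.spatial_range,
            "spatial_variance": float(np.exp(2 * vals["log_spatial_sd"]))
            if "log_spatial_sd" in vals
            else spec.spatial_variance,
            "rho": float(np.tanh(vals["atanh_rho"]))
            if "atanh_rho" in vals
            else spec.rho,
            "nugget_variance": float(np.exp(2 * vals["log_nugget_sd"]))
            if "log_nugget_sd" in vals
            else spec.nugget_variance,
            "group_effect_variance": float(np.exp(2 * vals["log_group_sd"]))
            if "log_group_sd" in vals
            else spec.group_effect_variance,
        }
        j = self.model.n_children
        if self.n_weights == 0:
            out["alpha"] = np.full(j, 1.0 / j)
        elif spec.constrain_weights_simplex:
            raw = np.append([vals[f"w{k}"] for k in range(self.n_weights)], 0.0)
            e = np.exp(raw - raw.max())
            out["alpha"] = e / e.sum()
        else:
            out["alpha"] = np.array([vals[f"w{k}"] for k in range(self.n_weights)])
        return out

    def log_prior(self, x: np.ndarray) -> float:
        """Prior density in natural parameters plus transform Jacobians."""
        spec = self.spec
        vals = dict(zip(self.names, np.atleast_1d(x)))
        lp = 0.0
        if "log_range" in vals:
            # log-Normal on range == Normal on log_range (Jacobian absorbed)
            lp += -0.5 * ((vals["log_range"] - np.log(spec.spatial_range))
                          / spec.range_prior_log_sd) ** 2
        for key in ("log_spatial_sd", "log_nugget_sd", "log_group_sd"):
            if key in vals:
                sd = np.exp(vals[key])
                # half-Normal(scale) on sd, with d sd / d log sd = sd
                lp += -0.5 * (sd / spec.sd_prior_scale) ** 2 + vals[key]
        if "atanh_rho" in vals:
            rho = np.tanh(vals["atanh_rho"])
            lo, hi = spec.rho_bounds
            if not lo < rho < hi:
                return -np.inf
            lp += np.log1p(-(rho**2))  # uniform prior, atanh Jacobian
        for k in range(self.n_weights):
            lp += -0.5 * (vals[f"w{k}"] / spec.weight_logit_prior_sd) ** 2
        return float(lp)


# ---------------------------------------------------------------------------
# Laplace machinery


def _binom_loglik(y: np.ndarray, n: np.ndarray, eta: np.ndarray) -> float:
    # constant binomial coefficient omitted (cancels in posterior)
    return float(y @ eta - n @ np.logaddexp(0.0, eta))


def _laplace(model: GeoModel, c: np.ndarray, m: np.ndarray, tol: float = 1e-8,
             maxiter: int = 60) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Gaussian approximation of p(eta | y) for fixed hyperparameters.

    Newton iteration in the standard stabilized form for GP models with
    non-Gaussian likelihoods; returns (mode, approximate log marginal
    likelihood, W at mode, converged flag).
    """
    y, n = model.successes, model.trials
    f = m.copy()
    psi_old = -np.inf
    converged = False
    sqrt_w = None
    for _ in range(maxiter):
        p = expit(f)
        w = n * p * (1 - p)
        grad = y - n * p
        sqrt_w = np.sqrt(np.maximum(w, 1e-12))
        b_mat = np.eye(model.n_obs) + sqrt_w[:, None] * c * sqrt_w[None, :]
        ll = np.linalg.cholesky(b_mat)
        b = w * (f - m) + grad
        cb = c @ b
        v = np.linalg.solve(ll, sqrt_w * cb)
        a = b - sqrt_w * np.linalg.solve(ll.T, v)
        f = m + c @ a
        psi = _binom_loglik(y, n, f) - 0.5 * float(a @ (f - m))
        if abs(psi - psi_old) < tol * (1 + abs(psi)):
            converged = True
            break
        psi_old = psi
    p = expit(f)
    w = n * p * (1 - p)
    sqrt_w = np.sqrt(np.maximum(w, 1e-12))
    b_mat = np.eye(model.n_obs) + sqrt_w[:, None] * c * sqrt_w[None, :]
    ll = np.linalg.cholesky(b_mat)
    a = np.linalg.solve(c + np.eye(model.n_obs) * 1e-12, f - m)
    log_marg = (
        _binom_loglik(y, n, f)
        - 0.5 * float((f - m) @ a)
        - float(np.log(np.diag(ll)).sum())
    )
    return f, log_marg, w, converged


def _posterior_cov_eta(c: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(C^-1 + W)^-1 in the stabilized form."""
    sqrt_w = np.sqrt(np.maximum(w, 1e-12))
    b_mat = np.eye(len(w)) + sqrt_w[:, None] * c * sqrt_w[None, :]
    ll = np.linalg.cholesky(b_mat)
    v = np.linalg.solve(ll, sqrt_w[:, None] * c)
    return c - v.T @ v


def _neg_log_post(x: np.ndarray, model: GeoModel, theta: _Theta) -> float:
    lp = theta.log_prior(x)
    if not np.isfinite(lp):
        return 1e12
    h = theta.unpack(x)
    c = model.marginal_cov(
        h["spatial_range"], h["spatial_variance"], h["rho"],
        h["nugget_variance"], h["group_effect_variance"],
    )
    m = model.prior_mean(h["alpha"])
    try:
        _, log_marg, _, _ = _laplace(model, c, m)
    except np.linalg.LinAlgError:
        return 1e12
    return -(log_marg + lp)


def _numerical_hessian(fun, x0: np.ndarray, step: float = 0.08) -> np.ndarray:
    k = len(x0)
    h = np.full(k, step)
    hess = np.zeros((k, k))
    f0 = fun(x0)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = fun(x0 + ei)
        fmm = fun(x0 - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpq = fun(x0 + ei + ej)
            fmq = fun(x0 - ei + ej)
            fpm = fun(x0 + ei - ej)
            fmn = fun(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fpq - fpm - fmq + fmn) / (4 * h[i] * h[j])
    return hess


def fit_posterior(
    model: GeoModel,
    n_draws: int,
    seed: int | np.random.Generator,
    engine_settings: dict | None = None,
) -> PosteriorFit:
    """Approximate posterior draws of (beta0, alpha, gamma, hyperparameters,
    u at the data support) for one stage.

    Hyperparameters are optimized on transformed scales, their posterior
    approximated by a Gaussian at the mode (Laplace), and ``n_theta``
    hyperparameter points sampled from it; each point carries an equal share
    of the ``n_draws`` latent-field draws, so the returned sample is a
    finite mixture over hyperparameter uncertainty.  Deterministic given
    (model, seed, settings).
    """
    if n_draws < 1:
        raise DataError("n_draws must be >= 1")
    settings = {
        "n_theta": 25,
        "max_opt_evals": 300,
        "hess_step": 0.08,
        "newton_tol": 1e-8,
    }
    settings.update(engine_settings or {})
    rng = np.random.default_rng(seed)
    theta = _Theta(model)
    diagnostics: dict = {"theta_names": list(theta.names)}

    if theta.dim > 0:
        res = optimize.minimize(
            _neg_log_post,
            theta.x0,
            args=(model, theta),
            method="Nelder-Mead",
            options={
                "maxfev": settings["max_opt_evals"],
                "xatol": 1e-3,
                "fatol": 1e-3,
                "adaptive": True,
            },
        )
        x_hat = res.x
        diagnostics["opt_evals"] = int(res.nfev)
        diagnostics["opt_converged"] = bool(res.success)
        diagnostics["log_post_at_mode"] = -float(res.fun)
        if not res.success:
            warnings.warn(
                "hyperparameter optimization did not fully converge; "
                "continuing with the best point found",
                RuntimeWarning,
                stacklevel=2,
            )
        hess = _numerical_hessian(
            lambda x: _neg_log_post(x, model, theta), x_hat, settings["hess_step"]
        )
        hess = 0.5 * (hess + hess.T)
        jitter = 1e-6
        while True:
            try:
                evals = np.linalg.eigvalsh(hess + jitter * np.eye(theta.dim))
                if evals.min() > 0:
                    break
            except np.linalg.LinAlgError:
                pass
            jitter *= 10
            if jitter > 1e6:  # pragma: no cover - degenerate surface
                hess = np.eye(theta.dim)
                jitter = 0.0
                break
        cov_theta = np.linalg.inv(hess + jitter * np.eye(theta.dim))
        diagnostics["hess_jitter"] = jitter
        n_theta = min(int(settings["n_theta"]), n_draws)
        chol_t = np.linalg.cholesky(cov_theta)
        theta_points = x_hat + rng.standard_normal((n_theta, theta.dim)) @ chol_t.T
    else:
        theta_points = np.zeros((1, 0))
        n_theta = 1
        diagnostics["opt_converged"] = True

    # allocate draws across hyperparameter points as evenly as possible
    base, extra = divmod(n_draws, n_theta)
    alloc = [base + (1 if i < extra else 0) for i in range(n_theta)]

    n, big_s, big_g, big_j = (
        model.n_obs,
        model.n_support,
        model.n_groups,
        model.n_children,
    )
    gp_on = model.spec.spatial_variance > 0 or "log_spatial_sd" in theta.names
    grp_on = (
        model.spec.group_effect_variance > 0 or "log_group_sd" in theta.names
    )

    beta0_d = np.empty(n_draws)
    alpha_d = np.empty((n_draws, big_j))
    gamma_d = np.zeros((n_draws, big_g))
    u_d = np.zeros((n_draws, big_s))
    eta_d = np.empty((n_draws, n))
    hyper_rows = []
    newton_failures = 0

    pos = 0
    for k in range(n_theta):
        h = theta.unpack(theta_points[k])
        c = model.marginal_cov(
            h["spatial_range"], h["spatial_variance"], h["rho"],
            h["nugget_variance"], h["group_effect_variance"],
        )
        m = model.prior_mean(h["alpha"])
        f_mode, _, w, conv = _laplace(model, c, m, tol=settings["newton_tol"])
        if not conv:
            newton_failures += 1
        cov_eta = _posterior_cov_eta(c, w)
        cov_eta = 0.5 * (cov_eta + cov_eta.T)
        cov_eta[np.diag_indices_from(cov_eta)] += 1e-10
        chol_eta = np.linalg.cholesky(cov_eta)

        # linear-Gaussian recovery of b = (beta0 [, gamma] [, u_support])
        blocks = [np.ones((n, 1))]
        prior_vars = [np.array([[model.spec.beta0_prior_sd**2]])]
        if grp_on:
            z = np.zeros((n, big_g))
            z[np.arange(n), model.group_code] = 1.0
            blocks.append(z)
            prior_vars.append(h["group_effect_variance"] * np.eye(big_g))
        if gp_on:
            s_map = np.zeros((n, big_s))
            s_map[np.arange(n), model.obs_sup] = 1.0
            blocks.append(s_map)
            k_sup = model.k_support(
                h["spatial_range"], h["spatial_variance"], h["rho"]
            )
            k_sup[np.diag_indices_from(k_sup)] += 1e-10
            prior_vars.append(k_sup)
        f_design = np.hstack(blocks)
        sigma_b = _block_diag(prior_vars)
        c_inv_f = np.linalg.solve(c, f_design)       # (n, p)
        gain = sigma_b @ c_inv_f.T                   # (p, n)
        cov_b = sigma_b - gain @ f_design @ sigma_b
        cov_b = 0.5 * (cov_b + cov_b.T)
        cov_b[np.diag_indices_from(cov_b)] += 1e-10
        chol_b = np.linalg.cholesky(cov_b)

        nk = alloc[k]
        z_eta = rng.standard_normal((nk, n))
        etas = f_mode + z_eta @ chol_eta.T
        mean_b = (etas - m) @ gain.T
        z_b = rng.standard_normal((nk, f_design.shape[1]))
        b_draws = mean_b + z_b @ chol_b.T

        sl = slice(pos, pos + nk)
        eta_d[sl] = etas
        beta0_d[sl] = b_draws[:, 0]
        col = 1
        if grp_on:
            gamma_d[sl] = b_draws[:, col:col + big_g]
            col += big_g
        if gp_on:
            u_d[sl] = b_draws[:, col:col + big_s]
        alpha_d[sl] = h["alpha"]
        hyper_rows.extend([
            {
                "spatial_range": h["spatial_range"],
                "spatial_variance": h["spatial_variance"],
                "rho": h["rho"],
                "nugget_variance": h["nugget_variance"],
                "group_effect_variance": h["group_effect_variance"],
                "theta_point": k,
            }
        ] * nk)
        pos += nk

    diagnostics["newton_failures"] = newton_failures
    diagnostics["n_theta"] = n_theta
    if newton_failures:
        warnings.warn(
            f"{newton_failures}/{n_theta} Laplace inner loops hit the iteration "
            "cap; posterior approximation may be degraded",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorFit(
        model=model,
        beta0=beta0_d,
        alpha=alpha_d,
        gamma=gamma_d,
        u_support=u_d,
        eta_obs=eta_d,
        hyper=pd.DataFrame(hyper_rows),
        diagnostics=diagnostics,
    )


def _block_diag(mats: list[np.ndarray]) -> np.ndarray:
    sizes = [m.shape[0] for m in mats]
    out = np.zeros((sum(sizes), sum(sizes)))
    pos = 0
    for m in mats:
        out[pos:pos + m.shape[0], pos:pos + m.shape[0]] = m
        pos += m.shape[0]
    return out


# ---------------------------------------------------------------------------
# prediction


def predict_surface(
    fit: PosteriorFit,
    stacker_surfaces: np.ndarray,
    seed: int | np.random.Generator,
    name: str = "",
) -> PosteriorDrawCube:
    """Posterior draws of the coverage probability over the full grid.

    ``stacker_surfaces`` has shape (n_children, n_years, n_pixels) of child
    probabilities.  Per draw: p = sigmoid(beta0 + sum_j alpha_j *
    logit(stacker_j) + gamma_group(pixel) + u*), where u* is a conditional
    GP draw given that draw's support values (Matheron's rule); the nugget
    is observation-level noise and is excluded from prediction.
    """
    model = fit.model
    grid, years = model.grid, model.years
    n_years, n_pix = len(years), grid.n_pixels
    stacker_surfaces = np.asarray(stacker_surfaces, dtype=float)
    if stacker_surfaces.shape != (model.n_children, n_years, n_pix):
        raise DataError(
            f"stacker surfaces shape {stacker_surfaces.shape} != "
            f"({model.n_children}, {n_years}, {n_pix})"
        )
    if n_years * n_pix > 20_000:
        raise SizeError("prediction grid too large for dense GP conditioning")
    rng = np.random.default_rng(seed)
    logit_surf = clipped_logit(stacker_surfaces).reshape(model.n_children, -1)

    gp_on = bool((fit.hyper["spatial_variance"] > 0).any()) and model.n_support > 0
    centers = grid.cell_centers()
    if gp_on:
        d_pix = cdist(centers, centers)
        d_fs = cdist(centers, centers[model.sup_pixel])
        yrs = np.asarray(years, dtype=float)
        lag_ts = np.abs(yrs[:, None] - yrs[model.sup_year_idx][None, :])

    n_draws = fit.n_draws
    out = np.empty((n_draws, n_years, n_pix))
    theta_groups = fit.hyper.groupby("theta_point", sort=True).indices \
        if "theta_point" in fit.hyper.columns else {0: np.arange(n_draws)}

    for _, idx in theta_groups.items():
        idx = np.asarray(idx)
        h = fit.hyper.iloc[idx[0]]
        u_star = np.zeros((len(idx), n_years * n_pix))
        if gp_on and h["spatial_variance"] > 0:
            m_pix = matern_covariance(
                None, h["spatial_range"], 1.0, nu=model.spec.nu, distances=d_pix
            )
            m_pix[np.diag_indices_from(m_pix)] += 1e-8
            l_s = np.linalg.cholesky(m_pix)
            r_t = ar1_correlation(h["rho"], years)
            r_t[np.diag_indices_from(r_t)] += 1e-10
            l_t = np.linalg.cholesky(r_t)
            sd = np.sqrt(h["spatial_variance"])

            m_fs = matern_covariance(
                None, h["spatial_range"], h["spatial_variance"],
                nu=model.spec.nu, distances=d_fs,
            )
            r_fs = h["rho"] ** lag_ts  # (n_years, S)
            k_fs = np.empty((n_years * n_pix, model.n_support))
            for t in range(n_years):
                k_fs[t * n_pix:(t + 1) * n_pix] = m_fs * r_fs[t][None, :]
            k_ss = model.k_support(
                h["spatial_range"], h["spatial_variance"], h["rho"]
            )
            k_ss[np.diag_indices_from(k_ss)] += 1e-8
            gain = np.linalg.solve(k_ss, k_fs.T).T  # (TP, S)

            sup_flat = model.sup_year_idx * n_pix + model.sup_pixel
            for row, d in enumerate(idx):
                z = rng.standard_normal((n_years, n_pix))
                u_prior = sd * (l_t @ z @ l_s.T)
                u_prior_vec = u_prior.ravel()
                resid = fit.u_support[d] - u_prior_vec[sup_flat]
                u_star[row] = u_prior_vec + gain @ resid

        gamma_pix = fit.gamma[idx][:, model.pixel_group]  # (nk, n_pix)
        for row, d in enumerate(idx):
            eta = (
                fit.beta0[d]
                + fit.alpha[d] @ logit_surf
                + np.tile(gamma_pix[row], n_years)
                + u_star[row]
            )
            out[d] = expit(eta).reshape(n_years, n_pix)

    return PosteriorDrawCube(grid=grid, years=list(years), values=out, name=name)


def combine_stages(p1: PosteriorDrawCube, p3c: PosteriorDrawCube) -> PosteriorDrawCube:
    """Continuation-ratio composition: p3 = p1 * p3c, draw-wise.

    Structurally guarantees p3 <= p1 in every draw at every (pixel, year).
    """
    if p1.values.shape != p3c.values.shape or p1.years != p3c.years:
        raise DataError("stage cubes are not aligned draw-wise")
    return PosteriorDrawCube(
        grid=p1.grid, years=list(p1.years), values=p1.values * p3c.values, name="p3"
    )
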