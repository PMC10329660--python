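"""Synthetic study region with the statistical structure the pipeline assumes.

Generates a "Borno-like" world: smooth spatial covariates with controllable
collinearity, latent continuation-ratio coverage surfaces (stage 1 = P(first
dose), stage 2 = P(third dose | first dose)) driven by covariates plus an
AR1-in-time x Matern-in-space Gaussian process, a heterogeneous population
raster, a two-level state/LGA partition, clustered conflict events, and a
cluster survey with conflict-induced dropout of whole LGAs.

Every simulator is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geo_io import AdminFrame, CovariateStack, DataError, PixelGrid
from .geostat import ar1_correlation, matern_covariance

logger = logging.getLogger("geovax")

__all__ = [
    "TruthSurfaces",
    "SurveyDesign",
    "EmptySurveyError",
    "simulate_gaussian_field",
    "simulate_covariates",
    "simulate_truth",
    "partition_admin",
    "simulate_population",
    "simulate_conflict",
    "simulate_survey",
]

_EVENT_TYPES = ["battle", "explosion", "violence against civilians", "riot"]


class EmptySurveyError(RuntimeError):
    """Every planned cluster was dropped; the survey is empty."""


@dataclass
class TruthSurfaces:
    """Latent true coverage surfaces per (year, pixel).

    p1 = P(>=1 dose), p3c = P(>=3 doses | >=1 dose), p3 = p1 * p3c.
    Arrays have shape (n_years, n_pixels).
    """

    grid: PixelGrid
    years: list[int]
    p1: np.ndarray
    p3c: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def p3(self) -> np.ndarray:
        return self.p1 * self.p3c

    def at(self, pixel: np.ndarray, year: np.ndarray, which: str = "p1") -> np.ndarray:
        t = np.array([self.years.index(int(y)) for y in np.atleast_1d(year)])
        p = np.atleast_1d(pixel).astype(int)
        return {"p1": self.p1, "p3c": self.p3c, "p3": self.p3}[which][t, p]


@dataclass(frozen=True)
class SurveyDesign:
    """Cluster-survey design: sizes, year, eligible ages and dropout."""

    n_clusters: int
    children_per_cluster: int = 20
    survey_year: int = 2017
    cohort_age_months: tuple[int, int] = (12, 59)
    conflict_dropout_prob: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.cohort_age_months
        if not (12 <= lo <= hi <= 59):
            raise DataError("cohort ages must lie within [12, 59] months")
        if not 0 <= self.conflict_dropout_prob <= 1:
            raise DataError("conflict_dropout_prob must lie in [0, 1]")


# ---------------------------------------------------------------------------
# fields and covariates


def simulate_gaussian_field(
    grid: PixelGrid,
    spatial_range: float,
    variance: float,
    seed: int | np.random.Generator,
    nu: float = 1.5,
) -> np.ndarray:
    """One zero-mean draw from a Matern GP over the grid's cell centers.

    Returns a (n_pixels,) row-major vector.  ``spatial_range`` is the
    Matern range in km; variance 0 returns the all-zero field.
    """
    if not spatial_range > 0:
        raise DataError("spatial_range must be > 0")
    if variance < 0:
        raise DataError("variance must be >= 0")
    if variance == 0:
        return np.zeros(grid.n_pixels)
    rng = np.random.default_rng(seed)
    coords = grid.cell_centers()
    cov = matern_covariance(coords, spatial_range, variance, nu=nu)
    cov[np.diag_indices_from(cov)] += 1e-8 * variance
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FloatingPointError("Matern covariance not positive definite") from exc
    return chol @ rng.standard_normal(grid.n_pixels)


def simulate_covariates(
    grid: PixelGrid,
    years: list[int],
    n_covariates: int,
    seed: int | np.random.Generator,
    collinear_pairs: list[tuple[int, int, float]] | None = None,
    spatial_range: float | None = None,
) -> CovariateStack:
    """Smooth standardized covariate fields, optionally collinear.

    ``collinear_pairs`` entries (i, j, r) rebuild covariate j as
    ``r * x_i + sqrt(1 - r^2) * z`` with z an independent smooth field, so
    the empirical correlation lands within about +/-0.05 of r.  Covariates
    are time-invariant (replicated across years), matching how most
    geospatial covariate layers enter the coverage model.
    """
    if n_covariates < 1:
        raise DataError("n_covariates must be >= 1")
    for i, j, r in collinear_pairs or []:
        if not -1 < r < 1:
            raise DataError(f"target correlation {r} outside (-1, 1)")
        if not (0 <= i < n_covariates and 0 <= j < n_covariates and i != j):
            raise DataError(f"invalid collinear pair ({i}, {j})")
    rng = np.random.default_rng(seed)
    if spatial_range is None:
        spatial_range = 0.35 * grid.cell_size * max(grid.n_rows, grid.n_cols)

    def one_field() -> np.ndarray:
        f = simulate_gaussian_field(grid, spatial_range, 1.0, rng)
        return (f - f.mean()) / (f.std() + 1e-12)

    fields = [one_field() for _ in range(n_covariates)]
    for i, j, r in collinear_pairs or []:
        z = one_field()
        fields[j] = r * fields[i] + np.sqrt(1 - r**2) * z
    values = np.stack(fields)[:, None, :].repeat(len(years), axis=1)
    names = [f"cov_{k}" for k in range(n_covariates)]
    return CovariateStack(
        grid=grid, years=list(years), names=names, values=values,
        is_time_varying=[False] * n_covariates,
    )


def _spacetime_gp(
    grid: PixelGrid,
    n_years: int,
    spatial_range: float,
    variance: float,
    rho: float,
    rng: np.random.Generator,
    nu: float = 1.5,
) -> np.ndarray:
    """(n_years, n_pixels) draw from the separable AR1 x Matern GP."""
    if variance == 0:
        return np.zeros((n_years, grid.n_pixels))
    coords = grid.cell_centers()
    ks = matern_covariance(coords, spatial_range, 1.0, nu=nu)
    ks[np.diag_indices_from(ks)] += 1e-8
    kt = ar1_correlation(rho, list(range(n_years)))
    kt[np.diag_indices_from(kt)] += 1e-10
    ls = np.linalg.cholesky(ks)
    lt = np.linalg.cholesky(kt)
    z = rng.standard_normal((n_years, grid.n_pixels))
    return np.sqrt(variance) * (lt @ z @ ls.T)


def simulate_truth(
    stack: CovariateStack,
    betas: dict[str, np.ndarray],
    gp_params: dict[str, dict],
    rho: float,
    seed: int | np.random.Generator,
) -> TruthSurfaces:
    """Latent continuation-ratio truth driven by covariates + space-time GP.

    For each stage s in {"p1", "p3c"}: logit(p_s) = beta0_s + X @ beta_s +
    u_s with u_s ~ AR1(rho) x Matern.  ``betas[s]`` is (intercept, then one
    coefficient per covariate); ``gp_params[s]`` supplies spatial_range /
    variance (variance 0 switches the GP off).  Linear predictors beyond
    +/-30 are clipped with a logged warning.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    n_years, n_pix = len(stack.years), grid.n_pixels
    X = stack.values  # (n_cov, n_years, n_pixels)
    surfaces = {}
    for stage in ("p1", "p3c"):
        b = np.asarray(betas[stage], dtype=float)
        if b.shape != (stack.n_covariates + 1,):
            raise DataError(
                f"stage {stage}: expected {stack.n_covariates + 1} betas, got {b.shape}"
            )
        gp = gp_params.get(stage, {})
        u = _spacetime_gp(
            grid, n_years,
            gp.get("spatial_range", 0.25 * grid.cell_size * max(grid.n_rows, grid.n_cols)),
            gp.get("variance", 0.0), rho, rng, nu=gp.get("nu", 1.5),
        )
        eta = b[0] + np.tensordot(b[1:], X, axes=(0, 0)) + u
        n_clip = int((np.abs(eta) > 30).sum())
        if n_clip:
            logger.warning("stage %s: clipped %d linear predictors beyond +/-30", stage, n_clip)
            eta = np.clip(eta, -30, 30)
        surfaces[stage] = 1.0 / (1.0 + np.exp(-eta))
    return TruthSurfaces(
        grid=grid, years=list(stack.years), p1=surfaces["p1"], p3c=surfaces["p3c"],
        params={"betas": {k: list(map(float, v)) for k, v in betas.items()},
                "gp_params": gp_params, "rho": rho},
    )


# ---------------------------------------------------------------------------
# admin partition, population, conflict


def partition_admin(
    grid: PixelGrid, n_states: int, lgas_per_state: int, seed: int | None = None
) -> AdminFrame:
    """Contiguous rectangular-ish two-level partition of the grid.

    States are horizontal bands of rows; each state is tiled into a
    near-square a x b LGA grid (a * b = lgas_per_state).  State ids are
    1..n_states; LGA ids are state_id * 100 + k.
    """
    if n_states * lgas_per_state > grid.n_pixels:
        raise DataError("more admin units than pixels")
    if n_states < 1 or lgas_per_state < 1:
        raise DataError("need at least one unit per level")

    owner = np.empty((grid.n_rows, grid.n_cols), dtype=object)
    rows_per_state = np.array_split(np.arange(grid.n_rows), n_states)

    # a x b tiling of each state band (a * b = lgas_per_state), choosing the
    # divisor pair nearest a square that still fits the band's shape
    band_rows = min(len(r) for r in rows_per_state)
    divisors = [d for d in range(1, lgas_per_state + 1) if lgas_per_state % d == 0]
    feasible = [
        d for d in divisors
        if d <= band_rows and lgas_per_state // d <= grid.n_cols
    ]
    if not feasible:
        raise DataError("grid too small for the requested LGA tiling")
    a = min(feasible, key=lambda d: abs(d - np.sqrt(lgas_per_state)))
    b = lgas_per_state // a
    units = [
        {"unit_id": s + 1, "level": 1, "parent_id": None} for s in range(n_states)
    ]
    for s, state_rows in enumerate(rows_per_state):
        row_blocks = np.array_split(state_rows, a)
        col_blocks = np.array_split(np.arange(grid.n_cols), b)
        k = 0
        for rblock in row_blocks:
            for cblock in col_blocks:
                k += 1
                uid = (s + 1) * 100 + k
                if rblock.size == 0 or cblock.size == 0:
                    raise DataError("empty LGA in partition; reduce lgas_per_state")
                owner[np.ix_(rblock, cblock)] = uid
                units.append({"unit_id": uid, "level": 2, "parent_id": s + 1})
    return AdminFrame(
        grid=grid, units=pd.DataFrame(units), pixel_owner=owner.ravel(), polygons=None
    )


def simulate_population(
    grid: PixelGrid,
    urban_centers: int,
    total_pop: float,
    seed: int | np.random.Generator,
    concentration: float = 0.7,
) -> np.ndarray:
    """Heterogeneous per-pixel population: radial urban kernels + uniform floor.

    ``concentration`` is the population share living in the urban mixture
    (0 centers gives a near-uniform surface).  The result is nonnegative and
    sums exactly to ``total_pop``.
    """
    if not total_pop > 0:
        raise DataError("total_pop must be > 0")
    rng = np.random.default_rng(seed)
    centers_xy = None
    coords = grid.cell_centers()
    density = np.ones(grid.n_pixels)
    if urban_centers > 0:
        idx = rng.choice(grid.n_pixels, size=urban_centers, replace=False)
        centers_xy = coords[idx]
        extent = grid.cell_size * max(grid.n_rows, grid.n_cols)
        sigma = 0.08 * extent
        d2 = cdist(coords, centers_xy, "sqeuclidean")
        kernels = np.exp(-0.5 * d2 / sigma**2).sum(axis=1)
        kernels /= kernels.sum()
        floor = np.full(grid.n_pixels, 1.0 / grid.n_pixels)
        density = concentration * kernels + (1 - concentration) * floor
    density = density / density.sum()
    return density * float(total_pop)


def simulate_conflict(
    admin: AdminFrame,
    affected_lgas: list,
    events_per_lga: float,
    fatality_mean: float,
    years: list[int],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Geolocated conflict events clustered in the affected LGAs.

    Event counts are Poisson(events_per_lga) per LGA-year, locations uniform
    inside each LGA (uniform pixel, then uniform within the cell), fatality
    counts Poisson(fatality_mean).  Columns: x, y, year, type, fatalities.
    """
    unknown = set(affected_lgas) - set(admin.lga_ids)
    if unknown:
        raise DataError(f"affected LGAs not in partition: {sorted(map(str, unknown))}")
    rng = np.random.default_rng(seed)
    grid = admin.grid
    centers = grid.cell_centers()
    rows = []
    for year in years:
        for lga in affected_lgas:
            n_events = rng.poisson(events_per_lga)
            if n_events == 0:
                continue
            pixels = admin.pixels_of(lga)
            chosen = rng.choice(pixels, size=n_events, replace=True)
            jitter = rng.uniform(-0.5, 0.5, size=(n_events, 2)) * grid.cell_size
            xy = centers[chosen] + jitter
            fatalities = rng.poisson(fatality_mean, size=n_events)
            types = rng.choice(_EVENT_TYPES, size=n_events)
            for k in range(n_events):
                rows.append(
                    {"x": xy[k, 0], "y": xy[k, 1], "year": int(year),
                     "type": types[k], "fatalities": int(fatalities[k]),
                     "lga_id": lga}
                )
    return pd.DataFrame(rows, columns=["x", "y", "year", "type", "fatalities", "lga_id"])


# ---------------------------------------------------------------------------
# survey


def simulate_survey(
    truth: TruthSurfaces,
    population: np.ndarray,
    admin: AdminFrame,
    design: SurveyDesign,
    conflict_lgas: list,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Cluster survey with conflict-induced dropout of whole LGAs.

    Clusters are placed at pixels with probability proportional to
    population; each LGA flagged as conflict-affected is dropped with
    probability ``design.conflict_dropout_prob``, taking all its clusters
    with it (whole admin units go unsampled, as observed when insecurity
    blocks field teams).  Children's ages are uniform over the eligible
    range; the birth cohort is ``survey_year - floor(age_months / 12)``.
    Stage outcomes are nested binomials from the truth surfaces:
    k1 ~ Binomial(N, p1) and k3 ~ Binomial(k1, p3c).

    Returns one row per (cluster, cohort year): columns cluster_id, x, y,
    lga_id, survey_year, cohort_year, N, k1, k3.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    pop = np.asarray(population, dtype=float)
    if pop.shape != (grid.n_pixels,):
        raise DataError("population raster does not match the grid")

    dropped = {
        lga for lga in conflict_lgas
        if rng.random() < design.conflict_dropout_prob
    }
    probs = pop / pop.sum()
    pixels = rng.choice(grid.n_pixels, size=design.n_clusters, p=probs, replace=True)
    centers = grid.cell_centers()

    rows = []
    ages_lo, ages_hi = design.cohort_age_months
    kept_clusters = 0
    for cid, pix in enumerate(pixels):
        lga = admin.pixel_owner[pix]
        if lga in dropped:
            continue
        kept_clusters += 1
        ages = rng.integers(ages_lo, ages_hi + 1, size=design.children_per_cluster)
        cohorts = design.survey_year - (ages // 12)
        for cohort_year, n_c in zip(*np.unique(cohorts, return_counts=True)):
            cohort_year = int(cohort_year)
            if cohort_year not in truth.years:
                raise DataError(
                    f"truth surfaces lack cohort year {cohort_year}; extend the year span"
                )
            p1 = float(truth.at(pix, cohort_year, "p1")[0])
            p3c = float(truth.at(pix, cohort_year, "p3c")[0])
            k1 = int(rng.binomial(int(n_c), p1))
            k3 = int(rng.binomial(k1, p3c)) if k1 > 0 else 0
            rows.append(
                {"cluster_id": cid, "x": centers[pix, 0], "y": centers[pix, 1],
                 "pixel_id": int(pix), "lga_id": lga,
                 "survey_year": design.survey_year, "cohort_year": cohort_year,
                 "N": int(n_c), "k1": k1, "k3": k3}
            )
    if not rows:
        raise EmptySurveyError("all planned clusters were dropped")
    if len(dropped):
        logger.info("dropped %d conflict-affected LGAs from the sample", len(dropped))
    return pd.DataFrame(rows)
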