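"""Raking to a national series and population-weighted admin aggregation.

Pixel-level posterior draws are calibrated ("raked") to an external
national coverage series by a logit-scale shift: for each dose-year a
scalar delta solves

    sum_s w_s * sigmoid(logit(p_s) + delta) = target,   w_s = pop_s / sum pop

which has a unique root by monotonicity.  Raked draws are then aggregated
to admin units as population-weighted means with percentile uncertainty
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .geo_io import AdminFrame, DataError, NationalSeries
from .geostat import PosteriorDrawCube

logger = logging.getLogger("geovax")

__all__ = [
    "AdminEstimateTable",
    "solve_raking_shift",
    "apply_raking",
    "aggregate_admin",
    "proportion_units_increasing",
]

_P_CLIP = 1e-12


@dataclass
class AdminEstimateTable:
    """Admin-unit coverage estimates with uncertainty intervals.

    ``table`` columns: unit_id, level, year, dose, mean, lower, upper.
    ``draws`` maps (unit_id, year, dose) -> per-draw values, preserved so
    downstream draw-level statistics keep the posterior pairing.
    """

    table: pd.DataFrame
    draws: dict[tuple, np.ndarray]
    percentiles: tuple[float, float] = (2.5, 97.5)

    def row(self, unit_id, year: int, dose: str) -> pd.Series:
        sel = self.table[
            (self.table["unit_id"] == unit_id)
            & (self.table["year"] == int(year))
            & (self.table["dose"] == dose)
        ]
        if sel.empty:
            raise DataError(f"no estimate for ({unit_id}, {year}, {dose})")
        return sel.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def solve_raking_shift(
    pixel_values: np.ndarray,
    pixel_populations: np.ndarray,
    target: float,
    tol: float = 1e-12,
) -> float:
    """Logit shift delta calibrating a weighted pixel mean to the target.

    Bracketed root finding on delta in [-30, 30]; the weighted-mean residual
    at the returned delta is below 1e-10.  Degenerate surfaces (all pixels
    at exactly 0 or 1) and targets outside (0, 1) are errors.
    """
    p = np.asarray(pixel_values, dtype=float)
    pop = np.asarray(pixel_populations, dtype=float)
    if not 0 < target < 1:
        raise DataError(f"raking target must lie in (0, 1), got {target}")
    if (pop < 0).any() or pop.sum() <= 0:
        raise DataError("populations must be nonnegative with positive total")
    if ((p <= 0) | (p >= 1)).all():
        raise DataError("all pixels at 0/1: raking shift is undefined")
    w = pop / pop.sum()
    lo = logit(np.clip(p, _P_CLIP, 1 - _P_CLIP))

    def residual(delta: float) -> float:
        return float(w @ expit(lo + delta)) - target

    r0 = residual(0.0)
    if abs(r0) < tol:
        return 0.0
    return float(brentq(residual, -30.0, 30.0, xtol=tol))


def apply_raking(
    cubes: dict[str, PosteriorDrawCube],
    national: NationalSeries,
    population: np.ndarray,
    mode: str = "mean",
) -> tuple[dict[str, PosteriorDrawCube], pd.DataFrame]:
    """Rake dose cubes to the national series; cap p3 at p1 within draws.

    mode "mean" (default): one delta per (dose, year), solved on the
    posterior-mean surface and applied to every draw.  mode "per-draw":
    delta solved separately for each draw.  Doses are raked independently;
    afterwards every draw's third-dose value is capped at its first-dose
    value and the number of capped cells is logged and returned.

    Returns (raked cubes, log DataFrame of deltas and cap counts).
    """
    if mode not in ("mean", "per-draw"):
        raise DataError("raking mode must be 'mean' or 'per-draw'")
    pop = np.asarray(population, dtype=float)
    logs = []
    out: dict[str, PosteriorDrawCube] = {}
    for dose, cube in cubes.items():
        values = cube.values.copy()
        for t, year in enumerate(cube.years):
            target = national.target(dose, year)
            if mode == "mean":
                # solved over draws jointly so the raked posterior-mean
                # surface hits the target exactly (sigmoid and draw-averaging
                # do not commute)
                n_draws = values.shape[0]
                delta = solve_raking_shift(
                    values[:, t, :].ravel(), np.tile(pop, n_draws), target
                )
                values[:, t, :] = expit(
                    logit(np.clip(values[:, t, :], _P_CLIP, 1 - _P_CLIP)) + delta
                )
                logs.append({"dose": dose, "year": year, "delta": delta})
            else:
                for d in range(cube.n_draws):
                    delta = solve_raking_shift(values[d, t, :], pop, target)
                    values[d, t, :] = expit(
                        logit(np.clip(values[d, t, :], _P_CLIP, 1 - _P_CLIP)) + delta
                    )
                logs.append({"dose": dose, "year": year, "delta": np.nan})
        out[dose] = PosteriorDrawCube(
            grid=cube.grid, years=list(cube.years), values=values, name=cube.name
        )

    n_capped = 0
    if "dtp1" in out and "dtp3" in out:
        excess = out["dtp3"].values > out["dtp1"].values
        n_capped = int(excess.sum())
        if n_capped:
            out["dtp3"].values[excess] = out["dtp1"].values[excess]
            logger.info("capped %d raked dtp3 cells at dtp1", n_capped)
    log_df = pd.DataFrame(logs)
    log_df.attrs["n_capped"] = n_capped
    return out, log_df


def _weighted_percentiles(draws: np.ndarray, percentiles: tuple[float, float]):
    lower, upper = np.percentile(draws, percentiles, method="linear")
    return float(lower), float(upper)


def aggregate_admin(
    cube: PosteriorDrawCube,
    population: np.ndarray,
    admin: AdminFrame,
    level: int,
    dose: str = "",
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> AdminEstimateTable:
    """Population-weighted aggregation of draws to admin units at one level.

    Per draw, a unit's value is sum(pop_s * p_s) / sum(pop_s) over the
    unit's pixels; means and percentile bounds are taken across draws.
    Zero-population units are flagged missing (NaN) and contribute nothing
    to their parents.
    """
    if level not in (1, 2):
        raise DataError("admin level must be 1 or 2")
    pop = np.asarray(population, dtype=float)
    if pop.shape != (cube.grid.n_pixels,):
        raise DataError("population raster does not match the cube grid")
    unit_ids = admin.state_ids if level == 1 else admin.lga_ids

    rows = []
    draws_store: dict[tuple, np.ndarray] = {}
    for unit in unit_ids:
        pixels = admin.pixels_of(unit)
        wsum = pop[pixels].sum()
        for t, year in enumerate(cube.years):
            if wsum <= 0:
                logger.warning("unit %s has zero population; flagged missing", unit)
                rows.append(
                    {"unit_id": unit, "level": level, "year": year, "dose": dose,
                     "mean": np.nan, "lower": np.nan, "upper": np.nan}
                )
                continue
            vals = cube.values[:, t, pixels] @ pop[pixels] / wsum  # (n_draws,)
            lower, upper = _weighted_percentiles(vals, percentiles)
            rows.append(
                {"unit_id": unit, "level": level, "year": year, "dose": dose,
                 "mean": float(vals.mean()), "lower": lower, "upper": upper}
            )
            draws_store[(unit, int(year), dose)] = vals
    return AdminEstimateTable(
        table=pd.DataFrame(rows), draws=draws_store, percentiles=percentiles
    )


def proportion_units_increasing(
    estimates: AdminEstimateTable,
    year0: int,
    year1: int,
    dose: str = "",
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> dict:
    """Share of level-2 units whose coverage strictly increased year0 -> year1.

    Computed per draw (preserving the posterior pairing), then summarized
    as mean and percentile bounds, all on the 0-100 scale.  Ties count as
    not increased.
    """
    units = sorted(
        {u for (u, y, d) in estimates.draws if d == dose and y == int(year0)}
    )
    if not units:
        raise DataError(f"no level-2 draws stored for dose {dose!r} in {year0}")
    per_draw = None
    for u in units:
        try:
            v0 = estimates.draws[(u, int(year0), dose)]
            v1 = estimates.draws[(u, int(year1), dose)]
        except KeyError as exc:
            raise DataError(f"missing draws for unit {u}: {exc}") from exc
        inc = (v1 > v0).astype(float)
        per_draw = inc if per_draw is None else per_draw + inc
    share = 100.0 * per_draw / len(units)
    lower, upper = np.percentile(share, percentiles, method="linear")
    return {
        "mean": float(share.mean()),
        "lower": float(lower),
        "upper": float(upper),
        "n_units": len(units),
    }
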