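"""Conflict overlay and survey-representativeness audit.

Quantifies how much of a state's territory and population a cluster survey
actually represents when insecurity blocks sampling: conflict events are
assigned to admin units, per-LGA conflict summaries computed, unsampled
LGA counts and population-representation fractions derived (under each
supplied population raster), and survey-reported estimates compared with
model-based ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .geo_io import AdminFrame, DataError
from .calibrate import AdminEstimateTable

logger = logging.getLogger("geovax")

__all__ = [
    "RepresentativenessReport",
    "assign_points_to_admin",
    "conflict_summary",
    "unsampled_fraction",
    "sampled_population_fraction",
    "compare_reported_vs_model",
]


def _round1(x: float) -> float:
    """Round half-up to one decimal (reporting convention for percentages)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass
class RepresentativenessReport:
    """Bundle of audit outputs, serializable as CSVs + one JSON summary."""

    lga_year: pd.DataFrame = None
    lgas_with_events: pd.DataFrame = None
    unsampled: dict = field(default_factory=dict)
    population_fractions: dict = field(default_factory=dict)
    comparisons: pd.DataFrame = None

    def summary(self) -> dict:
        return {
            "unsampled": self.unsampled,
            "population_fractions": self.population_fractions,
            "n_conflict_events": int(self.lga_year["events"].sum())
            if self.lga_year is not None
            else 0,
            "total_fatalities": int(self.lga_year["fatalities"].sum())
            if self.lga_year is not None
            else 0,
        }


def assign_points_to_admin(
    points: pd.DataFrame, admin: AdminFrame
) -> tuple[pd.DataFrame, int]:
    """Assign (x, y) points to level-2 units by containing-pixel lookup.

    Point-in-polygon is resolved through the pixel raster: each point maps
    to the pixel containing it and inherits that pixel's owner, which makes
    boundary ties follow the raster's (lowest unit_id) assignment.  Points
    outside the grid are excluded and counted.

    Returns (points with a ``unit_id`` column, count of excluded points).
    """
    if not {"x", "y"} <= set(points.columns):
        raise DataError("points need x and y columns")
    pix = admin.grid.pixel_of_xy(points["x"].to_numpy(), points["y"].to_numpy())
    inside = pix >= 0
    n_outside = int((~inside).sum())
    if n_outside:
        logger.info("excluded %d conflict points outside the grid", n_outside)
    out = points.loc[inside].copy()
    out["unit_id"] = admin.pixel_owner[pix[inside]]
    return out, n_outside


def conflict_summary(
    events: pd.DataFrame, admin: AdminFrame, years: list[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per LGA-year event counts and fatality sums, plus LGAs-with-events.

    All event types are pooled; the type column is preserved upstream for
    future stratification.  Returns (lga_year table with every LGA-year row
    including zeros, per-year count of LGAs with at least one event).
    """
    if "unit_id" not in events.columns:
        events, _ = assign_points_to_admin(events, admin)
    full_index = pd.MultiIndex.from_product(
        [admin.lga_ids, [int(y) for y in years]], names=["unit_id", "year"]
    )
    if events.empty:
        grouped = pd.DataFrame(
            {"events": 0, "fatalities": 0}, index=full_index
        ).reset_index()
    else:
        g = (
            events.groupby(["unit_id", "year"])
            .agg(events=("unit_id", "size"), fatalities=("fatalities", "sum"))
            .reindex(full_index, fill_value=0)
            .reset_index()
        )
        grouped = g
    grouped["conflict_flag"] = grouped["events"] >= 1
    per_year = (
        grouped[grouped["conflict_flag"]]
        .groupby("year")["unit_id"]
        .nunique()
        .reindex([int(y) for y in years], fill_value=0)
        .rename("lgas_with_events")
        .reset_index()
    )
    return grouped, per_year


def unsampled_fraction(admin_or_ids, sampled_ids) -> tuple[int, float]:
    """Count and percentage (1 decimal, half-up) of level-2 units unsampled.

    ``admin_or_ids`` is an AdminFrame or an explicit list of level-2 unit
    ids.  Sampled ids outside the unit set are a validation error.
    """
    if isinstance(admin_or_ids, AdminFrame):
        unit_ids = admin_or_ids.lga_ids
    else:
        unit_ids = list(admin_or_ids)
    sampled = set(sampled_ids)
    unknown = sampled - set(unit_ids)
    if unknown:
        raise DataError(f"sampled ids not in unit set: {sorted(map(str, unknown))}")
    n_unsampled = len(unit_ids) - len(sampled)
    pct = _round1(100.0 * n_unsampled / len(unit_ids))
    return n_unsampled, pct


def sampled_population_fraction(
    unit_population: pd.Series | dict,
    sampled_ids,
    age_fraction: float | None = None,
) -> float:
    """Percentage of population living in sampled units (1 decimal, half-up).

    ``unit_population`` maps level-2 unit id -> persons (one entry per
    unit, from one population raster; call once per raster to compare).
    ``age_fraction`` optionally scales total population to an age band
    (e.g. under-5) — a uniform multiplier cancels in the ratio but is
    accepted for rasters expressed as totals.
    """
    pop = pd.Series(unit_population, dtype=float)
    if (pop < 0).any():
        raise DataError("unit populations must be >= 0")
    if age_fraction is not None:
        pop = pop * float(age_fraction)
    total = pop.sum()
    if total <= 0:
        raise DataError("zero total population")
    sampled = set(sampled_ids)
    unknown = sampled - set(pop.index)
    if unknown:
        raise DataError(f"sampled ids not in population table: {sorted(map(str, unknown))}")
    return _round1(100.0 * pop[pop.index.isin(sampled)].sum() / total)


def compare_reported_vs_model(
    reported: pd.DataFrame, model: AdminEstimateTable, unit_id
) -> pd.DataFrame:
    """Survey-reported vs model-based estimates for one admin unit.

    ``reported`` needs columns dose, year, estimate (percent scale,
    0-100); optional lower/upper give the survey CI.  Each row is matched
    to the model row for (unit, year, dose); the difference is reported in
    percentage points (reported - model mean) together with whether the
    reported estimate falls inside the model's uncertainty interval.
    """
    required = {"dose", "year", "estimate"}
    if not required <= set(reported.columns):
        raise DataError(f"reported table needs columns {sorted(required)}")
    rows = []
    for _, r in reported.iterrows():
        m = model.row(unit_id, int(r["year"]), r["dose"])  # raises if absent
        model_mean = 100.0 * float(m["mean"])
        model_lo = 100.0 * float(m["lower"])
        model_hi = 100.0 * float(m["upper"])
        diff = float(r["estimate"]) - model_mean
        rows.append(
            {
                "unit_id": unit_id,
                "dose": r["dose"],
                "year": int(r["year"]),
                "reported": float(r["estimate"]),
                "model_mean": _round1(model_mean),
                "model_lower": _round1(model_lo),
                "model_upper": _round1(model_hi),
                "difference_pp": _round1(diff),
                "reported_inside_ui": bool(model_lo <= float(r["estimate"]) <= model_hi),
            }
        )
    return pd.DataFrame(rows)
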