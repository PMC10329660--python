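"""Config-driven orchestration: simulate -> select -> stack -> fit -> rake ->
aggregate -> audit, with per-stage seeds, persisted artifacts and a manifest.

The single configured seed is expanded into per-stage seeds through a
documented counter scheme (``SeedSequence([seed, stage_index])``), so any
stage rerun in isolation reproduces its output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geo_io import (
    NationalSeries,
    PixelGrid,
    RunConfig,
    write_raster,
)
from .calibrate import aggregate_admin, apply_raking, proportion_units_increasing
from .covariate_selection import prune_by_vif
from .geostat import (
    GpSpec,
    build_model,
    combine_stages,
    fit_posterior,
    predict_surface,
)
from .representativeness import (
    RepresentativenessReport,
    compare_reported_vs_model,
    conflict_summary,
    sampled_population_fraction,
    unsampled_fraction,
)
from .stacking import assign_folds, fit_child_models
from .synthetic_world import (
    SurveyDesign,
    partition_admin,
    simulate_conflict,
    simulate_covariates,
    simulate_population,
    simulate_survey,
    simulate_truth,
)

logger = logging.getLogger("geovax")

__all__ = ["RunManifest", "StageError", "run_pipeline", "STAGES"]

STAGES = ["simulate", "select", "stack", "fit", "rake", "aggregate", "audit"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunManifest:
    """Run provenance: config hash, seed, versions, per-stage artifacts."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, artifacts: dict[str, str], seconds: float,
               warnings_seen: list[str]) -> None:
        self.stages.append(
            {"stage": name, "status": "completed", "artifacts": artifacts,
             "seconds": round(seconds, 3), "warnings": warnings_seen}
        )

    def record_failure(self, name: str, message: str) -> None:
        self.stages.append({"stage": name, "status": "failed", "error": message})

    @property
    def completed(self) -> list[str]:
        return [s["stage"] for s in self.stages if s["status"] == "completed"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def stage_seed(seed: int, stage_index: int) -> np.random.Generator:
    """Per-stage generator from the documented counter scheme."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage_index]))


def stage_seed_int(seed: int, stage_index: int) -> int:
    """Integer per-stage seed (< 2^31) for libraries that require one."""
    return int(
        np.random.SeedSequence([int(seed), stage_index]).generate_state(1)[0]
        % (2**31)
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_truth_params(n_covariates: int) -> dict:
    """Generative coefficients for the Borno-like world: modest coverage,
    two informative covariates, the rest noise."""
    b1 = np.zeros(n_covariates + 1)
    b1[0] = -0.2
    b1[1] = 0.8
    if n_covariates >= 2:
        b1[2] = -0.5
    b2 = np.zeros(n_covariates + 1)
    b2[0] = 0.3
    b2[1] = 0.5
    return {"p1": b1, "p3c": b2}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full chain and return all in-memory artifacts + manifest.

    Stages run in order; a failure halts the run, raises :class:`StageError`
    and leaves a manifest recording which stages completed.  Artifacts are
    persisted under ``out_dir`` (CSV/JSON/TIFF) with sha256 digests in the
    manifest.
    """
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    cfg_hash = hashlib.sha256(
        json.dumps(config.settings, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, seed=seed)
    state: dict = {"config": config, "manifest": manifest}

    for idx, stage in enumerate(STAGES):
        t0 = time.perf_counter()
        artifacts: dict[str, str] = {}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                _STAGE_FUNCS[stage](state, config, stage_seed(seed, idx),
                                    stage_seed_int(seed, idx), out, artifacts)
            except Exception as exc:
                manifest.record_failure(stage, str(exc))
                manifest.to_json(out / "manifest.json")
                raise StageError(stage, str(exc)) from exc
        manifest.record(
            stage, artifacts, time.perf_counter() - t0,
            [str(w.message) for w in caught],
        )
    manifest.to_json(out / "manifest.json")
    state["out_dir"] = out
    return state


# ---------------------------------------------------------------------------
# stages


def _save_csv(df: pd.DataFrame, path: Path, artifacts: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    artifacts[path.name] = _digest(path)


def _stage_simulate(state, config, rng, seed_int, out, artifacts):
    g = config["grid"]
    grid = PixelGrid(int(g["n_rows"]), int(g["n_cols"]), float(g["cell_size"]))
    years = config.years
    n_cov = int(config["n_covariates"])
    stack = simulate_covariates(
        grid, years, n_cov, rng,
        collinear_pairs=[(0, n_cov - 1, 0.9)] if n_cov >= 3 else None,
    )
    gp_cfg = config["gp"]
    domain_diameter = grid.cell_size * float(np.hypot(grid.n_rows, grid.n_cols))
    spatial_range = gp_cfg.get("spatial_range") or 0.25 * domain_diameter
    truth = simulate_truth(
        stack,
        _default_truth_params(n_cov),
        {
            "p1": {"spatial_range": spatial_range,
                   "variance": float(gp_cfg["spatial_variance"]) * 0.3,
                   "nu": float(gp_cfg["nu"])},
            "p3c": {"spatial_range": spatial_range,
                    "variance": float(gp_cfg["spatial_variance"]) * 0.2,
                    "nu": float(gp_cfg["nu"])},
        },
        float(gp_cfg["rho"]),
        rng,
    )
    admin = partition_admin(grid, int(config["n_states"]), int(config["lgas_per_state"]))
    population = simulate_population(
        grid, int(config["urban_centers"]), float(config["total_population"]), rng
    )
    alt_population = simulate_population(
        grid, int(config["urban_centers"]) + 1, float(config["total_population"]),
        np.random.default_rng(np.random.SeedSequence([config.seed, 97])),
    )
    lgas = admin.lga_ids
    # conflict concentrates in populous LGAs, but the single most populous
    # unit (the state capital analogue) remains accessible to field teams:
    # dropout therefore removes the next-most-populous units, leaving the
    # capital plus a fringe of small LGAs in the sample
    unit_pop = admin.unit_population(population)[lgas].sort_values(ascending=False)
    conflict_lgas = list(unit_pop.index[1: 1 + int(config["n_conflict_lgas"])])
    events = simulate_conflict(
        admin, conflict_lgas, float(config["conflict_event_rate"]),
        float(config["conflict_fatality_mean"]), years, rng,
    )
    # survey fielded the year after the modelled span: eligible children
    # (12-59 months) then belong to birth cohorts years[-4] .. years[-1]
    design = SurveyDesign(
        n_clusters=int(config["n_clusters"]),
        children_per_cluster=int(config["children_per_cluster"]),
        survey_year=years[-1] + 1,
        conflict_dropout_prob=float(config["conflict_dropout_prob"]),
    )
    survey = simulate_survey(truth, population, admin, design, conflict_lgas, rng)

    # national series for calibration: population-weighted truth per dose-year
    w = population / population.sum()
    nat_rows = []
    for t, year in enumerate(years):
        nat_rows.append({"year": year, "dose": "dtp1",
                         "coverage": float(truth.p1[t] @ w)})
        nat_rows.append({"year": year, "dose": "dtp3",
                         "coverage": float(truth.p3[t] @ w)})
    national = NationalSeries(pd.DataFrame(nat_rows))

    state.update(
        grid=grid, years=years, stack=stack, truth=truth, admin=admin,
        population=population, alt_population=alt_population,
        conflict_lgas=conflict_lgas, events=events, survey=survey,
        national=national, design=design,
    )
    _save_csv(survey, out / "survey.csv", artifacts)
    _save_csv(events, out / "conflict_events.csv", artifacts)
    _save_csv(national.values, out / "national_series.csv", artifacts)
    write_raster(out / "population.tif", grid, population)
    artifacts["population.tif"] = _digest(out / "population.tif")


def _stage_select(state, config, rng, seed_int, out, artifacts):
    survey, stack = state["survey"], state["stack"]
    design_at_obs = stack.at(
        survey["pixel_id"].to_numpy(), survey["cohort_year"].to_numpy()
    )
    report = prune_by_vif(
        design_at_obs, threshold=float(config["vif_threshold"]), names=stack.names
    )
    state["vif_report"] = report
    state["selected"] = report.selected
    _save_csv(report.log, out / "vif_log.csv", artifacts)


def _stage_stack(state, config, rng, seed_int, out, artifacts):
    survey, stack = state["survey"].copy(), state["stack"]
    survey["observation_id"] = np.arange(len(survey))
    folds = assign_folds(
        survey, int(config["stacking_folds"]), rng,
        spatial=bool(config["stacking_spatial_folds"]),
    )
    children_p1 = fit_child_models(
        survey, stack, state["selected"], folds, seed_int,
        trials_col="N", successes_col="k1",
    )
    stage2 = survey[survey["k1"] > 0].reset_index(drop=True)
    children_p3c = fit_child_models(
        stage2, stack, state["selected"], folds[survey["k1"].to_numpy() > 0],
        seed_int, trials_col="k1", successes_col="k3",
    )
    state.update(survey_obs=survey, stage2_obs=stage2,
                 children={"p1": children_p1, "p3c": children_p3c})
    _save_csv(children_p1.oof, out / "stack_oof_p1.csv", artifacts)
    _save_csv(children_p3c.oof, out / "stack_oof_p3c.csv", artifacts)


def _stage_fit(state, config, rng, seed_int, out, artifacts):
    grid, years, admin = state["grid"], state["years"], state["admin"]
    gp_cfg = config["gp"]
    domain_diameter = grid.cell_size * float(np.hypot(grid.n_rows, grid.n_cols))
    spatial_range = gp_cfg.get("spatial_range") or 0.25 * domain_diameter
    n_draws = int(config["n_draws"])
    pixel_group = admin.state_of_pixel()
    state_of_lga = {u: admin.parent_of(u) for u in admin.lga_ids}

    cubes = {}
    fits = {}
    for stage_name, obs_key, trials_col, succ_col in (
        ("p1", "survey_obs", "N", "k1"),
        ("p3c", "stage2_obs", "k1", "k3"),
    ):
        obs = state[obs_key].copy()
        obs["year"] = obs["cohort_year"]
        obs["trials"] = obs[trials_col]
        obs["successes"] = obs[succ_col]
        obs["group_id"] = obs["lga_id"].map(state_of_lga)
        spec = GpSpec(
            spatial_range=spatial_range,
            spatial_variance=float(gp_cfg["spatial_variance"]) * (0.3 if stage_name == "p1" else 0.2),
            nu=float(gp_cfg["nu"]),
            rho=float(gp_cfg["rho"]),
            nugget_variance=float(gp_cfg["nugget_variance"]),
            group_effect_variance=float(gp_cfg["group_effect_variance"]),
        )
        model = build_model(
            spec, obs, state["children"][stage_name].oof, grid, years,
            pixel_group=pixel_group,
        )
        fit = fit_posterior(model, n_draws, stage_seed(config.seed, 30 + len(fits)))
        cube = predict_surface(
            fit, state["children"][stage_name].surface_array(),
            stage_seed(config.seed, 40 + len(fits)), name=stage_name,
        )
        fits[stage_name] = fit
        cubes[stage_name] = cube
    cubes_dose = {"dtp1": cubes["p1"], "dtp3": combine_stages(cubes["p1"], cubes["p3c"])}
    state.update(fits=fits, cubes=cubes_dose)
    hyper = pd.concat(
        [f.hyper.assign(stage=s) for s, f in fits.items()], ignore_index=True
    )
    _save_csv(hyper, out / "posterior_hyper.csv", artifacts)


def _stage_rake(state, config, rng, seed_int, out, artifacts):
    raked, log_df = apply_raking(
        state["cubes"], state["national"], state["population"],
        mode=config["raking_mode"],
    )
    state["raked_cubes"] = raked
    state["raking_log"] = log_df
    _save_csv(log_df, out / "raking_log.csv", artifacts)


def _stage_aggregate(state, config, rng, seed_int, out, artifacts):
    population = state.get("population")
    if "population" in config.get("paths", {}):
        from .geo_io import read_raster_stack

        population = read_raster_stack(
            [config["paths"]["population"]], state["grid"]
        ).values[0, 0]
    if population is None:
        raise ValueError("population raster unavailable")
    pct = tuple(float(p) for p in config["percentiles"])
    tables = []
    estimates = {}
    for dose, cube in state["raked_cubes"].items():
        for level in (1, 2):
            est = aggregate_admin(
                cube, population, state["admin"], level, dose=dose, percentiles=pct
            )
            estimates[(dose, level)] = est
            tables.append(est.table)
    # robustness: re-aggregate states under the alternative population raster
    shifts = {}
    for dose, cube in state["raked_cubes"].items():
        alt = aggregate_admin(
            cube, state["alt_population"], state["admin"], 1, dose=dose,
            percentiles=pct,
        )
        base = estimates[(dose, 1)].table.set_index(["unit_id", "year"])["mean"]
        altm = alt.table.set_index(["unit_id", "year"])["mean"]
        shifts[dose] = float((base - altm).abs().max())
        logger.info(
            "state-level %s means shift by at most %.4f under the "
            "alternative population raster", dose, shifts[dose],
        )
    state["admin_estimates"] = estimates
    state["population_sensitivity"] = shifts
    combined = pd.concat(tables, ignore_index=True)
    state["admin_table"] = combined
    _save_csv(combined, out / "admin_estimates.csv", artifacts)


def _stage_audit(state, config, rng, seed_int, out, artifacts):
    admin = state["admin"]
    years = state["years"]
    lga_year, per_year = conflict_summary(state["events"], admin, years)
    sampled = sorted(pd.unique(state["survey"]["lga_id"]))
    n_unsampled, pct_unsampled = unsampled_fraction(admin, sampled)
    unit_pop = admin.unit_population(state["population"])[admin.lga_ids]
    unit_pop_alt = admin.unit_population(state["alt_population"])[admin.lga_ids]
    pop_fracs = {
        "primary": sampled_population_fraction(unit_pop, sampled),
        "alternative": sampled_population_fraction(unit_pop_alt, sampled),
    }

    # survey-reported state estimates per cohort year vs model
    survey = state["survey"]
    reported_rows = []
    for year, g in survey.groupby("cohort_year"):
        reported_rows.append({"dose": "dtp1", "year": int(year),
                              "estimate": 100.0 * g["k1"].sum() / g["N"].sum()})
        reported_rows.append({"dose": "dtp3", "year": int(year),
                              "estimate": 100.0 * g["k3"].sum() / g["N"].sum()})
    reported = pd.DataFrame(reported_rows)
    comparisons = []
    state_id = admin.state_ids[0]
    for dose in ("dtp1", "dtp3"):
        est = state["admin_estimates"][(dose, 1)]
        sub = reported[reported["dose"] == dose]
        comparisons.append(compare_reported_vs_model(sub, est, state_id))
    comparisons = pd.concat(comparisons, ignore_index=True)

    report = RepresentativenessReport(
        lga_year=lga_year,
        lgas_with_events=per_year,
        unsampled={"count": n_unsampled, "total": len(admin.lga_ids),
                   "percent": pct_unsampled},
        population_fractions=pop_fracs,
        comparisons=comparisons,
    )
    state["report"] = report
    _save_csv(lga_year, out / "conflict_lga_year.csv", artifacts)
    _save_csv(comparisons, out / "survey_vs_model.csv", artifacts)
    summary = report.summary()
    summary["population_sensitivity"] = state.get("population_sensitivity", {})
    (out / "representativeness.json").write_text(json.dumps(summary, indent=2))
    artifacts["representativeness.json"] = _digest(out / "representativeness.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "select": _stage_select,
    "stack": _stage_stack,
    "fit": _stage_fit,
    "rake": _stage_rake,
    "aggregate": _stage_aggregate,
    "audit": _stage_audit,
}
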