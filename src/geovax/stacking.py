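"""Stacked generalization: child learners on cluster-level binomial outcomes.

Three child models — an additive smooth logistic model (per-covariate
B-spline bases), an L1-penalized logistic regression, and boosted
regression trees — are each fit to the selected covariates and produce

* out-of-fold predicted probabilities at every observation (used as
  predictors by the geostatistical stage, so no observation's prediction
  may use its own fold's data), and
* full-surface predictions at every (pixel, year) from a fit on all data.

Binomial observations (k successes of n trials) enter every child as two
weighted Bernoulli rows, so trials act as exact binomial weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_io import CovariateStack, DataError

logger = logging.getLogger("geovax")

__all__ = ["ChildPredictions", "CHILD_NAMES", "assign_folds", "fit_child_models"]

CHILD_NAMES = ("additive_smooth", "lasso_logistic", "boosted_trees")
_CLIP = 1e-4


@dataclass
class ChildPredictions:
    """Per-child out-of-fold observation predictions and full surfaces.

    ``oof`` columns: observation_id + one column per child (probabilities).
    ``surfaces``: child name -> (n_years, n_pixels) probability array.
    """

    oof: pd.DataFrame
    surfaces: dict[str, np.ndarray]
    folds: np.ndarray
    hyperparameters: dict = field(default_factory=dict)

    @property
    def child_names(self) -> list[str]:
        return [c for c in self.oof.columns if c != "observation_id"]

    def surface_array(self) -> np.ndarray:
        """(n_children, n_years, n_pixels), child order matching ``oof``."""
        return np.stack([self.surfaces[c] for c in self.child_names])


def assign_folds(
    obs: pd.DataFrame,
    n_folds: int,
    seed: int | np.random.Generator,
    spatial: bool = True,
) -> np.ndarray:
    """Spatially stratified fold labels (0..n_folds-1) per observation.

    Observations are grouped by LGA (column ``lga_id``); LGAs are shuffled
    and dealt round-robin to folds so same-LGA clusters always share a fold
    and fold sizes are within one LGA of balance.  With fewer LGAs than
    folds (or ``spatial=False``) the assignment falls back to random
    cluster-level folds with a warning.
    """
    if n_folds < 2:
        raise DataError("n_folds must be >= 2")
    if len(obs) < n_folds:
        raise DataError("need at least one observation per fold")
    rng = np.random.default_rng(seed)

    if spatial and "lga_id" in obs.columns:
        lgas = sorted(pd.unique(obs["lga_id"]))
        if len(lgas) >= n_folds:
            order = list(rng.permutation(len(lgas)))
            fold_of_lga = {lgas[j]: i % n_folds for i, j in enumerate(order)}
            return obs["lga_id"].map(fold_of_lga).to_numpy()
        warnings.warn(
            f"only {len(lgas)} LGAs for {n_folds} folds; "
            "falling back to random cluster-level folds",
            RuntimeWarning,
            stacklevel=2,
        )
    if "cluster_id" in obs.columns:
        clusters = sorted(pd.unique(obs["cluster_id"]))
        labels = rng.permuted(np.arange(len(clusters)) % n_folds)
        fold_of_cluster = dict(zip(clusters, labels))
        return obs["cluster_id"].map(fold_of_cluster).to_numpy()
    return rng.permuted(np.arange(len(obs)) % n_folds)


# ---------------------------------------------------------------------------
# child learners (contract: fit(X, k, n) then predict_proba(X) -> p)


def _bernoulli_expand(x: np.ndarray, k: np.ndarray, n: np.ndarray):
    """Duplicate rows into (outcome 1, weight k) and (outcome 0, weight n-k)."""
    y = np.concatenate([np.ones(len(x)), np.zeros(len(x))])
    w = np.concatenate([k, n - k]).astype(float)
    xx = np.vstack([x, x])
    keep = w > 0
    return xx[keep], y[keep], w[keep]


class _AdditiveSmoothChild:
    """Additive smooth logistic model: per-covariate B-spline basis + ridge."""

    name = CHILD_NAMES[0]
    hyperparameters = {"n_knots": 5, "degree": 3, "C": 1.0}

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, x, k, n):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import SplineTransformer, StandardScaler

        self._pipe = make_pipeline(
            StandardScaler(),
            SplineTransformer(
                n_knots=self.hyperparameters["n_knots"],
                degree=self.hyperparameters["degree"],
                extrapolation="constant",
            ),
            LogisticRegression(C=self.hyperparameters["C"], max_iter=2000),
        )
        xx, y, w = _bernoulli_expand(x, k, n)
        self._pipe.fit(xx, y, logisticregression__sample_weight=w)
        return self

    def predict_proba(self, x):
        return self._pipe.predict_proba(x)[:, 1]


class _LassoLogisticChild:
    """L1-penalized logistic regression, penalty chosen by internal CV."""

    name = CHILD_NAMES[1]
    hyperparameters = {"Cs": 8, "cv": 3}

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, x, k, n):
        from sklearn.linear_model import LogisticRegressionCV
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        self._pipe = make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                Cs=self.hyperparameters["Cs"],
                cv=self.hyperparameters["cv"],
                l1_ratios=(1.0,),
                solver="liblinear",
                scoring="neg_log_loss",
                # liblinear penalizes the intercept; a large scaling makes
                # that penalty negligible
                intercept_scaling=50.0,
                use_legacy_attributes=False,
                max_iter=2000,
                random_state=self.seed,
            ),
        )
        xx, y, w = _bernoulli_expand(x, k, n)
        self._pipe.fit(xx, y, logisticregressioncv__sample_weight=w)
        return self

    def predict_proba(self, x):
        return self._pipe.predict_proba(x)[:, 1]


class _BoostedTreesChild:
    """Gradient-boosted regression trees (xgboost, logistic objective)."""

    name = CHILD_NAMES[2]
    # weights are child counts, so min_child_weight and gamma are in
    # children-equivalent units; tuned to ignore pure noise at desk scale
    hyperparameters = {
        "n_estimators": 100, "max_depth": 3, "learning_rate": 0.05,
        "min_child_weight": 50.0, "gamma": 1.0, "reg_lambda": 5.0,
    }

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, x, k, n):
        import xgboost as xgb

        self._clf = xgb.XGBClassifier(
            **self.hyperparameters,
            objective="binary:logistic",
            n_jobs=1,
            random_state=self.seed,
            verbosity=0,
        )
        xx, y, w = _bernoulli_expand(x, k, n)
        if len(np.unique(y)) < 2:  # xgboost requires both classes
            raise ValueError("single-class outcome")
        self._clf.fit(xx, y, sample_weight=w)
        return self

    def predict_proba(self, x):
        return self._clf.predict_proba(x)[:, 1]


_CHILD_CLASSES = {
    CHILD_NAMES[0]: _AdditiveSmoothChild,
    CHILD_NAMES[1]: _LassoLogisticChild,
    CHILD_NAMES[2]: _BoostedTreesChild,
}


def _safe_fit_predict(child_cls, seed, x_fit, k_fit, n_fit, x_targets):
    """Fit one child and predict on target matrices; degrade to the
    observation-weighted mean rate if the child fails."""
    try:
        child = child_cls(seed=seed).fit(x_fit, k_fit, n_fit)
        return [child.predict_proba(xt) for xt in x_targets]
    except Exception as exc:  # noqa: BLE001 - graceful stack degradation
        rate = float(k_fit.sum() / n_fit.sum())
        warnings.warn(
            f"child {child_cls.name} failed ({exc}); using mean rate {rate:.3f}",
            RuntimeWarning,
            stacklevel=2,
        )
        return [np.full(len(xt), rate) for xt in x_targets]


def fit_child_models(
    obs: pd.DataFrame,
    stack: CovariateStack,
    selected: list[str],
    folds: np.ndarray,
    seed: int,
    trials_col: str = "N",
    successes_col: str = "k1",
) -> ChildPredictions:
    """Fit the three children with out-of-fold prediction and full surfaces.

    ``obs`` needs observation_id, pixel_id, a year column (``cohort_year``
    or ``year``), trials and successes columns; rows with zero trials must
    already be dropped (stage 2 tables drop rows with k1 = 0).  For each
    fold, children are fit on the other folds and predict the held-out
    fold; a separate all-data fit predicts every (pixel, year).
    Predictions are clipped to [1e-4, 1 - 1e-4].
    """
    obs = obs.reset_index(drop=True)
    year_col = "cohort_year" if "cohort_year" in obs.columns else "year"
    if (obs[trials_col] <= 0).any():
        raise DataError("rows with zero trials must be dropped before stacking")
    folds = np.asarray(folds)
    if len(folds) != len(obs):
        raise DataError("fold labels do not align with observations")

    sel_idx = [stack.names.index(s) for s in selected]
    x_obs = stack.at(obs["pixel_id"].to_numpy(), obs[year_col].to_numpy())[:, sel_idx]
    x_all = stack.design_matrix()[:, sel_idx]  # (n_years*n_pixels, k) time-major
    k = obs[successes_col].to_numpy(dtype=float)
    n = obs[trials_col].to_numpy(dtype=float)

    n_years, n_pix = len(stack.years), stack.grid.n_pixels
    oof = {name: np.empty(len(obs)) for name in CHILD_NAMES}
    surfaces = {}
    for name, cls in _CHILD_CLASSES.items():
        for f in np.unique(folds):
            mask = folds == f
            preds = _safe_fit_predict(
                cls, seed, x_obs[~mask], k[~mask], n[~mask], [x_obs[mask]]
            )
            oof[name][mask] = preds[0]
        (surface_flat,) = _safe_fit_predict(cls, seed, x_obs, k, n, [x_all])
        surfaces[name] = np.clip(
            surface_flat.reshape(n_years, n_pix), _CLIP, 1 - _CLIP
        )
        oof[name] = np.clip(oof[name], _CLIP, 1 - _CLIP)

    oof_df = pd.DataFrame({"observation_id": obs["observation_id"]
                           if "observation_id" in obs.columns
                           else np.arange(len(obs))})
    for name in CHILD_NAMES:
        oof_df[name] = oof[name]
    return ChildPredictions(
        oof=oof_df,
        surfaces=surfaces,
        folds=folds,
        hyperparameters={n: c.hyperparameters for n, c in _CHILD_CLASSES.items()},
    )
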