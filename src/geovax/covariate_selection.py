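"""Variance-inflation-factor pruning of the covariate set.

Multicollinear covariate layers destabilize the downstream child learners,
so before stacking the covariate set is pruned by iteratively removing the
covariate with the highest VIF until every remaining VIF is at or below a
threshold (default 5).  VIF_j = 1 / (1 - R^2_j), with R^2_j from an OLS
regression (with intercept) of covariate j on all the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_io import DataError

__all__ = ["VifReport", "compute_vif", "prune_by_vif"]

VIF_INF = np.inf  # sentinel for perfect collinearity (R^2 == 1)


@dataclass
class VifReport:
    """Iteration log of the pruning loop plus the final covariate set."""

    log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["iteration", "covariate", "vif", "removed"]
        )
    )
    selected: list[str] = field(default_factory=list)
    threshold: float = 5.0

    def removal_order(self) -> list[str]:
        removed = self.log[self.log["removed"]]
        return removed.sort_values("iteration")["covariate"].tolist()

    def to_csv(self, path) -> None:
        self.log.to_csv(path, index=False)


def compute_vif(design: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Per-column variance inflation factors of a design matrix.

    Requires at least two non-constant columns and more rows than columns.
    Perfectly collinear columns get the +inf sentinel.
    """
    if isinstance(design, pd.DataFrame):
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim != 2:
        raise DataError("design must be 2-D (observations x covariates)")
    n, k = design.shape
    if k < 2:
        raise DataError("VIF needs at least 2 covariates")
    if n <= k:
        raise DataError(f"VIF needs more rows ({n}) than covariates ({k})")
    stds = design.std(axis=0)
    if (stds == 0).any():
        bad = np.flatnonzero(stds == 0).tolist()
        raise DataError(f"constant covariate column(s) at index {bad}")

    vifs = np.empty(k)
    intercept = np.ones((n, 1))
    for j in range(k):
        y = design[:, j]
        x = np.hstack([intercept, np.delete(design, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            vifs[j] = VIF_INF
        else:
            vifs[j] = 1.0 / (1.0 - r2)
    return vifs


def prune_by_vif(
    design: np.ndarray | pd.DataFrame,
    threshold: float = 5.0,
    names: list[str] | None = None,
) -> VifReport:
    """Iteratively remove the highest-VIF covariate until all VIFs <= threshold.

    One covariate is removed per iteration (ties broken by column order:
    the earliest column is kept, so the last of the tied columns is the one
    removed); the loop stops when every VIF is at or below the threshold or
    a single covariate remains.  The design is typically the covariate
    stack sampled at the observation sites.
    """
    if not threshold > 1:
        raise DataError("VIF threshold must be > 1")
    if isinstance(design, pd.DataFrame):
        if names is None:
            names = list(design.columns)
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(design.shape[1])]
    if len(names) != design.shape[1]:
        raise DataError("names do not match design columns")

    active = list(range(design.shape[1]))
    rows = []
    iteration = 0
    while len(active) > 1:
        vifs = compute_vif(design[:, active])
        # tie rule: earliest column survives, the last tied maximum is removed
        worst = int(np.flatnonzero(vifs == vifs.max())[-1])
        remove = vifs[worst] > threshold
        for pos, col in enumerate(active):
            rows.append(
                {"iteration": iteration, "covariate": names[col],
                 "vif": vifs[pos], "removed": bool(remove and pos == worst)}
            )
        if not remove:
            break
        del active[worst]
        iteration += 1
    report = VifReport(
        log=pd.DataFrame(rows, columns=["iteration", "covariate", "vif", "removed"]),
        selected=[names[c] for c in active],
        threshold=float(threshold),
    )
    return report
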