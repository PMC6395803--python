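"""Can site indicator values be predicted from mapped predictors?

If a site EIV were merely a (possibly complex) combination of the mapped
environmental layers, a flexible regression should predict it well from
those layers.  This module fits four regression techniques (GLM with
linear + quadratic terms, GAM with univariate smooths, gradient-boosted
trees, random forest) to each site EIV dimension and scores them by
Pearson correlation and RMSE of predicted versus field-recorded site EIVs
over 25 repeated random 70/30 splits.

Site EIVs here are all-species means: there is no focal species in this
analysis, so no leave-one-out exclusion applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from sklearn.ensemble import (
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "EIV_MAPPING_TECHNIQUES",
    "EIVMappingResult",
    "cross_validate_eiv",
    "map_all_dimensions",
]

logger = logging.getLogger(__name__)

EIV_MAPPING_TECHNIQUES = ("GLM", "GAM", "GBM", "RF")


@dataclass
class EIVMappingResult:
    dimension: str
    technique: str
    fold_results: pd.DataFrame  # columns: repeat, pearson_r, rmse
    mean_r: float = field(init=False)
    sd_r: float = field(init=False)
    mean_rmse: float = field(init=False)
    sd_rmse: float = field(init=False)

    def __post_init__(self) -> None:
        r = self.fold_results["pearson_r"].dropna()
        rmse = self.fold_results["rmse"]
        self.mean_r = float(r.mean()) if len(r) else float("nan")
        self.sd_r = float(r.std(ddof=1)) if len(r) > 1 else float("nan")
        self.mean_rmse = float(rmse.mean())
        self.sd_rmse = float(rmse.std(ddof=1)) if len(rmse) > 1 else float(
            "nan"
        )


def _fit_predict(technique, X_tr, y_tr, X_te, seed, hp):
    if technique == "GLM":
        Z_tr = np.hstack([X_tr, X_tr**2])
        Z_te = np.hstack([X_te, X_te**2])
        reg = LinearRegression().fit(Z_tr, y_tr)
        return reg.predict(Z_te)
    if technique == "GAM":
        keep = X_tr.std(axis=0) > 0
        Xs, Xn = X_tr[:, keep], X_te[:, keep]
        k = Xs.shape[1]
        bs = BSplines(Xs, df=[4] * k, degree=[3] * k)
        res = GLMGam(
            y_tr, exog=np.ones((len(y_tr), 1)), smoother=bs,
            family=sm.families.Gaussian(),
        ).fit()
        Xn = np.clip(Xn, Xs.min(axis=0), Xs.max(axis=0))
        return np.asarray(
            res.predict(exog=np.ones((len(Xn), 1)), exog_smooth=Xn)
        )
    if technique == "GBM":
        reg = GradientBoostingRegressor(
            n_estimators=int(hp.get("n_estimators", 500)),
            max_depth=int(hp.get("max_depth", 3)),
            learning_rate=float(hp.get("learning_rate", 0.05)),
            random_state=seed,
        )
        return reg.fit(X_tr, y_tr).predict(X_te)
    if technique == "RF":
        reg = RandomForestRegressor(
            n_estimators=int(hp.get("n_estimators", 500)),
            random_state=seed, n_jobs=1,
        )
        return reg.fit(X_tr, y_tr).predict(X_te)
    raise ValueError(
        f"unknown technique {technique!r}; expected one of "
        f"{EIV_MAPPING_TECHNIQUES}"
    )


def cross_validate_eiv(
    site_eiv_values: pd.Series,
    predictors: pd.DataFrame,
    technique: str = "GLM",
    n_repeats: int = 25,
    seed: int = 0,
    test_fraction: float = 0.3,
    dimension: str | None = None,
    hyperparameters: dict | None = None,
) -> EIVMappingResult:
    """Repeated random-split cross-validation of one site-EIV dimension.

    Each repeat draws an independent seeded 70/30 split, fits on the 70%
    and scores Pearson r and RMSE of predicted versus observed site EIVs
    on the 30%.  Repeats whose test fold has constant observations leave
    r undefined; they are skipped in the mean (logged).
    """
    hp = hyperparameters or {}
    data = pd.concat([site_eiv_values.rename("y"), predictors], axis=1)
    data = data.dropna()
    if len(data) < 10:
        raise ValueError(f"need >= 10 complete plots, got {len(data)}")
    y = data["y"].to_numpy(dtype=float)
    X = data.drop(columns="y").to_numpy(dtype=float)
    n = len(y)
    n_test = int(np.floor(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError("test fold would be empty")

    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_repeats), start=1):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        fold_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        pred = _fit_predict(
            technique, X[train], y[train], X[test], fold_seed, hp
        )
        rmse = float(np.sqrt(np.mean((pred - y[test]) ** 2)))
        if np.std(y[test]) == 0 or np.std(pred) == 0:
            logger.info("repeat %d: constant fold, r undefined", rep)
            r = np.nan
        else:
            r = float(pearsonr(pred, y[test])[0])
        rows.append({"repeat": rep, "pearson_r": r, "rmse": rmse})
    return EIVMappingResult(
        dimension=dimension or str(site_eiv_values.name),
        technique=technique,
        fold_results=pd.DataFrame(rows),
    )


def map_all_dimensions(
    site_eivs: pd.DataFrame,
    predictors: pd.DataFrame,
    techniques=("GLM", "GAM", "GBM", "RF"),
    n_repeats: int = 25,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> pd.DataFrame:
    """Cross-validate every dimension x technique; tidy summary table."""
    rows = []
    ss = np.random.SeedSequence(seed)
    combos = [(d, t) for d in site_eivs.columns for t in techniques]
    for (dim, tech), child in zip(combos, ss.spawn(len(combos))):
        res = cross_validate_eiv(
            site_eivs[dim], predictors, technique=tech,
            n_repeats=n_repeats,
            seed=int(child.generate_state(1)[0]) & 0x7FFFFFFF,
            dimension=dim,
            hyperparameters=hyperparameters,
        )
        rows.append(
            dict(dimension=dim, technique=tech, mean_r=res.mean_r,
                 sd_r=res.sd_r, mean_rmse=res.mean_rmse,
                 sd_rmse=res.sd_rmse)
        )
    return pd.DataFrame(rows)
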