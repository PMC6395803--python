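"""Species distribution model engines behind one fit/predict contract.

Five techniques, all returning habitat-suitability scores in [0, 1]:

* ``GLM`` — binomial regression with linear + quadratic terms per
  predictor and a tiny ridge penalty that keeps coefficients finite under
  perfect separation.
* ``GAM`` — binomial model with univariate B-spline smooths (basis
  dimension 4 per predictor).
* ``RF`` — classification random forest; score is the presence-vote
  fraction.
* ``MAXENT`` — an L2-regularised presence/background binomial model on
  linear + quadratic features; with presence/absence plot data the
  absences serve as background.
* ``SRE`` — surface range envelope: a two-sided per-predictor quantile
  envelope of the presence points; scores are 0/1.

Quadratic terms are computed on standardised predictors to limit
collinearity.  Predictions from a fitted model are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from statsmodels.gam.api import BSplines, GLMGam

from .evaluation import binomial_deviance

__all__ = ["TECHNIQUES", "ModelSpec", "FittedSDM", "fit_sdm", "predict_sdm",
           "glm_from_coefficients"]

logger = logging.getLogger(__name__)

TECHNIQUES = ("GLM", "GAM", "RF", "MAXENT", "SRE")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "GLM": {"ridge": 1e-6},
    "GAM": {"df": 4, "degree": 3},
    "RF": {"n_estimators": 500},
    "MAXENT": {"l2": 1.0},
    "SRE": {"quantile": 0.025},
}


@dataclass(frozen=True)
class ModelSpec:
    technique: str
    predictor_names: tuple[str, ...]
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(
                f"unknown technique {self.technique!r}; expected one of "
                f"{TECHNIQUES}"
            )
        names = tuple(self.predictor_names)
        if not names:
            raise ValueError("predictor_names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate predictor names in {names}")
        object.__setattr__(self, "predictor_names", names)

    def param(self, key: str):
        return self.hyperparameters.get(key, _DEFAULTS[self.technique][key])


@dataclass
class FittedSDM:
    spec: ModelSpec
    n_plots: int
    n_presences: int
    state: dict[str, Any]
    #: (null deviance, residual deviance) on training data; GLM/GAM only
    training_deviance_pair: tuple[float, float] | None = None


def _validate_matrix(spec: ModelSpec, X: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in spec.predictor_names if c not in X.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    extra = [c for c in X.columns if c not in spec.predictor_names]
    if extra:
        raise ValueError(f"unexpected predictor columns: {extra}")
    X = X[list(spec.predictor_names)]
    if X.isna().to_numpy().any():
        raise ValueError("predictor matrix contains missing values")
    return X


def _standardise(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe_sd, mean, safe_sd


def _quad_features(Z: np.ndarray) -> np.ndarray:
    return np.hstack([Z, Z**2])


def fit_sdm(spec: ModelSpec, X: pd.DataFrame, y) -> FittedSDM:
    """Fit one technique on a plot x predictor matrix and 0/1 presences."""
    X = _validate_matrix(spec, X)
    y = np.asarray(y, dtype=int)
    if len(y) != len(X):
        raise ValueError("X and y lengths differ")
    n_pres = int(y.sum())
    if n_pres == 0 or n_pres == len(y):
        raise ValueError("need at least one presence and one absence")
    Xv = X.to_numpy(dtype=float)
    const = Xv.std(axis=0) == 0
    if const.any():
        logger.warning(
            "constant predictor column(s) retained: %s",
            [c for c, k in zip(spec.predictor_names, const) if k],
        )

    state: dict[str, Any] = {}
    dev_pair = None

    if spec.technique in ("GLM", "MAXENT"):
        Z, mean, sd = _standardise(Xv)
        F = _quad_features(Z)
        if spec.technique == "GLM":
            c_inv = float(spec.param("ridge"))
        else:
            c_inv = float(spec.param("l2"))
        clf = LogisticRegression(
            C=1.0 / c_inv, solver="lbfgs", max_iter=2000
        )
        clf.fit(F, y)
        state = {
            "intercept": float(clf.intercept_[0]),
            "coef": clf.coef_[0].copy(),
            "mean": mean,
            "sd": sd,
        }
    elif spec.technique == "GAM":
        # constant columns carry no information and break the spline
        # basis; they are dropped from the smoother (a zero smooth)
        keep = ~const
        if not keep.any():
            raise ValueError("all predictor columns are constant")
        Xs = Xv[:, keep]
        df = int(spec.param("df"))
        degree = int(spec.param("degree"))
        k = Xs.shape[1]
        bs = BSplines(Xs, df=[df] * k, degree=[degree] * k)
        model = GLMGam(
            y.astype(float),
            exog=np.ones((len(y), 1)),
            smoother=bs,
            family=sm.families.Binomial(),
        )
        res = model.fit()
        state = {
            "res": res,
            "keep": keep,
            "clip_lo": Xs.min(axis=0),
            "clip_hi": Xs.max(axis=0),
        }
    elif spec.technique == "RF":
        clf = RandomForestClassifier(
            n_estimators=int(spec.param("n_estimators")),
            random_state=int(spec.seed) & 0x7FFFFFFF,
            n_jobs=1,
        )
        clf.fit(Xv, y)
        state = {"clf": clf}
    elif spec.technique == "SRE":
        q = float(spec.param("quantile"))
        pres = Xv[y == 1]
        state = {
            "lower": np.quantile(pres, q, axis=0),
            "upper": np.quantile(pres, 1.0 - q, axis=0),
        }

    model = FittedSDM(
        spec=spec, n_plots=len(y), n_presences=n_pres, state=state
    )
    if spec.technique in ("GLM", "GAM"):
        p = predict_sdm(model, X)
        null = binomial_deviance(np.full(len(y), y.mean()), y)
        model.training_deviance_pair = (null, binomial_deviance(p, y))
    return model


def predict_sdm(model: FittedSDM, X_new: pd.DataFrame) -> np.ndarray:
    """Suitability in [0, 1] per row of ``X_new`` (exact spec columns)."""
    X = _validate_matrix(model.spec, X_new)
    return _predict_array(model, X.to_numpy(dtype=float))


def _predict_array(model: FittedSDM, Xv: np.ndarray) -> np.ndarray:
    """Prediction on a pre-validated array in spec column order."""
    tech = model.spec.technique
    st = model.state
    if tech in ("GLM", "MAXENT"):
        Z = (Xv - st["mean"]) / st["sd"]
        eta = st["intercept"] + _quad_features(Z) @ st["coef"]
        return 1.0 / (1.0 + np.exp(-eta))
    if tech == "GAM":
        Xs = np.clip(Xv[:, st["keep"]], st["clip_lo"], st["clip_hi"])
        p = st["res"].predict(
            exog=np.ones((len(Xs), 1)), exog_smooth=Xs
        )
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    if tech == "RF":
        proba = st["clf"].predict_proba(Xv)
        j = list(st["clf"].classes_).index(1)
        return proba[:, j]
    if tech == "SRE":
        inside = (Xv >= st["lower"]) & (Xv <= st["upper"])
        return inside.all(axis=1).astype(float)
    raise AssertionError(f"unhandled technique {tech}")  # pragma: no cover


def glm_from_coefficients(
    predictor_names,
    intercept: float,
    linear,
    quadratic,
    mean=None,
    sd=None,
) -> FittedSDM:
    """Build a GLM with fixed coefficients (no fitting) — useful for
    constructing models with known behaviour."""
    names = tuple(predictor_names)
    p = len(names)
    mean = np.zeros(p) if mean is None else np.asarray(mean, dtype=float)
    sd = np.ones(p) if sd is None else np.asarray(sd, dtype=float)
    coef = np.concatenate(
        [np.asarray(linear, dtype=float), np.asarray(quadratic, dtype=float)]
    )
    spec = ModelSpec(technique="GLM", predictor_names=names)
    return FittedSDM(
        spec=spec,
        n_plots=0,
        n_presences=0,
        state={"intercept": float(intercept), "coef": coef,
               "mean": mean, "sd": sd},
    )
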