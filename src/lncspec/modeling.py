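"""PLS and random-forest regression of LNC on spectral variables.

Both learners come from scikit-learn behind a thin surface that adds the
conventions used throughout this package: PLS component count chosen by
leave-one-out CV (capped at min(p, n-1)), RF with 500 trees, p/3 features
per split and a fixed seed, and evaluation via R^2, RMSE and NRMSE.

R^2 is the standard coefficient of determination 1 - SS_res/SS_tot on
measured-vs-predicted pairs.  RMSE = sqrt(mean((y - yhat)^2)); NRMSE is
RMSE divided by the mean of the observed target (a fraction; multiply by
100 for the percent form used in reports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)

RF_DEFAULT_TREES = 500
RF_DEFAULT_SEED = 20120731


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters for one learner."""

    kind: str = "PLS"                 # "PLS" | "RF"
    n_components: int | None = None   # None: choose by LOO CV
    n_trees: int = RF_DEFAULT_TREES
    max_features: int | str | None = None  # None: max(1, p // 3)
    seed: int = RF_DEFAULT_SEED


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float
    nrmse: float  # fraction of mean(y)

    @property
    def nrmse_percent(self) -> float:
        return 100.0 * self.nrmse

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "nrmse": self.nrmse}


@dataclass
class ModelReport:
    """Calibration/validation metrics for one (feature family, learner) pair."""

    family: str
    algorithm: str
    calibration: Metrics
    validation: Metrics
    n_cal: int
    n_val: int
    coefficients: pd.Series | None = None  # PLS betas or RF importances

    def to_rows(self) -> list[dict]:
        rows = []
        for label, m, n in (("calibration", self.calibration, self.n_cal),
                            ("validation", self.validation, self.n_val)):
            rows.append({"family": self.family, "algorithm": self.algorithm,
                         "set": label, "n": n, "r2": m.r2, "rmse": m.rmse,
                         "nrmse": m.nrmse})
        return rows


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def evaluate(model, X, y) -> Metrics:
    """R^2, RMSE and NRMSE of *model* predictions on (X, y)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 samples to evaluate")
    ybar = float(np.mean(y))
    if ybar == 0:
        raise ValueError("mean of y is zero: NRMSE undefined")
    yhat = predict(model, X)
    err = rmse(y, yhat)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return Metrics(r2=r2, rmse=err, nrmse=err / ybar)


def predict(model, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.asarray(model.predict(X), dtype=float).ravel()


def _loo_pls_rmse(X: np.ndarray, y: np.ndarray, n_components: int) -> float:
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = PLSRegression(n_components=n_components, scale=True)
        m.fit(X[mask], y[mask])
        preds[i] = float(m.predict(X[i:i + 1]).ravel()[0])
    return rmse(y, preds)


def fit_pls(X, y, spec: ModelSpec | None = None):
    """Fit a PLS regression; component count by LOO CV unless given.

    Collinear (even duplicated) columns are tolerated; a requested component
    count above the matrix rank is reduced with a warning.  Returns a fitted
    ``PLSRegression`` whose final coefficients live in the original feature
    space (one beta per input column).
    """
    spec = spec or ModelSpec(kind="PLS")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.std(y) == 0:
        raise ValueError("constant y: PLS undefined")
    rank = int(np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))) - 1
    cap = max(1, min(p, n - 1, rank))
    if spec.n_components is not None:
        k = spec.n_components
        if not k >= 1:
            raise ValueError("n_components must be >= 1")
        if k > cap:
            logger.warning("n_components=%d exceeds usable rank %d; reduced", k, cap)
            k = cap
    else:
        scores = {c: _loo_pls_rmse(X, y, c) for c in range(1, cap + 1)}
        k = min(scores, key=lambda c: (scores[c], c))
    model = PLSRegression(n_components=k, scale=True)
    model.fit(X, y)
    return model


def fit_rf(X, y, spec: ModelSpec | None = None):
    """Fit a bootstrap-aggregated regression forest with OOB error tracking."""
    spec = spec or ModelSpec(kind="RF")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 samples for a forest")
    max_features = spec.max_features
    if max_features is None:
        max_features = max(1, p // 3)
    model = RandomForestRegressor(
        n_estimators=spec.n_trees, max_features=max_features,
        random_state=spec.seed, bootstrap=True, oob_score=True)
    model.fit(X, y)
    oob_pred = model.oob_prediction_
    model.oob_rmse_ = rmse(y, oob_pred)
    return model


def descriptive_stats(y) -> dict[str, float]:
    """max, min, mean, SD (n-1 denominator) and CV = SD/mean of a target."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    if mean == 0:
        raise ValueError("mean is zero: CV undefined")
    return {"max": float(np.max(y)), "min": float(np.min(y)),
            "mean": mean, "sd": sd, "cv": sd / mean}


def fit_and_report(family: str, X_cal: pd.DataFrame, y_cal, X_val: pd.DataFrame,
                   y_val, pls_spec: ModelSpec | None = None,
                   rf_spec: ModelSpec | None = None):
    """Fit PLS and RF on the calibration split; report both on both splits.

    Returns ``(reports, fitted, predictions)`` where predictions maps
    algorithm name to (yhat_cal, yhat_val).
    """
    Xc = X_cal.to_numpy(dtype=float)
    Xv = X_val.to_numpy(dtype=float)
    yc = np.asarray(y_cal, dtype=float)
    yv = np.asarray(y_val, dtype=float)
    reports, fitted, predictions = [], {}, {}
    pls = fit_pls(Xc, yc, pls_spec)
    coefs = pd.Series(np.asarray(pls.coef_).ravel(), index=X_cal.columns, name="beta")
    reports.append(ModelReport(family, "PLS", evaluate(pls, Xc, yc),
                               evaluate(pls, Xv, yv), len(yc), len(yv), coefs))
    fitted["PLS"] = pls
    predictions["PLS"] = (predict(pls, Xc), predict(pls, Xv))
    rf = fit_rf(Xc, yc, rf_spec)
    imps = pd.Series(rf.feature_importances_, index=X_cal.columns, name="importance")
    reports.append(ModelReport(family, "RF", evaluate(rf, Xc, yc),
                               evaluate(rf, Xv, yv), len(yc), len(yv), imps))
    fitted["RF"] = rf
    predictions["RF"] = (predict(rf, Xc), predict(rf, Xv))
    return reports, fitted, predictions
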