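"""W_new composite model scoring and per-channel regression model selection.

The composite metric W_new folds five regression-quality numbers into one
value in (0, 1):

    P = R2_train + R2_val            (explanatory power)
    E = MSE + RMSE + MAE             (aggregate error)
    D = |R2_train - R2_val|          (train/validation discrepancy)
    A = (1 - D) / (1 + D)            (overfitting penalty)
    W = (P / E) * A
    W_new = W / (1 + W)

W_new is only applicable when both R-squared values lie in [0, 1]; fits
outside that interval are excluded rather than clipped, which acts as a
validity gate against uninformative regressors.

`ChannelModelSelector` is a scikit-learn style estimator that trains a
twelve-model zoo (trees, KNN, boosting ensembles, linear models, SVR
variants) over a hyperparameter grid with PCA or mutual-information feature
selection, scoring every grid cell by W_new on an internal 70:30
train/validation split and keeping the best cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from functools import partial
from itertools import product
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.feature_selection import SelectKBest, mutual_info_regression
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, NuSVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from xgboost import XGBRegressor

from .chem_features import FeatureMatrix
from .errors import ConfigError, DegenerateFitError, NoValidModelError, ValidityError
from .scoring_channels import ORIENTATIONS, ChannelScores

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# W_new
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WnewBreakdown:
    """The five inputs and every intermediate of the W_new chain."""

    r2_train: float
    r2_val: float
    mae: float
    rmse: float
    mse: float
    P: float
    E: float
    D: float
    A: float
    W: float
    w_new: float


def compute_wnew(r2_train: float, r2_val: float, mae: float, rmse: float,
                 mse: float) -> WnewBreakdown:
    """Evaluate the W_new chain from the five performance metrics.

    Raises :class:`ValidityError` when either R-squared is outside [0, 1]
    (the metric's applicability range) and :class:`DegenerateFitError` when
    all three error terms vanish.
    """
    for name, r2 in (("r2_train", r2_train), ("r2_val", r2_val)):
        if not 0.0 <= r2 <= 1.0:
            raise ValidityError(f"{name}={r2} outside [0, 1]; W_new not applicable")
    if min(mae, rmse, mse) < 0:
        raise ValueError("error metrics must be non-negative")
    P = r2_train + r2_val
    E = mse + rmse + mae
    if E <= 0.0:
        raise DegenerateFitError("MSE + RMSE + MAE = 0; W_new undefined")
    D = abs(r2_train - r2_val)
    A = (1.0 - D) / (1.0 + D)
    W = (P / E) * A
    w_new = W / (1.0 + W)
    return WnewBreakdown(r2_train, r2_val, mae, rmse, mse, P, E, D, A, W, w_new)


# --------------------------------------------------------------------------
# Model zoo
# --------------------------------------------------------------------------

def _zoo(seed: int) -> dict[str, tuple[BaseEstimator, dict[str, list]]]:
    """The twelve regressors with their default hyperparameter grids."""
    return {
        "decision_tree": (DecisionTreeRegressor(random_state=seed),
                          {"max_depth": [2, 4, 8, None]}),
        "knn": (KNeighborsRegressor(),
                {"n_neighbors": [3, 5, 7, 9]}),
        "adaboost": (AdaBoostRegressor(random_state=seed),
                     {"n_estimators": [50, 200], "learning_rate": [0.05, 0.3]}),
        "random_forest": (RandomForestRegressor(random_state=seed),
                          {"n_estimators": [50, 200], "max_depth": [4, None]}),
        "linear_regression": (LinearRegression(), {}),
        "elastic_net": (ElasticNet(max_iter=10000, random_state=seed),
                        {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.2, 0.5, 0.8]}),
        "gradient_boosting": (GradientBoostingRegressor(random_state=seed),
                              {"n_estimators": [50, 200], "learning_rate": [0.05, 0.3]}),
        "xgboost": (XGBRegressor(random_state=seed, verbosity=0, n_jobs=1),
                    {"n_estimators": [50, 200], "learning_rate": [0.05, 0.3]}),
        "svr_linear": (SVR(kernel="linear"), {"C": [0.1, 1.0, 10.0]}),
        "svr_sigmoid": (SVR(kernel="sigmoid"),
                        {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]}),
        "svr_rbf": (SVR(kernel="rbf"),
                    {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]}),
        "nu_svr": (NuSVR(kernel="rbf"), {"nu": [0.25, 0.5, 0.75]}),
    }


MODEL_NAMES = tuple(_zoo(0).keys())
SELECTORS = ("pca", "mutual_information")
DEFAULT_SELECTOR_SIZES = (10, 25, 50)


@dataclass
class ModelEvalReport:
    """One fitted grid cell: metrics, W_new breakdown, and hyperparameters."""

    channel: str
    model_name: str
    selector: str
    selector_size: int
    hyperparameters: dict[str, Any]
    cv_folds: int
    breakdown: WnewBreakdown | None
    valid: bool
    invalid_reason: str | None = None
    r2_external: float | None = None
    estimator: Any = field(default=None, repr=False, compare=False)
    feature_names: list[str] | None = field(default=None, repr=False, compare=False)

    @property
    def w_new(self) -> float | None:
        return self.breakdown.w_new if self.breakdown is not None else None

    def to_json(self) -> str:
        payload = {
            "channel": self.channel,
            "model_name": self.model_name,
            "selector": self.selector,
            "selector_size": self.selector_size,
            "hyperparameters": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                                    else repr(v))
                                for k, v in self.hyperparameters.items()},
            "cv_folds": self.cv_folds,
            "breakdown": asdict(self.breakdown) if self.breakdown else None,
            "valid": self.valid,
            "invalid_reason": self.invalid_reason,
            "r2_external": self.r2_external,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _make_front_end(selector: str, size: int, seed: int) -> Pipeline:
    """Scaling + feature-selection front end shared by every grid cell."""
    if selector == "pca":
        sel = PCA(n_components=size, random_state=seed)
    elif selector == "mutual_information":
        sel = SelectKBest(partial(mutual_info_regression, random_state=seed), k=size)
    else:
        raise ConfigError(f"unknown selector {selector!r}; valid: {SELECTORS}")
    return Pipeline([("scale", StandardScaler()), ("select", sel)])


class ChannelModelSelector(BaseEstimator, RegressorMixin):
    """Select the best regressor for one score channel by W_new.

    Parameters
    ----------
    channel : str
        Channel label carried into reports ("qsar", "similarity", ...).
    models : sequence of str or None
        Subset of the twelve-model zoo to evaluate (None = all twelve).
    selector : {"mutual_information", "pca"}
        Feature-selection route applied before each regressor.
    selector_sizes : sequence of int
        Candidate numbers of retained components / top-k features.
    train_frac : float
        Fraction of the fitted data used for training; the remainder is the
        validation partition on which R2_val/MAE/RMSE/MSE are measured.
    mode : {"wnew", "cv"}
        "wnew" ranks grid cells directly by W_new on the internal split;
        "cv" ranks by cross-validated RMSE and uses W_new only for the
        final report.
    cv_folds : int
        Folds for the "cv" mode (recorded in every report).
    split_seed, grid_seed : int
        Seeds for the internal split and for stochastic model components.

    Attributes
    ----------
    best_report_ : ModelEvalReport
    reports_ : list of ModelEvalReport (every grid cell, valid or not)
    best_estimator_ : fitted sklearn Pipeline
    """

    def __init__(self, channel: str = "qsar", models: Sequence[str] | None = None,
                 selector: str = "mutual_information",
                 selector_sizes: Sequence[int] = DEFAULT_SELECTOR_SIZES,
                 train_frac: float = 0.7, mode: str = "wnew", cv_folds: int = 5,
                 split_seed: int = 0, grid_seed: int = 1):
        self.channel = channel
        self.models = models
        self.selector = selector
        self.selector_sizes = selector_sizes
        self.train_frac = train_frac
        self.mode = mode
        self.cv_folds = cv_folds
        self.split_seed = split_seed
        self.grid_seed = grid_seed

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if len(y) < 10:
            raise ValueError(f"need at least 10 training compounds, got {len(y)}")
        if self.selector not in SELECTORS:
            raise ConfigError(f"unknown selector {self.selector!r}; valid: {SELECTORS}")
        if self.mode not in ("wnew", "cv"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        zoo = _zoo(self.grid_seed)
        names = list(self.models) if self.models is not None else list(zoo)
        unknown = [m for m in names if m not in zoo]
        if unknown:
            raise ConfigError(
                f"unknown model name(s) {unknown}; valid models: {sorted(zoo)}")

        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, train_size=self.train_frac, random_state=self.split_seed)
        max_size = min(X.shape[1], len(y_tr))
        sizes = sorted({min(s, max_size) for s in self.selector_sizes})

        # The selection transform depends only on the training partition and
        # the size, so fit it once per size and share it across grid cells.
        front_ends: dict[int, tuple[Pipeline, np.ndarray, np.ndarray]] = {}
        for size in sizes:
            front = _make_front_end(self.selector, size, self.grid_seed)
            T_tr = front.fit_transform(X_tr, y_tr)
            T_val = front.transform(X_val)
            front_ends[size] = (front, T_tr, T_val)

        reports: list[ModelEvalReport] = []
        for name in names:
            base, grid = zoo[name]
            keys = list(grid)
            for combo in product(*(grid[k] for k in keys)) if keys else [()]:
                params = dict(zip(keys, combo))
                if name == "knn" and params.get("n_neighbors", 1) > len(y_tr):
                    continue
                for size in sizes:
                    front, T_tr, T_val = front_ends[size]
                    model = clone(base).set_params(**params)
                    reports.append(self._evaluate_cell(
                        front, model, name, params, size,
                        T_tr, y_tr, T_val, y_val))
        best = select_best(reports)
        self.reports_ = reports
        self.best_report_ = best
        self.best_estimator_ = best.estimator
        self.n_features_in_ = X.shape[1]
        return self

    def _evaluate_cell(self, front, model, name, params, size,
                       T_tr, y_tr, T_val, y_val) -> ModelEvalReport:
        common = dict(channel=self.channel, model_name=name, selector=self.selector,
                      selector_size=size, hyperparameters=dict(params),
                      cv_folds=self.cv_folds)
        try:
            model.fit(T_tr, y_tr)
        except Exception as exc:  # a cell that cannot fit is invalid, not fatal
            return ModelEvalReport(**common, breakdown=None, valid=False,
                                   invalid_reason=f"fit failed: {exc}")
        pipe = Pipeline(list(front.steps) + [("model", model)])
        r2_train = r2_score(y_tr, model.predict(T_tr))
        pred_val = model.predict(T_val)
        r2_val = r2_score(y_val, pred_val)
        mae = mean_absolute_error(y_val, pred_val)
        mse = mean_squared_error(y_val, pred_val)
        rmse = float(np.sqrt(mse))
        try:
            breakdown = compute_wnew(r2_train, r2_val, mae, rmse, mse)
        except (ValidityError, DegenerateFitError) as exc:
            return ModelEvalReport(**common, breakdown=None, valid=False,
                                   invalid_reason=str(exc), estimator=pipe)
        if self.mode == "cv":
            # cv mode re-ranks by cross-validated RMSE (selection held fixed)
            score = cross_val_score(
                clone(model), T_tr, y_tr, cv=min(self.cv_folds, len(y_tr)),
                scoring="neg_root_mean_squared_error").mean()
            common["hyperparameters"]["cv_neg_rmse"] = float(score)
        return ModelEvalReport(**common, breakdown=breakdown, valid=True,
                               estimator=pipe)

    # -- prediction -------------------------------------------------------
    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        X = check_array(X)
        return self.best_estimator_.predict(X)

    def external_r2(self, X, y) -> float:
        """R-squared of the selected model on a held-out external set."""
        check_is_fitted(self, "best_estimator_")
        X, y = check_X_y(X, y, y_numeric=True)
        r2 = float(r2_score(y, self.best_estimator_.predict(X)))
        self.best_report_.r2_external = r2
        return r2


def select_best(reports: Sequence[ModelEvalReport]) -> ModelEvalReport:
    """The valid report with maximal w_new.

    Ties break to the higher validation R-squared, then to the
    lexicographically smaller model name; cv-mode reports rank by their
    cross-validated RMSE instead.
    """
    valid = [r for r in reports if r.valid and r.breakdown is not None]
    if not valid:
        reasons = {f"{r.model_name}/{r.selector_size}": r.invalid_reason
                   for r in reports}
        raise NoValidModelError(f"no grid cell passed the validity gate: {reasons}")
    if any("cv_neg_rmse" in r.hyperparameters for r in valid):
        key = lambda r: (r.hyperparameters.get("cv_neg_rmse", -np.inf),
                         r.breakdown.r2_val, _RevStr(r.model_name))
    else:
        key = lambda r: (r.breakdown.w_new, r.breakdown.r2_val, _RevStr(r.model_name))
    return max(valid, key=key)


class _RevStr(str):
    """max() prefers the lexicographically smaller name on full ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


# --------------------------------------------------------------------------
# FeatureMatrix-level conveniences
# --------------------------------------------------------------------------

def evaluate_model(features: FeatureMatrix, targets: Mapping[str, float] | pd.Series,
                   channel: str = "qsar", model_name: str = "linear_regression",
                   selector: str = "mutual_information",
                   selector_sizes: Sequence[int] = DEFAULT_SELECTOR_SIZES,
                   split_seed: int = 0, grid_seed: int = 1,
                   cv_folds: int = 5, mode: str = "wnew") -> ModelEvalReport:
    """Fit one named model (its whole grid) on a feature matrix and return
    the best cell's report."""
    sel = fit_channel_selector(features, targets, channel=channel,
                               models=[model_name], selector=selector,
                               selector_sizes=selector_sizes, split_seed=split_seed,
                               grid_seed=grid_seed, cv_folds=cv_folds, mode=mode)
    return sel.best_report_


def fit_channel_selector(features: FeatureMatrix,
                         targets: Mapping[str, float] | pd.Series,
                         **kwargs) -> ChannelModelSelector:
    """Fit a :class:`ChannelModelSelector` on the compounds that carry a
    target, in feature-matrix row order."""
    targets = pd.Series(dict(targets)) if not isinstance(targets, pd.Series) else targets
    ids = [c for c in features.compound_ids if c in targets.index]
    fm = features.select(ids)
    selector = ChannelModelSelector(**kwargs)
    selector.fit(fm.values, targets.loc[ids].to_numpy(dtype=float))
    selector.feature_names_ = list(fm.feature_names)
    selector.best_report_.feature_names = list(fm.feature_names)
    return selector


def external_r2(report: ModelEvalReport, features: FeatureMatrix,
                targets: Mapping[str, float] | pd.Series) -> float:
    """Coefficient of determination of a report's fitted model on an
    external set; stored back into the report."""
    if report.estimator is None:
        raise ValueError("report carries no fitted estimator")
    targets = pd.Series(dict(targets)) if not isinstance(targets, pd.Series) else targets
    ids = [c for c in features.compound_ids if c in targets.index]
    if not ids:
        raise ValueError("external set is empty")
    fm = features.select(ids)
    _check_feature_names(report, fm)
    y = targets.loc[ids].to_numpy(dtype=float)
    r2 = float(r2_score(y, report.estimator.predict(fm.values)))
    report.r2_external = r2
    return r2


def predict_channel_scores(report: ModelEvalReport,
                           features: FeatureMatrix) -> ChannelScores:
    """Model predictions for every compound in the feature matrix, in the
    channel's raw-score units and orientation."""
    if report.estimator is None:
        raise ValueError("report carries no fitted estimator")
    _check_feature_names(report, features)
    preds = report.estimator.predict(features.values)
    return ChannelScores(report.channel,
                         pd.Series(preds, index=features.compound_ids),
                         ORIENTATIONS.get(report.channel, "higher_better"))


def _check_feature_names(report: ModelEvalReport, features: FeatureMatrix) -> None:
    if report.feature_names is not None and \
            list(features.feature_names) != list(report.feature_names):
        raise ConfigError(
            "feature names differ from the configuration the model was "
            "trained with")


def leaderboard(reports: Sequence[ModelEvalReport]) -> pd.DataFrame:
    """All grid cells as one table, best first."""
    rows = []
    for r in reports:
        row = {"channel": r.channel, "model": r.model_name, "selector": r.selector,
               "selector_size": r.selector_size, "valid": r.valid,
               "invalid_reason": r.invalid_reason,
               "hyperparameters": json.dumps(
                   {k: v for k, v in r.hyperparameters.items()}, sort_keys=True,
                   default=repr)}
        if r.breakdown is not None:
            row.update(asdict(r.breakdown))
        rows.append(row)
    df = pd.DataFrame(rows)
    if "w_new" in df.columns:
        df = df.sort_values("w_new", ascending=False, na_position="last",
                            kind="mergesort").reset_index(drop=True)
    return df
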