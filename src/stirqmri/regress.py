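"""Seven regression models, seeded 5-fold cross-validation and the
study's evaluation statistics (MAE, fold-mean MAE, coefficient of
variation, Pearson/Spearman screens).

The model set spans parametric (linear, ridge, lasso) and non-parametric
(decision tree, random forest, k-nearest-neighbor, RBF support vector)
regressors, all with fixed documented hyperparameters — the comparison is
between workflows and model families, not a tuning exercise. Features are
standardized inside the CV loop with training-fold statistics only, and
an optional per-fold reducer (PCA or imbalance-based subset selection)
is refit on each training fold, so no information leaks from held-out
subjects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

MODEL_NAMES = ("LR", "Ridge", "Lasso", "TREE", "RF", "KNN", "SVM")

#: fixed defaults; all logged with each run
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "LR": {},
    "Ridge": {"alpha": 1.0},
    "Lasso": {"alpha": 0.01, "max_iter": 50_000},
    "TREE": {"max_depth": 5},
    "RF": {"n_estimators": 100},
    "KNN": {"n_neighbors": 5},
    "SVM": {"kernel": "rbf", "C": 1.0, "epsilon": 0.1},
}


@dataclass
class ModelSpec:
    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name: {self.name!r}; "
                             f"expected one of {MODEL_NAMES}")
        merged = dict(DEFAULT_HYPERPARAMS[self.name])
        merged.update(self.hyperparams)
        self.hyperparams = merged

    def build(self):
        hp = self.hyperparams
        if self.name == "LR":
            return LinearRegression(**hp)
        if self.name == "Ridge":
            return Ridge(**hp)
        if self.name == "Lasso":
            return Lasso(**hp)
        if self.name == "TREE":
            return DecisionTreeRegressor(random_state=self.seed, **hp)
        if self.name == "RF":
            return RandomForestRegressor(random_state=self.seed, **hp)
        if self.name == "KNN":
            return KNeighborsRegressor(**hp)
        return SVR(**hp)


def mae(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error, (1/N) sum |y_i - yhat_i|."""
    y = np.asarray(y, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.abs(y - y_pred).mean())


@dataclass
class CvResult:
    fold_maes: list[float]             # one MAE per fold
    mean_mae: float                    # arithmetic mean over folds
    sd: float                          # sample (k-1) SD across folds
    predictions: np.ndarray            # aligned with the input rows
    fold_assignment: np.ndarray        # fold index per row


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded shuffle into k contiguous folds of near-equal size
    (sizes differ by at most 1); returns the fold index per row."""
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return assignment


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def fit_predict(spec: ModelSpec, x_train: np.ndarray, y_train: np.ndarray,
                x_test: np.ndarray) -> np.ndarray:
    """Fit one model on (already standardized) training rows and predict
    the test rows."""
    x_train = np.atleast_2d(np.asarray(x_train, dtype=np.float64))
    x_test = np.atleast_2d(np.asarray(x_test, dtype=np.float64))
    if x_train.shape[0] == 1 and np.asarray(y_train).size != 1:
        x_train = x_train.T
    if x_test.shape[0] == 1 and x_train.shape[1] == 1:
        x_test = x_test.T
    model = spec.build()
    hp = dict(spec.hyperparams)
    if spec.name == "KNN":
        hp["n_neighbors"] = min(hp["n_neighbors"], x_train.shape[0])
        model = KNeighborsRegressor(**hp)
    model.fit(x_train, np.asarray(y_train, dtype=np.float64))
    return np.asarray(model.predict(x_test), dtype=np.float64)


def cross_validate(x: np.ndarray, y: np.ndarray, spec: ModelSpec,
                   k: int = 5, seed: int = 0,
                   reducer_factory: Callable[[], object] | None = None,
                   ) -> CvResult:
    """Seeded k-fold CV returning the per-fold MAEs, their mean and SD.

    ``reducer_factory``, when given, must return an object with
    ``fit(x_train, y_train)`` and ``transform(x)``; it is refit on every
    training fold (leakage control) before standardization and the model
    fit.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    assignment = make_folds(n, k, seed)
    fold_maes = []
    predictions = np.empty(n, dtype=np.float64)
    for fold in range(k):
        test = assignment == fold
        train = ~test
        x_tr, x_te = x[train], x[test]
        if reducer_factory is not None:
            red = reducer_factory()
            red.fit(x_tr, y[train])
            x_tr, x_te = red.transform(x_tr), red.transform(x_te)
        x_tr, x_te = _standardize(x_tr, x_te)
        pred = fit_predict(spec, x_tr, y[train], x_te)
        predictions[test] = pred
        fold_maes.append(mae(y[test], pred))
    return CvResult(fold_maes=fold_maes,
                    mean_mae=float(np.mean(fold_maes)),
                    sd=float(np.std(fold_maes, ddof=1)),
                    predictions=predictions,
                    fold_assignment=assignment)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Population SD divided by mean; errors on a zero mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty input")
    mu = v.mean()
    if mu == 0:
        raise ValueError("zero mean: CV undefined")
    return float(v.std() / mu)


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson (values) and Spearman (ranks) correlation with two-sided
    p-values; errors on constant input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series of >= 3 values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(pearson_r=float(pr.statistic),
                             pearson_p=float(pr.pvalue),
                             spearman_r=float(sr.statistic),
                             spearman_p=float(sr.pvalue))
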