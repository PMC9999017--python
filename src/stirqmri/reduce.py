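"""Dimensionality reduction: PCA (workflow 1) and information-imbalance
feature-subset selection (workflow 2).

The information imbalance Δ(A→B) of a feature space A with respect to a
target space B is estimated on N points as

    Δ(A→B) = (2 / N) * mean_i  rank_B( nn_A(i) )

where nn_A(i) is point i's nearest non-self neighbor under the Euclidean
distance in A, and rank_B is that neighbor's rank (1 = nearest) among
i's neighbors under the distance in B. A low Δ means neighborhoods in A
predict neighborhoods in B, i.e. the selected features carry the target's
information. Δ ranges from 2/N (perfect) to about 1 (independent).

Ties in either space are broken by ascending point index; the estimate
on discretized data depends on this rule, so it is fixed and stable.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA (workflow 1)

@dataclass
class PcaModel:
    """Fitted center/scale + principal axes; six components retain about
    90% of the variance on the radiomic tables this package produces."""

    feature_names: list[str]
    n_components: int
    scaler: StandardScaler
    pca: PCA

    @property
    def component_loadings(self) -> np.ndarray:      # features x components
        return self.pca.components_.T

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_


def fit_pca(table: pd.DataFrame, n_components: int = 6) -> PcaModel:
    """Fit z-scoring + PCA on a feature table (rows = subjects).

    Zero-variance features are dropped with a warning before the fit;
    center and scale come from the fitting rows only.
    """
    if len(table) < n_components:
        raise ValueError(f"need >= {n_components} rows, got {len(table)}")
    variances = table.var(axis=0, ddof=0)
    keep = variances[variances > 0].index.tolist()
    dropped = [c for c in table.columns if c not in keep]
    if dropped:
        logger.warning("dropping %d zero-variance features before PCA: %s",
                       len(dropped), dropped)
    x = table[keep].to_numpy(dtype=np.float64)
    scaler = StandardScaler().fit(x)
    n_comp = min(n_components, x.shape[1], x.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full").fit(
        scaler.transform(x))
    return PcaModel(feature_names=keep, n_components=n_comp,
                    scaler=scaler, pca=pca)


def project(model: PcaModel, table: pd.DataFrame) -> np.ndarray:
    """Project rows onto the fitted components (n_rows x n_components)."""
    x = table[model.feature_names].to_numpy(dtype=np.float64)
    return model.pca.transform(model.scaler.transform(x))


# ---------------------------------------------------------------------------
# information imbalance (workflow 2)

def _zscore_columns(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)           # constant column contributes 0
    return (x - mu) / sd


def _neighbor_ranks(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each point: index of nearest non-self neighbor, and the rank
    (1-based) of every other point; ties broken by ascending index."""
    n = x.shape[0]
    d = squareform(pdist(x, metric="euclidean"))
    np.fill_diagonal(d, np.inf)
    idx = np.arange(n)
    # lexsort: primary key distance, secondary key point index
    order = np.lexsort((np.broadcast_to(idx, (n, n)), d), axis=1)
    ranks = np.empty((n, n), dtype=np.int64)
    np.put_along_axis(ranks, order, np.broadcast_to(idx + 1, (n, n)), axis=1)
    nn = order[:, 0]
    return nn, ranks


def information_imbalance(a_values: np.ndarray, b_values: np.ndarray) -> float:
    """Δ(A→B) on z-scored Euclidean spaces; see the module docstring.

    ``a_values``: (N, d) feature matrix (or 1-D); ``b_values``: the 1-D
    target (a (N, k) array is accepted). Raises on N < 3 or a constant
    target (ranks in B undefined).
    """
    a = _zscore_columns(a_values)
    b = np.asarray(b_values, dtype=np.float64)
    if b.ndim == 1:
        b = b[:, None]
    n = a.shape[0]
    if b.shape[0] != n:
        raise ValueError("A and B must have the same number of points")
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.all(b.std(axis=0) == 0):
        raise ValueError("constant target: ranks in B undefined")
    b = _zscore_columns(b)
    nn_a, _ = _neighbor_ranks(a)
    _, ranks_b = _neighbor_ranks(b)
    r = ranks_b[np.arange(n), nn_a]
    return float(2.0 * r.mean() / n)


@dataclass
class ImbalanceResult:
    delta: float                       # minimum Δ over the curve
    subset: list[str]                  # feature names attaining it
    target: str
    n_points: int
    #: subset-size -> (best Δ found at that size, subset attaining it)
    curve: dict[int, tuple[float, list[str]]] = field(default_factory=dict)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"size": k, "delta": d, "subset": "|".join(names)}
             for k, (d, names) in sorted(self.curve.items())])


def select_subset_by_imbalance(table: pd.DataFrame, target: str,
                               max_size: int = 8,
                               feature_names: Sequence[str] | None = None,
                               ) -> ImbalanceResult:
    """Pick the feature subset minimizing Δ(subset → target).

    Sizes 1 and 2 are searched exhaustively; sizes 3..max_size grow the
    best pair greedily (at each step add the feature with the lowest
    resulting Δ). The reported subset is the curve's argmin; ties go to
    the smaller subset.
    """
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("FF_pp", "wT2_ms")]
    if target not in table.columns:
        raise ValueError(f"target column not in table: {target}")
    if not 1 <= max_size <= len(feature_names):
        raise ValueError("max_size must be in [1, n_features]")
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    x = _zscore_columns(table[list(feature_names)].to_numpy(np.float64))
    y = table[target].to_numpy(np.float64)
    names = list(feature_names)

    def delta_of(cols: tuple[int, ...]) -> float:
        return information_imbalance(x[:, list(cols)], y)

    curve: dict[int, tuple[float, list[str]]] = {}
    singles = [(delta_of((j,)), j) for j in range(len(names))]
    best1 = min(singles, key=lambda t: t[0])
    curve[1] = (best1[0], [names[best1[1]]])
    current: tuple[int, ...] = (best1[1],)
    if max_size >= 2:
        pairs = [(delta_of(c), c)
                 for c in itertools.combinations(range(len(names)), 2)]
        best2 = min(pairs, key=lambda t: t[0])
        curve[2] = (best2[0], [names[j] for j in best2[1]])
        current = best2[1]
    for size in range(3, max_size + 1):
        candidates = [j for j in range(len(names)) if j not in current]
        scored = [(delta_of(current + (j,)), j) for j in candidates]
        best_d, best_j = min(scored, key=lambda t: t[0])
        current = tuple(sorted(current + (best_j,)))
        curve[size] = (best_d, [names[j] for j in current])
    best_size = min(curve, key=lambda k: (curve[k][0], k))
    delta, subset = curve[best_size]
    return ImbalanceResult(delta=delta, subset=list(subset), target=target,
                           n_points=len(table), curve=curve)


# ---------------------------------------------------------------------------
# per-fold reducer adapters (leakage control inside cross-validation)

class FoldPcaReducer:
    """Array-interface PCA refit on each training fold."""

    def __init__(self, n_components: int = 6):
        self.n_components = n_components

    def fit(self, x: np.ndarray, y: np.ndarray | None = None):
        x = np.asarray(x, dtype=np.float64)
        sd = x.std(axis=0)
        self.keep_ = np.flatnonzero(sd > 0)
        x = x[:, self.keep_]
        self.scaler_ = StandardScaler().fit(x)
        n_comp = min(self.n_components, x.shape[1], x.shape[0])
        self.pca_ = PCA(n_components=n_comp, svd_solver="full").fit(
            self.scaler_.transform(x))
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)[:, self.keep_]
        return self.pca_.transform(self.scaler_.transform(x))


class FoldImbalanceReducer:
    """Array-interface imbalance subset selection refit per training fold.

    Selections for identical training folds are memoized on the instance
    level through ``cache`` (the fold split is shared across the seven
    models, so each fold's search runs once).
    """

    def __init__(self, feature_names: Sequence[str], max_size: int = 8,
                 cache: dict | None = None):
        self.feature_names = list(feature_names)
        self.max_size = max_size
        self.cache = cache if cache is not None else {}

    def fit(self, x: np.ndarray, y: np.ndarray):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        key = (x.tobytes(), y.tobytes())
        if key not in self.cache:
            df = pd.DataFrame(x, columns=self.feature_names)
            df["__target__"] = y
            res = select_subset_by_imbalance(
                df, "__target__",
                max_size=min(self.max_size, len(self.feature_names)),
                feature_names=self.feature_names)
            self.cache[key] = [self.feature_names.index(n)
                               for n in res.subset]
        self.cols_ = self.cache[key]
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=np.float64)[:, self.cols_]
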