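"""Feature-table cleaning, correlation screening, regressors, cut-point discretization.

The three regressor configurations: Random Forest (400 estimators, bootstrap
aggregation), HistGradientBoosting (max depth 6, 800 iterations, learning
rate 0.04) and Ridge (alpha 1.0, on standardized features). Tree models
consume unstandardized features (they are scale-invariant); ridge carries its
own fit-on-train standardizer.

Continuous predictions are mapped to integer labels by thresholds placed at
midpoints between adjacent class medians; non-monotone median sequences are
repaired by pool-adjacent-violators before midpoints are taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, InputError, NumericalError
from .features import ID_COLUMNS, LABEL_COLUMN

__all__ = [
    "FeatureMatrix",
    "Cleaner",
    "ModelSpec",
    "CutPoints",
    "clean",
    "select",
    "fit",
    "optimize_cutpoints",
    "discretize",
]

log = logging.getLogger(__name__)

MODEL_KINDS = ("rf", "histgbr", "ridge")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 400, "bootstrap": True},
    "histgbr": {"max_depth": 6, "max_iter": 800, "learning_rate": 0.04},
    "ridge": {"alpha": 1.0},
}


@dataclass
class FeatureMatrix:
    """Cleaned numeric features with aligned groups and labels."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise InputError("X, y and groups must be aligned")


class Cleaner:
    """Fit-on-train cleaning: column pruning plus median imputation.

    Drops non-numeric columns, columns that are constant over their observed
    values, and columns whose missing fraction exceeds ``missing_cap``.
    Remaining missing entries are imputed with the median of the fitting rows,
    so inside cross-validation no test-row statistics leak into training.
    """

    def __init__(self, missing_cap: float = 0.3) -> None:
        if not 0 <= missing_cap <= 1:
            raise ConfigError("missing_cap must lie in [0, 1]")
        self.missing_cap = missing_cap
        self.columns_: list[str] | None = None
        self.medians_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "Cleaner":
        numeric = X.select_dtypes(include=[np.number])
        keep: list[str] = []
        for col in numeric.columns:
            v = numeric[col]
            frac_missing = v.isna().mean()
            if frac_missing > self.missing_cap:
                continue
            observed = v.dropna()
            if observed.nunique() <= 1:
                continue  # constant (or empty) column
            keep.append(col)
        if not keep:
            raise InputError("no usable numeric columns remain after cleaning")
        self.columns_ = keep
        self.medians_ = numeric[keep].median()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise InputError("Cleaner must be fitted before transform")
        out = X[self.columns_].astype(float).copy()
        return out.fillna(self.medians_)

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def clean(
    table: pd.DataFrame,
    missing_cap: float = 0.3,
    label_column: str = LABEL_COLUMN,
    group_column: str = "subject_id",
) -> FeatureMatrix:
    """One-shot cleaning of a full learning table into a FeatureMatrix."""
    if table.empty:
        raise InputError("empty feature table")
    if label_column not in table.columns:
        raise InputError(f"table has no label column {label_column!r}")
    feature_df = table.drop(columns=[c for c in (*ID_COLUMNS, label_column) if c in table.columns])
    X = Cleaner(missing_cap).fit_transform(feature_df)
    y = table[label_column].to_numpy(dtype=int)
    groups = table[group_column].to_numpy() if group_column in table.columns else np.arange(len(table))
    return FeatureMatrix(X=X, y=y, groups=groups)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(xc * yc) / denom)


def select(
    X: pd.DataFrame,
    labels: np.ndarray,
    threshold: float = 0.5,
    fallback_k: int = 10,
) -> list[str]:
    """Columns whose |Pearson r| against the labels meets the threshold.

    Returned sorted by |r| descending. Columns with undefined r (zero
    variance after imputation) are excluded. If nothing passes, falls back to
    the top ``fallback_k`` by |r| with a logged warning.
    """
    y = np.asarray(labels, dtype=float)
    scores: list[tuple[float, str]] = []
    for col in X.columns:
        r = _pearson(X[col].to_numpy(dtype=float), y)
        if np.isnan(r):
            continue
        scores.append((abs(r), col))
    scores.sort(key=lambda t: -t[0])
    retained = [c for a, c in scores if a >= threshold]
    if not retained:
        retained = [c for _, c in scores[:fallback_k]]
        log.warning(
            "no feature reached |r| >= %.3g; falling back to top %d by |r|",
            threshold,
            len(retained),
        )
    return retained


@dataclass(frozen=True)
class ModelSpec:
    """One regressor configuration. ``hyperparams`` override the defaults."""

    kind: str = "rf"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")

    def resolved_hyperparams(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMS[self.kind])
        params.update(self.hyperparams)
        return params

    def to_dict(self) -> dict:
        return {"kind": self.kind, "hyperparams": dict(self.hyperparams), "seed": self.seed}


def fit(X: pd.DataFrame | np.ndarray, labels: np.ndarray, spec: ModelSpec):
    """Fit the regressor named by ``spec`` and return the fitted predictor.

    Ridge is wrapped in a pipeline with a standardizer so scaling statistics
    always come from the rows it is fitted on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise InputError("X must be 2-D and aligned with labels")
    if len(y) < 2:
        raise InputError("need at least 2 rows to fit")
    params = spec.resolved_hyperparams()
    if spec.kind == "rf":
        est = RandomForestRegressor(random_state=spec.seed, **params)
    elif spec.kind == "histgbr":
        est = HistGradientBoostingRegressor(random_state=spec.seed, **params)
    else:
        est = Pipeline(
            [("scale", StandardScaler()), ("ridge", Ridge(**params, random_state=spec.seed))]
        )
    est.fit(X, y)
    return est


@dataclass(frozen=True)
class CutPoints:
    """Ordered thresholds mapping continuous predictions to integer classes."""

    classes: tuple[int, ...]
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", np.asarray(self.thresholds, dtype=float))
        if len(self.classes) < 2:
            raise NumericalError("cut points need at least 2 classes")
        if list(self.classes) != sorted(self.classes):
            raise InputError("classes must be sorted")
        if self.thresholds.size != len(self.classes) - 1:
            raise InputError("need exactly len(classes) - 1 thresholds")
        if np.any(np.diff(self.thresholds) <= 0):
            raise InputError("thresholds must be strictly increasing")

    def to_dict(self) -> dict:
        return {"classes": list(self.classes), "thresholds": self.thresholds.tolist()}


def _pav(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: nearest non-decreasing sequence (L2)."""
    level_val: list[float] = []
    level_w: list[float] = []
    level_n: list[int] = []
    for v, w in zip(values, weights):
        level_val.append(float(v))
        level_w.append(float(w))
        level_n.append(1)
        while len(level_val) > 1 and level_val[-2] > level_val[-1]:
            v2, w2, n2 = level_val.pop(), level_w.pop(), level_n.pop()
            v1, w1, n1 = level_val.pop(), level_w.pop(), level_n.pop()
            w = w1 + w2
            level_val.append((v1 * w1 + v2 * w2) / w)
            level_w.append(w)
            level_n.append(n1 + n2)
    out = np.empty(values.size)
    i = 0
    for v, n in zip(level_val, level_n):
        out[i : i + n] = v
        i += n
    return out


def optimize_cutpoints(predictions: np.ndarray, labels: np.ndarray) -> CutPoints:
    """Median-based cut points between adjacent classes present in the data.

    For each adjacent pair of observed classes the threshold is the midpoint
    of their prediction medians. If the median sequence is not monotone it is
    first projected onto the nearest non-decreasing sequence (PAV, weighted by
    class counts); midpoints of pooled (equal) medians are then spread by a
    scale-relative epsilon so thresholds stay strictly increasing.
    """
    pred = np.asarray(predictions, dtype=float)
    lab = np.asarray(labels)
    if pred.size != lab.size:
        raise InputError("predictions and labels must be aligned")
    classes = np.unique(lab)
    if classes.size < 2:
        raise NumericalError(
            "only one distinct label present; bypass discretization for this data"
        )
    medians = np.array([np.median(pred[lab == c]) for c in classes])
    counts = np.array([np.sum(lab == c) for c in classes], dtype=float)
    monotone = _pav(medians, counts)
    thresholds = (monotone[:-1] + monotone[1:]) / 2.0
    scale = max(float(np.ptp(pred)), 1.0)
    eps = 1e-9 * scale
    for j in range(1, thresholds.size):
        if thresholds[j] <= thresholds[j - 1]:
            thresholds[j] = thresholds[j - 1] + eps
    return CutPoints(classes=tuple(int(c) for c in classes), thresholds=thresholds)


def discretize(pred: float | np.ndarray, cp: CutPoints) -> int | np.ndarray:
    """Map continuous predictions to integer classes; ties at a threshold go low."""
    arr = np.asarray(pred, dtype=float)
    idx = np.searchsorted(cp.thresholds, arr, side="left")
    out = np.asarray(cp.classes)[idx]
    if arr.ndim == 0:
        return int(out)
    return out
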