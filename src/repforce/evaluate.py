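"""Out-of-fold evaluation: CV schemes, continuous/tolerance/agreement metrics.

Two cross-validation schemes are supported: plain shuffled K-fold and
subject-grouped K-fold (all rows of a participant — both limbs, all sets —
stay on one side of every train/test split). All metrics are computed from
out-of-fold predictions.

Metric paths: R2/MAE/RMSE/Pearson r and Bland-Altman agreement are computed
on the continuous predictions; exact accuracy, the confusion matrix and the
error buckets on the discretized ones. Tolerance accuracies are reported for
both paths; the headline within-0.5/within-1.0 fields use the discretized
path so that within_1 >= within_05 >= exact_accuracy holds by construction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold

from .errors import ConfigError, InputError, NumericalError
from .features import ID_COLUMNS, LABEL_COLUMN
from .model import (
    Cleaner,
    CutPoints,
    ModelSpec,
    discretize,
    fit,
    optimize_cutpoints,
    select,
)

__all__ = [
    "CVScheme",
    "CVResult",
    "EvalReport",
    "make_folds",
    "cross_validate",
    "continuous_metrics",
    "tolerance_metrics",
    "bland_altman",
    "evaluate_predictions",
    "compare_models",
]

log = logging.getLogger(__name__)

SCHEME_KINDS = ("kfold5", "groupkfold")


@dataclass(frozen=True)
class CVScheme:
    kind: str = "groupkfold"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ConfigError(f"unknown CV scheme {self.kind!r}; expected one of {SCHEME_KINDS}")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_folds(
    scheme: CVScheme, n_rows: int, groups: np.ndarray | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (train_indices, test_indices) pairs for one scheme."""
    if scheme.kind == "kfold5":
        splitter = KFold(n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed)
        return list(splitter.split(np.zeros(n_rows)))
    if groups is None:
        raise InputError("groupkfold requires groups")
    n_groups = len(np.unique(groups))
    if n_groups < scheme.n_folds:
        raise InputError(
            f"groupkfold with {scheme.n_folds} folds needs >= {scheme.n_folds} groups, "
            f"got {n_groups}"
        )
    splitter = GroupKFold(n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed)
    return list(splitter.split(np.zeros(n_rows), groups=groups))


@dataclass
class CVResult:
    """Out-of-fold predictions aligned to table rows."""

    pred_continuous: np.ndarray
    pred_discrete: np.ndarray
    fold_id: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    retained_columns: list[list[str]]
    cutpoints: list[CutPoints | None]


def cross_validate(
    table: pd.DataFrame,
    spec: ModelSpec,
    scheme: CVScheme,
    *,
    selection_threshold: float = 0.5,
    fallback_k: int = 10,
    missing_cap: float = 0.3,
    leak_free: bool = True,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Out-of-fold continuous and discretized predictions for every row.

    With ``leak_free=True`` (default) cleaning statistics, imputation medians
    and the correlation screen are re-fit inside each training fold; the
    literal single-pass variant (``leak_free=False``) is kept for comparison.
    Per-fold cut points are fitted on training predictions only.
    """
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    groups = table["subject_id"].to_numpy()
    feature_df = table.drop(
        columns=[c for c in (*ID_COLUMNS, LABEL_COLUMN) if c in table.columns]
    )
    if folds is None:
        folds = make_folds(scheme, len(table), groups)

    pred_cont = np.full(len(table), np.nan)
    pred_disc = np.zeros(len(table), dtype=int)
    fold_id = np.full(len(table), -1, dtype=int)
    retained_all: list[list[str]] = []
    cutpoints_all: list[CutPoints | None] = []

    if not leak_free:
        global_cleaner = Cleaner(missing_cap).fit(feature_df)
        X_global = global_cleaner.transform(feature_df)
        global_cols = select(X_global, y, selection_threshold, fallback_k)

    for f, (train_idx, test_idx) in enumerate(folds):
        if leak_free:
            cleaner = Cleaner(missing_cap).fit(feature_df.iloc[train_idx])
            X_train = cleaner.transform(feature_df.iloc[train_idx])
            X_test = cleaner.transform(feature_df.iloc[test_idx])
            cols = select(X_train, y[train_idx], selection_threshold, fallback_k)
        else:
            X_train = X_global.iloc[train_idx]
            X_test = X_global.iloc[test_idx]
            cols = global_cols
        est = fit(X_train[cols], y[train_idx], spec)
        train_pred = np.asarray(est.predict(X_train[cols].to_numpy()), dtype=float)
        test_pred = np.asarray(est.predict(X_test[cols].to_numpy()), dtype=float)
        try:
            cp = optimize_cutpoints(train_pred, y[train_idx])
            disc = discretize(test_pred, cp)
        except NumericalError:
            cp = None
            disc = np.rint(test_pred).astype(int)
        pred_cont[test_idx] = test_pred
        pred_disc[test_idx] = disc
        fold_id[test_idx] = f
        retained_all.append(cols)
        cutpoints_all.append(cp)

    if np.any(fold_id < 0):
        raise NumericalError("cross-validation left rows without a prediction")
    return CVResult(
        pred_continuous=pred_cont,
        pred_discrete=pred_disc,
        fold_id=fold_id,
        y=y,
        groups=groups,
        retained_columns=retained_all,
        cutpoints=cutpoints_all,
    )


def continuous_metrics(pred: np.ndarray, true: np.ndarray) -> dict:
    """R2 (1 - SS_res/SS_tot), MAE, RMSE, Pearson r.

    R2 and r are NaN-flagged (not zeroed) when the truth is constant.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.size != t.size:
        raise InputError("pred and true must be aligned")
    if p.size < 2:
        raise InputError("need at least 2 rows")
    resid = p - t
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        return {"r2": float("nan"), "mae": mae, "rmse": rmse, "pearson_r": float("nan")}
    r2 = float(1.0 - np.sum(resid**2) / ss_tot)
    pc = p - p.mean()
    tc = t - t.mean()
    denom = np.sqrt(np.sum(pc**2) * np.sum(tc**2))
    pearson = float(np.sum(pc * tc) / denom) if denom > 0 else float("nan")
    return {"r2": r2, "mae": mae, "rmse": rmse, "pearson_r": pearson}


def tolerance_metrics(
    pred: np.ndarray,
    true: np.ndarray,
    tolerances: Sequence[float] = (0.5, 1.0),
    pred_discrete: np.ndarray | None = None,
) -> dict:
    """Tolerance accuracies (inclusive |error| <= tol), confusion, error buckets.

    Tolerance accuracies and buckets are computed on ``pred``; exact accuracy
    and the confusion matrix on ``pred_discrete`` (defaults to rounded
    ``pred``). Buckets count |error| <= 1, in (1, 2], and > 2.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.size != t.size:
        raise InputError("pred and true must be aligned")
    err = np.abs(p - t)
    accuracies = {f"within_{tol:g}": float(np.mean(err <= tol)) for tol in tolerances}
    disc = (
        np.rint(p).astype(int)
        if pred_discrete is None
        else np.asarray(pred_discrete, dtype=int)
    )
    ti = np.asarray(true)
    exact = float(np.mean(disc == ti))
    lo = int(min(disc.min(), ti.min()))
    hi = int(max(disc.max(), ti.max()))
    label_range = list(range(lo, hi + 1))
    k = len(label_range)
    confusion = np.zeros((k, k), dtype=int)
    for a, b in zip(ti.astype(int), disc):
        confusion[a - lo, b - lo] += 1
    buckets = {
        "le_1": int(np.sum(err <= 1.0)),
        "1_to_2": int(np.sum((err > 1.0) & (err <= 2.0))),
        "gt_2": int(np.sum(err > 2.0)),
    }
    return {
        "accuracies": accuracies,
        "exact_accuracy": exact,
        "confusion_labels": label_range,
        "confusion": confusion,
        "error_buckets": buckets,
    }


def bland_altman(
    pred: np.ndarray, true: np.ndarray, groups: np.ndarray | None = None
) -> dict:
    """Mean difference and 1.96 SD limits of agreement (diff = pred - true).

    SD uses the N-1 divisor. With ``groups``, the same quantities are computed
    within each group; groups with fewer than 2 pairs are flagged as None.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.size != t.size:
        raise InputError("pred and true must be aligned")
    if p.size < 2:
        raise InputError("Bland-Altman needs at least 2 pairs")

    def _ba(d: np.ndarray) -> dict:
        mean = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        return {
            "mean_diff": mean,
            "sd_diff": sd,
            "loa_low": mean - 1.96 * sd,
            "loa_high": mean + 1.96 * sd,
            "n": int(d.size),
        }

    out = _ba(p - t)
    if groups is not None:
        per_group: dict[str, dict | None] = {}
        for g in np.unique(groups):
            mask = groups == g
            per_group[str(g)] = _ba((p - t)[mask]) if int(mask.sum()) >= 2 else None
        out["per_group"] = per_group
    return out


@dataclass
class EvalReport:
    """Continuous, discrete and agreement metrics from out-of-fold predictions."""

    r2: float
    mae: float
    rmse: float
    pearson_r: float
    exact_accuracy: float
    acc_within_05: float
    acc_within_10: float
    confusion_labels: list[int]
    confusion: np.ndarray
    error_buckets: dict
    bland_altman: dict
    continuous_tolerance: dict
    discrete_metrics: dict
    folds: list[dict]
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return None
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return _clean(float(v))
            return v

        return {k: _clean(v) for k, v in dataclasses.asdict(self).items()}

    def summary_row(self) -> dict:
        return {
            "r2": self.r2,
            "mae": self.mae,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "within_05": self.acc_within_05,
            "within_1": self.acc_within_10,
        }


def evaluate_predictions(result: CVResult, manifest: dict | None = None) -> EvalReport:
    """Build the full report from a cross-validation result."""
    cont = continuous_metrics(result.pred_continuous, result.y)
    cont_tol = tolerance_metrics(
        result.pred_continuous, result.y, pred_discrete=result.pred_discrete
    )
    disc_tol = tolerance_metrics(
        result.pred_discrete.astype(float), result.y, pred_discrete=result.pred_discrete
    )
    disc_cont = continuous_metrics(result.pred_discrete.astype(float), result.y)
    ba = bland_altman(result.pred_continuous, result.y, groups=result.groups)

    folds = []
    for f in np.unique(result.fold_id):
        mask = result.fold_id == f
        fold_metrics = (
            continuous_metrics(result.pred_continuous[mask], result.y[mask])
            if int(mask.sum()) >= 2
            else {}
        )
        folds.append(
            {
                "fold": int(f),
                "n_test": int(mask.sum()),
                "retained_columns": result.retained_columns[int(f)],
                **fold_metrics,
            }
        )

    return EvalReport(
        r2=cont["r2"],
        mae=cont["mae"],
        rmse=cont["rmse"],
        pearson_r=cont["pearson_r"],
        exact_accuracy=disc_tol["exact_accuracy"],
        acc_within_05=disc_tol["accuracies"]["within_0.5"],
        acc_within_10=disc_tol["accuracies"]["within_1"],
        confusion_labels=disc_tol["confusion_labels"],
        confusion=disc_tol["confusion"],
        error_buckets=disc_tol["error_buckets"],
        bland_altman=ba,
        continuous_tolerance={
            "accuracies": cont_tol["accuracies"],
            "error_buckets": cont_tol["error_buckets"],
        },
        discrete_metrics={**disc_cont, "exact_accuracy": disc_tol["exact_accuracy"]},
        folds=folds,
        manifest=manifest or {},
    )


def compare_models(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec],
    scheme: CVScheme,
    **cv_kwargs,
) -> dict:
    """One report per spec from identical fold assignments, ranked by R2."""
    if len(specs) < 2:
        raise InputError("compare_models needs at least 2 specs")
    groups = table["subject_id"].to_numpy()
    folds = make_folds(scheme, len(table), groups)
    reports: dict[str, EvalReport] = {}
    for i, spec in enumerate(specs):
        name = spec.kind if spec.kind not in reports else f"{spec.kind}_{i}"
        result = cross_validate(table, spec, scheme, folds=folds, **cv_kwargs)
        reports[name] = evaluate_predictions(
            result, manifest={"model": spec.to_dict(), "scheme": scheme.to_dict()}
        )
    ranking = sorted(
        reports, key=lambda k: (reports[k].r2 if np.isfinite(reports[k].r2) else -np.inf),
        reverse=True,
    )
    return {"reports": reports, "ranking": ranking}


def report_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Human-readable metric table, one row per model."""
    rows = {name: rep.summary_row() for name, rep in reports.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
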