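"""Per-repetition and set-level feature engineering.

Primary descriptors (peak, mean, RMS, variance/SD, skewness/kurtosis, work,
time-to-peak, rate of force development) are computed per repetition and
aggregated to set level. Inter-set relative descriptors (baseline- and
previous-set-referenced differences and ratios), interaction composites and
log-transformed variants are added, and everything is assembled into one
learning table with an integer RPE label per (subject, limb, set).

Conventions
-----------
* Work is the discrete sum of force times the sampling interval (units N*s):
  under machine-controlled constant velocity it is proportional to mechanical
  work, and no displacement signal exists.
* The exported variance/SD use the N-1 divisor; skewness and kurtosis are the
  standard population moment ratios (1/N central moments over the population
  SD cubed / to the fourth). Kurtosis is not excess-corrected (Gaussian -> 3).
* Degenerate quantities (skew/kurt of a constant signal, ratios with zero
  denominators, previous-set features at set 1) are emitted as NaN and left
  for the model stage's single imputation policy.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .preprocess import Repetition

__all__ = [
    "PrimaryFeatures",
    "CompositeFeatures",
    "RelativeFeatures",
    "FeatureConfig",
    "PRIMARY_FIELDS",
    "primary_features",
    "composite_features",
    "aggregate_set",
    "relative_features",
    "build_table",
    "feature_columns",
]

log = logging.getLogger(__name__)

PRIMARY_FIELDS = (
    "peak_force",
    "mean_force",
    "rms",
    "variance",
    "sd",
    "skewness",
    "kurtosis",
    "work",
    "ttp_s",
    "rfd",
)

# Non-negative magnitude/energy features that get a log(1+x) variant.
LOG_FIELDS = ("peak_force", "mean_force", "rms", "work")

RELATIVE_SUFFIXES = ("delta_base", "ratio_base", "delta_prev", "ratio_prev")

ID_COLUMNS = ("subject_id", "limb")
LABEL_COLUMN = "rpe"


@dataclass(frozen=True)
class PrimaryFeatures:
    peak_force: float
    mean_force: float
    rms: float
    variance: float
    sd: float
    skewness: float
    kurtosis: float
    work: float
    ttp_s: float
    rfd: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CompositeFeatures:
    work_over_sd: float
    peak_times_rms: float
    delta_times_ratio: float


@dataclass(frozen=True)
class RelativeFeatures:
    """Relative descriptors of one feature at one set."""

    delta_base: float
    ratio_base: float
    delta_prev: float
    ratio_prev: float


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for table assembly.

    ``delta_times_ratio_base`` names the primary feature whose
    baseline-relative pair feeds the "delta x ratio" composite. ``exp_terms``
    enables an optional exp(f(s)/f(1)) column family for the magnitude
    features. ``include_relative=False`` drops all engineered relative columns
    (and the composite built from them) for ablation runs.
    """

    delta_times_ratio_base: str = "work"
    exp_terms: bool = False
    include_relative: bool = True

    def __post_init__(self) -> None:
        if self.delta_times_ratio_base not in PRIMARY_FIELDS:
            raise InputError(
                f"unknown delta_times_ratio_base {self.delta_times_ratio_base!r}"
            )


def primary_features(rep: Repetition | np.ndarray, dt: float | None = None) -> PrimaryFeatures:
    """Compute the primary descriptors of one repetition.

    Accepts a :class:`Repetition` (dt taken from it) or a bare force array
    with an explicit ``dt``.
    """
    if isinstance(rep, Repetition):
        forces = rep.forces_N
        dt = rep.sampling_interval_s if dt is None else dt
    else:
        forces = np.asarray(rep, dtype=float)
    if dt is None or dt <= 0:
        raise InputError("dt must be positive")
    n = forces.size
    if n < 2:
        raise InputError("a repetition needs at least 2 samples")

    peak = float(np.max(forces))
    mean = float(np.mean(forces))
    rms = float(np.sqrt(np.mean(forces**2)))
    centered = forces - mean
    m2 = float(np.mean(centered**2))
    variance = float(np.sum(centered**2) / (n - 1))
    sd = float(np.sqrt(variance))
    if m2 > 0:
        sigma_pop = np.sqrt(m2)
        skewness = float(np.mean(centered**3) / sigma_pop**3)
        kurtosis = float(np.mean(centered**4) / sigma_pop**4)
    else:
        skewness = float("nan")
        kurtosis = float("nan")
    work = float(np.sum(forces) * dt)
    ttp_s = float(int(np.argmax(forces)) * dt)
    rfd = float(np.max(np.diff(forces)) / dt)
    return PrimaryFeatures(
        peak_force=peak,
        mean_force=mean,
        rms=rms,
        variance=variance,
        sd=sd,
        skewness=skewness,
        kurtosis=kurtosis,
        work=work,
        ttp_s=ttp_s,
        rfd=rfd,
    )


def composite_features(
    p: PrimaryFeatures, delta_base: float = float("nan"), ratio_base: float = float("nan")
) -> CompositeFeatures:
    """Interaction composites: Work/SD, Peak x RMS, and delta x ratio.

    ``delta_base`` / ``ratio_base`` are the baseline-relative pair of the
    designated base feature (see :class:`FeatureConfig`).
    """
    work_over_sd = p.work / p.sd if p.sd > 0 else float("nan")
    return CompositeFeatures(
        work_over_sd=work_over_sd,
        peak_times_rms=p.peak_force * p.rms,
        delta_times_ratio=delta_base * ratio_base,
    )


def aggregate_set(reps: Sequence[PrimaryFeatures]) -> PrimaryFeatures:
    """Aggregate per-repetition features to one set-level record.

    Unweighted mean of each field, except peak force (max across reps) and
    work (sum across reps). NaN fields (e.g. undefined skewness) are skipped
    in the mean; an all-NaN field stays NaN.
    """
    if len(reps) == 0:
        raise InputError("cannot aggregate an empty set")
    values = {f: np.array([getattr(r, f) for r in reps], dtype=float) for f in PRIMARY_FIELDS}
    out = {}
    with np.errstate(invalid="ignore"):
        for f, v in values.items():
            if f == "peak_force":
                out[f] = float(np.max(v))
            elif f == "work":
                out[f] = float(np.sum(v))
            else:
                out[f] = float(np.nanmean(v)) if not np.all(np.isnan(v)) else float("nan")
    return PrimaryFeatures(**out)


def relative_features(set_values: Sequence[float]) -> list[RelativeFeatures]:
    """Baseline- and previous-set-relative descriptors of one feature series.

    ``set_values`` is f(1..S) in set order. At s=1 the baseline pair is
    (0, 1) by self-reference and the previous-set pair is missing. Ratios with
    a zero denominator are missing.
    """
    values = np.asarray(set_values, dtype=float)
    if values.size < 2:
        raise InputError("relative features need at least 2 sets")
    out: list[RelativeFeatures] = []
    base = values[0]
    for s, v in enumerate(values, start=1):
        if s == 1:
            out.append(RelativeFeatures(0.0, 1.0, float("nan"), float("nan")))
            continue
        prev = values[s - 2]
        out.append(
            RelativeFeatures(
                delta_base=v - base,
                ratio_base=v / base if base != 0 else float("nan"),
                delta_prev=v - prev,
                ratio_prev=v / prev if prev != 0 else float("nan"),
            )
        )
    return out


def feature_columns(config: FeatureConfig | None = None) -> list[str]:
    """Deterministic ordered list of numeric feature columns."""
    config = config or FeatureConfig()
    cols = ["set_index"]
    cols += list(PRIMARY_FIELDS)
    cols += [f"log1p_{f}" for f in LOG_FIELDS]
    cols += ["work_over_sd", "peak_times_rms"]
    if config.include_relative:
        cols += ["delta_times_ratio"]
        for f in PRIMARY_FIELDS:
            cols += [f"{f}_{suf}" for suf in RELATIVE_SUFFIXES]
    if config.exp_terms:
        cols += [f"exp_base_{f}" for f in LOG_FIELDS]
    return cols


def build_table(
    reps: Mapping[tuple[str, str, int], Sequence[Repetition]],
    labels: Mapping[tuple[str, str, int], int],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Assemble the learning table: one row per (subject, limb, set).

    ``reps`` maps (subject_id, limb, set_index) to that set's segmented
    repetitions (forces already filtered and normalized). Rows without an RPE
    label are skipped with a warning. Column order is deterministic.
    """
    config = config or FeatureConfig()
    by_limb: dict[tuple[str, str], dict[int, PrimaryFeatures]] = {}
    for (sid, limb, s), rep_list in reps.items():
        if len(rep_list) == 0:
            continue
        per_rep = [primary_features(r) for r in rep_list]
        by_limb.setdefault((sid, limb), {})[s] = aggregate_set(per_rep)

    rows = []
    for (sid, limb) in sorted(by_limb):
        sets = by_limb[(sid, limb)]
        set_order = sorted(sets)
        series = {f: [getattr(sets[s], f) for s in set_order] for f in PRIMARY_FIELDS}
        rel = {
            f: relative_features(series[f]) if len(set_order) >= 2 else None
            for f in PRIMARY_FIELDS
        }
        base_feature = config.delta_times_ratio_base
        for pos, s in enumerate(set_order):
            if (sid, limb, s) not in labels:
                log.warning("no RPE label for (%s, %s, set %d); row skipped", sid, limb, s)
                continue
            p = sets[s]
            row: dict[str, object] = {"subject_id": sid, "limb": limb, "set_index": s}
            row.update(p.as_dict())
            for f in LOG_FIELDS:
                row[f"log1p_{f}"] = float(np.log1p(max(getattr(p, f), 0.0)))
            if config.include_relative and rel[base_feature] is not None:
                rb = rel[base_feature][pos]
                comp = composite_features(p, rb.delta_base, rb.ratio_base)
            else:
                comp = composite_features(p)
            row["work_over_sd"] = comp.work_over_sd
            row["peak_times_rms"] = comp.peak_times_rms
            if config.include_relative:
                row["delta_times_ratio"] = comp.delta_times_ratio
                for f in PRIMARY_FIELDS:
                    r = rel[f][pos] if rel[f] is not None else RelativeFeatures(
                        float("nan"), float("nan"), float("nan"), float("nan")
                    )
                    row[f"{f}_delta_base"] = r.delta_base
                    row[f"{f}_ratio_base"] = r.ratio_base
                    row[f"{f}_delta_prev"] = r.delta_prev
                    row[f"{f}_ratio_prev"] = r.ratio_prev
            if config.exp_terms:
                for f in LOG_FIELDS:
                    base = series[f][0]
                    row[f"exp_base_{f}"] = (
                        float(np.exp(getattr(p, f) / base)) if base != 0 else float("nan")
                    )
            row[LABEL_COLUMN] = int(labels[(sid, limb, s)])
            rows.append(row)

    columns = list(ID_COLUMNS) + feature_columns(config) + [LABEL_COLUMN]
    table = pd.DataFrame(rows, columns=columns)
    return table
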