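"""Raw trace conditioning: low-pass filtering, repetition segmentation, force normalization.

A trace is one limb's continuous push-phase force record for one set. Traces
are filtered with a zero-phase Butterworth low-pass, cut into repetitions with
a relative-threshold hysteresis detector, and normalized either per unit body
mass or allometrically (force / mass**0.67).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigError, InputError

__all__ = [
    "ForceTrace",
    "Repetition",
    "FilterSpec",
    "SegmentationParams",
    "lowpass",
    "segment_reps",
    "normalize_force",
]


@dataclass(frozen=True)
class ForceTrace:
    """One limb's continuous force record for one set.

    ``times_s`` must be equally spaced at ``sampling_interval_s``; forces are
    in newtons (or normalized units after :func:`normalize_force`).
    """

    subject_id: str
    limb: str
    set_index: int
    times_s: np.ndarray
    forces_N: np.ndarray
    body_mass_kg: float
    sampling_interval_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "forces_N", np.asarray(self.forces_N, dtype=float))
        if self.times_s.shape != self.forces_N.shape:
            raise InputError("times_s and forces_N must have equal length")
        if self.set_index < 1:
            raise InputError("set_index is 1-based and must be >= 1")
        if self.body_mass_kg <= 0:
            raise InputError("body_mass_kg must be positive")
        if not np.all(np.isfinite(self.forces_N)):
            raise InputError("forces must be finite")
        if self.times_s.size >= 2:
            dt = np.diff(self.times_s)
            if np.any(dt <= 0):
                raise InputError("sample times must be strictly increasing")
            if not np.allclose(dt, self.sampling_interval_s, rtol=1e-6, atol=1e-9):
                raise InputError(
                    "sample times must be equally spaced at sampling_interval_s"
                )

    def __len__(self) -> int:
        return self.forces_N.size

    def with_forces(self, forces: np.ndarray) -> "ForceTrace":
        return ForceTrace(
            subject_id=self.subject_id,
            limb=self.limb,
            set_index=self.set_index,
            times_s=self.times_s,
            forces_N=np.asarray(forces, dtype=float),
            body_mass_kg=self.body_mass_kg,
            sampling_interval_s=self.sampling_interval_s,
        )


@dataclass(frozen=True)
class Repetition:
    """A segmented single push: a half-open sample window [start, end) of a trace."""

    subject_id: str
    limb: str
    set_index: int
    rep_index: int
    start_sample: int
    end_sample: int
    forces_N: np.ndarray
    t_start: float
    sampling_interval_s: float

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise InputError("repetition window must be non-empty (start < end)")
        object.__setattr__(self, "forces_N", np.asarray(self.forces_N, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_interval_s


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass configuration."""

    order: int = 4
    cutoff_hz: float = 20.0
    sampling_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")
        if self.cutoff_hz <= 0 or self.sampling_hz <= 0:
            raise ConfigError("cutoff_hz and sampling_hz must be positive")
        if self.cutoff_hz >= self.sampling_hz / 2:
            raise ConfigError(
                f"cutoff_hz ({self.cutoff_hz}) must be below the Nyquist "
                f"frequency ({self.sampling_hz / 2})"
            )

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return signal.butter(self.order, self.cutoff_hz, fs=self.sampling_hz)

    @property
    def min_trace_length(self) -> int:
        # filtfilt needs len(x) > padlen; padlen = 3 * (n_taps) with our
        # reflective padding, n_taps = order + 1.
        return 3 * (self.order + 1) + 1


@dataclass(frozen=True)
class SegmentationParams:
    """Relative-threshold hysteresis segmentation.

    Onset fires at the first of ``k_consecutive`` samples above
    ``alpha * max(trace)``; offset at the first of ``k_consecutive`` samples
    below ``beta * max(trace)`` after onset. Segments shorter than
    ``min_duration_s`` are discarded.
    """

    alpha: float = 0.15
    beta: float = 0.10
    k_consecutive: int = 3
    min_duration_s: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.beta < self.alpha < 1):
            raise ConfigError("thresholds must satisfy 0 < beta < alpha < 1")
        if self.k_consecutive < 1:
            raise ConfigError("k_consecutive must be >= 1")
        if self.min_duration_s < 0:
            raise ConfigError("min_duration_s must be >= 0")


def lowpass(trace: ForceTrace, spec: FilterSpec | None = None) -> ForceTrace:
    """Apply the zero-phase (forward-backward) Butterworth low-pass filter.

    The forward-backward pass doubles the attenuation (the effective magnitude
    response is the square of the single-pass response) and cancels phase lag,
    so time-to-peak is not biased. Edges are handled with reflective padding.
    """
    spec = spec or FilterSpec()
    if abs(1.0 / trace.sampling_interval_s - spec.sampling_hz) > 1e-6 * spec.sampling_hz:
        raise ConfigError(
            f"trace sampling rate {1.0 / trace.sampling_interval_s:.6g} Hz does not "
            f"match filter sampling_hz {spec.sampling_hz:.6g}"
        )
    b, a = spec.coefficients()
    padlen = 3 * (spec.order + 1)
    if len(trace) <= padlen:
        raise InputError(
            f"trace has {len(trace)} samples; filtering requires at least "
            f"{spec.min_trace_length} (one warm-up length of reflective padding)"
        )
    filtered = signal.filtfilt(b, a, trace.forces_N, padtype="even", padlen=padlen)
    return trace.with_forces(filtered)


def _first_run_start(mask: np.ndarray, k: int, start: int) -> int | None:
    """Index of the first run of >= k consecutive True values at or after start."""
    n = mask.size
    run = 0
    for i in range(start, n):
        if mask[i]:
            run += 1
            if run == k:
                return i - k + 1
        else:
            run = 0
    return None


def segment_reps(
    trace: ForceTrace, params: SegmentationParams | None = None
) -> list[Repetition]:
    """Split a (filtered) trace into ordered, disjoint repetitions.

    Thresholds are relative to the trace maximum, so segmentation is invariant
    to uniform force scaling. An onset without a subsequent offset (trace ends
    mid-push) is closed at the end of the trace. A flat or all-zero trace
    yields no repetitions.
    """
    params = params or SegmentationParams()
    forces = trace.forces_N
    if forces.size == 0:
        return []
    fmax = float(np.max(forces))
    if fmax <= 0:
        return []
    theta_on = params.alpha * fmax
    theta_off = params.beta * fmax
    above = forces > theta_on
    below = forces < theta_off
    k = params.k_consecutive
    min_samples = max(1, int(np.ceil(params.min_duration_s / trace.sampling_interval_s)))

    reps: list[Repetition] = []
    cursor = 0
    rep_index = 1
    n = forces.size
    while cursor < n:
        onset = _first_run_start(above, k, cursor)
        if onset is None:
            break
        offset = _first_run_start(below, k, onset)
        if offset is None:
            offset = n
        if offset - onset >= min_samples:
            reps.append(
                Repetition(
                    subject_id=trace.subject_id,
                    limb=trace.limb,
                    set_index=trace.set_index,
                    rep_index=rep_index,
                    start_sample=onset,
                    end_sample=offset,
                    forces_N=forces[onset:offset],
                    t_start=float(trace.times_s[onset]),
                    sampling_interval_s=trace.sampling_interval_s,
                )
            )
            rep_index += 1
        cursor = max(offset + 1, onset + 1)
    return reps


def normalize_force(
    force_N: float | Sequence[float] | np.ndarray,
    body_mass_kg: float,
    exponent: float = 0.67,
) -> float | np.ndarray:
    """Normalize force by body mass raised to ``exponent``.

    ``exponent=0.67`` gives allometric scaling (force / mass**0.67);
    ``exponent=1.0`` reduces to plain per-mass normalization.
    """
    if body_mass_kg <= 0:
        raise InputError("body_mass_kg must be positive")
    scale = body_mass_kg ** exponent
    arr = np.asarray(force_N, dtype=float)
    out = arr / scale
    if np.isscalar(force_N) or arr.ndim == 0:
        return float(out)
    return out
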