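"""Seeded synthetic cohort generator.

Produces force traces and end-of-set RPE labels with the statistical structure
the downstream analysis assumes: 50 Hz push-phase-only records, an early force
peak (within the first few percent of each push), per-set work declining
geometrically with a subject-specific fatigue rate, force noise growing with
fatigue, and integer 0-10 RPE labels that rise with latent fatigue.

The generator keeps ground truth (true repetition windows, per-set expected
work, latent fatigue) so segmentation and feature code can be tested against
an exact oracle.

Construction of a single push
-----------------------------
Each repetition is ``r + g * q`` where ``r`` is a fixed component (linear rise
to the peak over the first ~2% of samples plus an exponential settle bump) and
``q`` is a scalable plateau with a brief terminal taper. The per-set gain
``g`` is solved so that the noise-free work of a repetition in set ``s``
equals ``decay**(s-1)`` times its set-1 work, with ``decay = 1 - fatigue_rate``.
Because the rise (and hence the peak and the maximal slope) sits in the fixed
component, peak force, time-to-peak and rate of force development carry no
fatigue trend while work declines exactly geometrically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import ForceTrace

__all__ = [
    "FieldDist",
    "PopulationParams",
    "SubjectProfile",
    "ProtocolConfig",
    "SetTruth",
    "SessionData",
    "Cohort",
    "generate_subject",
    "generate_rep_trace",
    "generate_session",
    "generate_cohort",
    "export_cohort",
    "load_cohort_csv",
]

GENERATOR_VERSION = "1.0"

LIMBS = ("L", "R")

# Shape constants for a single push (fractions of the repetition).
_RISE_FRAC = 0.02          # linear rise occupies the first 2% of samples
_PLATEAU_FRAC = 0.80       # default plateau level as a fraction of peak (at gain 1)
_SETTLE_TAU_FRAC = 0.05    # settle time constant as a fraction of samples
_DROP_SAMPLES = 3          # terminal taper length
_DROP_FLOOR = 0.3          # taper end level as a fraction of plateau


@dataclass(frozen=True)
class FieldDist:
    """Normal distribution with hard clipping bounds for one profile field."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"sd must be >= 0, got {self.sd}")
        if not self.lo <= self.hi:
            raise ConfigError(f"invalid bounds [{self.lo}, {self.hi}]")
        if not self.lo <= self.mean <= self.hi:
            raise ConfigError(f"mean {self.mean} outside bounds [{self.lo}, {self.hi}]")

    def draw(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd), self.lo, self.hi))


@dataclass(frozen=True)
class PopulationParams:
    """Population moments for subject profiles.

    Body mass moments default to the cohort the protocol emulates
    (74.4 +/- 11.58 kg); the fatigue/RPE coupling constants are free
    parameters of the simulator, not population estimates.
    """

    body_mass_kg: FieldDist = FieldDist(74.4, 11.58, 40.0, 120.0)
    base_peak_force_N: FieldDist = FieldDist(400.0, 80.0, 100.0, 800.0)
    fatigue_rate: FieldDist = FieldDist(0.06, 0.025, 0.0, 0.14)
    variability_gain: FieldDist = FieldDist(0.15, 0.05, 0.0, 1.0)
    noise_sd_N: FieldDist = FieldDist(4.0, 1.0, 0.0, 20.0)
    plateau_frac: FieldDist = FieldDist(0.78, 0.08, 0.55, 0.92)
    rpe_intercept: FieldDist = FieldDist(3.0, 0.4, 0.0, 10.0)
    rpe_fatigue_gain: FieldDist = FieldDist(14.0, 2.0, 0.0, 30.0)
    limb_asymmetry: FieldDist = FieldDist(0.05, 0.02, 0.0, 0.3)
    label_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.label_noise_sd < 0:
            raise ConfigError("label_noise_sd must be >= 0")

    def replace(self, **kwargs) -> "PopulationParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = dataclasses.asdict(v) if isinstance(v, FieldDist) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            kwargs[f.name] = FieldDist(**v) if isinstance(v, dict) else v
        return cls(**kwargs)


@dataclass(frozen=True)
class SubjectProfile:
    """Latent per-subject parameters; both limbs derive from one profile."""

    subject_id: str
    body_mass_kg: float
    base_peak_force_N: float
    fatigue_rate: float
    variability_gain: float
    noise_sd_N: float
    plateau_frac: float
    rpe_intercept: float
    rpe_fatigue_gain: float
    limb_asymmetry: float

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ConfigError("body_mass_kg must be positive")
        if self.base_peak_force_N <= 0:
            raise ConfigError("base_peak_force_N must be positive")
        if not 0 <= self.fatigue_rate < 0.15:
            raise ConfigError(
                "fatigue_rate must lie in [0, 0.15) so per-set work targets stay feasible"
            )
        if self.variability_gain < 0 or self.noise_sd_N < 0:
            raise ConfigError("noise parameters must be >= 0")
        if not 0.3 <= self.plateau_frac <= 0.95:
            raise ConfigError("plateau_frac must lie in [0.3, 0.95]")
        if not 0 <= self.limb_asymmetry <= 0.3:
            raise ConfigError("limb_asymmetry must lie in [0, 0.3]")

    def limb_peak_force(self, limb: str) -> float:
        """Per-limb peak force; the R limb is scaled down by limb_asymmetry."""
        if limb == "L":
            return self.base_peak_force_N
        return self.base_peak_force_N * (1.0 - self.limb_asymmetry)


@dataclass(frozen=True)
class ProtocolConfig:
    n_sets: int = 7
    reps_per_set: int = 8
    sampling_interval_s: float = 0.02
    rep_duration_range_s: tuple[float, float] = (1.0, 4.0)
    inter_rep_gap_s: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 2:
            raise ConfigError("n_sets must be >= 2 (relative features need >= 2 sets)")
        if self.reps_per_set < 1:
            raise ConfigError("reps_per_set must be >= 1")
        if self.sampling_interval_s <= 0:
            raise ConfigError("sampling_interval_s must be positive")
        lo, hi = self.rep_duration_range_s
        if not 0 < lo <= hi:
            raise ConfigError("rep_duration_range_s must satisfy 0 < lo <= hi")
        if self.inter_rep_gap_s <= 0:
            raise ConfigError("inter_rep_gap_s must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rep_duration_range_s"] = list(self.rep_duration_range_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "rep_duration_range_s" in d:
            d["rep_duration_range_s"] = tuple(d["rep_duration_range_s"])
        return cls(**d)


@dataclass(frozen=True)
class SetTruth:
    """Ground truth for one (limb, set): exact noise-free quantities."""

    rep_windows: tuple[tuple[int, int], ...]
    rep_works: tuple[float, ...]
    expected_work: float
    latent_fatigue: float


@dataclass
class SessionData:
    subject_id: str
    traces: list[ForceTrace]
    rpe_labels: dict[tuple[str, int], int]
    ground_truth: dict[tuple[str, int], SetTruth]


@dataclass
class Cohort:
    profiles: list[SubjectProfile]
    sessions: list[SessionData]
    manifest: dict


def generate_subject(seed: int, population_params: PopulationParams | None = None) -> SubjectProfile:
    """Draw one subject profile; deterministic for a given seed.

    Fields are drawn from clipped normals, so a zero-SD population collapses
    to the mean profile.
    """
    pop = population_params or PopulationParams()
    rng = np.random.default_rng(seed)
    return SubjectProfile(
        subject_id=f"S{seed:04d}",
        body_mass_kg=pop.body_mass_kg.draw(rng),
        base_peak_force_N=pop.base_peak_force_N.draw(rng),
        fatigue_rate=min(pop.fatigue_rate.draw(rng), 0.14),
        variability_gain=pop.variability_gain.draw(rng),
        noise_sd_N=pop.noise_sd_N.draw(rng),
        plateau_frac=pop.plateau_frac.draw(rng),
        rpe_intercept=pop.rpe_intercept.draw(rng),
        rpe_fatigue_gain=pop.rpe_fatigue_gain.draw(rng),
        limb_asymmetry=pop.limb_asymmetry.draw(rng),
    )


def _rep_components(
    peak_N: float, n_samples: int, plateau_frac: float = _PLATEAU_FRAC
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed component r (rise + settle bump) and scalable component q (plateau).

    ``plateau_frac`` is subject-specific: curve shape varies across people, so
    a single row's absolute statistics cannot pin down that subject's fatigue
    gain without a baseline reference.
    """
    n = n_samples
    i = np.arange(n, dtype=float)
    n_rise = max(2, int(np.ceil(_RISE_FRAC * n)))
    tau = max(1.0, _SETTLE_TAU_FRAC * n)
    plateau = plateau_frac * peak_N

    r = np.zeros(n)
    q = np.zeros(n)
    r[: n_rise + 1] = peak_N * i[: n_rise + 1] / n_rise
    settle = i[n_rise + 1 :] - n_rise
    r[n_rise + 1 :] = (peak_N - plateau) * np.exp(-settle / tau)
    q[n_rise + 1 :] = plateau
    n_drop = min(_DROP_SAMPLES, max(0, n - n_rise - 2))
    if n_drop > 0:
        taper = np.linspace(1.0, _DROP_FLOOR, n_drop + 1)[1:]
        q[n - n_drop :] *= taper
    return r, q


def _rep_gain(r: np.ndarray, q: np.ndarray, set_index: int, fatigue_rate: float) -> float:
    """Gain on q so rep work equals decay**(set-1) times its set-1 work."""
    decay = 1.0 - fatigue_rate
    w_r = float(np.sum(r))
    w_q = float(np.sum(q))
    if w_q <= 0:
        raise ConfigError("repetition too short to carry a plateau")
    w1 = w_r + w_q
    g = (w1 * decay ** (set_index - 1) - w_r) / w_q
    if g <= 0:
        raise ConfigError(
            f"fatigue_rate {fatigue_rate} infeasible for set {set_index}: "
            "work target falls below the fixed rise component"
        )
    return g


def generate_rep_trace(
    profile: SubjectProfile,
    set_index: int,
    rep_index: int,
    rng: np.random.Generator,
    *,
    duration_s: float | None = None,
    sampling_interval_s: float = 0.02,
    duration_range_s: tuple[float, float] = (1.0, 4.0),
    peak_scale: float = 1.0,
) -> np.ndarray:
    """One push-phase force trace (newtons), noise already applied.

    The sample index of the maximum lies within the first 5% of the trace;
    expected work scales by ``(1 - fatigue_rate)**(set_index - 1)``; noise SD
    is ``noise_sd_N * (1 + variability_gain * (set_index - 1))``.
    """
    if set_index < 1 or rep_index < 1:
        raise ConfigError("set_index and rep_index are 1-based")
    if duration_s is None:
        duration_s = float(rng.uniform(*duration_range_s))
    # n >= 48 keeps the rise (>= 2 samples) inside the first 5% of samples.
    n = max(48, int(round(duration_s / sampling_interval_s)))
    peak = profile.base_peak_force_N * peak_scale
    r, q = _rep_components(peak, n, profile.plateau_frac)
    g = _rep_gain(r, q, set_index, profile.fatigue_rate)
    forces = r + g * q
    sd = profile.noise_sd_N * (1.0 + profile.variability_gain * (set_index - 1))
    if sd > 0:
        forces = forces + rng.normal(0.0, sd, size=n)
    return np.clip(forces, 0.0, None)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_session(
    profile: SubjectProfile,
    protocol: ProtocolConfig,
    rng: np.random.Generator | None = None,
    label_noise_sd: float = 0.5,
) -> SessionData:
    """Simulate one subject's full session: both limbs, all sets.

    Per-repetition durations are drawn once per limb and reused across sets so
    that, noise-free, the per-set work ratio follows the decay law exactly.
    The RPE label for set s is
    ``clip(round(rpe_intercept + rpe_fatigue_gain * latent + noise), 0, 10)``
    with ``latent = 1 - E[work(s)] / E[work(1)] = 1 - decay**(s-1)``; label
    noise is drawn per set and shared by both limbs, as a participant reports
    a single rating per set.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    dt = protocol.sampling_interval_s
    decay = 1.0 - profile.fatigue_rate

    # Per-set label noise, shared across limbs.
    set_noise = (
        rng.normal(0.0, label_noise_sd, size=protocol.n_sets)
        if label_noise_sd > 0
        else np.zeros(protocol.n_sets)
    )
    gap_n = max(1, int(round(protocol.inter_rep_gap_s / dt)))

    # Both limbs push the same bar: one duration draw per repetition, shared.
    durations = rng.uniform(*protocol.rep_duration_range_s, size=protocol.reps_per_set)
    rep_ns = [max(48, int(round(d / dt))) for d in durations]

    traces: list[ForceTrace] = []
    labels: dict[tuple[str, int], int] = {}
    truth: dict[tuple[str, int], SetTruth] = {}

    for limb in LIMBS:
        peak = profile.limb_peak_force(limb)
        components = [_rep_components(peak, n, profile.plateau_frac) for n in rep_ns]

        for s in range(1, protocol.n_sets + 1):
            sd = profile.noise_sd_N * (1.0 + profile.variability_gain * (s - 1))
            chunks: list[np.ndarray] = []
            windows: list[tuple[int, int]] = []
            rep_works: list[float] = []
            pos = 0

            def gap() -> np.ndarray:
                return rng.uniform(0.002 * peak, 0.01 * peak, size=gap_n)

            chunks.append(gap())
            pos += gap_n
            for r, q in components:
                g = _rep_gain(r, q, s, profile.fatigue_rate)
                clean = r + g * q
                rep_works.append(float(np.sum(clean)) * dt)
                forces = clean
                if sd > 0:
                    forces = forces + rng.normal(0.0, sd, size=clean.size)
                chunks.append(np.clip(forces, 0.0, None))
                windows.append((pos, pos + clean.size))
                pos += clean.size
                chunks.append(gap())
                pos += gap_n

            forces_all = np.concatenate(chunks)
            times = np.arange(forces_all.size) * dt
            traces.append(
                ForceTrace(
                    subject_id=profile.subject_id,
                    limb=limb,
                    set_index=s,
                    times_s=times,
                    forces_N=forces_all,
                    body_mass_kg=profile.body_mass_kg,
                    sampling_interval_s=dt,
                )
            )
            latent = 1.0 - decay ** (s - 1)
            truth[(limb, s)] = SetTruth(
                rep_windows=tuple(windows),
                rep_works=tuple(rep_works),
                expected_work=float(sum(rep_works)),
                latent_fatigue=latent,
            )
            raw = profile.rpe_intercept + profile.rpe_fatigue_gain * latent + set_noise[s - 1]
            labels[(limb, s)] = int(np.clip(_round_half_up(raw), 0, 10))

    return SessionData(
        subject_id=profile.subject_id, traces=traces, rpe_labels=labels, ground_truth=truth
    )


def generate_cohort(
    n_subjects: int,
    protocol: ProtocolConfig | None = None,
    population_params: PopulationParams | None = None,
) -> Cohort:
    """Generate a full cohort: ``2 * n_subjects`` limb datasets plus a manifest.

    Left and right limbs of one subject share the profile up to
    ``limb_asymmetry``, so limb feature values are positively correlated —
    the structure subject-grouped cross-validation exists to respect.
    """
    if n_subjects < 2:
        raise ConfigError("n_subjects must be >= 2")
    protocol = protocol or ProtocolConfig()
    pop = population_params or PopulationParams()

    root = np.random.SeedSequence(protocol.seed)
    subject_seeds = root.generate_state(n_subjects, dtype=np.uint32)

    profiles: list[SubjectProfile] = []
    sessions: list[SessionData] = []
    for i in range(n_subjects):
        profile = generate_subject(int(subject_seeds[i]), pop)
        profile = dataclasses.replace(profile, subject_id=f"S{i + 1:03d}")
        session_rng = np.random.default_rng([protocol.seed, i, 1])
        profiles.append(profile)
        sessions.append(
            generate_session(profile, protocol, session_rng, label_noise_sd=pop.label_noise_sd)
        )

    manifest = {
        "generator_version": GENERATOR_VERSION,
        "seed": protocol.seed,
        "n_subjects": n_subjects,
        "n_limb_datasets": 2 * n_subjects,
        "protocol": protocol.to_dict(),
        "population_params": pop.to_dict(),
    }
    return Cohort(profiles=profiles, sessions=sessions, manifest=manifest)


def cohort_frames(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(samples, labels, subjects) data frames for CSV export.

    The optional ground-truth ``rep_index`` column is 1-based; samples in
    inter-repetition gaps carry 0.
    """
    sample_rows = []
    label_rows = []
    for session in cohort.sessions:
        for trace in session.traces:
            key = (trace.limb, trace.set_index)
            rep_idx = np.zeros(len(trace), dtype=int)
            for j, (a, b) in enumerate(session.ground_truth[key].rep_windows, start=1):
                rep_idx[a:b] = j
            sample_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": trace.subject_id,
                        "limb": trace.limb,
                        "set_index": trace.set_index,
                        "rep_index": rep_idx,
                        "time_s": trace.times_s,
                        "force_N": trace.forces_N,
                    }
                )
            )
        for (limb, s), rpe in sorted(session.rpe_labels.items()):
            label_rows.append(
                {"subject_id": session.subject_id, "limb": limb, "set_index": s, "rpe": rpe}
            )
    samples = pd.concat(sample_rows, ignore_index=True)
    labels = pd.DataFrame(label_rows)
    subjects = pd.DataFrame([dataclasses.asdict(p) for p in cohort.profiles])
    return samples, labels, subjects


def export_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write samples.csv, labels.csv, subjects.csv and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, labels, subjects = cohort_frames(cohort)
    paths = {
        "samples": out / "samples.csv",
        "labels": out / "labels.csv",
        "subjects": out / "subjects.csv",
        "manifest": out / "manifest.json",
    }
    samples.to_csv(paths["samples"], index=False)
    labels.to_csv(paths["labels"], index=False)
    subjects.to_csv(paths["subjects"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def load_cohort_csv(
    samples_path: str | Path, labels_path: str | Path, subjects_path: str | Path
) -> tuple[list[ForceTrace], dict[tuple[str, str, int], int]]:
    """Rebuild traces and the label map from exported CSVs."""
    samples = pd.read_csv(samples_path)
    labels = pd.read_csv(labels_path)
    subjects = pd.read_csv(subjects_path).set_index("subject_id")

    traces: list[ForceTrace] = []
    for (sid, limb, s), grp in samples.groupby(
        ["subject_id", "limb", "set_index"], sort=True
    ):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy()
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.02
        traces.append(
            ForceTrace(
                subject_id=str(sid),
                limb=str(limb),
                set_index=int(s),
                times_s=times,
                forces_N=grp["force_N"].to_numpy(),
                body_mass_kg=float(subjects.loc[sid, "body_mass_kg"]),
                sampling_interval_s=dt,
            )
        )
    label_map = {
        (str(r.subject_id), str(r.limb), int(r.set_index)): int(r.rpe)
        for r in labels.itertuples()
    }
    return traces, label_map
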