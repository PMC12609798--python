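import numpy as np
import pytest

from repforce import synth
from repforce.features import FeatureConfig, build_table
from repforce.pipeline import PreprocessConfig, preprocess_cohort
from repforce.synth import FieldDist, PopulationParams, ProtocolConfig


def noise_free_population(**overrides) -> PopulationParams:
    """Population with all stochastic trace/label noise switched off."""
    base = dict(
        noise_sd_N=FieldDist(0.0, 0.0, 0.0, 20.0),
        variability_gain=FieldDist(0.0, 0.0, 0.0, 1.0),
        label_noise_sd=0.0,
    )
    base.update(overrides)
    return PopulationParams(**base)


def make_profile(**overrides) -> synth.SubjectProfile:
    defaults = dict(
        subject_id="S001",
        body_mass_kg=74.4,
        base_peak_force_N=400.0,
        fatigue_rate=0.06,
        variability_gain=0.0,
        noise_sd_N=0.0,
        plateau_frac=0.8,
        rpe_intercept=3.0,
        rpe_fatigue_gain=14.0,
        limb_asymmetry=0.05,
    )
    defaults.update(overrides)
    return synth.SubjectProfile(**defaults)


def cohort_table(
    seed: int,
    n_subjects: int = 6,
    population: PopulationParams | None = None,
    feature_config: FeatureConfig | None = None,
    protocol_kwargs: dict | None = None,
):
    """Small end-to-end table: simulate -> preprocess -> features."""
    protocol = ProtocolConfig(seed=seed, **(protocol_kwargs or {}))
    cohort = synth.generate_cohort(n_subjects, protocol, population or PopulationParams())
    traces = [t for s in cohort.sessions for t in s.traces]
    labels = {
        (s.subject_id, limb, si): r
        for s in cohort.sessions
        for (limb, si), r in s.rpe_labels.items()
    }
    reps_map, _ = preprocess_cohort(traces, PreprocessConfig())
    return build_table(reps_map, labels, feature_config)


@pytest.fixture(scope="session")
def small_table():
    """Default 6-subject table reused by model/evaluate tests."""
    return cohort_table(seed=5)


@pytest.fixture(scope="session")
def noise_free_session():
    """One noise-free session with known ground truth."""
    profile = make_profile(fatigue_rate=0.05)
    return profile, synth.generate_session(
        profile, ProtocolConfig(seed=0), np.random.default_rng(0), label_noise_sd=0.0
    )
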