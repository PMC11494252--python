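"""Shared fixtures: small fast cohorts plus one session-scoped study-scale
dataset reused by the slower end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

import rehabkit as rk


@pytest.fixture(scope="session")
def small_config() -> rk.SimulationConfig:
    """A few patients with short sessions — fast enough for unit tests."""
    return rk.SimulationConfig(
        n_patients=6,
        session_minutes_range=(2.0, 4.0),
        activities_per_session_range=(1, 3),
        sessions_per_patient_range=(2, 3),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> rk.Cohort:
    return rk.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_labeled(small_cohort) -> "pd.DataFrame":
    feats = rk.extract_features(small_cohort.streams)
    return rk.attach_labels(feats, small_cohort.assessments_frame())


STUDY_SEED = 5


@pytest.fixture(scope="session")
def study_labeled() -> "pd.DataFrame":
    """Default study-scale cohort (33 patients, >2000 activities), filtered
    and labeled — shared by the slower integration checks."""
    features, assessments = rk.generate_labeled_features(
        rk.SimulationConfig(seed=STUDY_SEED)
    )
    return rk.attach_labels(rk.filter_low_activity(features), assessments)


@pytest.fixture(scope="session")
def study_split(study_labeled) -> rk.SplitDataset:
    return rk.split_dataset(
        study_labeled, train_fraction=0.8, seed=STUDY_SEED, stratified=True
    )


def zigzag_stream(rng: np.random.Generator, n_segments: int, hysteresis: float):
    """Random piecewise-monotone signal with known interior extrema.

    Segment amplitudes are drawn far above the hysteresis band and the added
    noise stays far below half of it, so the exact movement count equals the
    number of interior extrema of the generating zigzag.
    """
    levels = [0.0]
    for i in range(n_segments):
        step = rng.uniform(4.0 * hysteresis, 10.0 * hysteresis)
        sign = 1.0 if i % 2 == 0 else -1.0
        levels.append(levels[-1] + sign * step)
    samples = []
    for a, b in zip(levels[:-1], levels[1:]):
        seg = np.linspace(a, b, rng.integers(8, 20), endpoint=False)
        samples.append(seg)
    x = np.concatenate(samples)
    x = x + rng.uniform(-0.2 * hysteresis, 0.2 * hysteresis, size=x.size)
    n_extrema = n_segments - 1
    return x, n_extrema
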