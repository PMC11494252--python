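"""Synthetic cohort generator for robotic wrist/ankle therapy sessions.

The original study data — 33 stroke survivors performing self-guided therapy
with a pneumatically assisted hand/foot device that streams joint angle
(degrees from a rest midpoint) and actuator pressure (PSI) at 30 Hz — were
never deposited.  This module generates cohorts with the same statistical
structure: per-patient residual-severity classes ("no", "low", "high" range
of motion), class-conditional volitional amplitude and assistance pressure,
sessions of 5-60 minutes containing 1-10 therapeutic activities, sensor
noise with occasional outlier spikes, and unstandardized per-game scores.

The angle signal is the sum of a volitional component (a slow sinusoid at
the patient's movement rate, with amplitude set by residual ability), a
machine component (the air muscle's slow stretch cycle, whose excursion is
the assistance pressure times a per-patient coupling constant), a smooth
jitter process and white sensor noise.  Assistance pressure is highest for
the weakest patients — the device does the moving for them — so observed
range of motion confounds volitional ability with machine assistance, and
adjacent severity classes overlap in every single feature.  The "low"
class is additionally a patient-level mixture of two phenotypes (little
assistance used, or large machine-assisted excursions under high
pressure), reflecting that low-ROM patients may or may not manage an
assisted assessment.  Severity is therefore recoverable only from feature
interactions (range of motion relative to pressure, movement counts
relative to duration), not from any linear combination of features.

Reproducibility: one master seed; the random stream for patient ``p`` is
seeded with ``SeedSequence([master, 1, p])``, the assessment stream with
``SeedSequence([master, 2, p])``, and activity ``g`` of session ``s`` with
``SeedSequence([master, 3, p, s, g])``, so any single stream can be
regenerated without simulating the whole cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import lfilter

SEVERITY_CLASSES = ("no", "low", "high")
PERIPHERALS = ("hand", "foot")

#: ankle range of motion is mechanically smaller than wrist range
FOOT_ROM_SCALE = 0.7

#: AR(1) pole of the slow movement-jitter process
_JITTER_RHO = 0.99


def _rng(seed: int | SeedSequence | Generator) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


@dataclass(frozen=True)
class ClassProfile:
    """Generating distribution for one residual-severity class.

    ``volitional_amplitude_deg`` and ``assist_pressure_psi`` are
    (mean, SD) pairs describing between-patient variation.  An optional
    alternative phenotype (``alt_*`` fields, drawn with probability
    ``alt_weight`` per patient) models within-class heterogeneity.
    ``passive_max_deg``/``passive_min_deg`` describe the clinician-stretched
    joint range recorded during assessment, which is largely independent of
    volitional ability.
    """

    label: str
    volitional_amplitude_deg: tuple[float, float]
    assist_pressure_psi: tuple[float, float]
    movement_rate_hz: float
    noise_sd_deg: float = 0.8
    spike_prob: float = 0.001
    spike_scale: float = 6.0
    alt_amplitude_deg: tuple[float, float] | None = None
    alt_assist_pressure_psi: tuple[float, float] | None = None
    alt_weight: float = 0.0
    assist_coupling_deg_per_psi: tuple[float, float] = (2.0, 0.6)
    assist_cycle_hz: float = 0.05
    rest_offset_sd_deg: float = 4.0  # per-activity placement shift of the midpoint
    passive_max_deg: tuple[float, float] = (35.0, 8.0)
    passive_min_deg: tuple[float, float] = (-16.0, 4.0)

    def __post_init__(self) -> None:
        if self.label not in SEVERITY_CLASSES:
            raise ValueError(f"unknown severity label {self.label!r}")
        if self.volitional_amplitude_deg[0] < 0 or self.volitional_amplitude_deg[1] < 0:
            raise ValueError("amplitude mean/SD must be >= 0")
        if self.noise_sd_deg < 0 or self.spike_scale < 0:
            raise ValueError("noise and spike scale must be >= 0")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError("spike_prob must lie in [0, 1]")
        if not 0.0 <= self.alt_weight <= 1.0:
            raise ValueError("alt_weight must lie in [0, 1]")
        if self.movement_rate_hz <= 0:
            raise ValueError("movement_rate_hz must be > 0")

    def draw_phenotype(self, rng: Generator) -> tuple[tuple[float, float], tuple[float, float]]:
        """Pick (amplitude dist, pressure dist), honouring the mixture."""
        if self.alt_weight > 0 and rng.random() < self.alt_weight:
            assert self.alt_amplitude_deg is not None
            assert self.alt_assist_pressure_psi is not None
            return self.alt_amplitude_deg, self.alt_assist_pressure_psi
        return self.volitional_amplitude_deg, self.assist_pressure_psi

    def resolve_patient(self, rng: Generator) -> "ClassProfile":
        """Collapse between-patient variation into one patient's profile.

        Draws the patient's own amplitude, assistance level and movement
        rate; the returned profile keeps a small within-patient SD so
        activities of one patient still vary.
        """
        amp_dist, press_dist = self.draw_phenotype(rng)
        amp = max(0.0, rng.normal(*amp_dist))
        press = max(0.0, rng.normal(*press_dist))
        rate = self.movement_rate_hz * rng.uniform(0.8, 1.25)
        coupling = max(0.0, rng.normal(*self.assist_coupling_deg_per_psi))
        return dataclasses.replace(
            self,
            volitional_amplitude_deg=(amp, 0.1 * amp + 0.3),
            assist_pressure_psi=(press, 0.25),
            movement_rate_hz=rate,
            assist_coupling_deg_per_psi=(coupling, 0.1 * coupling),
            alt_amplitude_deg=None,
            alt_assist_pressure_psi=None,
            alt_weight=0.0,
        )


def default_profiles() -> dict[str, ClassProfile]:
    """Default generating profiles for the three severity classes.

    Volitional amplitude orders no < low < high; assistance pressure is
    highest for "no" patients (the device does the moving) and lowest for
    "high" patients.  Half of the "low" class is an assisted phenotype with
    large excursions under high pressure.
    """
    return {
        "no": ClassProfile(
            label="no",
            volitional_amplitude_deg=(3.0, 2.0),
            assist_pressure_psi=(8.0, 1.5),
            movement_rate_hz=0.12,
            passive_max_deg=(38.0, 6.0),
            passive_min_deg=(-15.0, 4.0),
        ),
        "low": ClassProfile(
            label="low",
            volitional_amplitude_deg=(12.0, 6.0),
            assist_pressure_psi=(3.0, 1.0),
            movement_rate_hz=0.3,
            alt_amplitude_deg=(12.0, 6.0),
            alt_assist_pressure_psi=(7.5, 1.5),
            alt_weight=0.5,
            passive_max_deg=(40.0, 12.0),
            passive_min_deg=(-17.0, 4.0),
        ),
        "high": ClassProfile(
            label="high",
            volitional_amplitude_deg=(32.0, 10.0),
            assist_pressure_psi=(2.0, 0.8),
            movement_rate_hz=0.5,
            passive_max_deg=(17.0, 12.0),
            passive_min_deg=(-17.0, 3.0),
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generating conditions."""

    n_patients: int = 33
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    session_minutes_range: tuple[float, float] = (5.0, 60.0)
    activities_per_session_range: tuple[int, int] = (1, 10)
    sessions_per_patient_range: tuple[int, int] = (10, 15)
    sample_rate_hz: float = 30.0
    profiles: dict[str, ClassProfile] = field(default_factory=default_profiles)
    hand_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must be 3 nonnegative probabilities summing to 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        for lo, hi in (
            self.session_minutes_range,
            self.activities_per_session_range,
            self.sessions_per_patient_range,
        ):
            if lo > hi or lo <= 0:
                raise ValueError("ranges must be nonempty and positive")
        if set(self.profiles) != set(SEVERITY_CLASSES):
            raise ValueError("profiles must cover exactly the classes no/low/high")


@dataclass
class SensorStream:
    """Raw 30 Hz record of one therapeutic activity (one video game)."""

    timestamps: np.ndarray  # seconds, uniform
    angle: np.ndarray  # degrees from rest midpoint (flexion < 0 < extension)
    pressure: np.ndarray  # PSI
    score_events: list[tuple[float, float]]  # (time, cumulative score)
    peripheral: str = "hand"
    patient_id: int = 0
    session_id: int = 0
    game_id: int = 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if not (len(self.timestamps) == len(self.angle) == len(self.pressure)):
            raise ValueError("timestamps, angle and pressure must have equal length")
        if len(self.timestamps) > 1 and not (np.diff(self.timestamps) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.peripheral not in PERIPHERALS:
            raise ValueError(f"unknown peripheral {self.peripheral!r}")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def ids(self) -> tuple[int, int, int]:
        return (self.patient_id, self.session_id, self.game_id)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (time_s, angle_deg, pressure_psi, score).

        The score column carries the cumulative score forward between the
        irregular score events; NaN before the first event.
        """
        score = np.full(self.n_samples, np.nan)
        for t_ev, cum in self.score_events:
            score[self.timestamps >= t_ev - 1e-12] = cum
        return pd.DataFrame(
            {
                "time_s": self.timestamps,
                "angle_deg": self.angle,
                "pressure_psi": self.pressure,
                "score": score,
            }
        )


@dataclass(frozen=True)
class ClinicianAssessment:
    """One row of the clinician assessment table."""

    patient_id: int
    max_angle_deg: float
    min_angle_deg: float
    assessment: str  # "Passive" | "Assisted"
    label: str  # severity class

    def __post_init__(self) -> None:
        if self.label not in SEVERITY_CLASSES:
            raise ValueError(f"unknown severity label {self.label!r}")
        if self.assessment not in ("Passive", "Assisted"):
            raise ValueError(f"unknown assessment type {self.assessment!r}")


@dataclass
class Cohort:
    """Simulated cohort: raw streams plus ground-truth severity labels."""

    streams: list[SensorStream]
    truth_labels: dict[int, str]
    assessments: list[ClinicianAssessment]

    def assessments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": a.patient_id,
                    "max_angle_deg": a.max_angle_deg,
                    "min_angle_deg": a.min_angle_deg,
                    "assessment": a.assessment,
                    "label": a.label,
                }
                for a in self.assessments
            ],
            columns=["patient_id", "max_angle_deg", "min_angle_deg", "assessment", "label"],
        )


def simulate_activity(
    profile: ClassProfile,
    duration_s: float,
    rate_hz: float,
    peripheral: str = "hand",
    seed: int | SeedSequence | Generator = 0,
    ids: tuple[int, int, int] = (0, 0, 0),
    monotone_score: bool = True,
) -> SensorStream:
    """Simulate the raw sensor record of a single therapeutic activity.

    Angle = A·sin(2πft + φ) + slow jitter + white noise, with occasional
    outlier spikes replacing single samples by rest ± spike_scale·A (sensor
    faults; these motivate the winsorization step downstream).  Pressure is
    the patient's assistance level modulated anti-phase with the movement
    plus noise.  A sinusoid at frequency f reverses direction 2f times per
    second, so f = movement_rate/2.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    if peripheral not in PERIPHERALS:
        raise ValueError(f"unknown peripheral {peripheral!r}")
    rng = _rng(seed)

    n = int(np.ceil(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    amp_dist, press_dist = profile.draw_phenotype(rng)
    amp = max(0.0, rng.normal(*amp_dist))
    if peripheral == "foot":
        amp *= FOOT_ROM_SCALE
    assist = max(0.0, rng.normal(*press_dist))
    coupling = max(0.0, rng.normal(*profile.assist_coupling_deg_per_psi))
    machine_amp = coupling * assist
    if peripheral == "foot":
        machine_amp *= FOOT_ROM_SCALE

    f = profile.movement_rate_hz / 2.0
    phase = rng.uniform(0.0, 2.0 * np.pi)
    assist_phase = rng.uniform(0.0, 2.0 * np.pi)
    # the peripheral is re-donned for each activity, shifting the rest midpoint
    rest = rng.normal(0.0, profile.rest_offset_sd_deg) if profile.rest_offset_sd_deg else 0.0
    angle = rest + amp * np.sin(2.0 * np.pi * f * t + phase)
    # the air muscle also moves the joint passively: a slow stretch cycle
    # whose excursion scales with assistance pressure, so observed range of
    # motion confounds volitional ability with machine assistance
    angle = angle + machine_amp * np.sin(
        2.0 * np.pi * profile.assist_cycle_hz * t + assist_phase
    )

    if profile.noise_sd_deg > 0:
        white = rng.normal(0.0, profile.noise_sd_deg, n)
        innov = rng.normal(0.0, profile.noise_sd_deg, n)
        jitter = lfilter(
            [2.0 * np.sqrt(1.0 - _JITTER_RHO**2)], [1.0, -_JITTER_RHO], innov
        )
        angle = angle + jitter + white

    if profile.spike_prob > 0 and profile.spike_scale > 0:
        mask = rng.random(n) < profile.spike_prob
        k = int(mask.sum())
        if k:
            scale = profile.spike_scale * (amp + machine_amp)
            angle[mask] = rest + rng.choice([-1.0, 1.0], k) * scale

    # actuation depth varies between activities (game demands differ)
    depth = rng.uniform(0.15, 0.6)
    pressure = assist * (
        1.0
        + depth
        * np.sin(2.0 * np.pi * profile.assist_cycle_hz * t + assist_phase + np.pi)
    )
    pressure = pressure + rng.normal(0.0, 0.4, n)

    # unstandardized per-game scoring: event rate ~ movement rate, score
    # unit varies by orders of magnitude between games
    score_events: list[tuple[float, float]] = []
    unit = float(10 ** rng.integers(0, 3))
    t_ev = float(rng.exponential(1.0 / 0.15))
    cum = 0.0
    while t_ev < duration_s:
        delta = float(rng.integers(1, 6)) * unit
        if not monotone_score and rng.random() < 0.3:
            delta = -delta
        cum += delta
        score_events.append((t_ev, cum))
        t_ev += float(rng.exponential(1.0 / 0.15))

    return SensorStream(
        timestamps=t,
        angle=angle,
        pressure=pressure,
        score_events=score_events,
        peripheral=peripheral,
        patient_id=ids[0],
        session_id=ids[1],
        game_id=ids[2],
    )


def simulate_assessment(
    truth_label: str,
    profile: ClassProfile,
    seed: int | SeedSequence | Generator = 0,
) -> ClinicianAssessment:
    """Simulate the clinician's recorded assessment for one patient.

    The recorded min/max angles reflect the clinician stretching or
    assisting the joint, so they follow the profile's passive-range
    distributions rather than its volitional amplitude.  Assessment type
    follows the labeling protocol: "no" patients only complete the passive
    assessment, all "high" patients complete the assisted one, and "low"
    patients may or may not.
    """
    if truth_label not in SEVERITY_CLASSES:
        raise ValueError(f"unknown severity label {truth_label!r}")
    rng = _rng(seed)
    mx = rng.normal(*profile.passive_max_deg)
    mn = rng.normal(*profile.passive_min_deg)
    if mn > mx:
        mn, mx = mx, mn
    if truth_label == "no":
        kind = "Passive"
    elif truth_label == "high":
        kind = "Assisted"
    else:
        kind = "Passive" if rng.random() < 0.5 else "Assisted"
    return ClinicianAssessment(
        patient_id=0,
        max_angle_deg=float(mx),
        min_angle_deg=float(mn),
        assessment=kind,
        label=truth_label,
    )


def _patient_plan(config: SimulationConfig, p: int):
    """Deterministic per-patient draws (label, resolved profile, sessions)."""
    rng = default_rng(SeedSequence([config.seed, 1, p]))
    label = str(rng.choice(SEVERITY_CLASSES, p=config.class_mix))
    patient_profile = config.profiles[label].resolve_patient(rng)
    peripheral = "hand" if rng.random() < config.hand_fraction else "foot"
    lo_s, hi_s = config.sessions_per_patient_range
    n_sessions = int(rng.integers(lo_s, hi_s + 1))
    sessions = []
    lo_m, hi_m = config.session_minutes_range
    lo_a, hi_a = config.activities_per_session_range
    for s in range(n_sessions):
        minutes = float(rng.uniform(lo_m, hi_m))
        n_act = int(rng.integers(lo_a, hi_a + 1))
        fractions = rng.dirichlet(np.full(n_act, 2.0))
        durations = np.maximum(fractions * minutes * 60.0, 5.0)
        sessions.append(durations)
    return label, patient_profile, peripheral, sessions


def iter_streams(config: SimulationConfig) -> Iterator[SensorStream]:
    """Yield every activity stream of the cohort without holding them all.

    Memory-friendly path for large cohorts; `simulate_cohort` collects the
    same streams into a `Cohort`.
    """
    for p in range(config.n_patients):
        _, patient_profile, peripheral, sessions = _patient_plan(config, p)
        for s, durations in enumerate(sessions):
            for g, dur in enumerate(durations):
                yield simulate_activity(
                    patient_profile,
                    float(dur),
                    config.sample_rate_hz,
                    peripheral=peripheral,
                    seed=SeedSequence([config.seed, 3, p, s, g]),
                    ids=(p, s, g),
                )


def simulate_truth_and_assessments(
    config: SimulationConfig,
) -> tuple[dict[int, str], list[ClinicianAssessment]]:
    """Ground-truth labels and clinician-style assessments, one per patient."""
    truth: dict[int, str] = {}
    assessments: list[ClinicianAssessment] = []
    for p in range(config.n_patients):
        label, _, _, _ = _patient_plan(config, p)
        truth[p] = label
        a = simulate_assessment(
            label, config.profiles[label], SeedSequence([config.seed, 2, p])
        )
        assessments.append(dataclasses.replace(a, patient_id=p))
    return truth, assessments


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a full cohort (all raw streams held in memory)."""
    truth, assessments = simulate_truth_and_assessments(config)
    return Cohort(
        streams=list(iter_streams(config)),
        truth_labels=truth,
        assessments=assessments,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort as plain-text tables: one CSV per activity stream,
    a manifest, and the assessment table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for stream in cohort.streams:
        p, s, g = stream.ids
        name = f"stream_p{p:03d}_s{s:03d}_g{g:03d}.csv"
        stream.to_frame().to_csv(out / name, index=False)
        manifest.append(
            {
                "patient_id": p,
                "session_id": s,
                "game_id": g,
                "peripheral": stream.peripheral,
                "file": name,
            }
        )
    pd.DataFrame(
        manifest, columns=["patient_id", "session_id", "game_id", "peripheral", "file"]
    ).to_csv(out / "manifest.csv", index=False)
    cohort.assessments_frame().to_csv(out / "assessments.csv", index=False)


def read_stream_csv(path, peripheral: str = "hand", ids: tuple[int, int, int] = (0, 0, 0)) -> SensorStream:
    """Read one activity stream written by `write_cohort`."""
    df = pd.read_csv(path)
    score = df["score"].to_numpy() if "score" in df else np.full(len(df), np.nan)
    events: list[tuple[float, float]] = []
    last = np.nan
    for t, v in zip(df["time_s"].to_numpy(), score):
        if not np.isnan(v) and v != last:
            events.append((float(t), float(v)))
            last = v
    return SensorStream(
        timestamps=df["time_s"].to_numpy(),
        angle=df["angle_deg"].to_numpy(),
        pressure=df["pressure_psi"].to_numpy(),
        score_events=events,
        peripheral=peripheral,
        patient_id=ids[0],
        session_id=ids[1],
        game_id=ids[2],
    )
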