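"""Activity-level feature extraction from raw angle/pressure streams.

One therapeutic activity's 30 Hz record is reduced to the summary row used
by the classifiers: cleaning (winsorize outliers at the 1st/99th
percentiles, then a short centered moving average), then range-of-motion
and pressure summaries, a hysteresis movement count, direction-split
centripetal-force maxima from the angular velocity, activity duration,
maximum game score and the peripheral indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import SensorStream

#: canonical data-dictionary order of the model features
FEATURE_ORDER = [
    "F_flex",
    "F_ext",
    "N_mov",
    "R_min",
    "R_max",
    "t_game",
    "P_min",
    "P_max",
    "P_mean",
    "Score",
    "h",
]

#: features plus the mean ROM, which is computed and carried but not part of
#: the canonical dictionary
EXTENDED_FEATURES = FEATURE_ORDER[:5] + ["R_mean"] + FEATURE_ORDER[5:]

ID_COLUMNS = ["patient_id", "session_id", "game_id"]

#: peripheral indicator coding
H_CODES = {"hand": 0, "foot": 1}


@dataclass(frozen=True)
class CleaningParams:
    """Cleaning and summarization parameters.

    winsor_low_pct / winsor_high_pct
        percentile band outside which samples are clipped (default 1/99).
    smooth_window
        centered moving-average window in samples; 5 samples ≈ 0.17 s at
        30 Hz, enough to kill single-sample noise without flattening
        sub-second movements.
    movement_hysteresis_deg
        minimum excursion (degrees) between counted direction changes;
        2° keeps residual sensor noise from inflating the movement count.
    force_constant
        effective mass × lever-arm constant c in F = c·ω² (N·s²/rad²);
        only relative magnitudes matter once features are z-scored, so the
        default is 1.
    """

    winsor_low_pct: float = 1.0
    winsor_high_pct: float = 99.0
    smooth_window: int = 5
    movement_hysteresis_deg: float = 2.0
    force_constant: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.winsor_low_pct < self.winsor_high_pct <= 100.0:
            raise ValueError("winsor percentiles must satisfy 0 <= low < high <= 100")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.movement_hysteresis_deg < 0:
            raise ValueError("movement_hysteresis_deg must be >= 0")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")


@dataclass
class ActivityFeatures:
    """The summary row for one (patient, session, game) activity."""

    F_flex: float  # max centripetal force moving downward (reported <= 0), N
    F_ext: float  # max centripetal force moving upward (>= 0), N
    N_mov: int  # completed movements (direction changes)
    R_min: float  # degrees
    R_max: float  # degrees
    R_mean: float  # degrees
    t_game: float  # seconds
    P_min: float  # PSI
    P_max: float  # PSI
    P_mean: float  # PSI
    Score: float  # maximum cumulative game score
    h: int  # peripheral indicator (0 hand, 1 foot)
    patient_id: int = 0
    session_id: int = 0
    game_id: int = 0
    Class: str | None = None  # severity label, attached downstream

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ID_COLUMNS + EXTENDED_FEATURES}
        if self.Class is not None:
            d["Class"] = self.Class
        return d


def fill_missing(x, method: str = "ffill") -> np.ndarray:
    """Sanitize dropped sensor readings (NaNs) within one stream.

    "ffill" carries the last valid reading forward (leading NaNs take the
    first valid value); "drop" removes missing samples instead.  A series
    with no valid sample raises.
    """
    s = pd.Series(np.asarray(x, dtype=float))
    if s.size and s.isna().all():
        raise ValueError("series has no valid samples")
    if method == "ffill":
        return s.ffill().bfill().to_numpy()
    if method == "drop":
        return s.dropna().to_numpy()
    raise ValueError(f"unknown missing-value method {method!r}")


def winsorize_series(x, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Clip a series to its own [low_pct, high_pct] percentile band.

    Values inside the band are unchanged; length is preserved.  The bounds
    are the order statistics nearest outside the requested percentiles
    (floor index for the lower, ceil for the upper), which makes the
    operation exactly idempotent.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot winsorize an empty series")
    if not 0.0 <= low_pct < high_pct <= 100.0:
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
    lo = np.percentile(x, low_pct, method="lower")
    hi = np.percentile(x, high_pct, method="higher")
    return np.clip(x, lo, hi)


def smooth_series(x, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage.

    Near the edges the window shrinks to the available samples, so length
    is preserved and window=1 is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    if window == 1 or x.size <= 1:
        return x.copy()
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _turning_points(x: np.ndarray) -> np.ndarray:
    """Compress a series to its endpoints and strict local extrema.

    Plateaus are treated as a single point.  The hysteresis counter's
    decisions depend only on values at local extrema, so counting on the
    compressed sequence equals counting on the full series.
    """
    if x.size <= 2:
        return x
    d = np.diff(x)
    s = np.sign(d)
    # carry the previous direction through zero-steps (plateaus)
    nz = s != 0
    if not nz.any():
        return x[[0, -1]]
    idx = np.where(nz, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0)
    turns = np.where(filled[1:] * filled[:-1] < 0)[0] + 1
    keep = np.concatenate(([0], turns, [x.size - 1]))
    return x[keep]


def count_movements(angle, hysteresis_deg: float = 2.0) -> int:
    """Count direction changes of the (smoothed) angle signal.

    A change of direction is counted only once the signal has moved at
    least ``hysteresis_deg`` away from the last counted extremum, so
    residual noise below the hysteresis band contributes nothing.  The
    first establishment of a direction is not itself a change.  Empty or
    constant input yields 0.
    """
    if hysteresis_deg < 0:
        raise ValueError("hysteresis_deg must be >= 0")
    x = np.asarray(angle, dtype=float)
    if x.size < 2:
        return 0
    pts = _turning_points(x)
    count = 0
    direction = 0
    rmin = rmax = ext = pts[0]
    for v in pts[1:]:
        if direction == 0:
            rmin = min(rmin, v)
            rmax = max(rmax, v)
            if v - rmin >= hysteresis_deg and v >= rmax:
                direction, ext = 1, v
            elif rmax - v >= hysteresis_deg and v <= rmin:
                direction, ext = -1, v
        elif direction == 1:
            if v > ext:
                ext = v
            elif ext - v >= hysteresis_deg:
                count += 1
                direction, ext = -1, v
        else:
            if v < ext:
                ext = v
            elif v - ext >= hysteresis_deg:
                count += 1
                direction, ext = 1, v
    return count


def centripetal_forces(
    angle, rate_hz: float, force_constant: float = 1.0
) -> tuple[float, float]:
    """Direction-split maxima of the centripetal force c·ω².

    Angular velocity ω comes from central differences of the angle signal
    (degrees converted to radians before squaring).  F_ext is the maximum
    over samples moving upward (ω > 0); F_flex is the maximum over samples
    moving downward, reported as a negative number by convention.  A
    constant signal yields (0, 0).
    """
    x = np.asarray(angle, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to estimate angular velocity")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    omega = np.gradient(np.deg2rad(x), 1.0 / rate_hz)
    force = force_constant * omega**2
    up = omega > 0
    down = omega < 0
    f_ext = float(force[up].max()) if up.any() else 0.0
    f_flex = -float(force[down].max()) if down.any() else 0.0
    return f_flex, f_ext


def summarize_activity(
    stream: SensorStream, params: CleaningParams = CleaningParams()
) -> ActivityFeatures:
    """Reduce one raw stream to its activity-level feature row.

    Cleaning order: winsorize first (sensor-fault spikes), then smooth.
    ROM summaries come from the cleaned angle, pressure summaries from the
    cleaned pressure; the movement count and forces are computed on the
    cleaned angle.  t_game is the span of the timestamps and Score the
    maximum cumulative score (0 if the game emitted no score events).
    """
    if stream.n_samples == 0:
        raise ValueError("cannot summarize an empty stream")
    if stream.n_samples < 3:
        raise ValueError("need at least 3 samples to summarize an activity")

    angle = smooth_series(
        winsorize_series(
            fill_missing(stream.angle), params.winsor_low_pct, params.winsor_high_pct
        ),
        params.smooth_window,
    )
    pressure = smooth_series(
        winsorize_series(
            fill_missing(stream.pressure), params.winsor_low_pct, params.winsor_high_pct
        ),
        params.smooth_window,
    )
    dt = np.diff(stream.timestamps)
    rate_hz = 1.0 / float(np.median(dt))
    f_flex, f_ext = centripetal_forces(angle, rate_hz, params.force_constant)
    score = max((cum for _, cum in stream.score_events), default=0.0)
    return ActivityFeatures(
        F_flex=f_flex,
        F_ext=f_ext,
        N_mov=count_movements(angle, params.movement_hysteresis_deg),
        R_min=float(angle.min()),
        R_max=float(angle.max()),
        R_mean=float(angle.mean()),
        t_game=float(stream.timestamps[-1] - stream.timestamps[0]),
        P_min=float(pressure.min()),
        P_max=float(pressure.max()),
        P_mean=float(pressure.mean()),
        Score=float(score),
        h=H_CODES[stream.peripheral],
        patient_id=stream.patient_id,
        session_id=stream.session_id,
        game_id=stream.game_id,
    )


def extract_features(
    streams: Iterable[SensorStream], params: CleaningParams = CleaningParams()
) -> pd.DataFrame:
    """Summarize an iterable of streams into the feature table.

    Streams are consumed lazily, so this works with the generator from
    `rehabkit.simulate.iter_streams` without holding raw data in memory.
    """
    rows = [summarize_activity(s, params).as_dict() for s in streams]
    return pd.DataFrame(rows, columns=ID_COLUMNS + EXTENDED_FEATURES)
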