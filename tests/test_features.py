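"""Feature extraction: winsorization, smoothing, movement counting,
centripetal forces and the activity summary, each against an independent
oracle wherever the operation admits one."""

import numpy as np
import pytest

import rehabkit as rk
from rehabkit.simulate import SensorStream

from conftest import zigzag_stream


def sort_percentile_oracle(x, pct, side="interp"):
    """Sort-and-index percentile oracle, independent of np.percentile.

    side="low"/"high" returns the order statistic at the floor/ceil index
    (the winsorization bound convention); "interp" linearly interpolates.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    pos = pct / 100.0 * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    if side == "low":
        return xs[lo]
    if side == "high":
        return xs[hi]
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def _stream(angle, rate=30.0, pressure=None, events=None, peripheral="hand"):
    angle = np.asarray(angle, dtype=float)
    t = np.arange(angle.size) / rate
    p = np.zeros_like(angle) if pressure is None else np.asarray(pressure, float)
    return SensorStream(t, angle, p, events or [], peripheral=peripheral)


class TestWinsorize:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.3)
        assert np.array_equal(rk.winsorize_series(x), x)

    def test_outlier_clipped_to_percentile_of_input(self):
        x = np.arange(1, 1001, dtype=float)
        x[500] = 1e6
        out = rk.winsorize_series(x, 1, 99)
        assert out.max() == pytest.approx(sort_percentile_oracle(x, 99, "high"))
        assert out.min() == pytest.approx(sort_percentile_oracle(x, 1, "low"))

    def test_interior_values_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        lo = sort_percentile_oracle(x, 1, "low")
        hi = sort_percentile_oracle(x, 99, "high")
        out = rk.winsorize_series(x, 1, 99)
        inside = (x >= lo) & (x <= hi)
        assert np.array_equal(out[inside], x[inside])

    def test_length_one_series_unchanged(self):
        assert rk.winsorize_series(np.array([7.0])) == pytest.approx([7.0])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            rk.winsorize_series(np.array([]))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_cauchy(400)
        once = rk.winsorize_series(x)
        twice = rk.winsorize_series(once)
        assert np.allclose(once, twice)

    def test_matches_sort_oracle_on_random_streams(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 200)) * rng.uniform(0.1, 50)
            out = rk.winsorize_series(x, 1, 99)
            lo = sort_percentile_oracle(x, 1, "low")
            hi = sort_percentile_oracle(x, 99, "high")
            assert np.allclose(out, np.minimum(np.maximum(x, lo), hi))


class TestFillMissing:
    def test_forward_fill_carries_last_valid(self):
        x = np.array([np.nan, 1.0, np.nan, np.nan, 4.0])
        assert rk.fill_missing(x).tolist() == [1.0, 1.0, 1.0, 1.0, 4.0]

    def test_drop_removes_missing(self):
        x = np.array([np.nan, 1.0, np.nan, 4.0])
        assert rk.fill_missing(x, "drop").tolist() == [1.0, 4.0]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rk.fill_missing(np.array([np.nan, np.nan]))

    def test_stream_with_dropped_samples_summarizes(self):
        angle = np.sin(np.linspace(0, 20, 400)) * 30
        angle[50:60] = np.nan
        f = rk.summarize_activity(_stream(angle))
        assert np.isfinite([f.R_min, f.R_max, f.F_ext]).all()


class TestSmooth:
    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=100)
        assert np.array_equal(rk.smooth_series(x, 1), x)

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(50, dtype=float)
        out = rk.smooth_series(x, 5)
        # direct convolution oracle on the interior
        oracle = np.convolve(x, np.ones(5) / 5, mode="valid")
        assert np.allclose(out[2:-2], oracle)
        assert np.allclose(out[2:-2], x[2:-2])

    def test_noise_variance_shrinks_by_window(self):
        rng = np.random.default_rng(3)
        w = 5
        x = rng.normal(size=10_000)
        out = rk.smooth_series(x, w)
        interior = out[w : -w]
        assert np.var(interior) == pytest.approx(1.0 / w, rel=0.2)

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            rk.smooth_series(np.arange(5.0), 0)


class TestCountMovements:
    def test_monotone_ramp_has_no_movements(self):
        assert rk.count_movements(np.linspace(0, 50, 200), 2.0) == 0

    def test_constant_and_empty_series(self):
        assert rk.count_movements(np.zeros(100), 2.0) == 0
        assert rk.count_movements(np.array([]), 2.0) == 0

    def test_triangle_wave_interior_extrema(self):
        # 10 alternating segments -> 9 interior extrema, amplitude >> hysteresis
        seg = np.linspace(0, 30, 40, endpoint=False)
        wave = np.concatenate([seg if i % 2 == 0 else seg[::-1] for i in range(10)])
        assert rk.count_movements(wave, 2.0) == 9

    def test_ten_direction_changes_fixture(self):
        # 11 segments -> 10 qualifying direction changes, the magnitude the
        # data dictionary uses as its example movement count
        seg = np.linspace(0, 25, 30, endpoint=False)
        wave = np.concatenate([seg if i % 2 == 0 else seg[::-1] for i in range(11)])
        assert rk.count_movements(wave, 2.0) == 10

    def test_subhysteresis_wiggles_not_counted(self):
        t = np.linspace(0, 10, 600)
        x = 0.5 * np.sin(2 * np.pi * 2 * t)  # amplitude below 2 deg hysteresis
        assert rk.count_movements(x, 2.0) == 0

    def test_invariant_to_offset_and_scaling(self):
        rng = np.random.default_rng(5)
        x, _ = zigzag_stream(rng, 8, 2.0)
        base = rk.count_movements(x, 2.0)
        assert rk.count_movements(x + 123.4, 2.0) == base
        assert rk.count_movements(3.0 * x, 2.0) == base

    def test_matches_exact_waveform_extrema_on_random_zigzags(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_seg = int(rng.integers(2, 15))
            x, n_extrema = zigzag_stream(rng, n_seg, 2.0)
            assert rk.count_movements(x, 2.0) == n_extrema


class TestCentripetalForces:
    def test_constant_angle_gives_zero_forces(self):
        assert rk.centripetal_forces(np.zeros(100), 30.0) == (0.0, 0.0)

    def test_sinusoid_closed_form(self):
        # theta = A sin(2 pi f t): peak angular speed 2 pi f A, so the
        # analytic force is (2 pi f A * pi/180)^2 * c
        amp, freq, rate = 30.0, 0.5, 30.0
        t = np.arange(0, 60, 1 / rate)
        theta = amp * np.sin(2 * np.pi * freq * t)
        f_flex, f_ext = rk.centripetal_forces(theta, rate, force_constant=1.0)
        expected = (2 * np.pi * freq * amp * np.pi / 180.0) ** 2
        assert f_ext == pytest.approx(expected, rel=0.01)
        assert -f_flex == pytest.approx(expected, rel=0.01)

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300).cumsum()
        f_flex, f_ext = rk.centripetal_forces(x, 30.0)
        assert f_flex <= 0 <= f_ext

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            rk.centripetal_forces(np.array([1.0, 2.0]), 30.0)


class TestSummarizeActivity:
    def test_all_zero_stream(self):
        t = np.linspace(0.0, 15.0, 451)  # spans exactly 15 s
        stream = SensorStream(t, np.zeros(451), np.zeros(451), [])
        f = rk.summarize_activity(stream)
        assert f.R_min == f.R_max == f.R_mean == 0.0
        assert f.P_min == f.P_max == f.P_mean == 0.0
        assert f.N_mov == 0 and f.F_flex == f.F_ext == 0.0
        assert f.t_game == pytest.approx(15.0)
        assert f.Score == 0.0

    def test_row_exposes_canonical_feature_fields(self):
        stream = _stream(np.sin(np.linspace(0, 20, 500)) * 30)
        row = rk.summarize_activity(stream).as_dict()
        for name in rk.FEATURE_ORDER:
            assert name in row
        assert set(rk.features.ID_COLUMNS) <= set(row)

    def test_known_waveform_rom_recovered(self):
        amp = 25.0
        t = np.arange(0, 120, 1 / 30)
        stream = _stream(amp * np.sin(2 * np.pi * 0.25 * t))
        f = rk.summarize_activity(stream)
        assert f.R_max - f.R_min == pytest.approx(2 * amp, rel=0.05)

    def test_order_invariants_on_random_streams(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(10, 400))
            stream = _stream(rng.normal(size=n) * 20, pressure=rng.normal(size=n) * 3)
            f = rk.summarize_activity(stream)
            assert f.R_min <= f.R_mean <= f.R_max
            assert f.P_min <= f.P_mean <= f.P_max
            assert f.N_mov >= 0 and f.t_game > 0

    def test_matches_naive_full_scan_oracle(self):
        rng = np.random.default_rng(13)
        params = rk.CleaningParams()
        for _ in range(100):
            n = int(rng.integers(20, 300))
            angle = rng.normal(size=n) * rng.uniform(1, 40)
            pressure = rng.normal(size=n) * rng.uniform(0.5, 5)
            events = [(0.1, 5.0), (0.2, 11.0)] if rng.random() < 0.5 else []
            stream = _stream(angle, pressure=pressure, events=events)
            f = rk.summarize_activity(stream, params)

            # naive oracle: recompute every summary by direct scans
            def clean(x):
                lo = sort_percentile_oracle(x, params.winsor_low_pct, "low")
                hi = sort_percentile_oracle(x, params.winsor_high_pct, "high")
                clipped = [min(max(v, lo), hi) for v in x]
                w = params.smooth_window
                half = w // 2
                out = []
                for i in range(len(clipped)):
                    window = clipped[max(0, i - half) : i + half + 1]
                    out.append(sum(window) / len(window))
                return np.asarray(out)

            ca, cp = clean(angle), clean(pressure)
            assert f.R_min == pytest.approx(min(ca))
            assert f.R_max == pytest.approx(max(ca))
            assert f.R_mean == pytest.approx(sum(ca) / len(ca))
            assert f.P_min == pytest.approx(min(cp))
            assert f.P_max == pytest.approx(max(cp))
            assert f.P_mean == pytest.approx(sum(cp) / len(cp))
            assert f.N_mov == rk.count_movements(ca, params.movement_hysteresis_deg)
            assert f.Score == (11.0 if events else 0.0)
            assert f.t_game == pytest.approx((n - 1) / 30)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            rk.summarize_activity(_stream(np.array([])))

    def test_pure_sinusoid_force_symmetry(self):
        t = np.arange(0, 40, 1 / 30)
        stream = _stream(35 * np.sin(2 * np.pi * 0.4 * t))
        f = rk.summarize_activity(stream, rk.CleaningParams(smooth_window=1))
        assert -f.F_flex == pytest.approx(f.F_ext, rel=1e-2)
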