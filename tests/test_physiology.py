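import numpy as np
import pytest

from rosterfatigue.physiology import (
    DEFAULT_PARAMETERS,
    ConvergenceError,
    FatigueTrajectory,
    daily_max_fatigue,
    rested_initial_state,
    simulate,
    sleep_duration_stats,
)
from rosterfatigue.profiles import DEFAULT_PROFILE, make_profile
from rosterfatigue.shifts import ForcedWakeSchedule, compile_forced_wake

P = DEFAULT_PARAMETERS


def _rested(profile):
    return rested_initial_state(profile.d0_total(P), profile.tau_c, P)


def _simulate(profile, roster_row, days):
    wake = compile_forced_wake(roster_row) if roster_row else ForcedWakeSchedule(())
    return simulate(_rested(profile), wake, P, days,
                    d0=profile.d0_total(P), tau_c=profile.tau_c)


class TestRestedState:
    def test_unforced_periodicity(self):
        """From the rested state, further unforced days repeat the daily orbit."""
        traj = _simulate(DEFAULT_PROFILE, None, 7)
        maxima = [daily_max_fatigue(traj, d) for d in range(1, 8)]
        assert max(maxima) - min(maxima) < 0.01

    @pytest.mark.parametrize(
        "sleep_class,target_h", [("short", 5.0), ("normal", 7.0), ("long", 9.0)]
    )
    def test_steady_state_sleep_durations(self, sleep_class, target_h):
        profile = make_profile(sleep_class, "day")
        traj = _simulate(profile, None, 10)
        mean_h = sleep_duration_stats(traj).mean() / 60
        assert abs(mean_h - target_h) < 0.5

    def test_nonconvergence_raises(self):
        params = P.with_overrides(burn_in_tol=0.0, burn_in_days=1, max_burn_in_days=2)
        with pytest.raises(ConvergenceError, match="profile"):
            rested_initial_state(P.d0_base, P.tau_c_default_h, params)


class TestSimulate:
    def test_night_block_raises_later_days(self):
        """Two consecutive nights make days 3 and 4 notably more fatiguing."""
        traj = _simulate(DEFAULT_PROFILE, ["D", "N", "N", "O"], 5)
        maxima = [daily_max_fatigue(traj, d) for d in range(1, 5)]
        assert min(maxima[2], maxima[3]) > max(maxima[0], maxima[1])

    def test_never_asleep_when_forced(self):
        traj = _simulate(DEFAULT_PROFILE, ["N", "N", "N", "O", "D"], 6)
        assert not np.any(traj.asleep & traj.forced_wake)

    def test_determinism_bit_identical(self):
        a = _simulate(DEFAULT_PROFILE, ["D", "N", "N", "O"], 5)
        b = _simulate(DEFAULT_PROFILE, ["D", "N", "N", "O"], 5)
        assert np.array_equal(a.drive_mv, b.drive_mv)
        assert np.array_equal(a.asleep, b.asleep)

    def test_horizon_must_cover_wake_intervals(self):
        wake = compile_forced_wake(["O", "O", "O", "N"])
        with pytest.raises(ValueError, match="horizon"):
            simulate(_rested(DEFAULT_PROFILE), wake, P, 4,
                     d0=DEFAULT_PROFILE.d0_total(P), tau_c=DEFAULT_PROFILE.tau_c)

    def test_drive_range_on_rest_fortnight(self):
        traj = _simulate(DEFAULT_PROFILE, None, 14)
        assert traj.drive_mv.min() > -2.5
        assert traj.drive_mv.max() < 8.5


class TestForcingMonotonicity:
    @pytest.mark.parametrize("seed", range(20))
    def test_adding_a_shift_never_lowers_that_days_max(self, seed):
        rng = np.random.default_rng(seed)
        days = 6
        base = list(rng.choice(["D", "E", "N", "O"], size=days, p=[0.2, 0.2, 0.1, 0.5]))
        day = int(rng.integers(1, days))  # not the last day: keep horizon valid
        if base[day - 1] != "O":
            base[day - 1] = "O"
        harder = base.copy()
        harder[day - 1] = str(rng.choice(["D", "E", "N"]))
        t0 = _simulate(DEFAULT_PROFILE, base, days + 1)
        t1 = _simulate(DEFAULT_PROFILE, harder, days + 1)
        assert daily_max_fatigue(t1, day) >= daily_max_fatigue(t0, day) - 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_commute_never_lowers_max(self, seed):
        rng = np.random.default_rng(100 + seed)
        row = list(rng.choice(["D", "E", "N", "O"], size=5, p=[0.25, 0.25, 0.1, 0.4]))
        from rosterfatigue.shifts import ShiftCatalog

        no_commute = ShiftCatalog(commute_minutes=0)
        with_t = simulate(_rested(DEFAULT_PROFILE), compile_forced_wake(row), P, 6,
                          d0=DEFAULT_PROFILE.d0_total(P), tau_c=DEFAULT_PROFILE.tau_c)
        without_t = simulate(_rested(DEFAULT_PROFILE), compile_forced_wake(row, no_commute), P, 6,
                             d0=DEFAULT_PROFILE.d0_total(P), tau_c=DEFAULT_PROFILE.tau_c)
        assert with_t.drive_mv.max() >= without_t.drive_mv.max() - 1e-9


class TestDailyStats:
    def _synthetic(self, drive, asleep=None, forced=None):
        n = len(drive)
        return FatigueTrajectory(
            drive_mv=np.asarray(drive, dtype=float),
            asleep=np.zeros(n, dtype=bool) if asleep is None else np.asarray(asleep),
            forced_wake=np.zeros(n, dtype=bool) if forced is None else np.asarray(forced),
        )

    def test_constant_trajectory(self):
        traj = self._synthetic(np.full(2 * 1440, 1.25))
        assert daily_max_fatigue(traj, 1) == 1.25
        assert daily_max_fatigue(traj, 2) == 1.25

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        traj = self._synthetic(rng.normal(size=3 * 1440))
        for day in (1, 2, 3):
            window = traj.drive_mv[(day - 1) * 1440 : day * 1440]
            assert daily_max_fatigue(traj, day) == max(float(v) for v in window)

    def test_day_out_of_range(self):
        traj = self._synthetic(np.zeros(1440))
        with pytest.raises(IndexError):
            daily_max_fatigue(traj, 2)

    def test_rest_day_below_post_night_day(self):
        rest = _simulate(DEFAULT_PROFILE, None, 4)
        nights = _simulate(DEFAULT_PROFILE, ["O", "N", "N", "O"], 5)
        assert daily_max_fatigue(rest, 4) < daily_max_fatigue(nights, 4)

    def test_sleep_minutes_all_awake_and_all_asleep(self):
        awake = self._synthetic(np.zeros(2 * 1440))
        assert sleep_duration_stats(awake).tolist() == [0, 0]
        asleep = self._synthetic(np.zeros(2 * 1440), asleep=np.ones(2 * 1440, dtype=bool))
        assert sleep_duration_stats(asleep).tolist() == [1440, 1440]

    def test_asleep_flag_conflicts_with_forced_rejected(self):
        with pytest.raises(ValueError):
            self._synthetic(
                np.zeros(1440),
                asleep=np.ones(1440, dtype=bool),
                forced=np.ones(1440, dtype=bool),
            )


class TestParameterPersistence:
    def test_yaml_roundtrip_with_profiles(self, tmp_path):
        path = tmp_path / "params.yaml"
        P.save(path)
        loaded = type(P).load(path)
        assert loaded == P
        import yaml

        payload = yaml.safe_load(path.read_text())
        assert set(payload["profiles"]) == {str(i) for i in range(1, 10)}

    def test_unsupported_schema_rejected(self, tmp_path):
        path = tmp_path / "params.json"
        P.save(path)
        import json

        payload = json.loads(path.read_text())
        payload["model_parameters"]["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="schema"):
            type(P).load(path)

    def test_trajectory_csv_export(self, tmp_path):
        traj = _simulate(DEFAULT_PROFILE, None, 1)
        traj.to_csv(tmp_path / "traj.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "traj.csv")
        assert list(df.columns) == ["time_min", "drive_mV", "asleep", "forced_wake"]
        assert len(df) == 1440
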