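import numpy as np
import pytest

from rosterfatigue.model import (
    FatigueMatrix,
    Instance,
    Roster,
    compute_z,
    count_gmf_occurrences,
    validate,
)


def small_instance(**kw):
    defaults = dict(
        nurse_profiles=(1, 1, 1, 2),
        n_days=14,
        coverage={"D": 1, "E": 1, "N": 1},
        min_total_hours=4 * 8.5,
        max_total_hours=12 * 8.5,
    )
    defaults.update(kw)
    return Instance(**defaults)


def all_off(instance):
    return Roster([["O"] * instance.n_days for _ in range(instance.n_nurses)])


class TestInstance:
    def test_sundays_every_seventh_day(self):
        assert small_instance().sundays == (7, 14)

    def test_unsatisfiable_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            Instance(nurse_profiles=(1,) * 4, n_days=7, coverage={"D": 5, "E": 5, "N": 5})

    def test_roundtrip(self, tmp_path):
        inst = small_instance()
        for name in ("i.json", "i.yaml"):
            inst.save(tmp_path / name)
            assert Instance.load(tmp_path / name) == inst


class TestComputeZ:
    def test_all_off_is_zero(self):
        assert compute_z(["O"] * 10).sum() == 0

    def test_friday_night_blocks_weekend(self):
        row = ["O"] * 7
        row[4] = "N"  # Friday (t=5); Sunday is t=7
        z = compute_z(row)
        assert z[6] == 1

    def test_sunday_evening_counts_but_sunday_night_does_not(self):
        row = ["O"] * 7
        row[6] = "E"
        assert compute_z(row)[6] == 1
        row[6] = "N"
        assert compute_z(row)[6] == 0

    def test_window_semantics(self):
        # work on day t-1 (any shift) flips z_t
        row = ["O", "D", "O", "O"]
        assert compute_z(row).tolist() == [0, 1, 1, 0]


class TestValidator:
    def test_all_off_roster_counts(self):
        inst = small_instance()
        v = validate(all_off(inst), inst)
        coverage = [x for x in v if x.rule == "coverage"]
        hours = [x for x in v if x.rule == "min_total_hours"]
        assert len(coverage) == inst.n_days * 3
        assert len(hours) == inst.n_nurses

    def test_backward_rotation_night_to_day(self):
        inst = small_instance()
        r = all_off(inst)
        r.assignments[0][4] = "N"
        r.assignments[0][5] = "D"
        v = [x for x in validate(r, inst) if x.rule == "backward_rotation_night"]
        assert len(v) == 1 and v[0].nurse == 0 and v[0].day == 6

    def test_night_off_night(self):
        inst = small_instance()
        r = all_off(inst)
        r.assignments[1][2] = "N"
        r.assignments[1][4] = "N"
        v = [x for x in validate(r, inst) if x.rule == "night_off_night"]
        assert len(v) == 1 and v[0].day == 5

    def test_consecutive_nights_cap(self):
        inst = small_instance()
        r = all_off(inst)
        for d in range(4):
            r.assignments[0][d] = "N"
        assert any(x.rule == "max_consec_nights" for x in validate(r, inst))
        r.assignments[0][3] = "O"
        assert not any(x.rule == "max_consec_nights" for x in validate(r, inst))

    def test_consecutive_work_cap(self):
        inst = small_instance()
        r = all_off(inst)
        for d in range(6):
            r.assignments[0][d] = "D"
        assert any(x.rule == "max_consec_work" for x in validate(r, inst))

    def test_weekly_hours(self):
        inst = small_instance(max_consec_work=7)
        r = all_off(inst)
        for d in range(6):
            r.assignments[0][d] = "D"
        assert any(x.rule == "max_weekly_hours" for x in validate(r, inst))

    def test_two_days_off_window(self):
        inst = small_instance(two_day_off_window=5, max_consec_work=3)
        r = all_off(inst)
        # alternate work and single off days: never two consecutive off days
        for d in range(0, 14, 2):
            r.assignments[0][d] = "D"
        assert any(x.rule == "two_days_off" for x in validate(r, inst))

    def test_consecutive_weekends(self):
        inst = small_instance(max_consec_weekends=1)
        r = all_off(inst)
        r.assignments[0][5] = "D"   # Saturday week 1 (t=6)
        r.assignments[0][12] = "D"  # Saturday week 2 (t=13)
        v = [x for x in validate(r, inst) if x.rule == "max_consec_weekends"]
        assert len(v) == 1 and v[0].day == 14

    def test_min_hours_waivable(self):
        inst = small_instance()
        r = all_off(inst)
        assert not any(
            x.rule == "min_total_hours"
            for x in validate(r, inst, waive_min_hours=True)
        )

    def test_extras_credit_coverage(self):
        inst = small_instance()
        r = all_off(inst)
        r.extras.append((0, 3, "D"))
        cov = [x for x in validate(r, inst) if x.rule == "coverage" and x.day == 3]
        assert len(cov) == 2  # E and N still uncovered

    def test_shape_mismatch(self):
        inst = small_instance()
        with pytest.raises(ValueError, match="shape"):
            validate(Roster([["O"] * 5]), inst)


class TestFatigueMatrix:
    def test_counts_and_argmax(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 5, size=(6, 10))
        m = FatigueMatrix(vals)
        n, t, v = m.argmax()
        assert v == vals.max() and vals[n, t - 1] == v
        assert m.per_nurse_max.tolist() == vals.max(axis=1).tolist()

    def test_occurrence_count_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.choice([1.0, 2.0, 3.0], size=(5, 8))
        count = count_gmf_occurrences(FatigueMatrix(vals), 2.0, tol=1e-9)
        brute = sum(
            1 for i in range(5) for j in range(8) if abs(vals[i, j] - 2.0) <= 1e-9
        )
        assert count == brute

    def test_constant_matrix(self):
        m = FatigueMatrix(np.full((4, 6), 3.3))
        assert count_gmf_occurrences(m, 3.3) == 24
        assert count_gmf_occurrences(m, 4.0) == 0

    def test_negative_tol_rejected(self):
        with pytest.raises(ValueError):
            count_gmf_occurrences(FatigueMatrix(np.zeros((2, 2))), 0.0, tol=-1)
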