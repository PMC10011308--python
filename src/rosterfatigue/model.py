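"""Roster instances, the hard-constraint rule set, and fatigue matrices.

The rule set follows common fatigue-risk scheduling guidance: minimum
coverage per work shift and day; at most a fixed number of consecutive
nights; no backward rotation (a shift may not start earlier than the
previous day's shift); no night shift separated from the previous night
block by a single day; a cap on consecutive work days; total and weekly
hour limits; a cap on consecutive working weekends; and two consecutive
days off with a minimum frequency. The validator here is deliberately
plain day-by-day looping, independent of any solver encoding, so it can
serve as the solver's oracle.

Day indexing is 1-based and day 1 is a Monday, so Sundays are the days
with ``t mod 7 == 0``. Days at or before 0 are treated as off-shifts (a
long rest period is assumed before the planning horizon).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiles import ALL_PROFILES
from .shifts import ALL_SHIFTS, DEFAULT_CATALOG, ShiftCatalog, WORK_SHIFTS

DEFAULT_COVERAGE = {"D": 7, "E": 5, "N": 5}


@dataclass(frozen=True)
class Instance:
    """An NRP instance: staff, horizon, coverage and rest-rule parameters.

    Hour parameters are in hours; defaults correspond to a 42-day horizon
    with full-time staff (20-26 shifts of 8.5 h), a weekly cap of five
    shifts, at most three consecutive nights, five consecutive work days,
    two consecutive working weekends, and a two-day rest at least once
    every 13 days.
    """

    nurse_profiles: tuple[int, ...]
    n_days: int = 42
    coverage: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    max_consec_nights: int = 3
    max_consec_work: int = 5
    min_total_hours: float = 170.0
    max_total_hours: float = 221.0
    max_weekly_hours: float = 42.5
    max_consec_weekends: int = 2
    two_day_off_window: int = 13
    catalog: ShiftCatalog = field(default_factory=lambda: DEFAULT_CATALOG)
    metadata: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for pid in self.nurse_profiles:
            if pid not in ALL_PROFILES:
                raise ValueError(f"unknown biological profile id {pid}")
        if set(self.coverage) != set(WORK_SHIFTS):
            raise ValueError("coverage must be given for exactly D, E, N")
        if min(
            self.max_consec_nights, self.max_consec_work,
            self.max_consec_weekends, self.two_day_off_window,
        ) <= 0:
            raise ValueError("all rule parameters must be positive")
        # necessary staffing condition: demanded shifts vs deliverable shifts
        min_paid = min(self.catalog.paid_hours[s] for s in WORK_SHIFTS)
        demanded = sum(self.coverage.values()) * self.n_days
        deliverable = self.n_nurses * int(self.max_total_hours // min_paid)
        if demanded > deliverable:
            raise ValueError(
                f"coverage unsatisfiable: {demanded} shifts demanded but staff "
                f"can deliver at most {deliverable}"
            )

    @property
    def n_nurses(self) -> int:
        return len(self.nurse_profiles)

    @property
    def sundays(self) -> tuple[int, ...]:
        return tuple(t for t in range(1, self.n_days + 1) if t % 7 == 0)

    def profile_of(self, nurse: int) -> int:
        return self.nurse_profiles[nurse]

    # --- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nurse_profiles": list(self.nurse_profiles),
            "n_days": self.n_days,
            "coverage": dict(self.coverage),
            "max_consec_nights": self.max_consec_nights,
            "max_consec_work": self.max_consec_work,
            "min_total_hours": self.min_total_hours,
            "max_total_hours": self.max_total_hours,
            "max_weekly_hours": self.max_weekly_hours,
            "max_consec_weekends": self.max_consec_weekends,
            "two_day_off_window": self.two_day_off_window,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Instance":
        d = dict(d)
        d["nurse_profiles"] = tuple(d["nurse_profiles"])
        d["metadata"] = tuple(sorted(d.get("metadata", {}).items()))
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "Instance":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


@dataclass
class Roster:
    """Nurse x day assignment of shift codes, plus extras annotations.

    ``extras`` records post-processing substitutions ``(nurse, day, shift)``:
    the nurse's original ``shift`` on ``day`` was handed to a casual extra,
    so it still counts towards coverage although the nurse is off.
    """

    assignments: list[list[str]]
    extras: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        horizon = len(self.assignments[0])
        for row in self.assignments:
            if len(row) != horizon:
                raise ValueError("ragged roster")
            for code in row:
                if code not in ALL_SHIFTS:
                    raise ValueError(f"unknown shift code {code!r}")

    @property
    def n_nurses(self) -> int:
        return len(self.assignments)

    @property
    def n_days(self) -> int:
        return len(self.assignments[0])

    def row(self, nurse: int) -> list[str]:
        return self.assignments[nurse]

    def get(self, nurse: int, day: int) -> str:
        """Shift of 1-based ``day``; days at or before 0 are off."""
        return self.assignments[nurse][day - 1] if day >= 1 else "O"

    def copy(self) -> "Roster":
        return Roster([row[:] for row in self.assignments], list(self.extras))

    def as_array(self) -> np.ndarray:
        return np.array(self.assignments, dtype="U1")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.assignments,
            index=[f"nurse_{n+1}" for n in range(self.n_nurses)],
            columns=[f"day_{t}" for t in range(1, self.n_days + 1)],
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "Roster":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.astype(str).values.tolist())

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"assignments": self.assignments, "extras": self.extras}, indent=1)
        )

    @classmethod
    def from_json(cls, path) -> "Roster":
        d = json.loads(Path(path).read_text())
        return cls(d["assignments"], [tuple(e) for e in d.get("extras", [])])


@dataclass(frozen=True)
class Violation:
    rule: str
    nurse: int | None
    day: int | None
    detail: str


def compute_z(roster_row) -> np.ndarray:
    """Two-day work indicator z_t per day (1-based row, days <= 0 off).

    ``z_t = 1`` iff the nurse works in the two-day window ending on day t:
    the night shift of day t-2 (which runs into t-1), any shift on day t-1,
    or the day/evening shift of day t. For a Sunday t, ``z_t = 0`` is the
    weekend-off condition: no Friday night, nothing Saturday, no Sunday
    day/evening shift (the Sunday *night* shift belongs to the next window).
    """
    T = len(roster_row)

    def code(d: int) -> str:
        return roster_row[d - 1] if d >= 1 else "O"

    z = np.zeros(T, dtype=np.int8)
    for t in range(1, T + 1):
        z[t - 1] = int(
            code(t - 2) == "N"
            or code(t - 1) in WORK_SHIFTS
            or code(t) in ("D", "E")
        )
    return z


def _work_hours(instance: Instance, codes) -> float:
    return sum(instance.catalog.paid_hours[c] for c in codes)


def validate(
    roster: Roster, instance: Instance, *, waive_min_hours: bool = False
) -> list[Violation]:
    """All hard-constraint violations of a roster; empty means feasible.

    Extras-covered shifts count towards coverage. ``waive_min_hours``
    drops the minimum-total-hours floor (used after extras substitution,
    which removes shifts from individual nurses by design).
    """
    if roster.n_nurses != instance.n_nurses or roster.n_days != instance.n_days:
        raise ValueError(
            f"roster shape {roster.n_nurses}x{roster.n_days} does not match "
            f"instance {instance.n_nurses}x{instance.n_days}"
        )
    v: list[Violation] = []
    T = instance.n_days
    cat = instance.catalog

    # coverage, with extras credited
    extra_credit: dict[tuple[int, str], int] = {}
    for _, day, shift in roster.extras:
        extra_credit[(day, shift)] = extra_credit.get((day, shift), 0) + 1
    for t in range(1, T + 1):
        for s in WORK_SHIFTS:
            staffed = sum(1 for n in range(roster.n_nurses) if roster.get(n, t) == s)
            staffed += extra_credit.get((t, s), 0)
            if staffed < instance.coverage[s]:
                v.append(
                    Violation(
                        "coverage", None, t,
                        f"shift {s}: {staffed} staffed < {instance.coverage[s]} required",
                    )
                )

    for n in range(roster.n_nurses):
        get = lambda d: roster.get(n, d)  # noqa: E731

        # consecutive nights: any window of max+1 days all containing N
        P = instance.max_consec_nights
        for t in range(1, T + 1):
            if sum(1 for d in range(t - P, t + 1) if get(d) == "N") > P:
                v.append(Violation("max_consec_nights", n, t, f"more than {P} consecutive nights"))

        # backward rotation: N -> D/E and E -> D forbidden on consecutive days
        for t in range(1, T + 1):
            if get(t - 1) == "N" and get(t) in ("D", "E"):
                v.append(Violation("backward_rotation_night", n, t, f"N then {get(t)}"))
            if get(t - 1) == "E" and get(t) == "D":
                v.append(Violation("backward_rotation_evening", n, t, "E then D"))

        # night, non-night day, night
        for t in range(1, T + 1):
            if get(t - 2) == "N" and get(t) == "N" and get(t - 1) != "N":
                v.append(Violation("night_off_night", n, t, "single day between night shifts"))

        # consecutive work days
        P = instance.max_consec_work
        for t in range(1, T + 1):
            if sum(1 for d in range(t - P, t + 1) if get(d) in WORK_SHIFTS) > P:
                v.append(Violation("max_consec_work", n, t, f"more than {P} consecutive work days"))

        # total hours
        hours = _work_hours(instance, roster.row(n))
        if hours > instance.max_total_hours + 1e-9:
            v.append(Violation("max_total_hours", n, None, f"{hours}h > {instance.max_total_hours}h"))
        if not waive_min_hours and hours < instance.min_total_hours - 1e-9:
            v.append(Violation("min_total_hours", n, None, f"{hours}h < {instance.min_total_hours}h"))

        # weekly hours (calendar weeks ending on Sundays)
        for t in instance.sundays:
            wk = _work_hours(instance, [get(d) for d in range(t - 6, t + 1)])
            if wk > instance.max_weekly_hours + 1e-9:
                v.append(Violation("max_weekly_hours", n, t, f"{wk}h in week ending day {t}"))

        # weekend and two-day-rest rules via the z indicator
        z = compute_z(roster.row(n))

        def zval(d: int) -> int:
            return int(z[d - 1]) if d >= 1 else 0

        P = instance.max_consec_weekends
        for t in instance.sundays:
            if sum(zval(t - 7 * k) for k in range(P + 1)) > P:
                v.append(
                    Violation("max_consec_weekends", n, t, f"more than {P} consecutive working weekends")
                )

        P = instance.two_day_off_window
        for t in range(1, T + 1):
            if sum(zval(d) for d in range(t - P, t + 1)) > P:
                v.append(
                    Violation("two_days_off", n, t, f"no two consecutive days off in window ending day {t}")
                )

    return v


@dataclass
class FatigueMatrix:
    """Per-nurse, per-day fatigue scores (mV)."""

    values: np.ndarray  # (n_nurses, n_days)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def gmf(self) -> float:
        return float(self.values.max())

    @property
    def per_nurse_max(self) -> np.ndarray:
        return self.values.max(axis=1)

    def argmax(self) -> tuple[int, int, float]:
        """(nurse, 1-based day, value) of the maximum; ties broken in
        (nurse, day) order."""
        n, t = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(n), int(t) + 1, float(self.values[n, t])


def count_gmf_occurrences(fatigue: FatigueMatrix | np.ndarray, gmf: float, tol: float = 1e-9) -> int:
    """Number of nurse-days whose fatigue equals ``gmf`` within ``tol``."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    vals = fatigue.values if isinstance(fatigue, FatigueMatrix) else np.asarray(fatigue)
    return int(np.sum(np.abs(vals - gmf) <= tol))


def rhe_matrix(roster: Roster, instance: Instance, table) -> FatigueMatrix:
    """Approximated fatigue matrix of a roster via the lookup table."""
    from .approximation import rhe_evaluate

    rows = [
        rhe_evaluate(roster.row(n), instance.profile_of(n), table).values
        for n in range(roster.n_nurses)
    ]
    return FatigueMatrix(np.stack(rows))
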