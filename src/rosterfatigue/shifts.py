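"""Shift catalogue and forced-wakefulness compilation.

A roster assigns each nurse one code per day out of ``{D, E, N, O}``: day,
evening and night work shifts plus the off-shift. Work (and the commute
around it) forces the individual awake; the sleep model is driven purely by
those forced-wake intervals, so this module is the bridge between roster
space and physiology space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MINUTES_PER_DAY = 1440

WORK_SHIFTS = ("D", "E", "N")
ALL_SHIFTS = ("D", "E", "N", "O")


@dataclass(frozen=True)
class ShiftCatalog:
    """Clock times (minutes from midnight) and paid hours of the four codes.

    The night shift ends past midnight, so its ``end`` exceeds 1440 and the
    shift is attributed to the day it *starts* on. All three work shifts are
    paid ``paid_hours`` hours regardless of clock duration; the off-shift has
    no interval and zero paid hours. ``commute_minutes`` of forced wake time
    is added before and after every work shift.
    """

    start: dict[str, int] = field(
        default_factory=lambda: {"D": 7 * 60, "E": 14 * 60 + 30, "N": 22 * 60}
    )
    end: dict[str, int] = field(
        default_factory=lambda: {"D": 15 * 60, "E": 22 * 60 + 30, "N": 31 * 60 + 30}
    )
    paid_hours: dict[str, float] = field(
        default_factory=lambda: {"D": 8.5, "E": 8.5, "N": 8.5, "O": 0.0}
    )
    commute_minutes: int = 45

    def __post_init__(self) -> None:
        if set(self.start) != set(WORK_SHIFTS) or set(self.end) != set(WORK_SHIFTS):
            raise ValueError("catalog must define start/end for exactly D, E, N")
        if self.end["N"] <= MINUTES_PER_DAY:
            raise ValueError("night shift must cross midnight (end > 1440)")
        for s in WORK_SHIFTS:
            if not 0 <= self.start[s] < MINUTES_PER_DAY or self.end[s] <= self.start[s]:
                raise ValueError(f"invalid interval for shift {s!r}")

    def forced_interval(self, code: str, day: int) -> tuple[int, int] | None:
        """Forced-wake interval of ``code`` worked on 1-based ``day``.

        Returns minutes from planning-period start (day 1, 00:00 = minute 0),
        commute included, or ``None`` for the off-shift.
        """
        if code == "O":
            return None
        if code not in self.start:
            raise ValueError(f"unknown shift code {code!r}")
        offset = (day - 1) * MINUTES_PER_DAY
        return (
            offset + self.start[code] - self.commute_minutes,
            offset + self.end[code] + self.commute_minutes,
        )


DEFAULT_CATALOG = ShiftCatalog()


@dataclass(frozen=True)
class ForcedWakeSchedule:
    """Sorted, disjoint, merged half-open forced-wake intervals in minutes."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for a, b in self.intervals:
            if a < 0 or b <= a:
                raise ValueError(f"invalid interval [{a}, {b})")
            if prev_end is not None and a <= prev_end:
                raise ValueError("intervals must be sorted and non-adjacent")
            prev_end = b

    @property
    def end(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    def mask(self, horizon_minutes: int) -> "list[bool]":
        import numpy as np

        m = np.zeros(horizon_minutes, dtype=bool)
        for a, b in self.intervals:
            m[a : min(b, horizon_minutes)] = True
        return m


def merge_intervals(raw: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    out: list[list[int]] = []
    for a, b in sorted(raw):
        if out and a <= out[-1][1]:  # adjacent intervals merge too
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return tuple((a, b) for a, b in out)


def compile_forced_wake(
    roster_row, catalog: ShiftCatalog = DEFAULT_CATALOG
) -> ForcedWakeSchedule:
    """Turn a per-day shift sequence (day 1 first) into forced-wake intervals.

    Days before day 1 are implicitly off, so nothing precedes the sequence.
    Raises ``ValueError`` naming the offending 1-based day on unknown codes.
    """
    raw = []
    for i, code in enumerate(roster_row, start=1):
        if code not in ALL_SHIFTS:
            raise ValueError(f"unknown shift code {code!r} on day {i}")
        iv = catalog.forced_interval(code, i)
        if iv is not None:
            raw.append(iv)
    return ForcedWakeSchedule(merge_intervals(raw))
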