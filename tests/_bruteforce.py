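"""Exhaustive min-max-fatigue oracle for tiny instances.

Independent of the MILP backend: per-nurse rows are enumerated explicitly
and filtered through the plain validator; coverage (at most one nurse
required per shift/day) is checked by bitmask cover search. The optimal
global maximum fatigue is found by binary search over the realisable
per-row maxima. Only meant for <= 4 nurses and <= 7 days.
"""

from __future__ import annotations

import itertools

import numpy as np

from rosterfatigue.approximation import rhe_evaluate
from rosterfatigue.model import Instance, Roster, validate
from rosterfatigue.shifts import ALL_SHIFTS

_ROW_CACHE: dict[tuple, list[tuple[str, ...]]] = {}


def feasible_rows(instance: Instance) -> list[tuple[str, ...]]:
    """All individually feasible rows under the instance's rules."""
    key = (
        instance.n_days, instance.max_consec_nights, instance.max_consec_work,
        instance.min_total_hours, instance.max_total_hours,
        instance.max_weekly_hours, instance.max_consec_weekends,
        instance.two_day_off_window,
    )
    if key in _ROW_CACHE:
        return _ROW_CACHE[key]
    probe = Instance(
        nurse_profiles=(1,),
        n_days=instance.n_days,
        coverage={"D": 0, "E": 0, "N": 0},
        max_consec_nights=instance.max_consec_nights,
        max_consec_work=instance.max_consec_work,
        min_total_hours=instance.min_total_hours,
        max_total_hours=instance.max_total_hours,
        max_weekly_hours=instance.max_weekly_hours,
        max_consec_weekends=instance.max_consec_weekends,
        two_day_off_window=instance.two_day_off_window,
    )
    rows = [
        row
        for row in itertools.product(ALL_SHIFTS, repeat=instance.n_days)
        if not validate(Roster([list(row)]), probe)
    ]
    _ROW_CACHE[key] = rows
    return rows


def _superset_closure(masks: np.ndarray, n_bits: int) -> np.ndarray:
    """cover[m] = does some mask in ``masks`` contain all bits of m."""
    cover = np.zeros(1 << n_bits, dtype=bool)
    cover[masks] = True
    idx = np.arange(1 << n_bits)
    for b in range(n_bits):
        bit = 1 << b
        has = (idx & bit) != 0
        cover[idx[has] ^ bit] |= cover[idx[has]]
    return cover


def brute_force_min_gmf(instance: Instance, table) -> float:
    """Exact optimal GMF over all feasible rosters (coverage counts <= 1)."""
    assert instance.n_nurses <= 4 and instance.n_days <= 7
    assert all(c <= 1 for c in instance.coverage.values())

    required_bits = [
        (t, s)
        for t in range(1, instance.n_days + 1)
        for s in ("D", "E", "N")
        if instance.coverage[s] >= 1
    ]
    n_bits = len(required_bits)
    required = (1 << n_bits) - 1
    bit_of = {ts: i for i, ts in enumerate(required_bits)}

    rows = feasible_rows(instance)
    masks = np.array(
        [
            sum(
                1 << bit_of[(t, row[t - 1])]
                for t in range(1, instance.n_days + 1)
                if (t, row[t - 1]) in bit_of
            )
            for row in rows
        ],
        dtype=np.int64,
    )
    # per-profile row maxima of the table-approximated fatigue
    rowmax: dict[int, np.ndarray] = {}
    for pid in set(instance.nurse_profiles):
        rowmax[pid] = np.array(
            [rhe_evaluate(list(row), pid, table).values.max() for row in rows]
        )

    def feasible_at(bound: float) -> bool:
        per_nurse = []
        for n in range(instance.n_nurses):
            keep = rowmax[instance.profile_of(n)] <= bound + 1e-12
            if not keep.any():
                return False
            per_nurse.append(masks[keep])
        half = instance.n_nurses // 2
        left = per_nurse[0]
        for m in per_nurse[1:half] or []:
            left = np.unique(np.bitwise_or.outer(left, m).ravel())
        right = per_nurse[half]
        for m in per_nurse[half + 1:]:
            right = np.unique(np.bitwise_or.outer(right, m).ravel())
        cover = _superset_closure(np.unique(right), n_bits)
        need = required & ~left
        return bool(cover[need].any())

    candidates = np.unique(np.concatenate(list(rowmax.values())))
    lo, hi = 0, len(candidates) - 1
    if not feasible_at(float(candidates[hi])):
        raise RuntimeError("instance infeasible even at the loosest bound")
    while lo < hi:
        mid = (lo + hi) // 2
        if feasible_at(float(candidates[mid])):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])
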