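"""Fixed-neighbourhood roster subproblems on a mixed-integer backend.

Each large-neighbourhood-search iteration re-optimises the roster cells
marked free by a :class:`NeighborhoodMask` while all other cells stay at
their incumbent values. The rule set of :mod:`rosterfatigue.model` is
encoded linearly over one-hot shift variables ``y[n, t, s]``; the
nonlinear fatigue objective is handled through the lookup table:

* *min_gmf* — the global maximum fatigue is lowered by *threshold search*:
  forbid every evaluation pattern whose table value exceeds a bound ``B``
  (a linear no-good over the pattern's window cells) and ask for any
  feasible roster; the bound then descends along the table's distinct
  values until infeasibility or the time budget stops it.
* *min_occurrences* — patterns above the incumbent GMF are forbidden and a
  binary indicator per nurse-day, forced to 1 when a pattern *at* the GMF
  is matched, is minimised.

Because every pattern is tabulated, the fatigue score the solver reasons
about is exactly the score ``rhe_evaluate`` recomputes on the returned
roster, value for value.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .approximation import LookupTable
from .model import Instance, Roster, rhe_matrix
from .shifts import ALL_SHIFTS, WORK_SHIFTS

_S_INDEX = {s: i for i, s in enumerate(ALL_SHIFTS)}
_EPS = 1e-7  # separation between distinct table values


class Mode(str, Enum):
    FEASIBILITY = "feasibility"
    MIN_GMF = "min_gmf"
    MIN_OCCURRENCES = "min_occurrences"


@dataclass
class NeighborhoodMask:
    """Boolean nurse x day matrix; True cells may be reassigned."""

    free: np.ndarray

    def __post_init__(self) -> None:
        self.free = np.asarray(self.free, dtype=bool)

    @classmethod
    def all_free(cls, n_nurses: int, n_days: int) -> "NeighborhoodMask":
        return cls(np.ones((n_nurses, n_days), dtype=bool))

    @classmethod
    def all_fixed(cls, n_nurses: int, n_days: int) -> "NeighborhoodMask":
        return cls(np.zeros((n_nurses, n_days), dtype=bool))


@dataclass
class SubproblemResult:
    roster: Roster | None
    status: str  # "optimal" | "feasible" | "infeasible" | "timeout"
    objective: float | None = None


class _ModelBuilder:
    """Accumulates a sparse 0/1 MILP over free roster cells."""

    def __init__(self, instance: Instance, mask: NeighborhoodMask, incumbent: Roster | None):
        self.inst = instance
        self.mask = mask.free
        self.incumbent = incumbent
        self.n_vars = 0
        self.var_of: dict[tuple, int] = {}
        self.rows: list[list[tuple[int, float]]] = []
        self.lbs: list[float] = []
        self.ubs: list[float] = []
        N, T = instance.n_nurses, instance.n_days
        for n in range(N):
            for t in range(1, T + 1):
                if self.mask[n, t - 1]:
                    for s in ALL_SHIFTS:
                        self.var_of[("y", n, t, s)] = self.n_vars
                        self.n_vars += 1

    # --- variable helpers -------------------------------------------------
    def y_term(self, n: int, t: int, s: str):
        """(coefficient list, constant) of the 0/1 shift indicator."""
        if t < 1:
            return [], 1.0 if s == "O" else 0.0
        if self.mask[n, t - 1]:
            return [(self.var_of[("y", n, t, s)], 1.0)], 0.0
        assert self.incumbent is not None
        return [], 1.0 if self.incumbent.get(n, t) == s else 0.0

    def aux_var(self, key) -> int:
        if key not in self.var_of:
            self.var_of[key] = self.n_vars
            self.n_vars += 1
        return self.var_of[key]

    def add(self, terms, lb=-np.inf, ub=np.inf) -> None:
        """terms: list of (var, coef); constants must be pre-folded."""
        self.rows.append(terms)
        self.lbs.append(lb)
        self.ubs.append(ub)

    def add_expr(self, pieces, lb=-np.inf, ub=np.inf) -> None:
        """pieces: list of (coef, (terms, const)) products to sum."""
        terms: list[tuple[int, float]] = []
        const = 0.0
        for coef, (tt, cc) in pieces:
            terms.extend((v, coef * c) for v, c in tt)
            const += coef * cc
        if not terms:
            if not (lb - 1e-9 <= const <= ub + 1e-9):
                raise _TriviallyInfeasible()
            return
        self.add(terms, lb - const, ub - const)

    def matrix(self):
        data, ri, ci = [], [], []
        for i, row in enumerate(self.rows):
            for v, c in row:
                ri.append(i)
                ci.append(v)
                data.append(c)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(self.rows), self.n_vars))
        return A, np.array(self.lbs), np.array(self.ubs)


class _TriviallyInfeasible(Exception):
    pass


def _work_term(b: _ModelBuilder, n: int, t: int):
    pieces = [(1.0, b.y_term(n, t, s)) for s in WORK_SHIFTS]
    return pieces


def _add_rule_constraints(b: _ModelBuilder, extras_credit=None) -> None:
    inst = b.inst
    N, T = inst.n_nurses, inst.n_days
    paid = inst.catalog.paid_hours
    extras_credit = extras_credit or {}

    # exactly one shift per free nurse-day
    for n in range(N):
        for t in range(1, T + 1):
            if b.mask[n, t - 1]:
                b.add([(b.var_of[("y", n, t, s)], 1.0) for s in ALL_SHIFTS], 1.0, 1.0)

    # coverage
    for t in range(1, T + 1):
        for s in WORK_SHIFTS:
            need = inst.coverage[s] - extras_credit.get((t, s), 0)
            b.add_expr([(1.0, b.y_term(n, t, s)) for n in range(N)], lb=need)

    for n in range(N):
        # consecutive nights
        P = inst.max_consec_nights
        for t in range(1, T + 1):
            b.add_expr([(1.0, b.y_term(n, d, "N")) for d in range(t - P, t + 1)], ub=P)
        # backward rotation
        for t in range(1, T + 1):
            b.add_expr(
                [(1.0, b.y_term(n, t - 1, "N")), (1.0, b.y_term(n, t, "D")), (1.0, b.y_term(n, t, "E"))],
                ub=1.0,
            )
            b.add_expr([(1.0, b.y_term(n, t - 1, "E")), (1.0, b.y_term(n, t, "D"))], ub=1.0)
        # night / single non-night day / night
        for t in range(1, T + 1):
            b.add_expr(
                [(1.0, b.y_term(n, t - 2, "N"))]
                + [(1.0, b.y_term(n, t - 1, s)) for s in ("D", "E", "O")]
                + [(1.0, b.y_term(n, t, "N"))],
                ub=2.0,
            )
        # consecutive work days
        P = inst.max_consec_work
        for t in range(1, T + 1):
            b.add_expr(
                [p for d in range(t - P, t + 1) for p in _work_term(b, n, d)], ub=P
            )
        # total hours
        b.add_expr(
            [(paid[s], b.y_term(n, t, s)) for t in range(1, T + 1) for s in WORK_SHIFTS],
            lb=inst.min_total_hours,
            ub=inst.max_total_hours,
        )
        # weekly hours
        for t in inst.sundays:
            b.add_expr(
                [
                    (paid[s], b.y_term(n, d, s))
                    for d in range(t - 6, t + 1)
                    if d >= 1
                    for s in WORK_SHIFTS
                ],
                ub=inst.max_weekly_hours,
            )

        # z indicator, weekends, two-day rest; z is cheap, define for all days
        z_terms: dict[int, tuple[list, float]] = {}
        for t in range(1, T + 1):
            expr_pieces = (
                [(1.0, b.y_term(n, t - 2, "N"))]
                + [p for p in _work_term(b, n, t - 1)]
                + [(1.0, b.y_term(n, t, "D")), (1.0, b.y_term(n, t, "E"))]
            )
            terms: list[tuple[int, float]] = []
            const = 0.0
            for coef, (tt, cc) in expr_pieces:
                terms.extend((v, coef * c) for v, c in tt)
                const += coef * cc
            if not terms:
                z_terms[t] = ([], 1.0 if const > 0.5 else 0.0)
            else:
                zv = b.aux_var(("z", n, t))
                # 2z - expr >= 0  (z forced up; rules below push it down)
                b.add([(zv, 2.0)] + [(v, -c) for v, c in terms], const, np.inf)
                z_terms[t] = ([(zv, 1.0)], 0.0)

        def z_expr(d: int):
            return z_terms[d] if d >= 1 else ([], 0.0)

        P = inst.max_consec_weekends
        for t in inst.sundays:
            b.add_expr([(1.0, z_expr(t - 7 * k)) for k in range(P + 1)], ub=P)
        P = inst.two_day_off_window
        for t in range(1, T + 1):
            b.add_expr([(1.0, z_expr(d)) for d in range(t - P, t + 1)], ub=P)


def _pattern_cells(t: int, flag: bool, shifts: tuple[str, ...]):
    """(day, expected code, is_flag_cell) cells of a pattern scored on day t."""
    t_h = len(shifts)
    cells = [(t - t_h, "N", True)] if flag else [(t - t_h, None, True)]
    cells += [(t - t_h + 1 + i, s, False) for i, s in enumerate(shifts)]
    return cells


def _add_pattern_constraint(
    b: _ModelBuilder, n: int, t: int, flag: bool, shifts: tuple[str, ...],
    indicator: int | None,
) -> bool:
    """No-good (indicator None) or indicator-link constraint for one pattern.

    Returns False when the pattern cannot match given fixed cells (no
    constraint needed).
    """
    terms: list[tuple[int, float]] = []
    const = 0.0
    n_cells = 0
    for day, code, is_flag in _pattern_cells(t, flag, shifts):
        if is_flag and code is None:
            # flag False: require NOT night on the flag day
            tt, cc = b.y_term(n, day, "N")
            if not tt:
                if cc > 0.5:
                    return False  # fixed night -> pattern cannot match
                continue  # fixed non-night: trivially satisfied
            n_cells += 1
            terms.extend((v, -c) for v, c in tt)
            const += 1.0
        else:
            tt, cc = b.y_term(n, day, code)
            if not tt:
                if cc < 0.5:
                    return False
                n_cells += 1
                const += 1.0
            else:
                n_cells += 1
                terms.extend(tt)
    if not terms:
        # pattern fully fixed and matching
        if indicator is None:
            raise _TriviallyInfeasible()
        b.add([(indicator, 1.0)], 1.0, 1.0)
        return True
    if indicator is None:
        # sum of matches <= n_cells - 1
        b.add(terms, -np.inf, n_cells - 1 - const)
    else:
        # indicator >= sum of matches - (n_cells - 1)
        b.add([(indicator, 1.0)] + [(v, -c) for v, c in terms], const - (n_cells - 1), np.inf)
    return True


def _classify_patterns(table: LookupTable, profile_id: int, forbid_above: float, critical_at: float | None):
    forbidden, critical = [], []
    for (pid, flag, pat), v in table.values.items():
        if pid != profile_id:
            continue
        if v > forbid_above + _EPS:
            forbidden.append((flag, tuple(pat)))
        elif critical_at is not None and abs(v - critical_at) <= 1e-9:
            critical.append((flag, tuple(pat)))
    return forbidden, critical


def _solve_once(
    instance: Instance,
    table: LookupTable | None,
    mask: NeighborhoodMask,
    incumbent: Roster | None,
    forbid_above: float | None,
    critical_at: float | None,
    time_limit: float,
    extras_credit=None,
) -> SubproblemResult:
    try:
        b = _ModelBuilder(instance, mask, incumbent)
        _add_rule_constraints(b, extras_credit)
        objective_vars: list[int] = []
        if forbid_above is not None:
            assert table is not None
            by_profile: dict[int, tuple[list, list]] = {}
            for n in range(instance.n_nurses):
                pid = instance.profile_of(n)
                if pid not in by_profile:
                    by_profile[pid] = _classify_patterns(table, pid, forbid_above, critical_at)
                forbidden, critical = by_profile[pid]
                for t in range(1, instance.n_days + 1):
                    lo = t - table.t_h
                    window_free = any(
                        1 <= d <= instance.n_days and b.mask[n, d - 1] for d in range(lo, t + 1)
                    )
                    if not window_free:
                        # fully-fixed windows contribute constants only
                        continue
                    for flag, shifts in forbidden:
                        _add_pattern_constraint(b, n, t, flag, shifts, None)
                    if critical:
                        ind = b.aux_var(("occ", n, t))
                        any_link = False
                        for flag, shifts in critical:
                            any_link |= _add_pattern_constraint(b, n, t, flag, shifts, ind)
                        if any_link:
                            objective_vars.append(ind)
    except _TriviallyInfeasible:
        return SubproblemResult(None, "infeasible")

    if b.n_vars == 0:
        # everything fixed; rule constraints already verified as constants
        return SubproblemResult(incumbent.copy() if incumbent else None, "optimal", 0.0)

    c = np.zeros(b.n_vars)
    for v in objective_vars:
        c[v] = 1.0
    A, lb, ub = b.matrix()
    res = milp(
        c,
        constraints=LinearConstraint(A, lb, ub),
        integrality=np.ones(b.n_vars),
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit, "presolve": True},
    )
    if res.status == 2:
        return SubproblemResult(None, "infeasible")
    if res.x is None:
        return SubproblemResult(None, "timeout")

    x = np.round(res.x).astype(int)
    assignments = []
    for n in range(instance.n_nurses):
        row = []
        for t in range(1, instance.n_days + 1):
            if b.mask[n, t - 1]:
                chosen = [s for s in ALL_SHIFTS if x[b.var_of[("y", n, t, s)]] == 1]
                if len(chosen) != 1:
                    raise RuntimeError(f"non-one-hot solver output at nurse {n} day {t}")
                row.append(chosen[0])
            else:
                row.append(incumbent.get(n, t))
        assignments.append(row)
    roster = Roster(assignments, list(incumbent.extras) if incumbent else [])
    status = "optimal" if res.status == 0 else "feasible"
    return SubproblemResult(roster, status, float(res.fun) if res.fun is not None else None)


def solve_subproblem(
    instance: Instance,
    table: LookupTable | None,
    mask: NeighborhoodMask,
    incumbent: Roster | None,
    mode: Mode | str = Mode.FEASIBILITY,
    gmf_bound: float | None = None,
    time_limit: float = 10.0,
    max_descents: int = 4,
    extras_credit=None,
) -> SubproblemResult:
    """Solve one fixed-neighbourhood subproblem.

    ``feasibility`` ignores fatigue altogether (used for the initial
    solution). ``min_gmf`` returns a roster whose table-derived global
    maximum fatigue is at most the incumbent's, strictly lower when one is
    found within the time budget. ``min_occurrences`` keeps every score at
    or below ``gmf_bound`` and minimises how many nurse-days attain it.
    """
    mode = Mode(mode)
    if mode is not Mode.FEASIBILITY and table is None:
        raise ValueError("fatigue modes need a lookup table")
    if not mask.free.any():
        return SubproblemResult(incumbent.copy() if incumbent else None, "optimal")

    if mode is Mode.FEASIBILITY:
        return _solve_once(instance, None, mask, incumbent, None, None, time_limit, extras_credit)

    profile_ids = set(instance.nurse_profiles)
    values = table.distinct_values(profile_ids)

    if mode is Mode.MIN_OCCURRENCES:
        if gmf_bound is None:
            raise ValueError("min_occurrences needs gmf_bound")
        return _solve_once(
            instance, table, mask, incumbent, gmf_bound, gmf_bound, time_limit, extras_credit
        )

    # min_gmf: threshold search over the distinct table values strictly
    # below the incumbent GMF. Feasibility is monotone in the bound, and a
    # feasible solve is typically much cheaper than proving infeasibility,
    # so the search gallops downward: start at the largest candidate bound,
    # grow the step after each success (the achieved GMF usually undershoots
    # the bound anyway), and retreat halfway on failure. A timeout counts
    # as a failure, so the result is best-found rather than provably
    # neighbourhood-optimal.
    assert incumbent is not None
    inc_f = rhe_matrix(incumbent, instance, table)
    inc_gmf = inc_f.gmf
    # fatigue locked in by fully-fixed windows bounds what any candidate
    # roster can achieve; probing below it would be vacuous (those windows
    # generate no constraints) and unsound
    fixed_floor = -np.inf
    for n in range(instance.n_nurses):
        for t in range(1, instance.n_days + 1):
            lo = max(1, t - table.t_h)
            if not mask.free[n, lo - 1 : t].any():
                fixed_floor = max(fixed_floor, inc_f.values[n, t - 1])
    cand = values[(values < inc_gmf - _EPS) & (values >= fixed_floor - _EPS)]
    best: SubproblemResult | None = None
    last_status = "infeasible"
    lo_fail = -1          # highest index known (or assumed) infeasible
    top = len(cand) - 1   # largest index still worth probing
    pos, step, solves = top, 1, 0
    while solves < max_descents and lo_fail < pos <= top:
        r = _solve_once(
            instance, table, mask, incumbent, float(cand[pos]), None, time_limit, extras_credit
        )
        solves += 1
        last_status = r.status
        if r.roster is None:
            lo_fail = pos
            if pos >= top:
                break
            pos = (pos + top + 1) // 2
            step = 1
        else:
            achieved = rhe_matrix(r.roster, instance, table).gmf
            if achieved > cand[pos] + _EPS:
                raise RuntimeError("solver returned a roster violating its fatigue bound")
            best = r
            top = int(np.searchsorted(cand, achieved - _EPS)) - 1
            step *= 2
            pos = max(lo_fail + 1, top - step + 1)
    if best is not None:
        return best
    return SubproblemResult(None, last_status)
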