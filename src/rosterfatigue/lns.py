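"""Large neighbourhood search minimising the global maximum fatigue.

Starting from any feasible roster (found without fatigue in the model),
each iteration frees a neighbourhood — the full schedules of the nurses
currently attaining the global maximum fatigue (GMF), a few random
nurses, and every off-shift cell — and re-optimises it. The search
normally lowers the GMF directly; when the incumbent GMF has many
occurrences, or recent iterations have failed, it instead minimises the
*number of occurrences* of the GMF (the plateau-escape move: discrete
table values make large plateaus where only the occurrence count can
improve). A candidate is accepted iff it is lexicographically better in
(GMF, occurrences); the search stops after a configurable number of
iterations without acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .approximation import LookupTable
from .model import (
    FatigueMatrix,
    Instance,
    Roster,
    count_gmf_occurrences,
    rhe_matrix,
    validate,
)
from .subproblem import Mode, NeighborhoodMask, SubproblemResult, solve_subproblem

#: fatigue scores are table values; equality means same table entry
VALUE_TOL = 1e-9


class InfeasibleInstanceError(RuntimeError):
    """The instance admits no feasible roster."""


@dataclass
class LNSConfig:
    n_random: int = 2            # random nurses freed per iteration (n^R)
    n_gmf_cap: int = 3           # cap on freed GMF-nurses in occurrence mode (n^F)
    stall_limit: int = 20        # iterations without progress before stopping
    occurrence_threshold: int = 3  # "many occurrences" switch to occurrence mode
    failure_threshold: int = 5   # consecutive failures before switching mode
    solver_time_limit: float = 10.0
    max_descents: int = 4        # bound-search solves per min-GMF iteration
    max_iterations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_gmf_cap, self.stall_limit + 1, self.failure_threshold) <= 0:
            raise ValueError("LNS counts must be positive")
        if self.n_random < 0:
            raise ValueError("n_random must be non-negative")


@dataclass
class IterationRecord:
    iteration: int
    mode: str
    accepted: bool
    gmf: float
    occurrences: int
    neighborhood_size: int
    solver_status: str = ""
    per_nurse_max: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "mode": self.mode,
            "accepted": self.accepted,
            "gmf": self.gmf,
            "occurrences": self.occurrences,
            "neighborhood_size": self.neighborhood_size,
            "solver_status": self.solver_status,
            "per_nurse_max": list(self.per_nurse_max),
        }


@dataclass
class SearchState:
    incumbent: Roster
    fatigue: FatigueMatrix
    gmf: float
    occurrences: int
    stall: int = 0
    history: list[IterationRecord] = field(default_factory=list)
    seed: int = 0

    @property
    def per_nurse_max(self) -> np.ndarray:
        return self.fatigue.per_nurse_max

    @classmethod
    def from_roster(cls, roster: Roster, instance: Instance, table: LookupTable, seed: int = 0):
        f = rhe_matrix(roster, instance, table)
        gmf = f.gmf
        return cls(
            incumbent=roster,
            fatigue=f,
            gmf=gmf,
            occurrences=count_gmf_occurrences(f, gmf, VALUE_TOL),
            seed=seed,
        )


def initial_solution(instance: Instance, time_limit: float = 60.0) -> Roster:
    """Any feasible roster, fatigue ignored."""
    res = solve_subproblem(
        instance,
        None,
        NeighborhoodMask.all_free(instance.n_nurses, instance.n_days),
        None,
        Mode.FEASIBILITY,
        time_limit=time_limit,
    )
    if res.status == "infeasible":
        raise InfeasibleInstanceError("no roster satisfies the hard constraints")
    if res.roster is None:
        raise TimeoutError("no feasible roster found within the time limit")
    return res.roster


def select_mode(state: SearchState, config: LNSConfig) -> Mode:
    if (
        state.occurrences > config.occurrence_threshold
        or state.stall >= config.failure_threshold
    ):
        return Mode.MIN_OCCURRENCES
    return Mode.MIN_GMF


def build_neighborhood(
    state: SearchState,
    instance: Instance,
    config: LNSConfig,
    rng: np.random.Generator,
    mode: Mode,
) -> NeighborhoodMask:
    """Free the GMF nurses' rows, random rows, and all off-shift cells."""
    N, T = instance.n_nurses, instance.n_days
    free = np.zeros((N, T), dtype=bool)

    gmf_nurses = [
        n for n in range(N) if state.per_nurse_max[n] >= state.gmf - VALUE_TOL
    ]
    if mode is Mode.MIN_OCCURRENCES and len(gmf_nurses) > config.n_gmf_cap:
        order = rng.permutation(len(gmf_nurses))
        gmf_nurses = sorted(gmf_nurses[i] for i in order[: config.n_gmf_cap])
    for n in gmf_nurses:
        free[n, :] = True

    others = [n for n in range(N) if n not in set(gmf_nurses)]
    if others and config.n_random > 0:
        picked = rng.choice(len(others), size=min(config.n_random, len(others)), replace=False)
        for i in sorted(picked):
            free[others[i], :] = True

    arr = state.incumbent.as_array()
    free |= arr == "O"
    return NeighborhoodMask(free)


def accept_candidate(
    state: SearchState, candidate: Roster | None, instance: Instance, table: LookupTable
) -> tuple[bool, FatigueMatrix | None, float, int]:
    """Lexicographic acceptance on (GMF, occurrences of the GMF)."""
    if candidate is None:
        return False, None, state.gmf, state.occurrences
    f = rhe_matrix(candidate, instance, table)
    gmf = f.gmf
    if gmf < state.gmf - VALUE_TOL:
        return True, f, gmf, count_gmf_occurrences(f, gmf, VALUE_TOL)
    if gmf <= state.gmf + VALUE_TOL:
        occ = count_gmf_occurrences(f, state.gmf, VALUE_TOL)
        if occ < state.occurrences:
            return True, f, state.gmf, occ
    return False, None, state.gmf, state.occurrences


def run_lns(
    instance: Instance,
    table: LookupTable,
    config: LNSConfig | None = None,
    *,
    initial: Roster | None = None,
    check_each_incumbent: bool = True,
) -> SearchState:
    """Full search: initial solution, iterate, stop on stall (or cap)."""
    config = config or LNSConfig()
    rng = np.random.default_rng(config.seed)

    roster = initial if initial is not None else initial_solution(instance)
    if check_each_incumbent:
        bad = validate(roster, instance)
        if bad:
            raise ValueError(f"initial roster infeasible: {bad[0]}")
    state = SearchState.from_roster(roster, instance, table, seed=config.seed)
    state.history.append(
        IterationRecord(0, "initial", True, state.gmf, state.occurrences,
                        instance.n_nurses * instance.n_days,
                        per_nurse_max=tuple(np.round(state.per_nurse_max, 6)))
    )

    it = 0
    while state.stall < config.stall_limit and (
        config.max_iterations is None or it < config.max_iterations
    ):
        it += 1
        mode = select_mode(state, config)
        mask = build_neighborhood(state, instance, config, rng, mode)
        res: SubproblemResult = solve_subproblem(
            instance,
            table,
            mask,
            state.incumbent,
            mode,
            gmf_bound=state.gmf if mode is Mode.MIN_OCCURRENCES else None,
            time_limit=config.solver_time_limit,
            max_descents=config.max_descents,
        )
        accepted, f, gmf, occ = accept_candidate(state, res.roster, instance, table)
        if accepted:
            assert res.roster is not None
            if check_each_incumbent:
                bad = validate(res.roster, instance)
                if bad:
                    raise RuntimeError(f"solver produced an infeasible roster: {bad[0]}")
            state.incumbent = res.roster
            state.fatigue = f
            state.gmf = gmf
            state.occurrences = occ
            state.stall = 0
        else:
            state.stall += 1
        state.history.append(
            IterationRecord(
                it, mode.value, accepted, state.gmf, state.occurrences,
                int(mask.free.sum()), res.status,
                per_nurse_max=tuple(np.round(state.per_nurse_max, 6)),
            )
        )
    return state
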