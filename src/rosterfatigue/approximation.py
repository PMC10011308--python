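"""Rolling-horizon lookup-table approximation of the fatigue model.

The rostering model needs the fatigue score of nurse *n* on day *t* as a
function of the decision variables, but the score really depends on the
whole shift history through a nonlinear simulation. The approximation keys
each day's score on the *evaluation pattern*: the window of ``T_h`` shifts
ending on the scored day, plus a flag for a night shift on the day
immediately before the window (a night shift forces wakefulness into the
window's first day, so it perturbs the initial state). All
``2 * 4**T_h`` patterns per biological profile are simulated once from the
rested state and stored in a lookup table; evaluating a roster day is then
a constant-time lookup (the *rolling horizon evaluation*, RHE), while the
exact alternative simulates the entire roster in one run (the *full roster
evaluation*, FRE).
"""

from __future__ import annotations

import datetime
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import physiology
from .physiology import (
    DEFAULT_PARAMETERS,
    FatigueTrajectory,
    ModelParameters,
    rested_initial_state,
    simulate_batch,
)
from .profiles import ALL_PROFILES, BiologicalProfile, get_profile
from .shifts import ALL_SHIFTS, DEFAULT_CATALOG, MINUTES_PER_DAY, ShiftCatalog, compile_forced_wake

DEFAULT_HORIZON = 4
#: error magnitude below which a disagreement between RHE and FRE is
#: considered irrelevant (mV).
RELEVANCE_THRESHOLD_MV = 0.10


@dataclass(frozen=True)
class EvaluationPattern:
    """A ``T_h``-day shift window plus the preceding-night flag."""

    shifts: tuple[str, ...]
    preceded_by_night: bool

    def __post_init__(self) -> None:
        for s in self.shifts:
            if s not in ALL_SHIFTS:
                raise ValueError(f"unknown shift code {s!r} in pattern")

    @property
    def horizon(self) -> int:
        return len(self.shifts)

    @property
    def pattern_string(self) -> str:
        return "".join(self.shifts)

    def key(self) -> tuple[bool, str]:
        return (self.preceded_by_night, self.pattern_string)


def enumerate_patterns(
    t_h: int, catalog: ShiftCatalog = DEFAULT_CATALOG
) -> list[EvaluationPattern]:
    """All ``2 * 4**t_h`` evaluation patterns, in deterministic order."""
    if t_h < 1:
        raise ValueError("evaluation horizon must be at least one day")
    return [
        EvaluationPattern(shifts, flag)
        for flag in (False, True)
        for shifts in itertools.product(ALL_SHIFTS, repeat=t_h)
    ]


def extract_pattern(roster_row, t: int, t_h: int = DEFAULT_HORIZON) -> EvaluationPattern:
    """Evaluation pattern of day ``t`` (1-based); days before day 1 are off."""
    if t < 1:
        raise ValueError("day index is 1-based")

    def code(day: int) -> str:
        return roster_row[day - 1] if day >= 1 else "O"

    shifts = tuple(code(d) for d in range(t - t_h + 1, t + 1))
    return EvaluationPattern(shifts, preceded_by_night=code(t - t_h) == "N")


@dataclass
class LookupTable:
    """(profile, night-before flag, pattern) -> last-day max fatigue (mV)."""

    t_h: int
    values: dict[tuple[int, bool, str], float]
    params_fingerprint: str
    built_at: str = ""
    profile_ids: tuple[int, ...] = ()

    def get(self, profile_id: int, pattern: EvaluationPattern) -> float:
        key = (profile_id, pattern.preceded_by_night, pattern.pattern_string)
        try:
            return self.values[key]
        except KeyError:
            raise KeyError(
                f"lookup table has no entry for {key}; the table is stale or was "
                f"built for other profiles/horizon"
            ) from None

    def check_params(self, params: ModelParameters) -> None:
        if params.fingerprint() != self.params_fingerprint:
            raise ValueError(
                "lookup table was built under different model parameters "
                f"({self.params_fingerprint} != {params.fingerprint()})"
            )

    def distinct_values(self, profile_ids=None) -> np.ndarray:
        vals = [
            v
            for (pid, _, _), v in self.values.items()
            if profile_ids is None or pid in set(profile_ids)
        ]
        return np.unique(np.asarray(vals))

    # --- persistence: flat CSV + JSON metadata sidecar -------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        path = Path(path)
        rows = [
            {"profile_id": pid, "night_before": int(flag), "pattern": pat, "fatigue_mv": v}
            for (pid, flag, pat), v in sorted(self.values.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")
        meta = {
            "t_h": self.t_h,
            "params_fingerprint": self.params_fingerprint,
            "built_at": self.built_at,
            "profile_ids": list(self.profile_ids),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path, params: ModelParameters | None = None) -> "LookupTable":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        table = cls(
            t_h=int(meta["t_h"]),
            values={
                (int(r.profile_id), bool(r.night_before), str(r.pattern)): float(r.fatigue_mv)
                for r in df.itertuples()
            },
            params_fingerprint=meta["params_fingerprint"],
            built_at=meta.get("built_at", ""),
            profile_ids=tuple(meta.get("profile_ids", ())),
        )
        if params is not None:
            table.check_params(params)
        return table


def rested_state_for(profile: BiologicalProfile, params: ModelParameters = DEFAULT_PARAMETERS):
    return rested_initial_state(
        profile.d0_total(params), profile.tau_c, params,
        profile_name=f"profile {profile.profile_id}",
    )


def _pattern_forced_mask(pattern: EvaluationPattern, catalog: ShiftCatalog, n_min: int):
    """Forced-wake mask for one table scenario: [prepend day][pattern][buffer]."""
    row = (("N",) if pattern.preceded_by_night else ("O",)) + pattern.shifts + ("O",)
    return np.asarray(compile_forced_wake(row, catalog).mask(n_min), dtype=np.bool_)


def simulate_pattern(
    pattern: EvaluationPattern,
    profile: BiologicalProfile,
    params: ModelParameters = DEFAULT_PARAMETERS,
    catalog: ShiftCatalog = DEFAULT_CATALOG,
) -> float:
    """Oracle recomputation of one lookup entry via a fresh simulation."""
    t_h = pattern.horizon
    n_days = t_h + 2
    n_min = n_days * MINUTES_PER_DAY
    forced = _pattern_forced_mask(pattern, catalog, n_min)[None, :]
    state = rested_state_for(profile, params).as_array()[None, :]
    drive, _ = simulate_batch(
        state.copy(), forced,
        np.array([profile.d0_total(params)]), np.array([profile.tau_c]), params,
    )
    last = slice(t_h * MINUTES_PER_DAY, (t_h + 1) * MINUTES_PER_DAY)
    return float(np.max(drive[0, last]))


def build_lookup(
    profiles=None,
    t_h: int = DEFAULT_HORIZON,
    params: ModelParameters = DEFAULT_PARAMETERS,
    catalog: ShiftCatalog = DEFAULT_CATALOG,
    chunk_size: int = 512,
) -> LookupTable:
    """Simulate every evaluation pattern for every profile.

    The table is *total*: rule-violating patterns are tabulated too, so a
    lookup can never miss. Scenarios are batched through the vectorised
    simulator; each entry equals :func:`simulate_pattern` exactly (same
    integrator, same grid).
    """
    if profiles is None:
        profiles = list(ALL_PROFILES.values())
    profiles = [get_profile(p) if isinstance(p, int) else p for p in profiles]
    patterns = enumerate_patterns(t_h, catalog)
    n_days = t_h + 2
    n_min = n_days * MINUTES_PER_DAY
    last = slice(t_h * MINUTES_PER_DAY, (t_h + 1) * MINUTES_PER_DAY)

    masks = np.stack([_pattern_forced_mask(p, catalog, n_min) for p in patterns])

    values: dict[tuple[int, bool, str], float] = {}
    for profile in profiles:
        state0 = rested_state_for(profile, params).as_array()
        for start in range(0, len(patterns), chunk_size):
            block = slice(start, min(start + chunk_size, len(patterns)))
            n_block = block.stop - block.start
            states = np.repeat(state0[None, :], n_block, axis=0)
            drive, _ = simulate_batch(
                states,
                masks[block],
                np.full(n_block, profile.d0_total(params)),
                np.full(n_block, profile.tau_c),
                params,
            )
            maxima = drive[:, last].max(axis=1)
            for pat, v in zip(patterns[block], maxima):
                values[(profile.profile_id, pat.preceded_by_night, pat.pattern_string)] = float(v)

    return LookupTable(
        t_h=t_h,
        values=values,
        params_fingerprint=params.fingerprint(),
        built_at=datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
        profile_ids=tuple(p.profile_id for p in profiles),
    )


@dataclass
class FatigueSeries:
    """Per-day fatigue scores (mV) of one nurse's roster."""

    values: np.ndarray
    provenance: str  # "RHE_<t_h>" or "FRE"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fatigue series contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def rhe_evaluate(roster_row, profile_id: int, table: LookupTable) -> FatigueSeries:
    """Approximated per-day fatigue via table lookups."""
    vals = [
        table.get(profile_id, extract_pattern(roster_row, t, table.t_h))
        for t in range(1, len(roster_row) + 1)
    ]
    return FatigueSeries(np.array(vals), provenance=f"RHE_{table.t_h}")


def fre_evaluate(
    roster_row,
    profile: BiologicalProfile | int,
    params: ModelParameters = DEFAULT_PARAMETERS,
    catalog: ShiftCatalog = DEFAULT_CATALOG,
) -> FatigueSeries:
    """True per-day fatigue: one simulation of the whole roster from rest."""
    mat = fre_matrix([list(roster_row)], [profile], params, catalog)
    return FatigueSeries(mat[0], provenance="FRE")


def fre_matrix(
    roster_rows,
    profiles,
    params: ModelParameters = DEFAULT_PARAMETERS,
    catalog: ShiftCatalog = DEFAULT_CATALOG,
) -> np.ndarray:
    """Full roster evaluation of many nurses at once -> (n, T) daily maxima."""
    profiles = [get_profile(p) if isinstance(p, int) else p for p in profiles]
    if len(profiles) != len(roster_rows):
        raise ValueError("one profile per roster row required")
    horizon = len(roster_rows[0])
    if any(len(r) != horizon for r in roster_rows):
        raise ValueError("all roster rows must share the horizon")
    n_days = horizon + 1  # buffer day for a trailing night shift
    n_min = n_days * MINUTES_PER_DAY
    forced = np.stack(
        [np.asarray(compile_forced_wake(r, catalog).mask(n_min), dtype=np.bool_) for r in roster_rows]
    )
    states = np.stack([rested_state_for(p, params).as_array() for p in profiles])
    drive, _ = simulate_batch(
        states,
        forced,
        np.array([p.d0_total(params) for p in profiles]),
        np.array([p.tau_c for p in profiles]),
        params,
    )
    daily = drive[:, : horizon * MINUTES_PER_DAY].reshape(len(roster_rows), horizon, MINUTES_PER_DAY)
    return daily.max(axis=2)


def simulate_roster(
    roster_row,
    profile: BiologicalProfile | int,
    params: ModelParameters = DEFAULT_PARAMETERS,
    catalog: ShiftCatalog = DEFAULT_CATALOG,
    buffer_days: int = 1,
) -> FatigueTrajectory:
    """Full trajectory (not just daily maxima) of one roster from rest."""
    profile = get_profile(profile) if isinstance(profile, int) else profile
    wake = compile_forced_wake(roster_row, catalog)
    state = rested_state_for(profile, params)
    return physiology.simulate(
        state, wake, params, len(roster_row) + buffer_days,
        d0=profile.d0_total(params), tau_c=profile.tau_c,
    )


def error_percentiles(
    series_true,
    series_approx,
    percentiles=(1, 5, 10, 90, 95, 99),
    drop_first_days: int = 0,
) -> dict[float, float]:
    """Percentiles of FRE - RHE errors, pooled over one or many rosters.

    ``series_true``/``series_approx`` are either two equal-length 1-D arrays
    or two equal-length lists of such arrays (one per roster); the first
    ``drop_first_days`` days of every roster are discarded before pooling
    (inside the horizon the two evaluations coincide by construction).
    """
    if isinstance(series_true, (FatigueSeries, np.ndarray)) or (
        len(series_true) and np.isscalar(series_true[0])
    ):
        series_true, series_approx = [series_true], [series_approx]
    pool = []
    for st, sa in zip(series_true, series_approx, strict=True):
        a = np.asarray(getattr(st, "values", st), dtype=np.float64)
        b = np.asarray(getattr(sa, "values", sa), dtype=np.float64)
        if a.shape != b.shape:
            raise ValueError("true and approximate series must have equal length")
        pool.append((a - b)[drop_first_days:])
    pooled = np.concatenate(pool)
    if pooled.size == 0:
        raise ValueError("no data points left after dropping initial days")
    return {float(q): float(np.percentile(pooled, q)) for q in percentiles}
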