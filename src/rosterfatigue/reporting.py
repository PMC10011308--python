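"""Experiment harnesses and roster reports.

Everything here is recomputable from a roster, an instance and a lookup
table alone; reports are tidy DataFrames ready for CSV/JSON export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .approximation import LookupTable, fre_matrix
from .lns import LNSConfig, SearchState, run_lns
from .model import Instance, Roster, count_gmf_occurrences
from .physiology import DEFAULT_PARAMETERS, ModelParameters
from .postprocess import PostprocessConfig, apply_extras
from .profiles import ALL_PROFILES
from .instances import modify_staff


def triple_night_count(row, distinct_blocks: bool = False) -> int:
    """Days t with nights on t-2, t-1 and t (overlapping windows by
    default: four consecutive nights count as two triples)."""
    count = 0
    t = 2
    while t < len(row):
        if row[t] == "N" and row[t - 1] == "N" and row[t - 2] == "N":
            count += 1
            t += 3 if distinct_blocks else 1
        else:
            t += 1
    return count


def profile_shift_stats(
    roster: Roster, instance: Instance, distinct_blocks: bool = False
) -> pd.DataFrame:
    """Mean per-nurse D/E/N counts and triple-night counts by profile."""
    records = []
    for n in range(roster.n_nurses):
        row = roster.row(n)
        records.append(
            {
                "profile_id": instance.profile_of(n),
                "day_shifts": row.count("D"),
                "evening_shifts": row.count("E"),
                "night_shifts": row.count("N"),
                "triple_nights": triple_night_count(row, distinct_blocks),
            }
        )
    df = pd.DataFrame(records)
    out = df.groupby("profile_id").mean().reset_index()
    out.insert(1, "n_nurses", df.groupby("profile_id").size().values)
    out.insert(
        1, "sleep_time", [ALL_PROFILES[p].sleep_time_class for p in out["profile_id"]]
    )
    out.insert(
        2, "chronotype", [ALL_PROFILES[p].chronotype_class for p in out["profile_id"]]
    )
    return out


def cross_profile_evaluation(
    roster: Roster,
    instance: Instance,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Re-simulate the whole roster as if *all* nurses had each profile.

    Returns one row per profile with the global maximum fatigue the roster
    would produce for staff of that biology, plus an average row. Used to
    quantify the value of knowing individual biotypes.
    """
    rows = []
    for pid, prof in sorted(ALL_PROFILES.items()):
        mat = fre_matrix(
            roster.assignments, [pid] * roster.n_nurses, params, instance.catalog
        )
        rows.append(
            {
                "profile_id": pid,
                "sleep_time": prof.sleep_time_class,
                "chronotype": prof.chronotype_class,
                "gmf_mv": float(mat.max()),
            }
        )
    df = pd.DataFrame(rows)
    avg = {
        "profile_id": "average",
        "sleep_time": "",
        "chronotype": "",
        "gmf_mv": float(df["gmf_mv"].mean()),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


@dataclass
class PipelineResult:
    instance: Instance
    state: SearchState
    approx_gmf: float
    post: "object"  # PostprocessResult

    @property
    def true_gmf_pp(self) -> float:
        return self.post.true_gmf


def run_pipeline(
    instance: Instance,
    table: LookupTable,
    config: LNSConfig | None = None,
    params: ModelParameters = DEFAULT_PARAMETERS,
    pp_config: PostprocessConfig | None = None,
) -> PipelineResult:
    """Initial solution + LNS + full evaluation + extras post-processing."""
    state = run_lns(instance, table, config)
    post = apply_extras(state.incumbent, instance, state.gmf, params, pp_config)
    return PipelineResult(instance, state, state.gmf, post)


def staffing_experiment(
    base_instance: Instance,
    table: LookupTable,
    increments=(0, 1, 2),
    config: LNSConfig | None = None,
    params: ModelParameters = DEFAULT_PARAMETERS,
    profile_id: int = 1,
) -> pd.DataFrame:
    """Post-processed true GMF as staff is incremented by nurses of the
    most common profile; deltas are successive column differences."""
    rows = []
    for k in increments:
        inst = base_instance if k == 0 else modify_staff(base_instance, k, profile_id)
        result = run_pipeline(inst, table, config, params)
        rows.append(
            {
                "increment": k,
                "n_nurses": inst.n_nurses,
                "approx_gmf_mv": result.approx_gmf,
                "true_gmf_pp_mv": result.true_gmf_pp,
                "n_extras": result.post.n_extras,
                "iterations": len(result.state.history) - 1,
            }
        )
    df = pd.DataFrame(rows).sort_values("increment").reset_index(drop=True)
    df["delta_true_gmf_mv"] = -df["true_gmf_pp_mv"].diff()
    return df


def export_history(state: SearchState) -> list[dict]:
    """Per-iteration search records (plot-ready, JSON-serialisable)."""
    return [rec.to_dict() for rec in state.history]


def save_history(state: SearchState, path) -> None:
    payload = {
        "seed": state.seed,
        "final_gmf_mv": state.gmf,
        "final_occurrences": state.occurrences,
        "per_nurse_max_mv": [float(v) for v in state.per_nurse_max],
        "iterations": export_history(state),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def recount_occurrences(state: SearchState) -> int:
    """Independent recount of the incumbent's GMF occurrences."""
    return count_gmf_occurrences(state.fatigue, state.gmf)
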