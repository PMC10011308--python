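import numpy as np
import pytest

from rosterfatigue import build_lookup, homogeneous_instance
from rosterfatigue.model import Instance, Roster, validate


@pytest.fixture(scope="session")
def table1():
    """Lookup table for the default profile, 4-day horizon."""
    return build_lookup(profiles=[1], t_h=4)


@pytest.fixture(scope="session")
def table_all():
    """Lookup table for all nine profiles, 4-day horizon."""
    return build_lookup(t_h=4)


@pytest.fixture(scope="session")
def toy_instance():
    """6 nurses x 14 days with light coverage and scaled hour bounds."""
    return homogeneous_instance(
        1, n=6, n_days=14, coverage=(2, 1, 1),
        min_total_hours=4 * 8.5, max_total_hours=10 * 8.5,
    )


@pytest.fixture(scope="session")
def mid_instance():
    """12 nurses x 14 days, coverage (3,2,2)."""
    return homogeneous_instance(
        1, n=12, n_days=14, coverage=(3, 2, 2),
        min_total_hours=6 * 8.5, max_total_hours=10 * 8.5,
    )


def _row_instance(profile_id: int, n_days: int) -> Instance:
    """Single-nurse instance with no coverage, for per-row feasibility."""
    return Instance(
        nurse_profiles=(profile_id,),
        n_days=n_days,
        coverage={"D": 0, "E": 0, "N": 0},
        min_total_hours=0.0,
        max_total_hours=8.5 * n_days,
    )


def row_is_feasible(row, profile_id: int = 1) -> bool:
    """Does a single nurse's row satisfy all individual scheduling rules?"""
    inst = _row_instance(profile_id, len(row))
    return not validate(Roster([list(row)]), inst)


def random_feasible_rows(n_rows: int, n_days: int, seed: int, max_tries: int = 200_000):
    """Rejection-sample individually feasible shift rows."""
    rng = np.random.default_rng(seed)
    codes = np.array(list("DENO"))
    rows = []
    for _ in range(max_tries):
        row = list(rng.choice(codes, size=n_days, p=[0.2, 0.2, 0.15, 0.45]))
        if row_is_feasible(row):
            rows.append(row)
            if len(rows) == n_rows:
                return rows
    raise RuntimeError("could not sample enough feasible rows")
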