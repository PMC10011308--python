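"""Post-processing: reconcile approximated and true fatigue with extras.

The search optimises lookup-table (rolling-horizon) fatigue scores. After
it terminates, a full simulation of the final roster can reveal a *true*
global maximum fatigue above the approximated one. When the gap reaches
the relevance threshold (0.10 mV), single shifts are handed to casual
"extras": the GMF nurse's last work shift strictly before the day of the
true maximum is replaced by an off-shift (the shift itself when no
earlier one exists), the substituted shift still counting towards
coverage. This is repeated — re-simulating and re-locating the global
maximum each time — until the gap is irrelevant or the extras budget
(six shifts, one per week of the default horizon) is exhausted. Removing
shifts breaks the minimum-total-hours floor by design, so that floor is
waived for the repaired roster.
"""

from __future__ import annotations

from dataclasses import dataclass

from .approximation import RELEVANCE_THRESHOLD_MV, fre_matrix
from .model import FatigueMatrix, Instance, Roster
from .physiology import DEFAULT_PARAMETERS, ModelParameters
from .shifts import WORK_SHIFTS


@dataclass
class PostprocessConfig:
    relevance_threshold_mv: float = RELEVANCE_THRESHOLD_MV
    max_extras: int = 6

    def __post_init__(self) -> None:
        if self.relevance_threshold_mv < 0 or self.max_extras < 0:
            raise ValueError("threshold and extras budget must be non-negative")


@dataclass
class PostprocessResult:
    roster: Roster
    extras: list[tuple[int, int, str]]
    true_fatigue: FatigueMatrix
    true_gmf: float
    approx_gmf: float

    @property
    def n_extras(self) -> int:
        return len(self.extras)


def full_evaluation(
    roster: Roster, instance: Instance, params: ModelParameters = DEFAULT_PARAMETERS
) -> tuple[FatigueMatrix, tuple[int, int, float]]:
    """True fatigue matrix of every nurse plus its argmax (nurse, day, mV)."""
    mat = FatigueMatrix(
        fre_matrix(
            roster.assignments,
            list(instance.nurse_profiles),
            params,
            instance.catalog,
        )
    )
    return mat, mat.argmax()


def _substitution_target(row: list[str], argmax_day: int) -> int | None:
    """Day whose shift is handed to an extra: the last work day strictly
    before the fatigue peak, falling back to the peak day itself."""
    for d in range(argmax_day - 1, 0, -1):
        if row[d - 1] in WORK_SHIFTS:
            return d
    if row[argmax_day - 1] in WORK_SHIFTS:
        return argmax_day
    return None


def apply_extras(
    roster: Roster,
    instance: Instance,
    approx_gmf: float,
    params: ModelParameters = DEFAULT_PARAMETERS,
    config: PostprocessConfig | None = None,
) -> PostprocessResult:
    """Substitute up to ``max_extras`` shifts until the true GMF is within
    the relevance threshold of the approximated GMF."""
    config = config or PostprocessConfig()
    repaired = roster.copy()
    mat, (n, t, true_gmf) = full_evaluation(repaired, instance, params)
    extras: list[tuple[int, int, str]] = []

    while (
        true_gmf >= approx_gmf + config.relevance_threshold_mv - 1e-12
        and len(extras) < config.max_extras
    ):
        row = repaired.row(n)
        day = _substitution_target(row, t)
        if day is None:
            break  # peak not caused by any removable shift of this nurse
        extras.append((n, day, row[day - 1]))
        row[day - 1] = "O"
        # only nurse n's trajectory changed
        new_row = fre_matrix(
            [row], [instance.profile_of(n)], params, instance.catalog
        )[0]
        values = mat.values.copy()
        values[n, :] = new_row
        mat = FatigueMatrix(values)
        n, t, true_gmf = mat.argmax()

    repaired.extras.extend(extras)
    return PostprocessResult(
        roster=repaired,
        extras=extras,
        true_fatigue=mat,
        true_gmf=true_gmf,
        approx_gmf=approx_gmf,
    )
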