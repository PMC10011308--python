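"""The nine biological profiles: sleep-time class x chronotype class.

Two physiology parameters vary across the adult population in this model:
the constant sleep-drive offset ``D0`` (habitual sleep duration: roughly 5,
7 or 9 hours when fully rested) and the intrinsic circadian period
``tau_c`` (morning, day or evening chronotype). The nine combinations are
indexed 1-9 with the day-type chronotype row first:

    =========  ========  =======  =====
    sleep      morning   day      evening
    =========  ========  =======  =====
    normal ~7h    4        1        7
    short  ~5h    5        2        8
    long   ~9h    6        3        9
    =========  ========  =======  =====

The offsets and periods below were calibrated once against the rested-sleep
anchors (7 +/- 0.5 h, 5 +/- 0.5 h, 9 +/- 0.5 h; chronotype sleep-midpoint
shifts of roughly +/- 1 h) under the default :class:`ModelParameters`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .physiology import DEFAULT_PARAMETERS, ModelParameters

SLEEP_CLASSES = ("short", "normal", "long")
CHRONOTYPES = ("morning", "day", "evening")

#: (sleep_time_class, chronotype_class) -> profile id, matching the standard
#: indexing where normal/day is profile 1.
PROFILE_INDEX: dict[tuple[str, str], int] = {
    ("normal", "day"): 1,
    ("short", "day"): 2,
    ("long", "day"): 3,
    ("normal", "morning"): 4,
    ("short", "morning"): 5,
    ("long", "morning"): 6,
    ("normal", "evening"): 7,
    ("short", "evening"): 8,
    ("long", "evening"): 9,
}

#: Calibrated D0 offsets (mV) relative to ModelParameters.d0_base per sleep class.
D0_OFFSETS: dict[str, float] = {
    "short": -2.518,
    "normal": 0.0,
    "long": 2.473,
}

#: Calibrated intrinsic circadian periods (hours) per chronotype class.
TAU_C: dict[str, float] = {
    "morning": 23.55,
    "day": 24.15,
    "evening": 24.72,
}


@dataclass(frozen=True)
class BiologicalProfile:
    profile_id: int
    sleep_time_class: str
    chronotype_class: str
    d0_offset: float
    tau_c: float

    def d0_total(self, params: ModelParameters = DEFAULT_PARAMETERS) -> float:
        return params.d0_base + self.d0_offset


def make_profile(sleep_time_class: str, chronotype_class: str) -> BiologicalProfile:
    if sleep_time_class not in SLEEP_CLASSES:
        raise ValueError(f"unknown sleep-time class {sleep_time_class!r}")
    if chronotype_class not in CHRONOTYPES:
        raise ValueError(f"unknown chronotype class {chronotype_class!r}")
    return BiologicalProfile(
        profile_id=PROFILE_INDEX[(sleep_time_class, chronotype_class)],
        sleep_time_class=sleep_time_class,
        chronotype_class=chronotype_class,
        d0_offset=D0_OFFSETS[sleep_time_class],
        tau_c=TAU_C[chronotype_class],
    )


ALL_PROFILES: dict[int, BiologicalProfile] = {
    pid: make_profile(sc, ct) for (sc, ct), pid in PROFILE_INDEX.items()
}


def get_profile(profile_id: int) -> BiologicalProfile:
    try:
        return ALL_PROFILES[profile_id]
    except KeyError:
        raise ValueError(f"profile id must be 1-9, got {profile_id}") from None


DEFAULT_PROFILE = ALL_PROFILES[1]
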