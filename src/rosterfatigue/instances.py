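"""Synthetic instance generation and the two fixture rosters.

Instances emulate a 30-nurse intensive-care ward rostered over six weeks
with minimum coverage of 7 day-, 5 evening- and 5 night-shift nurses.
Biological profiles are drawn independently: 10% short / 80% normal /
10% long sleep time, and 10% morning / 80% day / 10% evening chronotype,
so the most common profile (normal sleep, day type, id 1) has probability
0.64. Two anonymised real 42-day rosters are shipped as code-level
fixtures for approximation-error analysis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .model import Instance
from .profiles import CHRONOTYPES, PROFILE_INDEX, SLEEP_CLASSES, get_profile

DEFAULT_SLEEP_DIST = {"short": 0.1, "normal": 0.8, "long": 0.1}
DEFAULT_CHRONO_DIST = {"morning": 0.1, "day": 0.8, "evening": 0.1}


@dataclass(frozen=True)
class ProfileSampler:
    """Independent draws of sleep-time class and chronotype class."""

    sleep_dist: tuple[tuple[str, float], ...] = tuple(DEFAULT_SLEEP_DIST.items())
    chrono_dist: tuple[tuple[str, float], ...] = tuple(DEFAULT_CHRONO_DIST.items())

    def __post_init__(self) -> None:
        for dist, names in ((self.sleep_dist, SLEEP_CLASSES), (self.chrono_dist, CHRONOTYPES)):
            if set(k for k, _ in dist) != set(names):
                raise ValueError("distribution keys must match the class names")
            if abs(sum(p for _, p in dist) - 1.0) > 1e-12:
                raise ValueError("probabilities must sum to 1")

    def joint_probability(self, profile_id: int) -> float:
        prof = get_profile(profile_id)
        return dict(self.sleep_dist)[prof.sleep_time_class] * dict(self.chrono_dist)[
            prof.chronotype_class
        ]

    def sample(self, n: int, seed: int | np.random.Generator) -> list[int]:
        if n < 1:
            raise ValueError("need at least one draw")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sleep_names, sleep_p = zip(*self.sleep_dist)
        chrono_names, chrono_p = zip(*self.chrono_dist)
        sleeps = rng.choice(len(sleep_names), size=n, p=sleep_p)
        chronos = rng.choice(len(chrono_names), size=n, p=chrono_p)
        return [
            PROFILE_INDEX[(sleep_names[s], chrono_names[c])] for s, c in zip(sleeps, chronos)
        ]


def sample_profiles(n: int, seed: int) -> list[int]:
    return ProfileSampler().sample(n, seed)


def _coverage_dict(coverage) -> dict[str, int]:
    if isinstance(coverage, dict):
        return dict(coverage)
    d, e, n = coverage
    return {"D": d, "E": e, "N": n}


def make_instance(
    n_nurses: int = 30,
    days: int = 42,
    coverage=(7, 5, 5),
    seed: int = 0,
    sampler: ProfileSampler | None = None,
    **rule_overrides,
) -> Instance:
    """A synthetic ward instance with sampled biological profiles."""
    sampler = sampler or ProfileSampler()
    profiles = tuple(sampler.sample(n_nurses, seed))
    meta = {"seed": str(seed), "profiles": "sampled"}
    meta.update({k: "user" for k in rule_overrides})
    return Instance(
        nurse_profiles=profiles,
        n_days=days,
        coverage=_coverage_dict(coverage),
        metadata=tuple(sorted(meta.items())),
        **rule_overrides,
    )


def modify_staff(instance: Instance, k: int, profile_id: int = 1) -> Instance:
    """Append ``k`` full-time nurses of the given profile (default: the
    most common one), leaving everything else untouched."""
    if k < 1:
        raise ValueError("k must be at least 1")
    get_profile(profile_id)
    d = instance.to_dict()
    d["nurse_profiles"] = list(instance.nurse_profiles) + [profile_id] * k
    d["metadata"]["staff_increment"] = str(k)
    return Instance.from_dict(d)


def homogeneous_instance(profile_id: int, n: int = 30, **kwargs) -> Instance:
    """All nurses share one biological profile."""
    get_profile(profile_id)
    meta = {"profiles": f"homogeneous_{profile_id}"}
    cov = _coverage_dict(kwargs.pop("coverage", (7, 5, 5)))
    return Instance(
        nurse_profiles=(profile_id,) * n,
        coverage=cov,
        metadata=tuple(sorted(meta.items())),
        **kwargs,
    )


def min_share(coverage, days: int, n_nurses: int) -> tuple[Fraction, ...]:
    """Minimum average shifts per nurse implied by coverage: c_s * T / N."""
    if n_nurses <= 0:
        raise ValueError("need at least one nurse")
    cov = _coverage_dict(coverage)
    return tuple(Fraction(cov[s] * days, n_nurses) for s in ("D", "E", "N"))


# --- fixture rosters --------------------------------------------------------
# Two anonymised real 42-day individual rosters used for approximation-error
# analysis; stored as constants with checksums guarding against silent edits.
_REALROSTER_1 = (
    "O,O,E,E,D,O,O,E,E,D,O,O,E,D,"
    "D,E,D,D,O,O,E,E,D,D,O,O,O,O,"
    "O,N,N,N,O,O,O,N,N,N,O,O,O,O"
)
_REALROSTER_2 = (
    "O,O,O,N,N,N,N,O,O,O,N,N,N,N,"
    "O,D,O,N,N,N,O,O,O,O,N,N,N,N,"
    "O,O,O,N,N,N,N,O,O,O,N,N,N,O"
)
_CHECKSUMS = {
    "realroster_1": "a8a7009a1e735737776fab664f9db0dc97c40d34971f53fcbfaa4963c5552b4d",
    "realroster_2": "2f67237a0b1cc9ffbcacc456be1b7a8a2aefddb9cae0a445a435f26494bd3d03",
}


def printed_rosters() -> dict[str, list[str]]:
    """The two fixture rosters as 42-day shift-code lists."""
    out = {}
    for name, text in (("realroster_1", _REALROSTER_1), ("realroster_2", _REALROSTER_2)):
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != _CHECKSUMS[name]:
            raise RuntimeError(f"fixture {name} was modified (checksum mismatch)")
        row = text.split(",")
        assert len(row) == 42
        out[name] = row
    return out
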