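"""Physiological sleep-drive ("fatigue") simulation.

The model couples three well-known ingredients:

* a *sleep/wake switch*: two mutually inhibitory neural populations
  (wake-active and sleep-active) with sigmoidal firing rates, so the system
  is bistable and flips between consolidated wake and sleep;
* a *homeostatic somnogen* ``H`` produced in proportion to wake-active
  firing and cleared first-order, the classic sleep-pressure process;
* a *circadian oscillator*: a light-driven van der Pol limit cycle whose
  state ``x`` modulates the sleep drive, with intrinsic period ``tau_c``
  (the chronotype parameter) and environmental light available between dawn
  and dusk while the individual is awake.

The total sleep drive, reported in mV and called *fatigue* throughout the
package, is ``D = nu_h * H + C(x, xc) + D0``. The constant offset ``D0``
sets habitual sleep duration and is the parameter varied across sleep-time
classes; ``tau_c`` is the parameter varied across chronotypes. Work shifts
act on the model solely by *forcing wakefulness*: during a forced interval
the sleep-active population is clamped to the wake branch (a strong
inhibitory wake-effort input) while the homeostat keeps accumulating.

Integration is fixed-step RK4 on a sub-minute step with a 1-minute output
grid, so trajectories are bit-reproducible for identical inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
from numba import njit

from .shifts import MINUTES_PER_DAY, ForcedWakeSchedule

__all__ = [
    "ModelParameters",
    "PhysiologicalState",
    "FatigueTrajectory",
    "SimulationError",
    "ConvergenceError",
    "rested_initial_state",
    "simulate",
    "simulate_batch",
    "daily_max_fatigue",
    "sleep_duration_stats",
]


class SimulationError(RuntimeError):
    """Raised when the integrator produces non-finite state."""


class ConvergenceError(RuntimeError):
    """Raised when the unforced model fails to settle on a daily orbit."""


@dataclass(frozen=True)
class ModelParameters:
    """Full constant set of the reference sleep-switch model (version 1).

    All of these are fixed physiology/environment inputs; rostering only
    ever supplies forced-wake intervals and the per-profile ``(D0, tau_c)``
    pair. Voltages in mV, times in minutes unless noted.
    """

    schema_version: int = 1
    # firing-rate sigmoid
    q_theta: float = 0.0
    q_sigma: float = 0.3
    # population coupling (mV)
    wake_drive: float = 1.3          # constant excitatory drive to wake-active pool
    inhib_sleep_to_wake: float = 2.0  # sleep-active -> wake-active inhibition
    inhib_wake_to_sleep: float = 2.3  # wake-active -> sleep-active inhibition
    tau_pop_min: float = 1.0          # population relaxation time
    # homeostat
    somnogen_gain: float = 20.0       # asymptotic H under sustained wake
    somnogen_tau_min: float = 2700.0  # first-order clearance time constant
    nu_h: float = 1.0                 # mV per unit H in the sleep drive
    # circadian
    circ_amp: float = 2.0             # linear circadian drive amplitude (mV)
    circ_quad: float = 1.2            # quadratic harmonic: sharpens the pre-dawn peak
    circ_phase_rad: float = 0.78      # delay of the circadian drive component, radians
    tau_c_default_h: float = 24.15    # intrinsic period, hours (day-type chronotype)
    d0_base: float = -14.733             # constant drive offset, normal sleep-time class
    light_gain: float = 0.3
    light_k: float = 0.55
    vdp_gamma: float = 0.13
    dawn_min: float = 360.0
    dusk_min: float = 1080.0
    # forced wakefulness
    wake_effort: float = 20.0         # inhibition clamping the switch awake (mV)
    # integrator
    dt_min: float = 0.25
    # rested-state burn-in
    burn_in_days: int = 30
    max_burn_in_days: int = 200
    burn_in_tol: float = 1e-6

    def kernel_array(self) -> np.ndarray:
        return np.array(
            [
                self.q_theta,
                self.q_sigma,
                self.wake_drive,
                self.inhib_wake_to_sleep,
                self.inhib_sleep_to_wake,
                self.tau_pop_min,
                self.somnogen_gain,
                self.somnogen_tau_min,
                self.nu_h,
                self.circ_amp,
                self.light_gain,
                self.light_k,
                self.vdp_gamma,
                self.dawn_min,
                self.dusk_min,
                self.wake_effort,
                self.dt_min,
                self.circ_phase_rad,
                self.circ_quad,
            ],
            dtype=np.float64,
        )

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def save(self, path) -> None:
        """Write the parameter set (with the embedded profile definitions)
        as a structured YAML/JSON config."""
        from .profiles import D0_OFFSETS, PROFILE_INDEX, TAU_C

        payload = {
            "model_parameters": asdict(self),
            "profiles": {
                str(pid): {"sleep_time_class": sc, "chronotype_class": ct,
                           "d0_offset": D0_OFFSETS[sc], "tau_c": TAU_C[ct]}
                for (sc, ct), pid in sorted(PROFILE_INDEX.items(), key=lambda kv: kv[1])
            },
        }
        from pathlib import Path

        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "ModelParameters":
        from pathlib import Path

        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(path.read_text())
        else:
            payload = json.loads(path.read_text())
        d = payload["model_parameters"]
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported parameter schema {d.get('schema_version')}")
        return cls(**d)


DEFAULT_PARAMETERS = ModelParameters()


@dataclass(frozen=True)
class PhysiologicalState:
    """Model state vector (Vv, Vm, H, x, xc) at a midnight."""

    vector: tuple[float, float, float, float, float]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=np.float64)


@dataclass
class FatigueTrajectory:
    """Sleep drive on a uniform 1-minute grid, plus activity flags.

    Grid point ``i`` is the state at minute ``i`` from the planning-period
    start; day ``d`` (1-based) covers indices ``[(d-1)*1440, d*1440)``.
    """

    drive_mv: np.ndarray
    asleep: np.ndarray
    forced_wake: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.asleep & self.forced_wake):
            raise ValueError("asleep flag set inside a forced-wake interval")

    @property
    def n_days(self) -> int:
        return len(self.drive_mv) // MINUTES_PER_DAY

    def day_slice(self, day: int) -> slice:
        if not 1 <= day <= self.n_days:
            raise IndexError(f"day {day} outside horizon of {self.n_days} days")
        return slice((day - 1) * MINUTES_PER_DAY, day * MINUTES_PER_DAY)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": np.arange(len(self.drive_mv)),
                "drive_mV": self.drive_mv,
                "asleep": self.asleep,
                "forced_wake": self.forced_wake,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@njit(cache=False)
def _simulate_kernel(state, forced, d0, tau_c, p, start_clock, n_min):  # pragma: no cover
    B = state.shape[0]
    drive = np.empty((B, n_min))
    asleep = np.empty((B, n_min), dtype=np.uint8)

    theta = p[0]
    sigma = p[1]
    a_m = p[2]
    g_vm = p[3]
    g_mv = p[4]
    tau_pop = p[5]
    mu = p[6]
    chi = p[7]
    nu_h = p[8]
    amp = p[9]
    light_gain = p[10]
    light_k = p[11]
    gamma = p[12]
    dawn = p[13]
    dusk = p[14]
    effort = p[15]
    dt = p[16]
    cphi = np.cos(p[17])
    sphi = np.sin(p[17])
    quad = p[18]

    omega = np.pi / 720.0
    nsub = int(round(1.0 / dt))
    h = 1.0 / nsub

    for b in range(B):
        vv = state[b, 0]
        vm = state[b, 1]
        hh = state[b, 2]
        x = state[b, 3]
        xc = state[b, 4]
        omsq = (24.0 / (0.99669 * tau_c[b])) ** 2
        for m in range(n_min):
            clock = (start_clock + m) % MINUTES_PER_DAY
            daylight = dawn <= clock < dusk
            is_forced = forced[b, m]
            c = -(x * cphi - xc * sphi)
            drive[b, m] = nu_h * hh + amp * c + quad * (c * c - 0.5) + d0[b]
            asleep[b, m] = 1 if (vv > theta and not is_forced) else 0
            for _ in range(nsub):
                # RK4 on (vv, vm, hh, x, xc)
                k1 = _deriv(
                    vv, vm, hh, x, xc, theta, sigma, a_m, g_vm, g_mv, tau_pop,
                    mu, chi, nu_h, amp, quad, d0[b], light_gain, light_k, gamma,
                    omsq, omega, daylight, is_forced, effort, cphi, sphi,
                )
                k2 = _deriv(
                    vv + 0.5 * h * k1[0], vm + 0.5 * h * k1[1], hh + 0.5 * h * k1[2],
                    x + 0.5 * h * k1[3], xc + 0.5 * h * k1[4],
                    theta, sigma, a_m, g_vm, g_mv, tau_pop,
                    mu, chi, nu_h, amp, quad, d0[b], light_gain, light_k, gamma,
                    omsq, omega, daylight, is_forced, effort, cphi, sphi,
                )
                k3 = _deriv(
                    vv + 0.5 * h * k2[0], vm + 0.5 * h * k2[1], hh + 0.5 * h * k2[2],
                    x + 0.5 * h * k2[3], xc + 0.5 * h * k2[4],
                    theta, sigma, a_m, g_vm, g_mv, tau_pop,
                    mu, chi, nu_h, amp, quad, d0[b], light_gain, light_k, gamma,
                    omsq, omega, daylight, is_forced, effort, cphi, sphi,
                )
                k4 = _deriv(
                    vv + h * k3[0], vm + h * k3[1], hh + h * k3[2],
                    x + h * k3[3], xc + h * k3[4],
                    theta, sigma, a_m, g_vm, g_mv, tau_pop,
                    mu, chi, nu_h, amp, quad, d0[b], light_gain, light_k, gamma,
                    omsq, omega, daylight, is_forced, effort, cphi, sphi,
                )
                vv += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                vm += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                hh += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
                x += h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
                xc += h / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        state[b, 0] = vv
        state[b, 1] = vm
        state[b, 2] = hh
        state[b, 3] = x
        state[b, 4] = xc
    return drive, asleep


@njit(cache=False, inline="always")
def _deriv(
    vv, vm, hh, x, xc, theta, sigma, a_m, g_vm, g_mv, tau_pop,
    mu, chi, nu_h, amp, quad, d0, light_gain, light_k, gamma,
    omsq, omega, daylight, is_forced, effort, cphi, sphi,
):  # pragma: no cover
    qv = 1.0 / (1.0 + np.exp(-(vv - theta) / sigma))
    qm = 1.0 / (1.0 + np.exp(-(vm - theta) / sigma))
    awake = is_forced or vv <= theta
    light = light_gain * (1.0 - 0.4 * x) * (1.0 - 0.4 * xc) if (daylight and awake) else 0.0
    c = -(x * cphi - xc * sphi)
    d_total = nu_h * hh + amp * c + quad * (c * c - 0.5) + d0
    vv_in = d_total - g_vm * qm - (effort if is_forced else 0.0)
    dvv = (-vv + vv_in) / tau_pop
    dvm = (-vm + a_m - g_mv * qv) / tau_pop
    dhh = (-hh + mu * qm) / chi
    dx = omega * (xc + light)
    dxc = omega * (gamma * (xc - 4.0 / 3.0 * xc**3) - x * (omsq + light_k * light))
    return dvv, dvm, dhh, dx, dxc


def _run_kernel(states, forced, d0, tau_c, params, start_clock=0):
    drive, asleep = _simulate_kernel(
        states, forced, d0, tau_c, params.kernel_array(), start_clock, forced.shape[1]
    )
    if not np.all(np.isfinite(drive)):
        bad = np.argwhere(~np.isfinite(drive))
        raise SimulationError(
            f"integrator diverged at minute {int(bad[0][1])} (batch row {int(bad[0][0])})"
        )
    return drive, asleep


def simulate_batch(
    states: np.ndarray,
    forced: np.ndarray,
    d0: np.ndarray,
    tau_c: np.ndarray,
    params: ModelParameters = DEFAULT_PARAMETERS,
):
    """Simulate a batch of individuals over a shared minute grid.

    ``states`` is (B, 5) and is advanced in place; ``forced`` is a (B, M)
    boolean mask of forced wakefulness; ``d0``/``tau_c`` are per-row profile
    parameters. Returns ``(drive, asleep)`` arrays of shape (B, M).
    """
    states = np.ascontiguousarray(states, dtype=np.float64)
    forced = np.ascontiguousarray(forced, dtype=np.bool_)
    return _run_kernel(
        states,
        forced,
        np.asarray(d0, dtype=np.float64),
        np.asarray(tau_c, dtype=np.float64),
        params,
    )


def simulate(
    state: PhysiologicalState,
    wake: ForcedWakeSchedule,
    params: ModelParameters,
    horizon_days: int,
    *,
    d0: float,
    tau_c: float,
) -> FatigueTrajectory:
    """Simulate ``horizon_days`` from ``state`` under a forced-wake schedule."""
    n_min = horizon_days * MINUTES_PER_DAY
    if wake.intervals and wake.end > n_min:
        raise ValueError(
            f"horizon of {horizon_days} days ends before the last forced-wake "
            f"interval (minute {wake.end})"
        )
    forced = np.asarray(wake.mask(n_min), dtype=np.bool_)[None, :]
    drive, asleep = simulate_batch(
        state.as_array()[None, :], forced, np.array([d0]), np.array([tau_c]), params
    )
    return FatigueTrajectory(
        drive_mv=drive[0], asleep=asleep[0].astype(bool), forced_wake=forced[0]
    )


_RESTED_CACHE: dict[tuple, PhysiologicalState] = {}


def rested_initial_state(
    d0: float,
    tau_c: float,
    params: ModelParameters = DEFAULT_PARAMETERS,
    *,
    profile_name: str = "",
) -> PhysiologicalState:
    """State of a well-rested individual at midnight.

    The unforced model is run until the full state vector at successive
    midnights differs by less than ``params.burn_in_tol`` (at least
    ``burn_in_days``, at most ``max_burn_in_days`` days), i.e. until the
    circadian rhythm is entrained and sleep timing is periodic.
    """
    key = (params.fingerprint(), float(d0), float(tau_c))
    if key in _RESTED_CACHE:
        return _RESTED_CACHE[key]

    # start awake near the expected entrained phase (x minimal early morning)
    state = np.array([[-4.0, params.wake_drive, params.somnogen_gain / 2.0, -0.26, -0.97]])
    forced = np.zeros((1, MINUTES_PER_DAY), dtype=np.bool_)
    d0a = np.array([float(d0)])
    tca = np.array([float(tau_c)])
    prev = state.copy()
    for day in range(1, params.max_burn_in_days + 1):
        _run_kernel(state, forced, d0a, tca, params)
        diff = float(np.max(np.abs(state - prev)))
        if day >= params.burn_in_days and diff < params.burn_in_tol:
            result = PhysiologicalState(tuple(float(v) for v in state[0]))
            _RESTED_CACHE[key] = result
            return result
        prev = state.copy()
    label = profile_name or f"(D0={d0}, tau_c={tau_c})"
    raise ConvergenceError(
        f"no periodic rested orbit for profile {label} within "
        f"{params.max_burn_in_days} days (last midnight drift {diff:.2e})"
    )


def daily_max_fatigue(trajectory: FatigueTrajectory, day: int) -> float:
    """Highest sleep drive during the 24 hours of 1-based ``day``."""
    return float(np.max(trajectory.drive_mv[trajectory.day_slice(day)]))


def sleep_duration_stats(trajectory: FatigueTrajectory) -> np.ndarray:
    """Minutes asleep per calendar day of the trajectory."""
    n = trajectory.n_days
    return trajectory.asleep[: n * MINUTES_PER_DAY].reshape(n, MINUTES_PER_DAY).sum(axis=1)
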