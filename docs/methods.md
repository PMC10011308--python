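# Methods

## Problem

A ward must staff three fixed shifts every day — day (07:00–15:00),
evening (14:30–22:30) and night (22:00–07:30 next day) — over a planning
horizon, subject to the usual fatigue-risk scheduling rules (coverage,
no backward rotation, limits on consecutive nights/work days/weekends,
hour bounds, guaranteed two-day rests). Beyond these rules, the package
models the *physiology* of each nurse and minimises the single highest
sleep drive any nurse experiences on any day: the global maximum
fatigue (GMF, in mV). Minimising a maximum is a deliberate equity
choice — the roster is only as good as its most exhausted nurse-day.

## Sleep-drive model

The simulator couples three standard ingredients of biomathematical
fatigue modelling:

* **Sleep/wake switch.** Two mutually inhibitory neural populations
  (wake-active `Vm`, sleep-active `Vv`) with sigmoidal firing rates
  `Q(V) = 1/(1+exp(-(V-θ)/σ))`. Mutual inhibition makes the system
  bistable: consolidated wake and sleep states with hysteresis.
* **Homeostat.** A somnogen `H` produced in proportion to wake-active
  firing and cleared first-order (`χ Ḣ = -H + μ Qm`), i.e. sleep
  pressure grows while awake and dissipates during sleep.
* **Circadian oscillator.** A van der Pol limit cycle `(x, xc)` driven
  by environmental light, available between dawn (06:00) and dusk
  (18:00) while the individual is awake. Its intrinsic period `tau_c`
  is the chronotype parameter; light entrains it to 24 h with a phase
  that depends on `tau_c`.

The reported fatigue is the total sleep drive

```
D(t) = nu_h * H(t) + C(x, xc) + D0        [mV]
```

where `C = a*c + b*(c² - ½)` with `c` the (phase-rotated, negated)
circadian state: the linear term gives the familiar ~24 h oscillation
and the small quadratic harmonic makes the pre-dawn peak sharper than
the afternoon trough, as observed in circadian alertness data. `D0` is
a constant offset and the sleep-time parameter.

Work enters the model solely as **forced wakefulness**: during a shift
plus a 45-minute commute on each side, the sleep-active population is
clamped to the wake branch by a strong inhibitory "wake effort" input
while the homeostat keeps accumulating. Night shifts belong to the day
they start on and force wakefulness past midnight into the next day.

**Integration.** Fixed-step RK4 at 0.25 min on a 1-minute output grid.
This makes trajectories bit-reproducible and lets the whole table/FRE
machinery be exact rather than tolerance-laden; population time
constants are set to 1 min (fast relative to every process of interest,
slow enough for the step size). The batched kernel is numba-compiled
and simulates hundreds of scenarios simultaneously, which is what makes
exhaustive pattern tabulation cheap.

**Rested initial state.** The unforced model is run from a canonical
state until the full state vector at successive midnights moves by less
than 1e-6 (at least 30, at most 200 days); this is "a well-rested
individual with an entrained rhythm". Rested states are cached per
(parameter fingerprint, profile).

## Calibration

The model's structure is fixed; its constants were calibrated once,
before any roster experiments, to the stated anchors and then frozen in
`ModelParameters`:

* rested sleep ≈ 7 h for the normal sleep-time class, ≈ 5 h and ≈ 9 h
  for the short/long classes (all within ±0.2 h as shipped), achieved
  by the `D0` offsets −2.518 / 0 / +2.473 mV;
* rested sleep onset near 23:50 and wake near 06:50 for the day-type
  chronotype; intrinsic periods 23.55 / 24.15 / 24.72 h shift the
  entrained sleep midpoint by roughly ∓1 h for morning/evening types;
* the drive stays within about [−2, +4] mV at rest and saturates below
  8 mV under sustained night work;
* consecutive night shifts raise later-day maxima sharply (the worst
  feasible 4-day windows are the three-night blocks, ≈ 6.8–7.0 mV for
  profile 1), and short sleepers tolerate nights better than long
  sleepers.

Calibrated values live in code, versioned and fingerprinted; a lookup
table records the fingerprint of the parameters it was built under and
refuses to load against different ones.

## Rolling-horizon lookup table

Fatigue on day `t` is approximated by the *evaluation pattern*: the
4-day shift window ending at `t` plus a flag for a night shift on the
day before the window (that night forces wakefulness into the window).
All `2·4⁴ = 512` patterns per profile are simulated once from the
rested state — off-days assumed before the window; the night-before
state realised by literally prepending one night shift, which is
equivalent to storing a second initial state and simpler — and the
scored value is the last pattern day's 24 h maximum drive. The table is
*total*: rule-violating patterns are tabulated too, so a lookup can
never miss (the solver's constraints simply make them unreachable).

RHE (rolling-horizon evaluation) reads each day from the table; FRE
(full roster evaluation) simulates the entire roster in one run. Inside
the first horizon the two coincide by construction (bar the sub-µV
burn-in residual). Differences of less than 0.10 mV between them are
treated as irrelevant throughout. Approximation error is quantified as
percentiles of `FRE − RHE` pooled over roster-days, discarding the
first 7 days of each roster.

## Roster model and subproblem solver

Hard constraints follow the common fatigue-risk rule set, with day 1 a
Monday (Sundays are the days `t mod 7 = 0`) and days ≤ 0 treated as
off. Hours accounting uses 8.5 paid hours for every work shift; clock
times drive physiology only. Defaults for the 42-day ward: coverage
(7, 5, 5), ≤ 3 consecutive nights, ≤ 5 consecutive work days, total
hours in [170, 221], ≤ 42.5 weekly hours, ≤ 2 consecutive working
weekends, a two-consecutive-days-off rest at least once every 13 days.
All of these are per-instance configurable; the instance constructor
rejects parameterisations that fail a necessary staffing condition.
The validator is implemented as plain loops, deliberately independent
of the solver encoding, and serves as the solver's oracle in the tests.

Subproblems (a free cell set, everything else fixed to the incumbent)
are solved with HiGHS mixed-integer programming via
`scipy.optimize.milp` over one-hot shift variables. The nonlinear
fatigue objective is linearised through the lookup table:

* **min-GMF** is a *threshold search*: for a bound `B`, every pattern
  whose table value exceeds `B` becomes a linear no-good over its
  window cells, and the model is solved for feasibility. The bound
  gallops down the table's distinct values — feasible solves are cheap
  and usually undershoot their bound, infeasible ones are expensive, so
  the search starts just below the incumbent GMF, grows its step after
  each success and retreats halfway on failure. With enough probes this
  reaches the neighbourhood optimum (verified against exhaustive
  enumeration at toy scale); under a time budget it is best-found.
* **min-occurrences** forbids values above the incumbent GMF and
  minimises binary indicators forced to 1 when a pattern *at* the GMF
  is matched.

Because the table is total and the solver reasons in exactly its
values, solver-internal scores equal an `rhe_evaluate` recomputation on
the returned roster value-for-value; score equality uses a 1e-9 mV
tolerance (table precision), unrelated to the 0.10 mV relevance
threshold.

## Large neighbourhood search

Iterations free: the full rows of all nurses attaining the GMF (capped
at `n_F = 3` random ones in occurrence mode), `n_R = 2` random other
nurses, and every off-shift cell of the incumbent. Candidates are
accepted iff lexicographically better in (GMF, occurrences of the
GMF); the search stops after 20 iterations without acceptance
(configurable). Occurrence minimisation is selected when the incumbent
GMF occurs more than 3 times or after 5 consecutive failed iterations;
the thresholds are design defaults, logged with every run. Table values
are discrete, so the search spends long stretches on plateaus where
only the occurrence count falls — that is expected behaviour, not
stagnation. All randomness flows from one seed; HiGHS is deterministic,
so runs with equal seeds produce identical logs.

## Post-processing with extras

After the search, a full simulation may reveal a true GMF above the
approximated one (the approximation can miss knock-on effects such as a
pre-shift nap present in one evaluation but not the other). If the gap
reaches 0.10 mV, single shifts are handed to casual "extras": the GMF
nurse's latest work shift on a day strictly before the peak day is
replaced by an off-shift (the peak day's own shift if no earlier one
exists — the stricter "last work day prior" reading of the two natural
conventions), the substituted shift still counts toward coverage, and
the peak is relocated globally after each substitution. The budget is
six shifts (one per week of the default horizon). Removing shifts can
undercut the minimum-hours floor; exactly that floor is waived for
repaired rosters (weekly caps and all other rules still hold). Extras
are annotations on the roster, never synthetic nurses, so no fatigue is
attributed to them.

## Synthetic instances

Profiles are drawn independently (10/80/10 % short/normal/long sleep;
10/80/10 % morning/day/evening chronotype), giving the common profile
1 probability 0.64. The default ward is 30 nurses × 42 days with
coverage (7, 5, 5) — each nurse must average at least 9.8 day, 7
evening and 7 night shifts. Staffing experiments append profile-1
nurses; biotype experiments use homogeneous wards. Two anonymised real
42-day rosters are embedded as checksummed constants for error
analysis; synthetic rosters for that analysis are random work/rest
blocks (1–4 work days of one shift type, 1–3 off days), which emulates
real rosters' block structure but not their full rule-feasibility —
deliberate, since error analysis should include tough rosters.

What the generator does *not* emulate: part-time contracts and skill
mix, preference/soft constraints, season- or weather-dependent light
exposure, naps driven by social factors. Passing tests therefore show
the machinery is correct under the stated physiology, not that the
specific mV values transfer to any real ward.

## Problem sizes and numerical choices

The shipped tests exercise toy (6×14) and mid (12×14) instances and a
single-profile table; the acceptance script builds the full nine-profile
table, runs a 30-roster × 9-profile error pool (9450 retained
roster-days) and one full 30×42 pipeline with a 45-iteration search
cap. Those sizes keep a complete from-scratch run in the minutes range
on one core; all of them are configuration, not structure — the same
code runs larger searches by raising the stall limit and per-solve time
budget. Degenerate inputs are rejected loudly (unknown shift codes with
the offending day, stale lookup tables, non-convergent burn-ins naming
the profile, infeasible instances at construction time). Fatigue ties
in the argmax are broken in (nurse, day) order; GMF-nurse ties in the
neighbourhood builder by seeded shuffle.

## Known limitations

* The physiology is a calibrated reference implementation of the
  standard switch + homeostat + pacemaker structure; its constants are
  this package's own, so absolute mV values are comparable only within
  the package (orderings and contrasts, not decimals, are the portable
  content).
* The min-GMF step is exact only when given enough probes; under tight
  time budgets the LNS compensates by iterating.
* The solver backend is a single MILP; the occurrence-mode indicator
  relaxation is exact but can be slow on large plateaus with many
  critical patterns.
* Extras repair is the simple shift-removal strategy; re-optimisation
  after repair is out of scope.
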