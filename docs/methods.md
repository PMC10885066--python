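# Methods

## Model

Two relaxation regulators ("somnostats") with identical kinetics operate
at nested time scales.

**Process S (circadian somnostat).**  During wake, S builds up toward an
upper asymptote; during sleep it relaxes downward:

- wake:  S(t) = S_u − (S_u − S_entry)·e^(−(t−t₀)/T_b)
- sleep: S(t) = S_l + (S_entry − S_l)·e^(−(t−t₀)/T_d)

where t₀ is the phase onset and S_entry the value of S there.  Writing
the phases in terms of the entry value (rather than the fixed constants
S_b/S_d) keeps multi-day protocols with arbitrary wake durations
continuous; with the habitual timing the two coincide.  Note the sign of
the decay: some printed forms of the sleep-phase equation
(asymptote − (start − asymptote)·e^(−Δt/T)) violate the boundary
condition that the decay departs from its entry value; we use
asymptote + (start − asymptote)·e^(−Δt/T), which satisfies continuity and
reduces to the classical two-process discharge.  Numerically both phases
are evaluated with `expm1` so the entry value is reproduced exactly at
Δt = 0.

**Circadian modulation.**  C(t) = A·sin(2πt/τ + φ₀) with
φ₀ = π/2 − 2π·φ_max/τ, so the maximum A falls at clock hour φ_max.  The
modulated process adds C(t) to the asymptote and subtracts k·C(t) from
the result; with A = 0 (the default, and the fitted value) it reduces to
the unmodulated kinetics to machine precision.  The literal modulated
formula is discontinuous at phase onsets when A ≠ 0 (the value at zero
elapsed time is entry − k·C(t₀)); we implement it literally and keep
A = 0 in all default protocols.

**Process s (ultradian somnostat) and the nesting.**  Within sleep, s
restarts at its lower threshold s_b at every sleep onset (naps included)
and alternates NREM buildups with REM decays:

- NREM: s(t) = s_u(t) − (s_u(t) − s_entry)·e^(−Δt/t_b)
- REM:  s(t) = s_l + (s_entry − s_l)·e^(−Δt/t_d)

The NREM asymptote is the *moving* setpoint — Process S itself:

s_u(t) = s_u + (S_onset − s_u)·e^(−c(t)/T_set)

with S_onset the value of S at the episode's onset and c(t) the setpoint
clock.  By default c advances only during NREM (the setpoint is frozen
during REM); an elapsed-sleep-time clock is available.  After the NREM
phase of the fourth cycle (configurable `freeze_after_cycle`) the
setpoint is held constant for the rest of the episode, so the final
cycle's NREM buildup is a single exponential.  During sleep the reported
S(t) *is* s_u(t) — they are one trace.  s is undefined (NaN) during wake;
the ultradian process exists only within sleep.

The NREM formula substitutes the moving asymptote into the closed form
(an algebraic superposition of two exponentials, as the model prescribes),
not the solution of an ODE with time-varying input; the distinction
matters for any comparison integrator.

## Parameters (defaults = the fitted all-night column)

| symbol | meaning | default | units |
|---|---|---|---|
| S_u / S_l | wake/sleep asymptotes of S | 1.41 / 0.20 | indicator |
| S_d / S_b | upper/lower thresholds of S | 1.10 / 0.22 | indicator |
| T_b / T_d | S buildup / decay time constants | 12.01 / 1.40 | h |
| s_u / s_l | setpoint baseline / REM asymptote | 0.70 / −0.34 | indicator |
| s_d / s_b | NREM→REM and REM→NREM thresholds | 0.22 / −0.30 | indicator |
| t_b / t_d | s buildup / decay time constants | 0.22 / 0.36 | h |
| T_set | setpoint relaxation time constant | 1.40 | h |
| A, τ, φ_max, k | circadian amplitude, period, peak hour, impact | 0, 24, 0, 2 | —, h, h, — |
| t₁ / t₂ | habitual sleep offset / onset | 7.00 / 23.00 | clock h |

The nap-study column differs only in the morning initial value
(S_b = 0.23 at t₁ = 6.00).  T_set defaults to T_d: the printed setpoint
equation carries the wake time constant (12.01 h), which cannot bring the
setpoint near its baseline within the ~3 h of cumulative NREM the model
requires by the fourth cycle; the sleep-decay constant can.

All times are decimal clock hours on a continuous axis (day d, hour h →
24·d + h); two-day protocols simply run past 24.

## Protocols

- **All-night** (`build_allnight_schedule`): wake 7.00→23.00, then five
  90-min cycles whose REM episodes lengthen 10/15/20/25/30 min (NREM
  80/75/70/65/60).  The lengthening-REM architecture is the textbook
  pattern of adult sleep and the pattern the model itself predicts for
  the growth of the below-zero interval; a flat-REM night is available by
  passing scalars.
- **12-nap protocols** (`build_nap_schedule`): SD — continuous wake from
  7.00, then 20-min naps at every even hour from 6:00 of day 1; SR — wake
  to 23.00, sleep restricted to 23.00–6.00, naps at every odd hour from
  7:00.  Naps default to all-NREM (`nrem_fraction_of_nap = 1`).  The SR
  morning restarts S at the fitted value 0.23 (a `Schedule.s_resets`
  entry): the sleep-phase dynamics of S describe setpoint relaxation
  toward 0.70, not the overnight homeostatic discharge to morning levels,
  so the morning value is an independent fitted initial condition — this
  is the one deliberate discontinuity in any default protocol.  Because
  SR naps then start below the setpoint baseline, the setpoint relaxation
  is applied from either side during protocol simulation (the standalone
  `setpoint_trace` keeps the above-baseline precondition).

Schedules are contiguous half-open intervals [start, end); a switch
falling exactly on a boundary belongs to the earlier interval.  In
**scheduled** mode the NREM/REM boundaries are imposed and the
thresholds s_b/s_d are ignored (pure continuity); in **relay** mode sleep
is a window and the boundaries emerge from the thresholds, as in the
thermostat.  Both are exposed because the empirical figures could have
been produced either way; with the fitted thresholds, relay mode yields
~67-min cycles dominated by REM (~57 min), shorter than the ~90-min
cycles the schedule mode imposes — a known tension of the parameter set.

## Numerics

- Trajectories are piecewise closed forms compiled per segment; sampling
  (default dt = 1 min, typical spectral-EEG epoching) and evaluation at
  arbitrary times are separate steps, so fitting never interpolates.
- Relay switch times: REM→NREM and frozen-setpoint NREM→REM crossings use
  the exact log inversion; NREM crossings under a decaying setpoint have
  no closed form and are bracketed on a fine scan then polished with
  Brent's method (xtol 1e−13 h).  Switching never depends on the
  reporting grid; boundary continuity of S, s_u and s is exact to <1e−9
  (tested), and the thermostat's simulated period matches the closed form
  T_h·ln((A_h−L)/(A_h−U)) + T_c·ln((U−A_c)/(L−A_c)) to 1e−9.
- An NREM phase whose threshold s_d is not below the current setpoint
  raises an unreachable-threshold error; a threshold merely unreached
  within the window simply runs the phase to the window end.

## Fitting

`fit` minimises Σ(observed − s(t))² over sleep epochs (optionally adding
S(t) residuals over wake epochs) with bounded trust-region least squares
from seeded Sobol multi-starts; the best of n_starts is kept, so the
objective is non-increasing in the number of starts and the result is
deterministic given (data, bounds, n_starts, seed).  Epoch order is
irrelevant.  The schedule is treated as known; boundary estimation is out
of scope.  `recovery_experiment` wraps simulate → noise → fit and reports
bias, RMSE and median absolute relative error per parameter; with one
synthetic night at σ = 0.02 the trio {t_b, t_d, T_set} is recovered with
median error well under 10%.

## Synthetic data

`generate_indicator` adds i.i.d. Gaussian epoch noise (default
σ = 0.02) to the noiseless trajectory on sleep epochs — homoscedastic and
epoch-independent, the simplest contract consistent with what is known;
real spectral-EEG indicators are heteroscedastic and autocorrelated, so a
green recovery test establishes identifiability under the stated noise
model, not under real recording noise.  The SWA-like variant applies an
affine map (default a = 1, b = 3) so values sit on a positive ln-power
scale.  `generate_hypnogram` labels epochs {W, NREM, REM} at epoch
midpoints.  On the noiseless default night the NREM-epoch median of the
indicator is positive and exceeds the REM-epoch median, and REM values
reach below zero by the last cycle; REM *medians* are not negative under
this schedule (the fitted REM decay is slow relative to 10–25 min REM
episodes), so the empirical sign convention for REM holds as an ordering,
not as a median sign.

## Known limitations

- The ~90-min scheduled cycles and the threshold-driven (relay) cycles
  are mutually inconsistent under the fitted thresholds (see above); the
  below-zero-interval growth is therefore tested on the relay episode,
  where it is an analytic consequence of the setpoint decay.
- Circadian modulation with A ≠ 0 introduces phase-onset discontinuities
  by construction of the literal formula; all defaults use A = 0.
- No N1/N2/N3 sub-staging, no stochastic dynamics, no neuronal-population
  mechanisms, no analysis of real polysomnographic recordings.
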