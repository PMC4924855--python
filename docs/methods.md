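# Methods

## The model

`addyn` simulates addictive behaviour as a discrete-time dynamical system
with a weekly time step (lifestyle is roughly week-periodic).  Two state
variables evolve:

* **craving** `C ∈ [0, 1]` — the desire to act out the behaviour;
* **effect of self-control** `S` — suppresses acting out; modelled as a
  finite resource that restores toward a ceiling `S⁺` and is depleted by
  craving and by the behaviour itself; may turn negative.

The **addiction vulnerability** aggregates the state with an external
parameter `E` (positive = societal protection, negative = peer pressure):

    V = min(1, max(0, C − S − E))

and weekly acting-out intensity (for alcohol: kg of pure alcohol per week)
is `A = q·V`, with `q` the maximal weekly consumption.  The updates are

    C(t+1) = C(t) + b·min(1, 1−C(t))·A(t) − d·C(t)
    S(t+1) = S(t) + p·max(0, S⁺ − S(t)) − h·C(t) − k·A(t)

Craving unlearns geometrically at rate `d` and grows with consumption at a
saturating rate (`b·min(1, 1−C)` — the closer craving is to its maximum,
the smaller the marginal impact of one more unit of consumption).  This
saturation is the model's only nonlinearity besides the clamps, and it is
what creates bistability.  Self-control restores proportionally to its
remaining headroom (`p` = psychological resilience) and is depleted
linearly by craving (`h`) and consumption (`k`).

Both `C(t+1)` and `S(t+1)` are evaluated **synchronously** from week-`t`
values.  Fixed points are identical under sequential evaluation; transients
differ only marginally (we measured < 1 point difference in the Monte Carlo
intervention success rate), so the symmetric convention is used.

### Cue forcing

Cues (social exposure, opportunity) arrive as a Poisson process with weekly
intensity `λ`; the weekly count `R ~ Poisson(λ)` adds `q/7` of consumption
per event — one-seventh of a maximal week per cue — capped so the total
never exceeds the weekly maximum:

    A(t) = q·V(t) + min(R·q/7, q·(1 − V(t)))

At full vulnerability cues add nothing (the person already consumes
maximally).  With `λ = 0` the stochastic system reduces *exactly* to the
deterministic one (a tested contract).

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `d` | 0.2 | /week | craving unlearns on a time scale of months |
| `q` | 0.8 | kg alcohol/week | an extremely high level: ~80 drinks/week |
| `b` | `2d/q` = 0.5 | /(kg/week) | half-maximal consumption holds craving stationary at `C = 1/2` |
| `p` | `2d` = 0.4 | /week | self-control restores faster than craving decays |
| `S⁺` | 0.5 | — | chosen so self-control can compete with craving on the same scale |
| `h` | `p·S⁺` = 0.2 | /week | craving-depletion balances half the maximal restoring force |
| `k` | `p·S⁺/q` = 0.25 | /(kg/week) | consumption-depletion balances the other half (`h/2 = kq/2 = pS⁺/2`) |

`default_params()` derives `b, p, h, k` from these identities at run time
rather than hard-coding them, so the calibration itself is testable.  All
quantities are dimensionless except `A` and `q`; units are documentation
only and never converted.

### Boundedness without clamping

No clamping is applied to `C` or `S`.  Instead the parameter container
enforces `b·q < 1`, under which `C ∈ [0, 1]` is a theorem:
`C' − 1 = (C − 1)(1 − bA) − dC ≤ 0` and `C' ≥ (1 − d)C ≥ 0`.  Silent
clamping would mask parameter-regime errors, so invalid sets are rejected
at construction.  Two further sharp bounds follow (used below):
`C(t) < bq/(d + bq) = 2/3` whenever `C(0) ≤ 2/3`, and
`S(t) ≥ S⁺ − (h·(2/3) + kq)/p = −1/3`, hence `V < 1 − E` along every
trajectory started at or below those levels.

## Equilibria and the branch diagram

The clamp splits the state space into three regimes, each linear, so all
fixed points are closed-form:

* **abstinent** `(0, S⁺)`, valid iff `E ≥ −S⁺`; Jacobian
  `[[1−d, 0], [−h, 1−p]]`, always stable where valid.
* **interior** (`0 < V < 1`): the linear S-balance
  `p(S⁺−S) = hC + kq(C−S−E)` gives `S(C)` (singular when `kq = p`, in
  which case the solver signals and the numeric oracle takes over;
  defaults give `kq − p = −0.2`), and the C-balance
  `bq(1−C)(C−S−E) = dC` becomes a quadratic — for the defaults
  `3C² − (3.5+2E)C + (1+2E) = 0`.  Roots are kept when `0 ≤ C < 1`,
  `0 < V < 1` and `S ≤ S⁺`.
* **saturated** (`V = 1`, `A = q`): `C* = bq/(d+bq)`,
  `S* = S⁺ − (hC* + kq)/p`, valid iff `C* − S* − E ≥ 1` (defaults:
  `(2/3, −1/3)`, valid for `E ≤ 0`).

Stability comes from the regime-specific 2×2 Jacobian (both eigen-moduli
`< 1 − 1e−9`).  Fixed points landing exactly on a regime boundary (`V = 0`
or `1`) are assigned to the clamped regime, flagged, and the interior-sided
linearization is reported alongside, because the map is continuous but not
differentiable there.

Sweeping `E` (default window `[−0.6, 0.35]`, slightly wider than the
bistable region so both branch endpoints are visible) yields the branch
diagram: an abstinent branch for `E ≥ −0.5`, an addicted branch (saturated
for `E ≤ 0`, interior for small `E > 0`) and the unstable saddle branch
between them.  The addicted/unstable pair merges at a **fold** located by
bisection on the interior quadratic's discriminant — exact rather than
eigenvalue tracking — at `E_fold = (10 − √96)/8 ≈ 0.02526` for the
defaults.  Count changes with no discriminant sign flip (the abstinent
endpoint at `E = −S⁺`) are refined by bisection on the count itself.

An independent numeric oracle (`brute_force_equilibria`: multi-start Newton
on the fixed-point residual with the analytic piecewise Jacobian, grid of
starts over `[0,1] × [−1.5, S⁺]`) cross-checks completeness of the
closed-form census; the suite verifies agreement on 200 random parameter
draws.  The domain stops at `S = S⁺`: above the ceiling the restoration
term vanishes and every `(0, S ≥ S⁺)` is trivially stationary — a
non-generic continuum that depletion-driven dynamics never enter.

## Scenarios

**Onset.**  From `(C, S) = (0, S⁺)` with `E` falling from 1 and `λ` rising
from 0.5.  The weekly decrements/increments are configurable; the defaults
(`dE = dλ = 0.01/week`, floors/ceilings `E_end = 0`, `λ_end = 1`) traverse
the fold within a ~3-year window.  The stationary end values decide the
outcome, so assertions about onset are qualitative (capture happens in some
runs; protective end states prevent it in all runs).

**Stationary / relapse.**  Fixed drivers.  Because the cue term is
one-sided (cues only add consumption), the relapse phenomenology is a
noise-driven alternation between the abstinent state and a cue-sustained
high-vulnerability state.  The `V < 1 − E` bound above caps the excursions:
at the scenario default `E = 0.1525` the ceiling is `0.8475`, and measured
excursions are rare (0/20 runs of 520 weeks reach `V > 0.8`); pronounced
two-sided switching — the majority of runs repeatedly visiting both
`V > 0.9` and `V < 0.1` — requires `E ≲ 0.1` at `λ = 1` (at `E = 0.05`:
20/20 runs).  The `relapse.py` example prints both regimes side by side.

**Intervention.**  Initial state = the stable addicted deterministic
equilibrium of the baseline environment (`S⁺ = 0.5, λ = 0.5, E = 0` →
`(2/3, −1/3)`); a stochastic burn-in would add variance without changing
the mean outcome, and the deterministic start is exactly reproducible.
Treatment occupies weeks `0..6` (duration 7); it doubles resilience
(`p = 0.8`) and halves cue intensity (`λ = 0.25`).  Under the treated
parameters no addicted equilibrium exists (the interior discriminant is
negative and the saturated clamp fails), so the deterministic part of the
treated flow always escapes; failures arise from cue noise afterwards.
Success is evaluated at the single week `t = 100`: `V(100) < 0.5`, with
exact equality (probability ~0) conservatively counted as failure.  The
Monte Carlo harness runs replicates on independent substreams seeded by
`(master_seed, replicate_index)` — any replicate is reproducible in
isolation — and reports the success rate with a 95% Wilson score interval
(well-behaved at small `n` and extreme rates).  With the default protocol
the measured success rate is ~93% (n = 2000), with failures being
post-treatment relapses; treatment-phase failures essentially never occur.

## What the generator does and does not emulate

The simulator *is* the study object here (there is no external data): cue
randomness is the only stochastic ingredient, aggregated to one Poisson
count per week.  Real cue streams are bursty and autocorrelated; weekly
Poisson aggregation makes high-cue weeks rarer than clustered reality, so
transition rates between the two states should be read as orders of
magnitude, not point predictions.  Sub-weekly dynamics (acts happen on a
time scale of hours), the latent self-control *capacity* and its slow
change over years, and personality covariates are all outside the model;
passing tests say nothing about them.

## Numerical choices

* Regime/boundary tolerance `1e−9`; coordinate deduplication `1e−9`;
  fixed-point residual requirement `1e−10`; fold bisection 60 halvings.
* Stability margin `1e−9` on the eigen-moduli.
* RNG: NumPy `Generator` (PCG64); substreams via `SeedSequence([master, r])`.
* Monte Carlo sizes: 50 replicates for the headline experiment (plus 2000
  for a tight interval), 500 for monotonicity properties — chosen so the
  binomial error is small against the effects being checked.
* Degenerate inputs: `kq = p` falls back to the numeric oracle; `dE = 0`
  or `dλ = 0` schedules are valid (constant drivers); `duration_weeks = 0`
  is a valid no-treatment control.

## Known limitations

* The equilibrium solvers assume the restoration branch `S ≤ S⁺`; the
  non-generic continuum of neutral points at `C = 0, S > S⁺` (reachable
  only by initialising above the ceiling) is deliberately not enumerated.
* With `h = k = 0` and `C = 0` the S-dynamics are restoration-only; the
  census handles this but the regime labels lose their behavioural
  interpretation.
* The fold refinement assumes a single count change per grid interval;
  grids coarser than the distance between the abstinent endpoint and the
  fold would merge them.
* The relapse and onset outcomes are sensitive to `E` near the fold (that
  is the point of the model); reported switching rates are specific to the
  weekly-Poisson cue idealisation.
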