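"""The three scenario experiments and the Monte Carlo harness.

* **Onset** — a lifestyle change: protection ``E`` decays from 1 while the
  cue intensity ``lam`` grows from 0.5; once ``E`` falls past the fold the
  addicted state exists and cue fluctuations can tip the system into it.
* **Stationary / relapse** — fixed drivers; near criticality (e.g.
  ``E = 0.1525, lam = 1``) the vulnerability alternates between near-0 and
  near-1 excursions: repeated relapse and recovery.
* **Therapeutic intervention** — starting from the addicted equilibrium, a
  7-week treatment doubles the resilience ``p`` and halves the cue
  intensity; success is a vulnerability below 0.5 at week 100.  A Monte
  Carlo batch estimates the success probability with a Wilson interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .cues import total_consumption
from .equilibria import all_equilibria
from .model import ModelParams, Trajectory, update_craving, update_selfcontrol

__all__ = [
    "OnsetSchedule",
    "InterventionProtocol",
    "MonteCarloSummary",
    "simulate",
    "run_onset",
    "run_stationary",
    "run_intervention",
    "monte_carlo_intervention",
]

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate(
    params: ModelParams,
    C0: float,
    S0: float,
    E,
    lam,
    T: int,
    seed=None,
    params_by_week: Sequence[ModelParams] | None = None,
) -> Trajectory:
    """Simulate ``T`` weeks (records t = 0 .. T-1) of the stochastic map.

    Each week: draw the cue count ``R ~ Poisson(lam(t))``, form the realized
    consumption ``A`` and vulnerability ``V`` from the current state, record
    the week, then update ``C`` and ``S`` synchronously from the week-t
    values.  ``E`` and ``lam`` may be scalars or length-``T`` arrays;
    ``params_by_week`` optionally overrides the parameter set per week
    (used by the intervention protocol).

    Bit-for-bit reproducible given the seed.
    """
    if T < 1:
        raise ValueError(f"horizon T must be >= 1, got {T}")
    if not 0.0 <= C0 <= 1.0:
        raise ValueError(f"initial craving C0 must lie in [0, 1], got {C0}")
    E_arr = np.broadcast_to(np.asarray(E, dtype=float), (T,))
    lam_arr = np.broadcast_to(np.asarray(lam, dtype=float), (T,))
    if np.any(lam_arr < 0):
        raise ValueError("cue intensity lam must be nonnegative")
    rng = _as_rng(seed)

    t_out = np.arange(T)
    C_out = np.empty(T)
    S_out = np.empty(T)
    R_out = np.empty(T, dtype=np.int64)
    A_out = np.empty(T)
    V_out = np.empty(T)
    C, S = float(C0), float(S0)
    for t in range(T):
        pars = params if params_by_week is None else params_by_week[t]
        R = int(rng.poisson(lam_arr[t]))
        A, V = total_consumption(C, S, float(E_arr[t]), R, pars)
        C_out[t], S_out[t], R_out[t], A_out[t], V_out[t] = C, S, R, A, V
        C, S = update_craving(C, A, pars), update_selfcontrol(S, C, A, pars)
    return Trajectory(
        t=t_out, C=C_out, S=S_out, E=E_arr.copy(), lam=lam_arr.copy(),
        R=R_out, A=A_out, V=V_out, seed=seed,
    )


@dataclass(frozen=True)
class OnsetSchedule:
    """Driver schedule for the lifestyle-change (onset) scenario.

    Protection starts high (``E0 = 1``) and decreases by ``dE`` per week to
    the floor ``E_end``; the cue intensity starts at ``lam0 = 0.5`` and
    grows by ``dlam`` per week to the ceiling ``lam_end``.  The stationary
    end values determine whether addiction can take hold.
    """

    E0: float = 1.0
    dE: float = 0.01
    E_end: float = 0.0
    lam0: float = 0.5
    dlam: float = 0.01
    lam_end: float = 1.0

    def __post_init__(self) -> None:
        if self.E_end > self.E0:
            raise ValueError("E_end must not exceed E0")
        if self.lam0 > self.lam_end:
            raise ValueError("lam0 must not exceed lam_end")
        if self.dE < 0 or self.dlam < 0:
            raise ValueError("dE and dlam must be nonnegative")
        if self.lam0 < 0:
            raise ValueError("lam0 must be nonnegative")

    def E_series(self, T: int) -> np.ndarray:
        return np.maximum(self.E_end, self.E0 - self.dE * np.arange(T))

    def lam_series(self, T: int) -> np.ndarray:
        return np.minimum(self.lam_end, self.lam0 + self.dlam * np.arange(T))


def run_onset(params: ModelParams, schedule: OnsetSchedule, T: int, seed=None) -> Trajectory:
    """Onset scenario: start abstinent at ``(C, S) = (0, S_plus)`` under the
    decaying-protection / growing-cue schedule."""
    return simulate(
        params, 0.0, params.S_plus, schedule.E_series(T), schedule.lam_series(T), T, seed=seed
    )


def run_stationary(params: ModelParams, E: float, lam: float, T: int, seed=None,
                   C0: float = 0.0, S0: float | None = None) -> Trajectory:
    """Fixed-driver simulation (the repeated-relapse regime)."""
    if S0 is None:
        S0 = params.S_plus
    return simulate(params, C0, S0, E, lam, T, seed=seed)


@dataclass(frozen=True)
class InterventionProtocol:
    """A resilience-boosting, cue-avoiding treatment and its evaluation.

    During ``duration_weeks`` (weeks 0 .. duration-1) the resilience is
    raised to ``p_treat`` and the cue intensity lowered to ``lam_treat``;
    afterwards the post-treatment environment (``baseline_*``) applies.
    Success means the vulnerability at ``eval_week`` is strictly below
    ``success_threshold``.
    """

    duration_weeks: int = 7
    p_treat: float = 0.8
    lam_treat: float = 0.25
    baseline_S_plus: float = 0.5
    baseline_lam: float = 0.5
    baseline_E: float = 0.0
    eval_week: int = 100
    success_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.duration_weeks < 0:
            raise ValueError("duration_weeks must be nonnegative")
        if not self.duration_weeks < self.eval_week:
            raise ValueError("duration_weeks must be smaller than eval_week")
        if not 0.0 < self.success_threshold < 1.0:
            raise ValueError("success_threshold must lie in (0, 1)")
        if self.lam_treat < 0 or self.baseline_lam < 0:
            raise ValueError("cue intensities must be nonnegative")


def _addicted_equilibrium(params: ModelParams, E: float):
    cands = [eq for eq in all_equilibria(params, E) if eq.stable and eq.C_star > 1e-9]
    if not cands:
        raise ValueError(
            "no stable addicted equilibrium exists under the baseline parameters "
            f"(E = {E}); nothing to treat"
        )
    return max(cands, key=lambda eq: eq.C_star)


def run_intervention(
    params: ModelParams, protocol: InterventionProtocol, seed=None
) -> tuple[bool, Trajectory]:
    """One treatment run from the addicted state; returns (success, trajectory).

    The initial state is the stable addicted *deterministic* equilibrium of
    the baseline environment (reproducible, and 'being addicted' by
    construction).  Cues stay stochastic throughout treatment and follow-up.
    """
    baseline = params.with_(S_plus=protocol.baseline_S_plus)
    treated = baseline.with_(p=protocol.p_treat)
    eq = _addicted_equilibrium(baseline, protocol.baseline_E)
    T = protocol.eval_week + 1
    params_by_week = [
        treated if t < protocol.duration_weeks else baseline for t in range(T)
    ]
    lam = np.where(
        np.arange(T) < protocol.duration_weeks, protocol.lam_treat, protocol.baseline_lam
    )
    traj = simulate(
        baseline, eq.C_star, eq.S_star, protocol.baseline_E, lam, T,
        seed=seed, params_by_week=params_by_week,
    )
    success = bool(traj.V[protocol.eval_week] < protocol.success_threshold)
    return success, traj


@dataclass(frozen=True)
class MonteCarloSummary:
    """Success-rate estimate over independent intervention replicates."""

    n_replicates: int
    n_success: int
    success_rate: float
    ci_low: float
    ci_high: float
    master_seed: int

    def __post_init__(self) -> None:
        assert self.n_success <= self.n_replicates
        assert self.ci_low - 1e-12 <= self.success_rate <= self.ci_high + 1e-12


def monte_carlo_intervention(
    params: ModelParams, protocol: InterventionProtocol, n: int, master_seed: int
) -> MonteCarloSummary:
    """Estimate the treatment success probability over ``n`` replicates.

    Replicate ``r`` runs on the independent substream seeded by
    ``(master_seed, r)``, so any single replicate is reproducible in
    isolation.  The 95% confidence interval is Wilson's score interval,
    which behaves well at small ``n`` and extreme rates.
    """
    if n < 1:
        raise ValueError(f"replicate count n must be >= 1, got {n}")
    successes = 0
    for r in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, r]))
        ok, _ = run_intervention(params, protocol, seed=rng)
        successes += ok
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return MonteCarloSummary(
        n_replicates=n, n_success=successes, success_rate=successes / n,
        ci_low=float(lo), ci_high=float(hi), master_seed=master_seed,
    )
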