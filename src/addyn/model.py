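"""Core state types and the deterministic one-week update rules.

The model describes addictive behaviour with two coupled state variables
updated once per week:

* craving ``C`` in [0, 1] — the desire to act out the behaviour,
* the effect of self-control ``S`` — suppresses acting out; may turn
  negative under depletion.

Acting-out intensity ``A`` (e.g. kg of pure alcohol per week) is proportional
to the *addiction vulnerability* ``V = min(1, max(0, C - S - E))``, where the
external parameter ``E`` captures societal protection (positive) or peer
pressure (negative).  The weekly updates are

    C(t+1) = C(t) + b * min(1, 1 - C(t)) * A(t) - d * C(t)
    S(t+1) = S(t) + p * max(0, S_plus - S(t)) - h * C(t) - k * A(t)

with unlearning rate ``d``, cue sensitivity ``b``, resilience ``p``, maximal
self-control effect ``S_plus``, and depletion coefficients ``h`` (per unit
craving) and ``k`` (per unit consumption).  Craving stays in [0, 1] without
any clamping provided ``b * q < 1``, which the parameter container enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "SystemState",
    "WeekRecord",
    "Trajectory",
    "default_params",
    "vulnerability",
    "deterministic_consumption",
    "update_craving",
    "update_selfcontrol",
    "step",
]


@dataclass(frozen=True)
class ModelParams:
    """The seven structural constants of the weekly map.

    Parameters
    ----------
    d : float
        Unlearning (craving decay) rate per week, in (0, 1).
    b : float
        Cue sensitivity: impact of one unit of consumption on craving.
    q : float
        Maximum consumption per week (kg pure alcohol/week for the
        alcohol instantiation).
    p : float
        Psychological resilience: weekly restoration rate of self-control
        toward its ceiling ``S_plus``.
    S_plus : float
        Maximum effect of self-control, on the same scale as craving.
    h : float
        Depletion of S per unit craving per week.
    k : float
        Depletion of S per unit consumption per week.

    Raises
    ------
    ValueError
        If a parameter is out of range, or if ``b * q >= 1`` (the condition
        ``b*q < 1`` guarantees craving remains in [0, 1] without clamping).
    """

    d: float
    b: float
    q: float
    p: float
    S_plus: float
    h: float
    k: float

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ValueError(f"d must lie in (0, 1), got d={self.d}")
        if self.p <= 0.0:
            raise ValueError(f"p must be positive, got p={self.p}")
        if self.q <= 0.0:
            raise ValueError(f"q must be positive, got q={self.q}")
        for name in ("b", "h", "k", "S_plus"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative, got {name}={getattr(self, name)}")
        if self.b * self.q >= 1.0:
            raise ValueError(
                f"boundedness of craving requires b*q < 1; got b*q = {self.b * self.q}"
            )

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


def default_params() -> ModelParams:
    """Default parameter set for the weekly alcohol-consumption instantiation.

    Only ``d = 0.2`` (craving unlearns on a time scale of months),
    ``q = 0.8`` kg/week (about 80 drinks) and ``S_plus = 0.5`` are chosen
    directly.  The rest follow from calibration identities:

    * ``b = 2d/q`` — half-maximal consumption ``A = q/2`` holds craving
      stationary at ``C = 1/2``;
    * ``p = 2d`` — self-control restores faster than craving decays;
    * ``h = p*S_plus`` and ``k = p*S_plus/q`` — at full depletion the
      craving- and consumption-depletion terms each balance half the
      maximal restoring force (``h/2 = k*q/2 = p*S_plus/2``).
    """
    d = 0.2
    q = 0.8
    S_plus = 0.5
    b = 2.0 * d / q
    p = 2.0 * d
    h = p * S_plus
    k = p * S_plus / q
    return ModelParams(d=d, b=b, q=q, p=p, S_plus=S_plus, h=h, k=k)


@dataclass(frozen=True)
class SystemState:
    """One week's state: time index, craving, self-control effect, drivers."""

    t: int
    C: float
    S: float
    E: float
    lam: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"week index t must be nonnegative, got {self.t}")
        if self.lam < 0:
            raise ValueError(f"cue intensity lam must be nonnegative, got {self.lam}")


class WeekRecord(NamedTuple):
    """State plus realized stochastic quantities for one week."""

    t: int
    C: float
    S: float
    E: float
    lam: float
    R: int
    A: float
    V: float


#: Column order shared by Trajectory frames and CSV output.
TRAJECTORY_COLUMNS = ["t", "C", "S", "E", "lambda", "R", "A", "V"]


@dataclass
class Trajectory:
    """Time-indexed simulation record; one row per simulated week.

    Week ``t`` stores the state *at the start* of week ``t`` together with
    the cue count ``R``, consumption ``A`` and vulnerability ``V`` realized
    during that week.  Bit-for-bit reproducible from (params, schedule, seed).
    """

    t: np.ndarray
    C: np.ndarray
    S: np.ndarray
    E: np.ndarray
    lam: np.ndarray
    R: np.ndarray
    A: np.ndarray
    V: np.ndarray
    seed: object = None

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[WeekRecord]:
        for i in range(len(self)):
            yield WeekRecord(
                int(self.t[i]), float(self.C[i]), float(self.S[i]), float(self.E[i]),
                float(self.lam[i]), int(self.R[i]), float(self.A[i]), float(self.V[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        """Return the trajectory as a DataFrame with the canonical columns."""
        return pd.DataFrame(
            {
                "t": self.t.astype(int),
                "C": self.C,
                "S": self.S,
                "E": self.E,
                "lambda": self.lam,
                "R": self.R.astype(int),
                "A": self.A,
                "V": self.V,
            }
        )


def vulnerability(C: float, S: float, E: float) -> float:
    """Addiction vulnerability ``V = min(1, max(0, C - S - E))``.

    Piecewise linear; weakly increasing in craving, weakly decreasing in
    self-control and in the external parameter.
    """
    return min(1.0, max(0.0, C - S - E))


def deterministic_consumption(V: float, q: float) -> float:
    """Deterministic weekly consumption ``A = q * V`` in [0, q]."""
    return q * V


def update_craving(C: float, A: float, params: ModelParams) -> float:
    """One-week craving update ``C + b*min(1, 1-C)*A - d*C``.

    For ``C`` in [0, 1], ``A`` in [0, q] and ``b*q < 1`` the result stays
    in [0, 1]; no clamping is applied (out-of-regime parameters are
    rejected at construction instead of silently masked).
    """
    return C + params.b * min(1.0, 1.0 - C) * A - params.d * C


def update_selfcontrol(S: float, C: float, A: float, params: ModelParams) -> float:
    """One-week self-control update ``S + p*max(0, S_plus - S) - h*C - k*A``.

    The restoration term vanishes once ``S`` is at or above its ceiling.
    """
    return S + params.p * max(0.0, params.S_plus - S) - params.h * C - params.k * A


def step(state: SystemState, A_total: float, params: ModelParams) -> SystemState:
    """Advance the state one week given the realized weekly consumption.

    Both ``C(t+1)`` and ``S(t+1)`` are evaluated synchronously from the
    week-``t`` values; the drivers ``E`` and ``lam`` are carried through
    unchanged (scenario code owns driver schedules).
    """
    if not 0.0 <= A_total <= params.q + 1e-12:
        raise ValueError(f"A_total must lie in [0, q={params.q}], got {A_total}")
    C_next = update_craving(state.C, A_total, params)
    S_next = update_selfcontrol(state.S, state.C, A_total, params)
    return SystemState(t=state.t + 1, C=C_next, S=S_next, E=state.E, lam=state.lam)
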