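"""Stochastic cue forcing of weekly consumption.

Cues (social exposure, opportunity) arrive as a Poisson process; the weekly
cue count ``R ~ Poisson(lam)`` adds ``q/7`` of consumption per event, capped
at ``q*(1 - V)`` so the weekly total never exceeds the maximum ``q``:

    A(t) = q*V(t) + min(R * q/7, q*(1 - V(t)))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, vulnerability

__all__ = ["CueModel", "sample_cue_count", "cue_contribution", "total_consumption"]


@dataclass(frozen=True)
class CueModel:
    """Poisson cue process at intensity ``lam`` (expected cues/week)."""

    lam: float
    q: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"cue intensity lam must be nonnegative, got {self.lam}")
        if self.q <= 0:
            raise ValueError(f"q must be positive, got {self.q}")

    @property
    def increment(self) -> float:
        """Consumption added per cue event: one-seventh of the weekly maximum."""
        return self.q / 7.0


def sample_cue_count(lam: float, rng: np.random.Generator) -> int:
    """Draw one weekly cue count ``R ~ Poisson(lam)``.

    Deterministic given the generator's stream position; ``lam = 0`` is the
    degenerate cue-free case (always 0).
    """
    if lam < 0:
        raise ValueError(f"cue intensity lam must be nonnegative, got {lam}")
    return int(rng.poisson(lam))


def cue_contribution(R: int, V: float, q: float) -> float:
    """Consumption added by ``R`` cue events, capped at ``q*(1 - V)``.

    Weakly increasing in ``R`` and weakly decreasing in ``V``; the cap keeps
    total weekly consumption at or below ``q``.
    """
    return min(R * q / 7.0, q * (1.0 - V))


def total_consumption(
    C: float, S: float, E: float, R: int, params: ModelParams
) -> tuple[float, float]:
    """Realized weekly consumption and vulnerability, ``(A, V)``.

    ``A = q*V + cue_contribution(R, V, q)`` is in [0, q] for every cue
    count; at full vulnerability (``V = 1``) cues add nothing.
    """
    V = vulnerability(C, S, E)
    A = params.q * V + cue_contribution(R, V, params.q)
    return A, V
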