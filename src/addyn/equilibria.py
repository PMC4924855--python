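"""Fixed points and branch structure of the deterministic (cue-free) map.

The piecewise-linear clamp in the vulnerability ``V = min(1, max(0, C-S-E))``
splits the state space into three regimes, each with its own closed-form
fixed-point condition:

* **abstinent** — ``V`` clamped at 0, so ``A = 0``: the fixed point is
  ``(C, S) = (0, S_plus)``, valid while ``E >= -S_plus``.
* **interior** — ``0 < V < 1``: eliminating ``S`` through the linear
  S-balance reduces the C-balance to a quadratic; zero, one or two roots.
* **saturated** — ``V`` clamped at 1, so ``A = q``: ``C* = b*q/(d + b*q)``
  independent of ``E``; valid while ``C* - S* - E >= 1``.

Stability is read off the regime-specific 2x2 Jacobian of the weekly map
(both eigenvalue moduli < 1).  Sweeping the external parameter ``E``
reconstructs the branch diagram: an abstinent branch, an addicted branch,
and an unstable branch between them where both stable states coexist
(hysteresis).  The addicted and unstable branches merge and vanish at a
fold bifurcation, located exactly from the interior quadratic's
discriminant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, SystemState, step, vulnerability

__all__ = [
    "Equilibrium",
    "BranchDiagram",
    "DegenerateParameterError",
    "abstinent_equilibrium",
    "interior_equilibria",
    "saturated_equilibrium",
    "all_equilibria",
    "jacobian",
    "jacobian_and_stability",
    "sweep_branches",
    "brute_force_equilibria",
]

#: Tolerance for regime-boundary detection and coordinate deduplication.
_BOUNDARY_TOL = 1e-9
#: Stability margin: stable iff both eigen-moduli < 1 - _STAB_TOL.
_STAB_TOL = 1e-9


class DegenerateParameterError(ValueError):
    """Raised when ``k*q == p`` makes the interior S-elimination singular."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the deterministic weekly map at external parameter E."""

    E: float
    C_star: float
    S_star: float
    regime: str  # "abstinent" | "interior" | "saturated"
    eigen_moduli: tuple[float, float]
    stable: bool
    boundary: bool = False
    #: One-sided interior linearization when the point sits exactly on a
    #: regime boundary (V = 0 or V = 1); None elsewhere.
    eigen_moduli_interior_side: tuple[float, float] | None = None

    @property
    def V_star(self) -> float:
        return vulnerability(self.C_star, self.S_star, self.E)

    def residual(self, params: ModelParams) -> float:
        """Sup-norm of step(x) - x with the self-consistent A = q*V."""
        A = params.q * self.V_star
        state = SystemState(t=0, C=self.C_star, S=self.S_star, E=self.E, lam=0.0)
        nxt = step(state, A, params)
        return max(abs(nxt.C - self.C_star), abs(nxt.S - self.S_star))


def _classify(moduli: np.ndarray) -> tuple[tuple[float, float], bool]:
    m = tuple(sorted((float(moduli[0]), float(moduli[1])), reverse=True))
    return m, bool(m[0] < 1.0 - _STAB_TOL)


def jacobian(params: ModelParams, C: float, S: float, E: float, regime: str) -> np.ndarray:
    """Jacobian of the one-week map in the given regime's linear branch.

    The min/max terms are differentiated along the branch the regime
    selects; ``min(1, 1-C) = 1-C`` throughout since ``C <= 1``.
    """
    d, b, q, p, h, k = params.d, params.b, params.q, params.p, params.h, params.k
    if regime == "abstinent":
        # A clamped at 0; restoration branch active (approach from S < S_plus).
        return np.array([[1.0 - d, 0.0], [-h, 1.0 - p]])
    if regime == "saturated":
        # A clamped at q: constant, so no V-coupling.
        return np.array([[1.0 - b * q - d, 0.0], [-h, 1.0 - p]])
    if regime == "interior":
        V = C - S - E
        j11 = 1.0 - d - b * q * V + b * q * (1.0 - C)
        j12 = -b * q * (1.0 - C)
        j21 = -h - k * q
        j22 = 1.0 - p + k * q
        return np.array([[j11, j12], [j21, j22]])
    raise ValueError(f"unknown regime {regime!r}")


def jacobian_and_stability(
    params: ModelParams, C: float, S: float, E: float, regime: str
) -> tuple[tuple[float, float], bool, bool, tuple[float, float] | None]:
    """Eigen-moduli and stability flag of a fixed point.

    Returns ``(moduli, stable, boundary, moduli_interior_side)``.  When the
    point lies exactly on a regime boundary (V = 0 or V = 1) the map is
    continuous but not differentiable there: the clamped-regime
    linearization decides ``stable`` and the interior-sided one is reported
    alongside.
    """
    moduli, stable = _classify(np.abs(np.linalg.eigvals(jacobian(params, C, S, E, regime))))
    V = C - S - E
    boundary = abs(V) <= _BOUNDARY_TOL or abs(V - 1.0) <= _BOUNDARY_TOL
    interior_side = None
    if boundary and regime != "interior":
        m_int, _ = _classify(
            np.abs(np.linalg.eigvals(jacobian(params, C, S, E, "interior")))
        )
        interior_side = m_int
    return moduli, stable, boundary, interior_side


def _make_equilibrium(params: ModelParams, E: float, C: float, S: float, regime: str) -> Equilibrium:
    moduli, stable, boundary, interior_side = jacobian_and_stability(params, C, S, E, regime)
    return Equilibrium(
        E=E, C_star=C, S_star=S, regime=regime, eigen_moduli=moduli,
        stable=stable, boundary=boundary, eigen_moduli_interior_side=interior_side,
    )


def abstinent_equilibrium(params: ModelParams, E: float) -> Equilibrium | None:
    """The craving-free fixed point ``(0, S_plus)``, if the clamp holds.

    Requires ``0 - S_plus - E <= 0`` i.e. ``E >= -S_plus``; otherwise a
    zero-craving state already has positive vulnerability and cannot be
    stationary.
    """
    if -params.S_plus - E > _BOUNDARY_TOL:
        return None
    return _make_equilibrium(params, E, 0.0, params.S_plus, "abstinent")


def interior_equilibria(params: ModelParams, E: float) -> list[Equilibrium]:
    """Fixed points with ``0 < V < 1``, from the reduced quadratic in C.

    The linear S-balance ``p*(S_plus - S) = h*C + k*q*(C - S - E)`` gives
    ``S(C)``; substituting into the C-balance
    ``b*q*(1 - C)*(C - S - E) = d*C`` yields a quadratic whose real roots
    are kept when ``0 <= C < 1``, ``0 < V < 1`` and ``S <= S_plus``.

    Raises
    ------
    DegenerateParameterError
        If ``k*q == p`` (the S-elimination divides by ``p - k*q``); callers
        fall back to the numeric oracle.
    """
    d, b, q, p, S_plus, h, k = (
        params.d, params.b, params.q, params.p, params.S_plus, params.h, params.k,
    )
    D = p - k * q
    if abs(D) < 1e-12:
        raise DegenerateParameterError(
            f"interior solver is singular at k*q == p (k*q = {k * q}, p = {p})"
        )
    # S(C) = beta - alpha*C; V(C) = u*C - v.
    alpha = (h + k * q) / D
    beta = (p * S_plus + k * q * E) / D
    u = 1.0 + alpha
    v = beta + E
    # b*q*(1-C)*(u*C - v) = d*C  =>  a2*C^2 + a1*C + a0 = 0
    a2 = b * q * u
    a1 = -(b * q * (u + v) - d)
    a0 = b * q * v
    if abs(a2) < 1e-14:
        roots = [] if abs(a1) < 1e-14 else [-a0 / a1]
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc < 0.0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-a1 - sq) / (2.0 * a2), (-a1 + sq) / (2.0 * a2)]
    out: list[Equilibrium] = []
    for C in roots:
        S = beta - alpha * C
        V = C - S - E
        if not (_BOUNDARY_TOL < V < 1.0 - _BOUNDARY_TOL):
            continue  # clamped-regime (or boundary) point: owned by the other solvers
        if not (-_BOUNDARY_TOL <= C < 1.0):
            continue
        if S > S_plus + _BOUNDARY_TOL:
            continue  # restoration branch assumed; S above ceiling is inconsistent
        out.append(_make_equilibrium(params, E, C, S, "interior"))
    return out


def saturated_equilibrium(params: ModelParams, E: float) -> Equilibrium | None:
    """The fully-addicted fixed point with consumption clamped at ``q``.

    ``C* = b*q/(d + b*q)`` and ``S* = S_plus - (h*C* + k*q)/p`` do not
    depend on ``E``; the clamp is self-consistent iff ``C* - S* - E >= 1``.
    """
    C = params.b * params.q / (params.d + params.b * params.q)
    S = params.S_plus - (params.h * C + params.k * params.q) / params.p
    if C - S - E < 1.0 - _BOUNDARY_TOL:
        return None
    if S > params.S_plus + _BOUNDARY_TOL:
        return None
    return _make_equilibrium(params, E, C, S, "saturated")


def _dedupe(eqs: list[Equilibrium]) -> list[Equilibrium]:
    """Collapse coordinate-coincident fixed points, preferring clamped regimes."""
    kept: list[Equilibrium] = []
    for eq in eqs:
        dup = None
        for i, other in enumerate(kept):
            if (
                abs(eq.C_star - other.C_star) < 1e-9
                and abs(eq.S_star - other.S_star) < 1e-9
            ):
                dup = i
                break
        if dup is None:
            kept.append(eq)
        elif kept[dup].regime == "interior" and eq.regime != "interior":
            kept[dup] = eq
    return kept


def all_equilibria(params: ModelParams, E: float) -> list[Equilibrium]:
    """All fixed points of the deterministic map at external parameter ``E``.

    Runs the three regime solvers and deduplicates regime-boundary
    coincidences.  In the degenerate case ``k*q == p`` the interior solver
    is replaced by the brute-force numeric oracle.
    """
    eqs: list[Equilibrium] = []
    ab = abstinent_equilibrium(params, E)
    if ab is not None:
        eqs.append(ab)
    try:
        eqs.extend(interior_equilibria(params, E))
    except DegenerateParameterError:
        for C, S in brute_force_equilibria(params, E):
            V = C - S - E
            if _BOUNDARY_TOL < V < 1.0 - _BOUNDARY_TOL:
                eqs.append(_make_equilibrium(params, E, C, S, "interior"))
    sat = saturated_equilibrium(params, E)
    if sat is not None:
        eqs.append(sat)
    return _dedupe(sorted(eqs, key=lambda e: e.C_star))


# ---------------------------------------------------------------------------
# Numeric oracle: multi-start Newton on the fixed-point residual.
# ---------------------------------------------------------------------------

def _map_and_jac(params: ModelParams, C: np.ndarray, S: np.ndarray, E: float):
    """Vectorized one-week map and its piecewise Jacobian at (C, S)."""
    d, b, q, p, S_plus, h, k = (
        params.d, params.b, params.q, params.p, params.S_plus, params.h, params.k,
    )
    raw = C - S - E
    V = np.clip(raw, 0.0, 1.0)
    interior = (raw > 0.0) & (raw < 1.0)
    A = q * V
    m = np.minimum(1.0, 1.0 - C)
    mprime = np.where(C > 0.0, -1.0, 0.0)
    restoring = S < S_plus
    FC = C + b * m * A - d * C
    FS = S + p * np.maximum(0.0, S_plus - S) - h * C - k * A
    dVdC = np.where(interior, 1.0, 0.0)
    J11 = 1.0 - d + b * (mprime * A + m * q * dVdC)
    J12 = b * m * q * (-dVdC)
    J21 = -h - k * q * dVdC
    J22 = np.where(restoring, 1.0 - p, 1.0) + k * q * dVdC
    return FC, FS, J11, J12, J21, J22


def brute_force_equilibria(
    params: ModelParams, E: float, n_grid: int = 9, n_iter: int = 60
) -> list[tuple[float, float]]:
    """Independent numeric census of all fixed points (stable and unstable).

    Newton iteration on the residual ``step(x) - x`` from a dense grid of
    starts over ``(C, S) in [0, 1] x [-1.5, S_plus]``, using the analytic
    piecewise Jacobian; converged points are filtered to the admissible
    domain and deduplicated.  States with ``S > S_plus`` are excluded: above
    the ceiling the restoration term vanishes and (with C = 0) every point
    is trivially stationary — a non-generic continuum never reached from
    admissible initial conditions, since depletion only pushes S downward.
    Used in tests to confirm the closed-form regime solvers find *all*
    fixed points.
    """
    Cg, Sg = np.meshgrid(
        np.linspace(0.0, 1.0, n_grid),
        np.linspace(-1.5, params.S_plus, n_grid),
    )
    C = Cg.ravel().astype(float).copy()
    S = Sg.ravel().astype(float).copy()
    for _ in range(n_iter):
        FC, FS, J11, J12, J21, J22 = _map_and_jac(params, C, S, E)
        gC, gS = FC - C, FS - S
        a, b_, c, d_ = J11 - 1.0, J12, J21, J22 - 1.0
        det = a * d_ - b_ * c
        ok = np.abs(det) > 1e-14
        dC = np.where(ok, (d_ * gC - b_ * gS) / np.where(ok, det, 1.0), 0.0)
        dS = np.where(ok, (-c * gC + a * gS) / np.where(ok, det, 1.0), 0.0)
        # damped full step; the map is piecewise linear so Newton settles fast
        C = C - dC
        S = S - dS
    FC, FS, *_ = _map_and_jac(params, C, S, E)
    res = np.maximum(np.abs(FC - C), np.abs(FS - S))
    good = (
        (res < 1e-10)
        & (C > -1e-8) & (C < 1.0 + 1e-8)
        & (S <= params.S_plus + 1e-8)
        & np.isfinite(C) & np.isfinite(S)
    )
    pts: list[tuple[float, float]] = []
    for Ci, Si in zip(C[good], S[good]):
        if not any(abs(Ci - Pc) < 1e-6 and abs(Si - Ps) < 1e-6 for Pc, Ps in pts):
            pts.append((float(Ci), float(Si)))
    return sorted(pts)


# ---------------------------------------------------------------------------
# Branch sweep over the external parameter E.
# ---------------------------------------------------------------------------

@dataclass
class BranchDiagram:
    """Equilibria on an E grid, with fold locations where the count changes."""

    E_grid: np.ndarray
    equilibria: list[list[Equilibrium]]
    E_folds: list[float] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        return np.array([len(eqs) for eqs in self.equilibria])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eqs in self.equilibria:
            for eq in eqs:
                rows.append(
                    {
                        "E": eq.E, "C_star": eq.C_star, "S_star": eq.S_star,
                        "regime": eq.regime, "stable": eq.stable,
                        "eig1": eq.eigen_moduli[0], "eig2": eq.eigen_moduli[1],
                    }
                )
        return pd.DataFrame(rows, columns=["E", "C_star", "S_star", "regime", "stable", "eig1", "eig2"])


def _interior_discriminant(params: ModelParams, E: float) -> float:
    d, b, q, p, S_plus, h, k = (
        params.d, params.b, params.q, params.p, params.S_plus, params.h, params.k,
    )
    D = p - k * q
    alpha = (h + k * q) / D
    beta = (p * S_plus + k * q * E) / D
    u = 1.0 + alpha
    v = beta + E
    a1 = b * q * (u + v) - d
    return a1 * a1 - 4.0 * (b * q) ** 2 * u * v


def sweep_branches(
    params: ModelParams, E_min: float, E_max: float, step_size: float
) -> BranchDiagram:
    """Reconstruct the branch diagram over an E grid.

    At each grid point the three closed-form regime solvers run and their
    results are deduplicated; where the equilibrium count changes between
    adjacent grid points a transition location is refined — by bisection on
    the interior quadratic's discriminant when its sign flips there (the
    fold of the addicted/unstable pair), otherwise by bisection on the
    count itself (branch-validity endpoints such as ``E = -S_plus``).
    """
    if not E_min < E_max:
        raise ValueError("E_min must be < E_max")
    if step_size <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(E_min, E_max + 0.5 * step_size, step_size)
    eqs = [all_equilibria(params, float(E)) for E in grid]
    folds: list[float] = []
    counts = [len(e) for e in eqs]
    for i in range(len(grid) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = float(grid[i]), float(grid[i + 1])
        try:
            dlo = _interior_discriminant(params, lo)
            dhi = _interior_discriminant(params, hi)
        except ZeroDivisionError:
            dlo = dhi = float("nan")
        if np.isfinite(dlo) and np.isfinite(dhi) and dlo * dhi < 0.0:
            # fold of the interior pair: exact root of the discriminant
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if _interior_discriminant(params, mid) * dlo <= 0.0:
                    hi = mid
                else:
                    lo = mid
                    dlo = _interior_discriminant(params, lo)
            folds.append(0.5 * (lo + hi))
        else:
            n_lo = counts[i]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if len(all_equilibria(params, mid)) == n_lo:
                    lo = mid
                else:
                    hi = mid
            folds.append(0.5 * (lo + hi))
    return BranchDiagram(E_grid=grid, equilibria=eqs, E_folds=folds)
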