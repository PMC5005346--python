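"""Deterministic (mass-action) description of the burst model.

On the molecule scale the ODE reads ``dn/dt = f(n) - delta * n`` — bursting
enters only through its mean, so the mean burst size cancels and fixed points
are the intersections of ``f(n)/delta`` with the identity line.  All analysis
is done on the molecule scale; concentrations are reported as ``n / V``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .burst_model import BurstyGeneModel

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "find_fixed_points",
    "classify_stability",
    "integrate_ode",
]

#: relative tolerance on |f'(n*) - delta| below which stability is "marginal"
MARGINAL_RTOL = 1e-9

_ROOT_XTOL = 1e-10
_BASE_GRID = 2048
_REFINE_FACTOR = 64


@dataclass(frozen=True)
class FixedPoint:
    n_star: float          # molecules
    c_star: float          # concentration, n_star / V
    stability: str         # "stable" | "unstable" | "marginal"


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    @property
    def stable(self) -> tuple:
        return tuple(p for p in self.points if p.stability == "stable")

    @property
    def unstable(self) -> tuple:
        return tuple(p for p in self.points if p.stability == "unstable")


def _default_n_max(model: BurstyGeneModel) -> float:
    sup = model.f.f_sup
    if not np.isfinite(sup):
        raise ValueError(
            "n_max must be given explicitly for unbounded feedback functions"
        )
    return 1.5 * sup / model.delta + 10.0


def find_fixed_points(
    model: BurstyGeneModel, n_max: float | None = None
) -> FixedPointSet:
    """All solutions of ``f(n) = delta * n`` on ``[0, n_max]`` with stability.

    Roots are bracketed by sign changes of ``g(n) = f(n) - delta*n`` on a
    2048-point grid, with one round of 64-fold refinement inside every grid
    cell (close root pairs of sigmoidal feedback can share a coarse cell),
    then polished by Brent's method.  ``n_max`` defaults to
    ``1.5 * sup(f)/delta + 10`` so every intersection is bracketed.
    """
    if n_max is None:
        n_max = _default_n_max(model)
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    if np.isfinite(model.f.f_sup) and model.f.f_sup / model.delta > n_max:
        raise ValueError("n_max too small: f/delta exceeds it, roots may escape")

    g = lambda n: model.f(float(n)) - model.delta * float(n)
    grid = np.linspace(0.0, float(n_max), _BASE_GRID + 1)
    gv = model.f(grid) - model.delta * grid

    roots: list[float] = []
    if abs(gv[0]) == 0.0:  # f(0) == 0: extinction state is a fixed point
        roots.append(0.0)
    for a, b, ga, gb in zip(grid[:-1], grid[1:], gv[:-1], gv[1:]):
        if ga == 0.0 and a > 0.0:
            roots.append(float(a))
        if ga * gb < 0.0:
            roots.append(brentq(g, a, b, xtol=_ROOT_XTOL))
        elif ga * gb > 0.0:
            # refine: a cell may hide an even number of close roots
            sub = np.linspace(a, b, _REFINE_FACTOR + 1)
            gs = model.f(sub) - model.delta * sub
            for aa, bb, gaa, gbb in zip(sub[:-1], sub[1:], gs[:-1], gs[1:]):
                if gaa * gbb < 0.0:
                    roots.append(brentq(g, aa, bb, xtol=_ROOT_XTOL))
    if gv[-1] == 0.0:
        roots.append(float(grid[-1]))

    # dedupe (refinement may rediscover a root found at a grid node)
    roots = sorted(roots)
    merged: list[float] = []
    for r in roots:
        if not merged or abs(r - merged[-1]) > 10 * _ROOT_XTOL + 1e-12 * abs(r):
            merged.append(r)

    pts = tuple(
        FixedPoint(
            n_star=r,
            c_star=r / model.volume,
            stability=classify_stability(model, r),
        )
        for r in merged
    )
    return FixedPointSet(points=pts)


def classify_stability(model: BurstyGeneModel, n_star: float) -> str:
    """Linearized stability of a fixed point: stable iff ``f'(n*) < delta``.

    Returns ``"marginal"`` when ``|f'(n*) - delta|`` is below numeric
    derivative accuracy (relative tolerance 1e-9).
    """
    fprime = model.f.derivative(n_star, 1)
    if abs(fprime - model.delta) < MARGINAL_RTOL * model.delta:
        return "marginal"
    return "stable" if fprime < model.delta else "unstable"


def integrate_ode(
    model: BurstyGeneModel,
    n0: float,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate ``dn/dt = f(n) - delta*n`` from ``n0``; returns n on ``t_grid``.

    Monotone toward the attracting fixed point of the basin of ``n0``; the
    state is clipped at zero against solver round-off.
    """
    if n0 < 0:
        raise ValueError("initial molecule number must be nonnegative")
    t_grid = np.asarray(t_grid, dtype=float)
    rhs = lambda t, y: [model.f(max(float(y[0]), 0.0)) - model.delta * y[0]]
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [float(n0)],
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed ({sol.message}); mu_star={model.mu_star}, "
            f"delta={model.delta}, feedback variant={model.f.variant!r}"
        )
    return np.clip(sol.y[0], 0.0, None)
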