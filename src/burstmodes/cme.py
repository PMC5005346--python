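"""Exact stochastic analysis of the bursty gene-expression model.

The chemical master equation of the burst scheme is

    dp_n/dt = sum_{mu=1}^{n} g(mu) f(n-mu)/mu* p_{n-mu}  -  f(n)/mu* p_n
              + delta (n+1) p_{n+1}  -  delta n p_n,

with ``g`` the geometric burst-size pmf (mean ``mu_star``).  Its stationary
solution obeys the two-term recursion

    p_1 = f(0)/(delta mu*) p_0,
    (n+1) p_{n+1} = f(n)/(delta mu*) p_n + (mu*-1)/mu* n p_n,

which this module evaluates in log space with a certified tail bound.  The
sign of the discrepancy ``d(n) = f(n)/delta - (n + mu_star)`` controls where
the PMF rises or falls, hence the modes (``n = ceil(f(n)/delta - mu_star)``)
and the per-step relative slope ``s(n) = d(n) / (mu_star (n+1))`` used as a
local precision measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csc_matrix

from .burst_model import BurstyGeneModel

__all__ = [
    "StationaryPMF",
    "ExtremaSet",
    "MomentSummary",
    "TransientSolution",
    "stationary_pmf",
    "stationary_moments",
    "find_extrema",
    "analytic_extrema",
    "precision_profile",
    "transient_cme",
    "moment_ode_residuals",
    "taylor_mean_expansion",
    "burst_generator",
    "stationary_pmf_nullspace",
]

#: relative tolerance below which adjacent probabilities count as a tie/plateau
PLATEAU_RTOL = 1e-12


@dataclass(frozen=True)
class StationaryPMF:
    """Truncated, normalized stationary distribution of protein copy number."""

    probs: np.ndarray              # index n = 0..N_max
    truncation_tail: float         # certified bound on mass beyond N_max
    model_fingerprint: str

    @property
    def support(self) -> int:
        return len(self.probs)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))


@dataclass(frozen=True)
class ExtremaSet:
    """Local maxima/minima of a PMF as plateaus ``(n_lo, n_hi)`` (inclusive).

    Exact ties (within relative tolerance 1e-12) merge into one plateau; a
    plateau's left edge is where the analytic ceiling condition points.  One
    extremum always sits at the boundary n = 0.
    """

    maxima: tuple
    minima: tuple
    boundary_extremum_at_zero: str  # "maximum" | "minimum"

    @property
    def n_modes(self) -> int:
        return len(self.maxima)

    @property
    def mode_positions(self) -> tuple:
        """Left edge of every maximum plateau."""
        return tuple(lo for lo, _hi in self.maxima)


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    variance: float
    cov_nf: float                 # Cov(N, f(N))
    central_moments: np.ndarray   # z[r] = E[(N-E[N])^r], r = 0..order
    mean_f: float                 # E[f(N)]


@dataclass(frozen=True)
class TransientSolution:
    """CME solution on the truncated lattice 0..n_cap.

    ``pmfs[i]`` is the (lattice) distribution at ``times[i]``; ``leaked[i]``
    is the probability mass that has escaped past ``n_cap`` by then, so
    ``pmfs[i].sum() + leaked[i] == 1`` up to integrator tolerance.
    """

    times: np.ndarray
    pmfs: np.ndarray        # shape (T, n_cap + 1)
    leaked: np.ndarray      # shape (T,)
    n_cap: int


# ----------------------------------------------------------------- recursion

def _ratio(model: BurstyGeneModel, n: int) -> float:
    """Recursion ratio p_{n+1}/p_n of the unnormalized stationary solution."""
    mu, d = model.mu_star, model.delta
    return (model.f(float(n)) / (d * mu) + n * (mu - 1.0) / mu) / (n + 1.0)


def _ratio_upper_bound(model: BurstyGeneModel, n: int) -> float:
    """Upper bound on the recursion ratio valid for every index >= n."""
    mu, d = model.mu_star, model.delta
    f = model.f
    if f.variant in ("constant", "michaelis_menten", "hill"):
        return (mu - 1.0) / mu + f.f_sup / (d * mu * (n + 1.0))
    if f.variant == "linear":
        return (
            f.slope / (d * mu)
            + (mu - 1.0) / mu
            + f.b / (d * mu * (n + 1.0))
        )
    # custom: heuristic — assume the ratio is nonincreasing past the last mode
    return _ratio(model, n)


def stationary_pmf(
    model: BurstyGeneModel,
    tail_tol: float = 1e-12,
    n_cap: int = 200_000,
) -> StationaryPMF:
    """Stationary PMF via the two-term recursion, truncated with a tail bound.

    The unnormalized weights are carried as logarithms (they span hundreds of
    orders of magnitude for large ``f/delta``); the support is extended until
    the discrepancy ``d(n)`` is negative (past every mode candidate) and the
    geometric tail bound ``p_n * rbar/(1 - rbar) < tail_tol`` holds, where
    ``rbar`` bounds all remaining recursion ratios.
    """
    if not (0.0 < tail_tol <= 1e-3):
        raise ValueError("tail_tol must lie in (0, 1e-3]")
    if n_cap < 10:
        raise ValueError("n_cap must be at least 10")

    if model.f(0.0) == 0.0:
        # no basal production: extinction at n = 0 is absorbing
        return StationaryPMF(
            probs=np.array([1.0]),
            truncation_tail=0.0,
            model_fingerprint=model.fingerprint(),
        )

    logw = [0.0]
    log_norm = 0.0  # log sum of weights so far
    n = 0
    while True:
        r = _ratio(model, n)
        if r == 0.0:
            break
        logw.append(logw[-1] + math.log(r))
        log_norm = np.logaddexp(log_norm, logw[-1])
        n += 1
        if model.discrepancy(n) < 0.0:
            rbar = _ratio_upper_bound(model, n)
            if rbar < 1.0:
                log_tail = logw[-1] + math.log(rbar) - math.log1p(-rbar)
                if log_tail - log_norm < math.log(tail_tol):
                    tail = math.exp(log_tail - log_norm)
                    break
        if n >= n_cap:
            rbar = _ratio_upper_bound(model, n)
            if rbar < 1.0:
                need = n + int(
                    (math.log(tail_tol) - (logw[-1] - log_norm)) / math.log(rbar)
                )
                hint = f"; roughly n_cap >= {need} is required"
            else:
                hint = " (the distribution may not be normalizable)"
            raise RuntimeError(
                f"stationary support exceeds n_cap={n_cap} before reaching "
                f"tail_tol={tail_tol}{hint}"
            )

    w = np.asarray(logw)
    probs = np.exp(w - w.max())
    probs /= probs.sum()
    return StationaryPMF(
        probs=probs,
        truncation_tail=tail if r != 0.0 else 0.0,
        model_fingerprint=model.fingerprint(),
    )


# ------------------------------------------------------------------- moments

def stationary_moments(
    pmf: StationaryPMF, model: BurstyGeneModel, order: int = 4
) -> MomentSummary:
    """Mean, variance, Cov(N, f(N)) and central moments by direct summation.

    In steady state these obey ``E[N] = E[f(N)]/delta`` and
    ``var = mu* E[N] + Cov(N, f(N))/delta``; for constant production the
    variance-to-mean ratio (Fano factor) is exactly ``mu_star``.
    """
    p = pmf.probs
    n = np.arange(len(p), dtype=float)
    fvals = model.f(n)
    mean = float(np.dot(n, p))
    mean_f = float(np.dot(fvals, p))
    centered = n - mean
    z = np.array([float(np.dot(centered**r, p)) for r in range(order + 1)])
    variance = z[2] if order >= 2 else float(np.dot(centered**2, p))
    cov_nf = float(np.dot(centered * (fvals - mean_f), p))
    return MomentSummary(
        mean=mean,
        variance=variance,
        cov_nf=cov_nf,
        central_moments=z,
        mean_f=mean_f,
    )


# ------------------------------------------------------------------- extrema

def _extrema_from_step_signs(signs: np.ndarray) -> ExtremaSet:
    """Classify extrema from the sign of each step ``x_{n+1} - x_n``.

    ``signs[n]`` is +1/-1/0 for rise/fall/tie of step ``n -> n+1``.  Runs of
    equal values (ties) merge into plateaus; the final (truncation-tail) run
    is not reported unless the profile is still rising there.
    """
    maxima: list = []
    minima: list = []
    prev = 0
    run_start = 0
    N = len(signs)
    for n in range(N):
        s = signs[n]
        if s == 0:
            continue
        run = (run_start, n)
        if s < 0:
            if prev > 0 or run_start == 0:
                maxima.append(run)
        else:
            if prev < 0 or run_start == 0:
                minima.append(run)
        prev = s
        run_start = n + 1
    if prev == 0:
        # wholly flat profile: one big boundary plateau
        maxima.append((0, N))
    elif prev > 0:
        # still rising at the right edge: the last run is a (cut-off) maximum
        maxima.append((run_start, N))
    boundary = "maximum" if (maxima and maxima[0][0] == 0) else "minimum"
    return ExtremaSet(
        maxima=tuple(maxima), minima=tuple(minima), boundary_extremum_at_zero=boundary
    )


def find_extrema(pmf: StationaryPMF) -> ExtremaSet:
    """Modes and antimodes of a computed PMF from sign changes of p_{n+1}-p_n.

    Adjacent probabilities equal within relative tolerance 1e-12 merge into a
    plateau; n = 0 is classified a maximum iff ``p_0 > p_1`` (a tie joins the
    plateau).
    """
    p = pmf.probs
    if len(p) == 1:
        return ExtremaSet(
            maxima=((0, 0),), minima=(), boundary_extremum_at_zero="maximum"
        )
    diff = p[1:] - p[:-1]
    scale = np.maximum(p[1:], p[:-1])
    signs = np.sign(diff)
    signs[np.abs(diff) <= PLATEAU_RTOL * scale] = 0
    return _extrema_from_step_signs(signs.astype(int))


def analytic_extrema(
    model: BurstyGeneModel, n_range: int | tuple
) -> ExtremaSet:
    """Extrema predicted from the discrepancy ``d(n) = f(n)/delta - (n + mu*)``.

    The PMF rises at step ``n`` iff ``d(n) >= 0``, so downward sign changes
    of ``d`` are maxima and upward ones are minima; the resulting positions
    satisfy the ceiling condition ``n = ceil(f(n)/delta - mu_star)``, with an
    exact zero of ``d`` at integer ``n`` producing a two-point plateau.
    ``n_range`` must cover the PMF support.
    """
    n_hi = n_range if isinstance(n_range, (int, np.integer)) else n_range[1]
    n = np.arange(int(n_hi) + 1, dtype=float)
    d = model.discrepancy(n)
    scale = model.f(n) / model.delta + n + model.mu_star
    signs = np.sign(d)
    signs[np.abs(d) <= PLATEAU_RTOL * np.maximum(scale, 1.0)] = 0
    return _extrema_from_step_signs(signs.astype(int))


def significant_maxima(
    pmf: StationaryPMF, extrema: ExtremaSet | None = None, rel_threshold: float = 1e-6
) -> tuple:
    """Maxima whose peak probability reaches ``rel_threshold`` of the global
    maximum; suppresses floating-point phantom modes in flat tails."""
    if extrema is None:
        extrema = find_extrema(pmf)
    p = pmf.probs
    peak = p.max()
    return tuple(
        (lo, hi) for lo, hi in extrema.maxima if p[lo] >= rel_threshold * peak
    )


def precision_profile(model: BurstyGeneModel, pmf: StationaryPMF) -> np.ndarray:
    """Per-step relative slope ``s(n) = d(n) / (mu_star (n+1))``.

    Identically equals ``(p_{n+1} - p_n)/p_n`` wherever ``p_n > 0``; large
    ``|s|`` means the PMF changes fast relative to its height, i.e. sharp
    peaks, which requires a large discrepancy and a small burst size.
    """
    n = np.arange(pmf.support, dtype=float)
    return model.discrepancy(n) / (model.mu_star * (n + 1.0))


# ----------------------------------------------------------------- generator

def burst_generator(
    model: BurstyGeneModel, n_cap: int, conservative: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated CME generator ``G`` (``dp/dt = G p``) on states 0..n_cap.

    Burst jumps carry geometric weights; degradation steps down by one.
    Returns ``(G, leak_rates)`` where ``leak_rates[m]`` is the propensity of
    bursts from ``m`` that overshoot ``n_cap``.  With ``conservative=True``
    overshooting bursts are removed from the outflow instead (columns sum to
    zero), which is the form whose null space approximates the stationary
    distribution.
    """
    mu, d = model.mu_star, model.delta
    size = n_cap + 1
    n = np.arange(size, dtype=float)
    f_over_mu = model.f(n) / mu
    # geometric weights g(1..n_cap)
    if mu == 1.0:
        g = np.zeros(n_cap)
        if n_cap >= 1:
            g[0] = 1.0
        gtail = np.zeros(size)  # mass of bursts > k is 0 for k >= 1
        gtail[0] = 1.0
    else:
        q = 1.0 - 1.0 / mu
        g = (1.0 / mu) * q ** np.arange(n_cap)
        gtail = q ** np.arange(size)  # P(burst > k) = q**k
    G = np.zeros((size, size))
    for m in range(size):
        room = n_cap - m
        if room > 0:
            G[m + 1 : m + 1 + room, m] = f_over_mu[m] * g[:room]
        if m >= 1:
            G[m - 1, m] += d * m
    leak = f_over_mu * gtail[n_cap - np.arange(size, dtype=int)]
    out = f_over_mu - leak if conservative else f_over_mu
    G[np.arange(size), np.arange(size)] -= out + d * n
    return G, leak


def stationary_pmf_nullspace(model: BurstyGeneModel, n_cap: int) -> np.ndarray:
    """Stationary distribution as the null vector of the conservative
    truncated generator (independent linear-algebra oracle for the recursion).
    """
    G, _ = burst_generator(model, n_cap, conservative=True)
    # replace one balance equation by the normalization constraint
    A = G.copy()
    A[-1, :] = 1.0
    rhs = np.zeros(n_cap + 1)
    rhs[-1] = 1.0
    p = np.linalg.solve(A, rhs)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


# ----------------------------------------------------------------- transient

def transient_cme(
    model: BurstyGeneModel,
    p0: np.ndarray,
    t_grid: np.ndarray,
    n_cap: int,
    leak_tol: float = 1e-8,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TransientSolution:
    """Integrate the truncated CME from ``p0`` over ``t_grid``.

    Mass that bursts past ``n_cap`` accumulates in a tracked overflow
    account so total probability is conserved exactly at the generator level;
    a final leak above ``leak_tol`` raises with advice to enlarge ``n_cap``.
    """
    p0 = np.asarray(p0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if p0.ndim != 1 or len(p0) > n_cap + 1:
        raise ValueError("p0 must be a vector supported within n_cap")
    if abs(p0.sum() - 1.0) > 1e-10:
        raise ValueError("p0 must be normalized")
    if np.any(p0 < 0):
        raise ValueError("p0 must be nonnegative")
    G, leak = burst_generator(model, n_cap, conservative=False)
    size = n_cap + 1
    # extended system: last component accumulates the leaked mass
    A = np.zeros((size + 1, size + 1))
    A[:size, :size] = G
    A[size, :size] = leak
    A_sp = csc_matrix(A)
    y0 = np.zeros(size + 1)
    y0[: len(p0)] = p0
    sol = solve_ivp(
        lambda t, y: A_sp @ y,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method="BDF",
        jac=A_sp,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"transient CME integration failed: {sol.message}")
    pmfs = sol.y[:size, :].T
    leaked = sol.y[size, :]
    if leaked[-1] > leak_tol:
        raise RuntimeError(
            f"{leaked[-1]:.3e} probability mass leaked past n_cap={n_cap} "
            f"(tolerance {leak_tol}); increase n_cap"
        )
    return TransientSolution(times=sol.t, pmfs=pmfs, leaked=leaked, n_cap=n_cap)


def moment_ode_residuals(
    model: BurstyGeneModel, transient: TransientSolution
) -> dict:
    """Residuals of the mean and variance ODEs along a transient solution.

    At each snapshot the instantaneous derivatives of ``E[N]`` and ``var(N)``
    are evaluated through the generator action ``dp/dt = G p`` and compared
    with the moment equations

        dE[N]/dt   = E[f(N)] - delta E[N]
        dvar/dt    = 2 Cov(N, f(N)) - (E[f(N)] - delta E[N])
                     + 2 mu* E[f(N)] - 2 delta var.

    Returns the maximum absolute and relative residuals of both equations.
    """
    G, _ = burst_generator(model, transient.n_cap, conservative=False)
    n = np.arange(transient.n_cap + 1, dtype=float)
    fvals = model.f(n)
    res16 = []
    res17 = []
    scale16 = []
    scale17 = []
    for p in transient.pmfs:
        pdot = G @ p
        m = float(np.dot(n, p))
        Ef = float(np.dot(fvals, p))
        var = float(np.dot((n - m) ** 2, p))
        cov = float(np.dot((n - m) * (fvals - Ef), p))
        dm = float(np.dot(n, pdot))
        dEn2 = float(np.dot(n**2, pdot))
        dvar = dEn2 - 2.0 * m * dm
        rhs_mean = Ef - model.delta * m
        rhs_var = (
            2.0 * cov
            - rhs_mean
            + 2.0 * model.mu_star * Ef
            - 2.0 * model.delta * var
        )
        res16.append(abs(dm - rhs_mean))
        res17.append(abs(dvar - rhs_var))
        scale16.append(max(abs(Ef), model.delta * abs(m), 1e-30))
        scale17.append(max(2 * model.mu_star * abs(Ef), 2 * model.delta * var, 1e-30))
    res16, res17 = np.asarray(res16), np.asarray(res17)
    return {
        "mean_abs": float(res16.max()),
        "mean_rel": float((res16 / np.asarray(scale16)).max()),
        "var_abs": float(res17.max()),
        "var_rel": float((res17 / np.asarray(scale17)).max()),
    }


# -------------------------------------------------------------------- taylor

def taylor_mean_expansion(
    model: BurstyGeneModel, pmf: StationaryPMF, order: int = 4
) -> float:
    """Approximate ``E[f(N)]`` by the Taylor expansion of ``f`` around the mean:

        f(E[N]) + sum_{r=2}^{order} z_r f^(r)(E[N]) / r!

    with ``z_r`` the central moments of the stationary PMF.  Exact for
    polynomials of degree <= order (in particular for constant and linear
    feedback at any order); for saturating feedback the truncation error need
    not decrease monotonically on multimodal distributions.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    mom = stationary_moments(pmf, model, order=order)
    total = model.f(mom.mean)
    for r in range(2, order + 1):
        total += mom.central_moments[r] * model.f.derivative(mom.mean, r) / math.factorial(r)
    return float(total)
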