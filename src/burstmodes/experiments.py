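"""Comparative experiments: simulation ensembles, system-size scaling,
stability/modality regime classification, matched scenario pairs, and mean
first-passage times.

These operations combine the deterministic and stochastic analyses to map
where bistability and bimodality agree — and construct the counterexamples
(bistable-unimodal, monostable-bimodal) where they do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .burst_model import BurstyGeneModel, FeedbackFunction, sample_burst
from .cme import (
    StationaryPMF,
    burst_generator,
    find_extrema,
    significant_maxima,
    stationary_pmf,
)
from .deterministic import find_fixed_points
from .reaction_core import Trajectory

__all__ = [
    "EnsembleSummary",
    "RegimeLabel",
    "ScenarioPair",
    "MFPTResult",
    "simulate_burst_trajectory",
    "ensemble_endpoint",
    "scale_system",
    "thermodynamic_convergence",
    "classify_regime",
    "scenario_shifted_basal",
    "scenario_hill_vs_mm",
    "scenario_mm_vs_mm",
    "mfpt",
    "mfpt_between_modes",
]


# ------------------------------------------------------------------ sampling

def simulate_burst_trajectory(
    model: BurstyGeneModel,
    n0: int,
    t_end: float,
    rng: np.random.Generator | int,
) -> Trajectory:
    """Exact SSA sample path of the two-channel burst model.

    Channels: a burst event with propensity ``f(n)/mu_star`` adding a
    geometric number of molecules, and degradation with propensity
    ``delta * n`` removing one.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    n = int(n0)
    t = 0.0
    times = [0.0]
    states = [n]
    while True:
        rb = model.burst_propensity(n)
        rd = model.delta * n
        total = rb + rd
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        if rng.random() * total < rb:
            n += sample_burst(model.mu_star, rng)
        else:
            n -= 1
        times.append(t)
        states.append(n)
    times.append(t_end)
    states.append(n)
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states)[None, :],
        species_labels=("X",),
    )


def _ssa_endpoints(
    model: BurstyGeneModel,
    n_init: np.ndarray,
    t_f: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Endpoint states of many independent SSA runs, advanced one event per
    pass over the active set (vectorized direct method)."""
    n = np.asarray(n_init, dtype=np.int64).copy()
    t = np.zeros(n.shape, dtype=float)
    active = np.ones(n.shape, dtype=bool)
    mu, delta = model.mu_star, model.delta
    while active.any():
        idx = np.flatnonzero(active)
        nn = n[idx]
        rb = model.f(nn.astype(float)) / mu
        rd = delta * nn
        total = rb + rd
        frozen = total <= 0.0
        dt = rng.exponential(size=idx.size) / np.where(frozen, 1.0, total)
        t_new = t[idx] + dt
        done = (t_new >= t_f) | frozen
        t[idx] = t_new
        active[idx[done]] = False
        rem = ~done
        ridx = idx[rem]
        if ridx.size:
            u = rng.random(ridx.size)
            is_burst = u * total[rem] < rb[rem]
            bidx = ridx[is_burst]
            if bidx.size:
                n[bidx] += sample_burst(mu, rng, size=bidx.size)
            n[ridx[~is_burst]] -= 1
    return n


@dataclass(frozen=True)
class EnsembleSummary:
    """Endpoint histogram of an SSA ensemble at final time ``t_f``."""

    histogram: np.ndarray     # counts by n, index 0..max endpoint
    n_runs: int
    empirical_mean: float
    empirical_variance: float
    seed: int
    t_f: float

    @property
    def pmf(self) -> np.ndarray:
        return self.histogram / self.n_runs

    def tv_distance(self, probs: np.ndarray) -> float:
        """Total-variation distance to a reference PMF."""
        L = max(len(self.histogram), len(probs))
        a = np.zeros(L)
        b = np.zeros(L)
        a[: len(self.histogram)] = self.pmf
        b[: len(probs)] = probs
        return 0.5 * float(np.abs(a - b).sum())


def ensemble_endpoint(
    model: BurstyGeneModel,
    init_rule,
    t_f: float,
    n_runs: int,
    seed: int,
    stationarity_check: bool = False,
    stationarity_tv: float = 0.05,
) -> EnsembleSummary:
    """Endpoint ensemble of ``n_runs`` independent burst-model SSA runs.

    ``init_rule`` is an integer initial copy number, an array of length
    ``n_runs``, or a callable ``(rng, n_runs) -> array``.  With
    ``stationarity_check=True`` a second ensemble started from perturbed
    random initial conditions is compared; a total-variation distance above
    ``stationarity_tv`` triggers a warning (``t_f`` too small for approximate
    stationarity).
    """
    if t_f <= 0:
        raise ValueError("t_f must be positive")
    rng = np.random.default_rng(seed)
    if callable(init_rule):
        n0 = np.asarray(init_rule(rng, n_runs), dtype=np.int64)
    elif np.isscalar(init_rule):
        n0 = np.full(n_runs, int(init_rule), dtype=np.int64)
    else:
        n0 = np.asarray(init_rule, dtype=np.int64)
    if len(n0) != n_runs:
        raise ValueError("init_rule must yield one initial state per run")
    endpoints = _ssa_endpoints(model, n0, t_f, rng)
    hist = np.bincount(endpoints)
    summary = EnsembleSummary(
        histogram=hist,
        n_runs=n_runs,
        empirical_mean=float(endpoints.mean()),
        empirical_variance=float(endpoints.var()),
        seed=seed,
        t_f=t_f,
    )
    if stationarity_check:
        scale = max(int(2 * summary.empirical_mean), 10)
        alt0 = rng.integers(0, scale, size=n_runs)
        alt = _ssa_endpoints(model, alt0, t_f, rng)
        alt_hist = np.bincount(alt)
        L = max(len(hist), len(alt_hist))
        a = np.zeros(L)
        b = np.zeros(L)
        a[: len(hist)] = hist / n_runs
        b[: len(alt_hist)] = alt_hist / n_runs
        tv = 0.5 * float(np.abs(a - b).sum())
        if tv > stationarity_tv:
            warnings.warn(
                f"endpoint ensembles from two initial conditions differ by "
                f"TV={tv:.3f} > {stationarity_tv}; t_f={t_f} may be too small "
                f"for stationarity",
                stacklevel=2,
            )
    return summary


# ------------------------------------------------------------------- scaling

def scale_system(model: BurstyGeneModel, s: float) -> BurstyGeneModel:
    """System enlarged ``s``-fold: volume ``s V`` and production
    ``f_s(n) = s f(n/s)`` so all fixed-point *concentrations* are unchanged.

    For the parametric feedback variants the rescaling stays in the family:
    basal and maximal rates scale by ``s`` and the half-saturation constant
    by ``s`` (Michaelis-Menten) or ``s**h`` (Hill).
    """
    if s <= 0:
        raise ValueError("scale factor s must be positive")
    f = model.f
    if f.variant == "constant":
        fs = replace(f, b=s * f.b)
    elif f.variant == "linear":
        fs = replace(f, b=s * f.b)  # slope * (n/s) * s = slope * n
    elif f.variant == "michaelis_menten":
        fs = replace(f, b=s * f.b, v=s * f.v, K=s * f.K)
    elif f.variant == "hill":
        fs = replace(f, b=s * f.b, v=s * f.v, K=s**f.h * f.K)
    else:
        base = f.func
        fs = FeedbackFunction.custom(
            lambda n, g=base, s=s: s * np.asarray(g(np.asarray(n) / s)),
            b=s * f.b,
        )
    return replace(model, f=fs, volume=s * model.volume)


def thermodynamic_convergence(
    model: BurstyGeneModel,
    s_list,
    tail_tol: float = 1e-10,
    mode_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Convergence of stochastic modes to deterministic fixed points as the
    system is blown up.

    For each scale ``s`` the modes of the ``s``-fold system are matched
    (nearest neighbour on the concentration axis) to the stable fixed-point
    concentrations of the base model; the deviation shrinks like
    ``(mu_star + 1)/(s V)``.  Rows where mode and fixed-point counts differ
    are flagged.
    """
    fps = find_fixed_points(model)
    c_stars = np.array([p.c_star for p in fps.stable])
    rows = []
    for s in s_list:
        scaled = scale_system(model, float(s))
        pmf = stationary_pmf(scaled, tail_tol=tail_tol)
        modes = significant_maxima(pmf, rel_threshold=mode_threshold)
        mode_ns = np.array([lo for lo, _ in modes], dtype=float)
        mode_cs = mode_ns / scaled.volume
        flagged = len(mode_cs) != len(c_stars)
        for mode_n, mode_c in zip(mode_ns, mode_cs):
            j = int(np.argmin(np.abs(c_stars - mode_c))) if len(c_stars) else -1
            c_star = c_stars[j] if j >= 0 else np.nan
            rows.append(
                {
                    "s": float(s),
                    "mode_n": mode_n,
                    "mode_conc": mode_c,
                    "c_star": c_star,
                    "deviation": abs(mode_c - c_star),
                    "bound": (model.mu_star + 1.0) / scaled.volume,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- regimes

@dataclass(frozen=True)
class RegimeLabel:
    n_stable_fixed_points: int
    n_modes: int
    label: str
    mode_positions: tuple = ()
    fixed_points: tuple = ()


def classify_regime(
    model: BurstyGeneModel,
    tail_tol: float = 1e-12,
    mode_threshold: float = 1e-6,
) -> RegimeLabel:
    """Joint stability/modality label of a model.

    Combines the number of stable deterministic fixed points with the number
    of stationary-PMF maxima (after suppressing maxima below
    ``mode_threshold`` of the global peak).
    """
    if model.f(0.0) <= 0.0:
        raise ValueError("classification requires basal production f(0) > 0")
    fps = find_fixed_points(model)
    n_stable = len(fps.stable)
    pmf = stationary_pmf(model, tail_tol=tail_tol)
    modes = significant_maxima(pmf, rel_threshold=mode_threshold)
    n_modes = len(modes)
    key = (n_stable, n_modes)
    label = {
        (1, 1): "monostable-unimodal",
        (1, 2): "monostable-bimodal",
        (2, 1): "bistable-unimodal",
        (2, 2): "bistable-bimodal",
    }.get(key, "other")
    return RegimeLabel(
        n_stable_fixed_points=n_stable,
        n_modes=n_modes,
        label=label,
        mode_positions=tuple(lo for lo, _ in modes),
        fixed_points=tuple(
            (p.n_star, p.stability) for p in fps
        ),
    )


# ----------------------------------------------------------------- scenarios

@dataclass(frozen=True)
class ScenarioPair:
    """Two models matched so that burst size and feedback shape can be
    compared at fixed mode locations."""

    model_a: BurstyGeneModel
    model_b: BurstyGeneModel
    matched_property: str
    construction: str


def _discrepancy_grid(model: BurstyGeneModel, n_hi: int) -> np.ndarray:
    return model.discrepancy(np.arange(n_hi + 1, dtype=float))


def scenario_shifted_basal(
    f1: FeedbackFunction,
    mu1: float,
    mu2: float,
    delta: float,
    volume: float = 1.0,
) -> ScenarioPair:
    """Same discrepancy, different burst size.

    System 2 gets the larger burst size ``mu2 > mu1`` and the compensating
    basal shift ``f2 = f1 + delta (mu2 - mu1)``, so both systems share the
    discrepancy function and therefore every analytic extremum; the
    larger-burst system still ends up with the broader distribution.
    """
    if not (mu2 > mu1 >= 1):
        raise ValueError("need mu2 > mu1 >= 1")
    f2 = f1.shifted(delta * (mu2 - mu1))
    a = BurstyGeneModel(f=f1, mu_star=mu1, delta=delta, volume=volume)
    b = BurstyGeneModel(f=f2, mu_star=mu2, delta=delta, volume=volume)
    n_hi = int(max(f2.f_sup / delta + mu2, 50)) if np.isfinite(f2.f_sup) else 1000
    if np.max(np.abs(_discrepancy_grid(a, n_hi) - _discrepancy_grid(b, n_hi))) > 1e-9:
        raise AssertionError("shifted-basal construction failed: discrepancies differ")
    return ScenarioPair(
        model_a=a,
        model_b=b,
        matched_property="identical discrepancy f/delta - (n + mu*), hence identical extrema",
        construction="shifted_basal",
    )


def _discrepancy_crossings(
    f: FeedbackFunction, mu_star: float, delta: float
) -> list[float]:
    """Real crossings of f(n)/delta with the line n + mu_star, ordered."""
    if not np.isfinite(f.f_sup):
        raise ValueError("crossing search requires bounded feedback")
    n_hi = f.f_sup / delta + mu_star + 10.0
    grid = np.linspace(0.0, n_hi, 4096)
    d = f(grid) / delta - (grid + mu_star)
    g = lambda x: f(float(x)) / delta - (x + mu_star)
    roots = []
    for x0, x1, d0, d1 in zip(grid[:-1], grid[1:], d[:-1], d[1:]):
        if d0 == 0.0:
            roots.append(float(x0))
        if d0 * d1 < 0.0:
            roots.append(brentq(g, x0, x1, xtol=1e-12))
    return roots


def _solve_mm_through(
    b: float, delta: float, mu_star: float, n_a: float, n_b: float
) -> tuple[float, float]:
    """(v, K) of a Michaelis-Menten function with basal ``b`` whose
    discrepancy vanishes at ``n_a`` and ``n_b``: solves the linear system
    ``v n_i - y_i K = y_i n_i`` with ``y_i = delta (n_i + mu*) - b``."""
    y_a = delta * (n_a + mu_star) - b
    y_b = delta * (n_b + mu_star) - b
    A = np.array([[n_a, -y_a], [n_b, -y_b]])
    rhs = np.array([y_a * n_a, y_b * n_b])
    det = np.linalg.det(A)
    if abs(det) < 1e-12 * max(abs(n_a * y_b), abs(n_b * y_a), 1.0):
        raise ValueError("through-point system is singular; points too close")
    v, K = np.linalg.solve(A, rhs)
    if v <= 0 or K <= 0:
        raise ValueError(
            f"no valid Michaelis-Menten function through the requested points "
            f"(v={v:.4g}, K={K:.4g})"
        )
    return float(v), float(K)


def scenario_hill_vs_mm(
    f3: FeedbackFunction,
    mu_star: float,
    delta: float,
    volume: float = 1.0,
) -> ScenarioPair:
    """Cooperative vs non-cooperative feedback at matched modes.

    Builds the Michaelis-Menten function ``f4`` with the same basal rate as
    the Hill function ``f3`` whose discrepancy vanishes at the same two
    points, so both stationary distributions place their interior extrema at
    the same copy numbers; pointwise the non-cooperative discrepancy is
    smaller in magnitude, so the cooperative system has the sharper peaks.
    If ``f3`` has more than two crossings, the last two (antimode and upper
    mode) are used.
    """
    if f3.variant != "hill":
        raise ValueError("f3 must be a Hill feedback function")
    crossings = _discrepancy_crossings(f3, mu_star, delta)
    if len(crossings) < 2:
        raise ValueError(
            f"f3/delta intersects n + mu* at {len(crossings)} points; need >= 2"
        )
    n_a, n_b = crossings[-2], crossings[-1]
    v4, K4 = _solve_mm_through(f3.b, delta, mu_star, n_a, n_b)
    f4 = FeedbackFunction.michaelis_menten(b=f3.b, v=v4, K=K4)
    a = BurstyGeneModel(f=f3, mu_star=mu_star, delta=delta, volume=volume)
    b = BurstyGeneModel(f=f4, mu_star=mu_star, delta=delta, volume=volume)
    # construction constraints
    for n_i in (n_a, n_b):
        if abs(f4(n_i) - delta * (n_i + mu_star)) > 1e-9 * max(f4(n_i), 1.0):
            raise AssertionError("MM through-point constraint violated")
    n_hi = int(max(f3.f_sup, f4.f_sup) / delta + mu_star + 10)
    ns = np.arange(n_hi + 1, dtype=float)
    d3 = np.abs(_discrepancy_grid(a, n_hi))
    d4 = np.abs(_discrepancy_grid(b, n_hi))
    # equality is allowed only where the functions coincide (n = 0 shares the
    # basal rate) or at the matched crossings themselves
    same_f = np.abs(f3(ns) - f4(ns)) <= 1e-9 * np.maximum(f3(ns), 1.0)
    near = np.zeros(n_hi + 1, dtype=bool)
    for n_i in (n_a, n_b):
        near |= np.abs(ns - n_i) <= 1.0
    ok = (d4 < d3) | near | same_f
    if not ok.all():
        raise AssertionError("discrepancy ordering |d4| < |d3| violated off-crossing")
    return ScenarioPair(
        model_a=a,
        model_b=b,
        matched_property="shared basal rate and extrema locations; |d_mm| < |d_hill| pointwise",
        construction="hill_vs_mm",
    )


def scenario_mm_vs_mm(
    b: float,
    n_a: float,
    n_b: float,
    mu5: float,
    mu6: float,
    delta: float,
    volume: float = 1.0,
) -> ScenarioPair:
    """Two non-cooperative systems with shared basal rate and mode locations
    but different burst sizes ``mu5 > mu6``.

    Each Michaelis-Menten function is fitted so its discrepancy vanishes at
    ``n_a < n_b``; the larger-burst system has the pointwise larger
    discrepancy magnitude, which counteracts its broader bursts — which
    effect wins requires explicit computation of both PMFs.
    """
    if not (mu5 > mu6 >= 1):
        raise ValueError("need mu5 > mu6 >= 1")
    if not (0 <= n_a < n_b):
        raise ValueError("need 0 <= n_a < n_b")
    v5, K5 = _solve_mm_through(b, delta, mu5, n_a, n_b)
    v6, K6 = _solve_mm_through(b, delta, mu6, n_a, n_b)
    f5 = FeedbackFunction.michaelis_menten(b=b, v=v5, K=K5)
    f6 = FeedbackFunction.michaelis_menten(b=b, v=v6, K=K6)
    m5 = BurstyGeneModel(f=f5, mu_star=mu5, delta=delta, volume=volume)
    m6 = BurstyGeneModel(f=f6, mu_star=mu6, delta=delta, volume=volume)
    n_hi = int(max(f5.f_sup, f6.f_sup) / delta + mu5 + 10)
    d5 = np.abs(_discrepancy_grid(m5, n_hi))
    d6 = np.abs(_discrepancy_grid(m6, n_hi))
    ns = np.arange(n_hi + 1)
    near = (np.abs(ns - n_a) <= 1.0) | (np.abs(ns - n_b) <= 1.0)
    if np.any(d5[~near] <= d6[~near]):
        raise AssertionError("discrepancy ordering |d5| > |d6| violated off-crossing")
    return ScenarioPair(
        model_a=m5,
        model_b=m6,
        matched_property="shared basal rate and mode locations; |d5| > |d6| pointwise",
        construction="mm_vs_mm",
    )


# ----------------------------------------------------------------------- MFPT

@dataclass(frozen=True)
class MFPTResult:
    value: float
    stderr: float | None   # None for the exact linear-solve method
    method: str
    n_samples: int | None = None


def _target_mask(target, n_cap: int) -> np.ndarray:
    mask = np.zeros(n_cap + 1, dtype=bool)
    if isinstance(target, tuple) and len(target) == 2 and target[0] in ("ge", "le"):
        kind, m = target
        if kind == "ge":
            mask[int(m) :] = True
        else:
            mask[: int(m) + 1] = True
    else:
        idx = np.asarray(sorted(set(int(x) for x in target)))
        idx = idx[idx <= n_cap]
        mask[idx] = True
    if not mask.any():
        raise ValueError("target set is empty within the truncation cap")
    return mask


def _in_target(n: np.ndarray, target) -> np.ndarray:
    if isinstance(target, tuple) and len(target) == 2 and target[0] in ("ge", "le"):
        kind, m = target
        return n >= int(m) if kind == "ge" else n <= int(m)
    return np.isin(n, np.asarray(sorted(set(int(x) for x in target))))


def mfpt(
    model: BurstyGeneModel,
    start_n: int,
    target,
    method: str = "exact",
    rng: np.random.Generator | int | None = None,
    n_cap: int | None = None,
    n_traj: int = 10_000,
    t_max: float | None = None,
) -> MFPTResult:
    """Mean first-passage time from ``start_n`` into ``target``.

    ``target`` is an iterable of states or an interval spec ``("ge", m)`` /
    ``("le", m)`` (reachable despite burst overshoot).  The ``exact`` method
    solves the linear hitting-time system of the truncated burst-death chain
    (bursts overshooting the cap are redirected to the cap state, which is
    benign when the cap sits far in the decaying tail); ``ssa`` averages
    first-hitting times over simulated trajectories.
    """
    if method not in ("exact", "ssa"):
        raise ValueError("method must be 'exact' or 'ssa'")
    if method == "exact":
        if n_cap is None:
            pmf = stationary_pmf(model, tail_tol=1e-12)
            n_cap = pmf.support - 1 + int(40 * model.mu_star) + 20
        mask = _target_mask(target, n_cap)
        if mask[int(start_n)]:
            return MFPTResult(0.0, None, "exact")
        mu, d = model.mu_star, model.delta
        size = n_cap + 1
        free = np.flatnonzero(~mask)
        pos = {int(s): i for i, s in enumerate(free)}
        A = np.zeros((free.size, free.size))
        rhs = -np.ones(free.size)
        q = 1.0 - 1.0 / mu
        for i, m_state in enumerate(free):
            f_over_mu = model.f(float(m_state)) / mu
            total = f_over_mu + d * m_state
            if total <= 0.0:
                raise RuntimeError(
                    f"state {m_state} is absorbing but not in the target set; "
                    "the passage time is infinite"
                )
            A[i, i] = -total
            if m_state >= 1 and not mask[m_state - 1]:
                A[i, pos[m_state - 1]] += d * m_state
            room = n_cap - m_state
            if room >= 1:
                if mu == 1.0:
                    w = np.zeros(room)
                    w[0] = 1.0
                else:
                    w = (1.0 / mu) * q ** np.arange(room)
                    w[-1] += q**room  # redirect overshoot to the cap state
                dests = m_state + 1 + np.arange(room)
                for dest, wt in zip(dests, w):
                    if wt and not mask[dest]:
                        A[i, pos[dest]] += f_over_mu * wt
        tau = np.linalg.solve(A, rhs)
        return MFPTResult(float(tau[pos[int(start_n)]]), None, "exact")

    # --- ssa ---
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = np.full(n_traj, int(start_n), dtype=np.int64)
    t = np.zeros(n_traj)
    hit = np.full(n_traj, np.nan)
    active = ~_in_target(n, target)
    hit[~active] = 0.0
    mu, delta = model.mu_star, model.delta
    if t_max is None:
        t_max = 1e7 / delta
    while active.any():
        idx = np.flatnonzero(active)
        nn = n[idx]
        rb = model.f(nn.astype(float)) / mu
        rd = delta * nn
        total = rb + rd
        if np.any(total <= 0.0):
            raise RuntimeError("trajectory frozen outside the target set")
        dt = rng.exponential(size=idx.size) / total
        t[idx] += dt
        if np.any(t[idx] > t_max):
            raise RuntimeError(
                f"first passage not reached within t_max={t_max}; "
                "the target may be effectively unreachable"
            )
        u = rng.random(idx.size)
        is_burst = u * total < rb
        bidx = idx[is_burst]
        if bidx.size:
            n[bidx] += sample_burst(mu, rng, size=bidx.size)
        n[idx[~is_burst]] -= 1
        newly = _in_target(n[idx], target)
        done = idx[newly]
        hit[done] = t[done]
        active[done] = False
    mean = float(hit.mean())
    se = float(hit.std(ddof=1) / np.sqrt(n_traj))
    return MFPTResult(mean, se, "ssa", n_samples=n_traj)


def mfpt_between_modes(
    model: BurstyGeneModel,
    method: str = "exact",
    rng: np.random.Generator | int | None = None,
    pmf: StationaryPMF | None = None,
    **kwargs,
) -> dict:
    """MFPTs between the two basins of a bimodal stationary distribution.

    The inactive/active states are operationalized as the two PMF maxima; the
    transition is complete when the trajectory first crosses the interior
    PMF minimum into the other basin.  Returns ``{"up": ..., "down": ...}``.
    """
    if pmf is None:
        pmf = stationary_pmf(model, tail_tol=1e-12)
    modes = significant_maxima(pmf)
    extrema = find_extrema(pmf)
    if len(modes) != 2 or len(extrema.minima) < 1:
        raise ValueError("model is not bimodal; basins are undefined")
    lo_mode = modes[0][0]
    hi_mode = modes[1][0]
    valley = next(
        (mn for mn in extrema.minima if lo_mode < mn[0] < hi_mode), None
    )
    if valley is None:
        raise ValueError("no interior minimum between the two modes")
    n_min = valley[0]
    return {
        "up": mfpt(model, lo_mode, ("ge", n_min), method=method, rng=rng, **kwargs),
        "down": mfpt(model, hi_mode, ("le", n_min), method=method, rng=rng, **kwargs),
    }
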