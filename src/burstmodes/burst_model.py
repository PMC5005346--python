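"""The bursty gene-expression model.

Reaction scheme (protein copy number ``n``)::

    0 --( f(n)/mu_star )-->  mu X      burst of geometric size mu, mean mu_star
    X --( delta * n    )-->  0         first-order degradation

``f`` is a smooth, monotonically nondecreasing production (feedback) function
evaluated at the integer molecule number; dividing the burst frequency by
``mu_star`` keeps the mean production flux ``f(n)`` independent of the burst
size, so distributions for different ``mu_star`` are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable

import numpy as np

__all__ = [
    "FeedbackFunction",
    "BurstyGeneModel",
    "geometric_pmf",
    "sample_burst",
    "evaluate_feedback",
    "burst_event_propensity",
]

_VARIANTS = ("constant", "linear", "michaelis_menten", "hill", "custom")


@dataclass(frozen=True)
class FeedbackFunction:
    """Protein production rate ``f(n)`` as a function of copy number.

    Variants
    --------
    constant            ``f(n) = b``
    linear              ``f(n) = b + slope * n``
    michaelis_menten    ``f(n) = b + v * n / (n + K)``          (K in molecules)
    hill                ``f(n) = b + v * n**h / (n**h + K)``    (K in molecules**h)
    custom              arbitrary nondecreasing callable

    For the Hill variant ``K`` carries units of molecules**h; use
    :meth:`hill` to construct from a half-saturation point instead.
    """

    variant: str
    b: float = 0.0
    v: float = 0.0
    K: float = 1.0
    h: float = 2.0
    slope: float = 0.0
    func: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown feedback variant {self.variant!r}")
        if self.b < 0:
            raise ValueError("basal rate b must be nonnegative")
        if self.variant in ("michaelis_menten", "hill"):
            if self.v < 0:
                raise ValueError("v must be nonnegative")
            if self.K <= 0:
                raise ValueError("half-saturation constant K must be positive")
        if self.variant == "hill" and self.h <= 1:
            raise ValueError("Hill coefficient h must exceed 1")
        if self.variant == "linear" and self.slope < 0:
            raise ValueError("linear slope must be nonnegative (f nondecreasing)")
        if self.variant == "custom" and self.func is None:
            raise ValueError("custom variant requires a callable")

    # ---------------------------------------------------------------- builders
    @classmethod
    def constant(cls, b: float) -> "FeedbackFunction":
        return cls(variant="constant", b=b)

    @classmethod
    def linear(cls, b: float, slope: float) -> "FeedbackFunction":
        return cls(variant="linear", b=b, slope=slope)

    @classmethod
    def michaelis_menten(cls, b: float, v: float, K: float) -> "FeedbackFunction":
        return cls(variant="michaelis_menten", b=b, v=v, K=K)

    @classmethod
    def hill(cls, b: float, v: float, K_half: float, h: float) -> "FeedbackFunction":
        """Hill feedback from its half-saturation point (``f = b + v/2`` there)."""
        if K_half <= 0:
            raise ValueError("half-saturation point must be positive")
        return cls(variant="hill", b=b, v=v, K=float(K_half) ** h, h=h)

    @classmethod
    def custom(cls, func: Callable, b: float = 0.0) -> "FeedbackFunction":
        return cls(variant="custom", b=b, func=func)

    # -------------------------------------------------------------- evaluation
    def __call__(self, n):
        """Evaluate ``f`` at (scalar or array) copy number ``n >= 0``."""
        arr = np.asarray(n, dtype=float)
        if np.any(arr < 0):
            raise ValueError("feedback is defined for nonnegative n only")
        if self.variant == "constant":
            out = np.full_like(arr, self.b)
        elif self.variant == "linear":
            out = self.b + self.slope * arr
        elif self.variant == "michaelis_menten":
            out = self.b + self.v * arr / (arr + self.K)
        elif self.variant == "hill":
            nh = arr**self.h
            out = self.b + self.v * nh / (nh + self.K)
        else:
            out = np.asarray(self.func(arr), dtype=float)
        return out if isinstance(n, np.ndarray) else float(out)

    def derivative(self, n: float, order: int = 1) -> float:
        """``order``-th derivative of ``f`` at real ``n >= 0``.

        Closed forms for constant/linear/Michaelis-Menten, symbolically
        generated (cached) expressions for Hill, central differences for
        custom callables.
        """
        if order < 1:
            raise ValueError("order must be >= 1")
        if self.variant == "constant":
            return 0.0
        if self.variant == "linear":
            return self.slope if order == 1 else 0.0
        if self.variant == "michaelis_menten":
            # d^r/dn^r [v n/(n+K)] = (-1)^(r-1) r! v K / (n+K)^(r+1)
            return (
                (-1.0) ** (order - 1)
                * math.factorial(order)
                * self.v
                * self.K
                / (n + self.K) ** (order + 1)
            )
        if self.variant == "hill":
            fn = _hill_derivative(self.h, order)
            return float(fn(max(n, 1e-12), self.K)) * self.v
        return _numeric_derivative(self.func, n, order)

    @property
    def f_sup(self) -> float:
        """Supremum of ``f`` over ``n >= 0`` (``inf`` for unbounded variants)."""
        if self.variant == "constant":
            return self.b
        if self.variant in ("michaelis_menten", "hill"):
            return self.b + self.v
        return math.inf

    def shifted(self, offset: float) -> "FeedbackFunction":
        """Return ``f + offset`` (same shape, raised basal level)."""
        if self.variant == "custom":
            f = self.func
            return FeedbackFunction.custom(lambda n, f=f, o=offset: f(n) + o,
                                           b=self.b + offset)
        return replace(self, b=self.b + offset)

    def to_dict(self) -> dict:
        if self.variant == "custom":
            raise TypeError("custom feedback functions are not serializable")
        d = {"variant": self.variant, "b": self.b}
        if self.variant == "linear":
            d["slope"] = self.slope
        elif self.variant == "michaelis_menten":
            d.update(v=self.v, K=self.K)
        elif self.variant == "hill":
            d.update(v=self.v, K=self.K, h=self.h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackFunction":
        return cls(**d)


@lru_cache(maxsize=None)
def _hill_derivative(h: float, order: int):
    import sympy

    n, K = sympy.symbols("n K", positive=True)
    expr = sympy.diff(n**h / (n**h + K), n, order)
    return sympy.lambdify((n, K), expr, modules="numpy")


def _numeric_derivative(func: Callable, n: float, order: int) -> float:
    # central finite differences on a stencil of 2*order+1 points
    step = max(1e-3, 1e-3 * max(abs(n), 1.0))
    offsets = np.arange(-order, order + 1)
    pts = np.maximum(n + offsets * step, 0.0)
    vals = np.asarray([float(func(p)) for p in pts])
    coeffs = _fd_coeffs(tuple(offsets), order)
    return float(np.dot(coeffs, vals)) / step**order


@lru_cache(maxsize=None)
def _fd_coeffs(offsets: tuple, order: int) -> np.ndarray:
    # Fornberg-style weights from the Vandermonde moment conditions
    off = np.asarray(offsets, dtype=float)
    m = len(off)
    A = np.vander(off, m, increasing=True).T
    rhs = np.zeros(m)
    rhs[order] = math.factorial(order)
    return np.linalg.solve(A, rhs)


@dataclass(frozen=True)
class BurstyGeneModel:
    """Bursty production / linear degradation model of one protein species.

    Parameters
    ----------
    f : FeedbackFunction
        Production rate (molecules/time) as a function of copy number.
    mu_star : float
        Mean burst size, >= 1 (molecules per burst); burst sizes are geometric
        on {1, 2, ...}.  ``mu_star == 1`` means every burst adds one molecule.
    delta : float
        First-order degradation rate constant (1/time).
    volume : float
        Fixed cell volume; concentrations are always ``n / volume``.
    """

    f: FeedbackFunction
    mu_star: float
    delta: float
    volume: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_star < 1:
            raise ValueError("mean burst size mu_star must be >= 1")
        if self.delta <= 0:
            raise ValueError("degradation rate delta must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    def burst_propensity(self, n):
        """Propensity of a burst event in state ``n``: ``f(n) / mu_star``."""
        return self.f(n) / self.mu_star

    def degradation_propensity(self, n):
        return self.delta * np.asarray(n, dtype=float) if isinstance(
            n, np.ndarray
        ) else self.delta * float(n)

    def discrepancy(self, n):
        """``d(n) = f(n)/delta - (n + mu_star)``.

        The stationary PMF rises at ``n`` (``p_{n+1} >= p_n``) exactly when
        ``d(n) >= 0``; its sign changes locate the modes and antimodes.
        """
        arr = np.asarray(n, dtype=float)
        out = self.f(arr) / self.delta - (arr + self.mu_star)
        return out if isinstance(n, np.ndarray) else float(out)

    def fingerprint(self) -> str:
        import hashlib

        key = repr(
            (
                self.f.variant,
                self.f.b,
                self.f.v,
                self.f.K,
                self.f.h,
                self.f.slope,
                id(self.f.func) if self.f.variant == "custom" else None,
                self.mu_star,
                self.delta,
                self.volume,
            )
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "feedback": self.f.to_dict(),
            "mu_star": self.mu_star,
            "delta": self.delta,
            "volume": self.volume,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BurstyGeneModel":
        return cls(
            f=FeedbackFunction.from_dict(d["feedback"]),
            mu_star=float(d["mu_star"]),
            delta=float(d["delta"]),
            volume=float(d.get("volume", 1.0)),
        )


# ------------------------------------------------------------------ geometric

def geometric_pmf(mu_star: float, mu) -> float | np.ndarray:
    """Geometric burst-size pmf ``g(mu) = (1/mu*) (1 - 1/mu*)^(mu-1)`` on mu >= 1.

    For ``mu_star == 1`` this degenerates to a point mass at 1 (the ``0**0``
    convention).
    """
    if mu_star < 1:
        raise ValueError("mu_star must be >= 1")
    arr = np.asarray(mu)
    if np.any(arr < 1) or not np.issubdtype(arr.dtype, np.integer) and np.any(
        arr != np.floor(arr)
    ):
        raise ValueError("burst size mu must be a positive integer")
    p = 1.0 / mu_star
    if mu_star == 1.0:
        out = np.where(arr == 1, 1.0, 0.0)
    else:
        out = p * (1.0 - p) ** (arr - 1)
    return out if isinstance(mu, np.ndarray) else float(out)


def sample_burst(mu_star: float, rng: np.random.Generator, size=None):
    """Draw geometric burst sizes with mean ``mu_star`` by inverse CDF.

    ``mu = 1 + floor(log(u) / log(1 - 1/mu*))`` with ``u ~ U(0, 1)``; the
    degenerate ``mu_star == 1`` branch returns 1 directly.
    """
    if mu_star < 1:
        raise ValueError("mu_star must be >= 1")
    if mu_star == 1.0:
        out = np.ones(size if size is not None else (), dtype=np.int64)
        return out if size is not None else 1
    u = rng.random(size)
    out = 1 + np.floor(np.log(u) / np.log1p(-1.0 / mu_star)).astype(np.int64)
    return out if size is not None else int(out)


# --------------------------------------------------- thin functional wrappers

def evaluate_feedback(f: FeedbackFunction, n):
    """Evaluate the feedback function at nonnegative ``n``."""
    return f(n)


def burst_event_propensity(model: BurstyGeneModel, n):
    """Burst-event propensity ``f(n)/mu_star`` in state ``n``."""
    return model.burst_propensity(n)
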