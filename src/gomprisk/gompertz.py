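"""The generalized (3-parameter) Gompertz distribution, including its improper regime.

The family used throughout this package is

    F(t) = [1 - exp(-(lam/gamma) * (exp(gamma*t) - 1))]**theta ,   t >= 0,

with power ``theta > 0``, shape ``gamma`` (any real, per year) and rate
``lam > 0`` (per year).  For ``gamma >= 0`` this is a proper distribution;
for ``gamma < 0`` the cumulative hazard of the inner exponential saturates
at ``-lam/gamma`` and the distribution is *improper*: its CDF plateaus at

    plateau = [1 - exp(lam/gamma)]**theta < 1 .

The residual mass ``1 - plateau`` is the probability the event never occurs,
which is exactly what lets one cause's sub-distribution leave room for a
competing cause.  ``theta = 1`` recovers the classical two-parameter
Gompertz; ``theta = 1, gamma -> 0`` recovers the exponential.

All evaluators switch to the analytic ``gamma -> 0`` limit when
``|gamma| < GAMMA_BRANCH`` to avoid cancellation in ``(exp(gamma*t)-1)/gamma``,
and use ``expm1``/``log1p`` forms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAMMA_BRANCH",
    "GompertzParams",
    "cdf",
    "pdf",
    "logpdf",
    "plateau",
    "quantile",
    "sample",
    "subdistribution_hazard",
]

#: below this |gamma| the gamma->0 series limit is used
GAMMA_BRANCH = 1e-8


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of one cause's (possibly improper) Gompertz sub-distribution.

    Parameters
    ----------
    theta : float
        Power exponent, dimensionless, > 0.
    gamma : float
        Gompertz shape, per year.  Negative values give an improper
        distribution with a plateau (cure/competing-cause) mass.
    lam : float
        Rate, per year, > 0.
    """

    theta: float
    gamma: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("theta", "gamma", "lam"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float, np.floating)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite real number, got {v!r}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")


# ---------------------------------------------------------------------------
# array kernels (scalar theta/gamma; lam may be an array, which is what the
# regression layer uses to push covariate-dependent rates through)
# ---------------------------------------------------------------------------

def _G(t, gamma: float, lam):
    """Inner exponent G(t) = lam * (exp(gamma*t) - 1) / gamma, with gamma->0 limit."""
    t = np.asarray(t, dtype=float)
    if abs(gamma) < GAMMA_BRANCH:
        return lam * t
    return lam * np.expm1(gamma * t) / gamma


def _cdf_kernel(t, theta: float, gamma: float, lam):
    g = _G(t, gamma, lam)
    return np.power(-np.expm1(-g), theta)


def _logpdf_kernel(t, theta: float, gamma: float, lam):
    t = np.asarray(t, dtype=float)
    g = _G(t, gamma, lam)
    base = -np.expm1(-g)  # 1 - exp(-G), in [0, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # theta == 1 at base == 0 hits 0 * (-inf); callers patch that case
        return (
            np.log(theta) + np.log(lam) + gamma * t - g
            + (theta - 1.0) * np.log(base)
        )


def _plateau_kernel(theta: float, gamma: float, lam):
    if gamma >= 0:
        return np.ones_like(np.asarray(lam, dtype=float) * 1.0)
    return np.power(-np.expm1(np.asarray(lam, dtype=float) / gamma), theta)


def _quantile_kernel(u, theta: float, gamma: float, lam):
    u = np.asarray(u, dtype=float)
    v = np.power(u, 1.0 / theta)
    g = -np.log1p(-v)  # inner exponent at the quantile
    if abs(gamma) < GAMMA_BRANCH:
        return g / lam
    return np.log1p(gamma * g / lam) / gamma


def _as_result(x, scalar_in: bool):
    x = np.asarray(x, dtype=float)
    return float(x) if scalar_in and x.ndim == 0 else x


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def cdf(t, p: GompertzParams):
    """Sub-distribution function F(t); bounded above by ``plateau(p)``."""
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return _as_result(_cdf_kernel(t, p.theta, p.gamma, p.lam), scalar)


def pdf(t, p: GompertzParams):
    """Density f(t) = dF/dt, per year."""
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(over="ignore"):
        out = np.exp(_logpdf_kernel(t, p.theta, p.gamma, p.lam))
    # theta=1 at t=0 gives 0*log(0) -> nan in the kernel; the density is lam there
    if p.theta == 1.0:
        out = np.where(t == 0.0, p.lam, out)
    return _as_result(out, scalar)


def logpdf(t, p: GompertzParams):
    """Log-density; -inf where the density vanishes."""
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = _logpdf_kernel(t, p.theta, p.gamma, p.lam)
    if p.theta == 1.0:
        out = np.where(t == 0.0, math.log(p.lam), out)
    return _as_result(out, scalar)


def plateau(p: GompertzParams) -> float:
    """Total mass lim_{t->inf} F(t): 1 if gamma >= 0, else [1-exp(lam/gamma)]**theta."""
    if p.gamma >= 0:
        return 1.0
    return float(np.power(-np.expm1(p.lam / p.gamma), p.theta))


def quantile(u, p: GompertzParams):
    """Inverse of ``cdf``; defined for 0 <= u < plateau(p)."""
    scalar = np.isscalar(u)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("u must be >= 0")
    pl = plateau(p)
    if np.any(u >= pl):
        raise ValueError(f"u must be < plateau = {pl}; no finite quantile exists")
    return _as_result(_quantile_kernel(u, p.theta, p.gamma, p.lam), scalar)


def sample(p: GompertzParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` event times; ``np.inf`` marks 'never' (the plateau deficit).

    Inverse-transform: U ~ Uniform(0,1); U >= plateau(p) -> never, else
    quantile(U).  Reproducible under a seeded generator.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    u = rng.uniform(size=n)
    pl = plateau(p)
    out = np.full(n, np.inf)
    finite = u < pl
    if np.any(finite):
        out[finite] = _quantile_kernel(u[finite], p.theta, p.gamma, p.lam)
    return out


def subdistribution_hazard(t, p: GompertzParams):
    """Sub-distribution hazard f(t) / (1 - F(t)), per year."""
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    F = _cdf_kernel(t, p.theta, p.gamma, p.lam)
    if np.any(F >= 1.0):
        raise ValueError("subdistribution hazard undefined where F(t) = 1")
    f = pdf(t, p)
    return _as_result(np.asarray(f) / (1.0 - F), scalar)
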