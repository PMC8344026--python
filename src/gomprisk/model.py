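"""Two-cause competing-risks regression on improper Gompertz sub-distributions.

Each cause ``k`` in {1, 2} has its own sub-distribution F_k(t | x) of the
generalized Gompertz form, with covariates acting multiplicatively on the
rate:

    lam_k(x) = lam_k * exp(x' beta_k) ,

so ``exp(beta)`` is the reported sub-hazard ratio (S-HR).  The power and
shape parameters are baseline-only.  The joint log-likelihood over records
(t_i, delta_i, x_i) with event codes 0 = censored, 1 = cause one,
2 = cause two is

    sum_i  [delta_i = 1] log f_1(t_i|x_i)
         + [delta_i = 2] log f_2(t_i|x_i)
         + [delta_i = 0] log(1 - F_1(t_i|x_i) - F_2(t_i|x_i)) .

Fitting maximizes this over the transformed parameter vector
(log theta_k, gamma_k, log lam_k, beta_k) with quasi-Newton multistart;
the covariance is the inverse observed information from a central-difference
Hessian, and Wald intervals on beta are exponentiated endpoint-wise to the
S-HR scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gompertz import GompertzParams, _cdf_kernel, _logpdf_kernel, _plateau_kernel

__all__ = [
    "CauseModel",
    "ModelFit",
    "WaldCI",
    "cause_cdf",
    "overall_survival",
    "validity_check",
    "log_likelihood",
    "fit_mle",
    "wald_ci",
    "shr_table",
    "cif_curve",
]

logger = logging.getLogger(__name__)

#: smooth-penalty floor for the censored-survival term (see log_likelihood)
PENALTY_EPS = 1e-10


@dataclass(frozen=True)
class CauseModel:
    """Baseline sub-distribution plus log-S-HR coefficients for one cause."""

    baseline: GompertzParams
    covariates: tuple[str, ...] = ()
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if beta.shape != (len(self.covariates),):
            raise ValueError(
                f"beta has length {beta.shape[0]} but {len(self.covariates)} covariates named"
            )

    def rate(self, X) -> np.ndarray:
        """Covariate-specific rate lam * exp(x' beta); X is (n, p) or (p,)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.baseline.lam * np.exp(X @ self.beta)


@dataclass
class ModelFit:
    """MLE result on the transformed scale.

    ``param_names`` aligns with ``estimates`` and the rows/cols of
    ``covariance``; baseline entries are ``log_theta``, ``gamma``,
    ``log_lam`` prefixed by cause, coefficient entries are
    ``cause{k}:{covariate}``.
    """

    param_names: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray | None
    loglik: float
    converged: bool
    n_used: int
    n_dropped: int
    covariates1: tuple[str, ...]
    covariates2: tuple[str, ...]
    n_starts: int = 1
    message: str = ""

    def cause_model(self, cause: int) -> CauseModel:
        """Back-transform the fitted parameters of one cause."""
        names, covs = _cause_slices(self.covariates1, self.covariates2)[cause - 1]
        idx = [self.param_names.index(nm) for nm in names]
        th, g, lm = self.estimates[idx[:3]]
        beta = self.estimates[idx[3:]]
        return CauseModel(
            baseline=GompertzParams(theta=math.exp(th), gamma=g, lam=math.exp(lm)),
            covariates=covs,
            beta=beta,
        )

    def index_of(self, which: str) -> int:
        """Locate a parameter by full name, or by bare covariate name if unique."""
        if which in self.param_names:
            return self.param_names.index(which)
        hits = [i for i, nm in enumerate(self.param_names) if nm.split(":", 1)[-1] == which]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise KeyError(f"no parameter named {which!r}")
        raise KeyError(f"parameter name {which!r} is ambiguous: "
                       + ", ".join(self.param_names[i] for i in hits))


def _cause_slices(covs1, covs2):
    names1 = ("cause1:log_theta", "cause1:gamma", "cause1:log_lam") + tuple(
        f"cause1:{c}" for c in covs1
    )
    names2 = ("cause2:log_theta", "cause2:gamma", "cause2:log_lam") + tuple(
        f"cause2:{c}" for c in covs2
    )
    return (names1, tuple(covs1)), (names2, tuple(covs2))


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def cause_cdf(t, x, cm: CauseModel):
    """Model cumulative incidence F_k(t | x) for one cause."""
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    rate = float(cm.rate(x)[0]) if len(cm.covariates) else cm.baseline.lam
    out = _cdf_kernel(t, cm.baseline.theta, cm.baseline.gamma, rate)
    return float(out) if scalar and out.ndim == 0 else out


def overall_survival(t, x, cm1: CauseModel, cm2: CauseModel):
    """S(t|x) = 1 - F_1(t|x) - F_2(t|x); errors if the model is invalid at x."""
    F1 = cause_cdf(t, x, cm1)
    F2 = cause_cdf(t, x, cm2)
    S = 1.0 - np.asarray(F1) - np.asarray(F2)
    if np.any(S < -1e-12):
        raise ValueError(
            "invalid competing-risks model at this covariate profile: F1 + F2 > 1"
        )
    S = np.clip(S, 0.0, 1.0)
    return float(S) if np.isscalar(t) else S


def _plateau_at(cm: CauseModel, X) -> np.ndarray:
    if len(cm.covariates):
        rate = cm.rate(X)
    else:
        rate = np.full(np.atleast_2d(np.asarray(X, dtype=float)).shape[0] or 1,
                       cm.baseline.lam)
    return np.atleast_1d(_plateau_kernel(cm.baseline.theta, cm.baseline.gamma, rate))


def validity_check(cm1: CauseModel, cm2: CauseModel, X=None):
    """Worst-case plateau_1(x) + plateau_2(x) over the rows of X.

    Returns ``(worst_total, ok)``; ``ok`` iff the total never exceeds 1.
    With ``X`` empty or None only the baseline profile is checked.
    """
    if X is None or (hasattr(X, "__len__") and len(X) == 0):
        X1 = np.zeros((1, len(cm1.covariates)))
        X2 = np.zeros((1, len(cm2.covariates)))
    else:
        X1 = _design(X, cm1.covariates)
        X2 = _design(X, cm2.covariates)
    total = _plateau_at(cm1, X1) + _plateau_at(cm2, X2)
    worst = float(np.max(total))
    return worst, worst <= 1.0 + 1e-12


def _design(data, covariates) -> np.ndarray:
    """Extract an (n, p) design matrix from a DataFrame / dict / array."""
    if isinstance(data, pd.DataFrame):
        missing = [c for c in covariates if c not in data.columns]
        if missing:
            raise KeyError(f"missing covariate column(s): {missing}")
        return data.loc[:, list(covariates)].to_numpy(dtype=float) if covariates else np.zeros((len(data), 0))
    if isinstance(data, dict):
        return np.column_stack([np.asarray(data[c], dtype=float) for c in covariates]) \
            if covariates else np.zeros((1, 0))
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[1] != len(covariates):
        raise ValueError("design width does not match covariate names")
    return arr


def _loglik_vector(t, event, X1, X2, th1, g1, l1, b1, th2, g2, l2, b2,
                   eps: float = PENALTY_EPS) -> np.ndarray:
    """Per-record log-likelihood contributions (vectorized)."""
    ll = np.empty_like(t)

    with np.errstate(divide="ignore", over="ignore", invalid="ignore", under="ignore"):
        r1 = l1 * np.exp(X1 @ b1) if X1.shape[1] else np.full(t.shape, l1)
        r2 = l2 * np.exp(X2 @ b2) if X2.shape[1] else np.full(t.shape, l2)
        for code, th, g, r in ((1, th1, g1, r1), (2, th2, g2, r2)):
            m = event == code
            if np.any(m):
                ll[m] = _logpdf_kernel(t[m], th, g, r[m])
        cen = event == 0
        if np.any(cen):
            F1 = _cdf_kernel(t[cen], th1, g1, r1[cen])
            F2 = _cdf_kernel(t[cen], th2, g2, r2[cen])
            S = 1.0 - F1 - F2
            # smooth penalty below eps keeps the objective finite and pushes back
            ll[cen] = np.where(S > eps,
                               np.log(np.maximum(S, eps)),
                               math.log(eps) + (S - eps) / eps)
    return ll


def _validate_records(data: pd.DataFrame, covariates) -> tuple:
    for col in ("time", "event"):
        if col not in data.columns:
            raise ValueError(f"data must contain a {col!r} column")
    t = data["time"].to_numpy(dtype=float)
    event = data["event"].to_numpy()
    if not np.all(np.isin(event, (0, 1, 2))):
        raise ValueError("event codes must be in {0, 1, 2}")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("follow-up times must be finite and > 0")
    X = _design(data, covariates)
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite covariate values; use fit_mle for complete-case handling")
    return t, event.astype(int), X


def log_likelihood(data: pd.DataFrame, cm1: CauseModel, cm2: CauseModel,
                   eps: float = PENALTY_EPS) -> float:
    """Joint competing-risks log-likelihood of the records under (cm1, cm2)."""
    if len(data) == 0:
        raise ValueError("data must be nonempty")
    allcov = tuple(dict.fromkeys(cm1.covariates + cm2.covariates))
    t, event, _ = _validate_records(data, allcov)
    X1 = _design(data, cm1.covariates)
    X2 = _design(data, cm2.covariates)
    ll = _loglik_vector(
        t, event, X1, X2,
        cm1.baseline.theta, cm1.baseline.gamma, cm1.baseline.lam, cm1.beta,
        cm2.baseline.theta, cm2.baseline.gamma, cm2.baseline.lam, cm2.beta,
        eps,
    )
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _unpack(x, p1: int, p2: int):
    th1, g1, l1 = math.exp(x[0]), x[1], math.exp(x[2])
    b1 = x[3:3 + p1]
    o = 3 + p1
    th2, g2, l2 = math.exp(x[o]), x[o + 1], math.exp(x[o + 2])
    b2 = x[o + 3:o + 3 + p2]
    return th1, g1, l1, b1, th2, g2, l2, b2


def fit_mle(data: pd.DataFrame, covariates1=(), covariates2=(), *,
            multistart: int = 5, tol: float = 1e-8, seed: int = 0,
            eps: float = PENALTY_EPS) -> ModelFit:
    """Maximum-likelihood fit of the two-cause Gompertz regression.

    Parameters
    ----------
    data : DataFrame with columns ``time``, ``event`` (codes 0/1/2) and the
        named covariates.  Rows with missing covariates are dropped
        (complete-case) with a logged count.
    covariates1, covariates2 : covariate names entering cause 1 / cause 2.
    multistart : number of quasi-Newton starts; the first is the
        deterministic moment-style initializer, the rest are jittered.
    """
    covariates1 = tuple(covariates1)
    covariates2 = tuple(covariates2)
    allcov = tuple(dict.fromkeys(covariates1 + covariates2))

    work = data.loc[:, ["time", "event", *allcov]].copy()
    n_total = len(work)
    work = work.dropna()
    n_dropped = n_total - len(work)
    if n_dropped:
        logger.warning("dropped %d record(s) with missing covariates (complete-case)",
                       n_dropped)
    t, event, _ = _validate_records(work, allcov)
    if not np.any(event == 1) or not np.any(event == 2):
        raise ValueError("need at least one event of each cause to fit both sub-distributions")

    X1 = _design(work, covariates1)
    X2 = _design(work, covariates2)
    for covs, X in ((covariates1, X1), (covariates2, X2)):
        for j, c in enumerate(covs):
            if X.shape[0] and np.ptp(X[:, j]) == 0.0:
                raise ValueError(f"covariate {c!r} is constant; its effect is "
                                 "not separable from the baseline rate")
    p1, p2 = X1.shape[1], X2.shape[1]

    # optimize on a standardized design (an exact affine reparameterization)
    # so raw-scale covariates do not wreck the conditioning; estimates and
    # covariance are mapped back through the constant Jacobian below
    m1 = X1.mean(axis=0) if p1 else np.zeros(0)
    s1 = X1.std(axis=0) if p1 else np.ones(0)
    m2 = X2.mean(axis=0) if p2 else np.zeros(0)
    s2 = X2.std(axis=0) if p2 else np.ones(0)
    Z1 = (X1 - m1) / s1 if p1 else X1
    Z2 = (X2 - m2) / s2 if p2 else X2

    def negll(x):
        th1, g1, l1, b1, th2, g2, l2, b2 = _unpack(x, p1, p2)
        val = np.sum(_loglik_vector(t, event, Z1, Z2, th1, g1, l1, b1,
                                    th2, g2, l2, b2, eps))
        return -val if np.isfinite(val) else 1e12

    def negll_grad(x):
        # accurate central-difference gradient: lets the optimizer converge
        # on the gradient norm rather than on objective stalls
        g = np.empty_like(x)
        h = 1e-6
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = h
            g[i] = (negll(x + e) - negll(x - e)) / (2.0 * h)
        return g

    total_time = float(np.sum(t))
    x0 = np.concatenate([
        [0.0, -0.1, math.log(max(np.sum(event == 1), 1) / total_time)], np.zeros(p1),
        [0.0, -0.1, math.log(max(np.sum(event == 2), 1) / total_time)], np.zeros(p2),
    ])
    bounds = (
        [(-4, 4), (-10, 10), (-12, 6)] + [(-15, 15)] * p1
        + [(-4, 4), (-10, 10), (-12, 6)] + [(-15, 15)] * p2
    )

    rng = np.random.default_rng(seed)
    best = None
    any_ok = False
    for s in range(max(1, multistart)):
        start = x0 if s == 0 else x0 + rng.normal(0.0, 0.3, size=x0.size)
        with np.errstate(over="ignore", invalid="ignore"):
            res = optimize.minimize(negll, start, jac=negll_grad, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"ftol": tol * 1e-4, "gtol": 1e-6,
                                             "maxiter": 500})
        any_ok = any_ok or bool(res.success)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    names1, _ = _cause_slices(covariates1, covariates2)[0]
    names2, _ = _cause_slices(covariates1, covariates2)[1]
    param_names = names1 + names2

    cov = None
    if best is not None and any_ok:
        # Newton polish: quasi-Newton stalls on objective decrements before
        # the gradient is fully driven down; a couple of Newton steps with
        # the observed information sharpen the optimum.
        x_opt, f_opt = best.x.copy(), float(best.fun)
        H = _numerical_hessian(negll, x_opt)
        for _ in range(3):
            g = negll_grad(x_opt)
            if np.linalg.norm(g) < 1e-6:
                break
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            x_new = x_opt - step
            f_new = negll(x_new)
            if not np.isfinite(f_new) or f_new > f_opt + 1e-9:
                break
            x_opt, f_opt = x_new, float(f_new)
            H = _numerical_hessian(negll, x_opt)
        best.x, best.fun = x_opt, f_opt
        cov = _safe_inverse(H)
        if cov is None:
            logger.warning("observed information singular; covariance unavailable")

    # map estimates/covariance from the standardized-design scale back to
    # the raw covariate scale: beta_j = beta'_j / s_j and
    # log lam = log lam' - sum_j beta'_j m_j / s_j (constant Jacobian A)
    k = 6 + p1 + p2
    A = np.eye(k)
    o = 3 + p1
    for j in range(p1):
        A[3 + j, 3 + j] = 1.0 / s1[j]
        A[2, 3 + j] = -m1[j] / s1[j]
    for j in range(p2):
        A[o + 3 + j, o + 3 + j] = 1.0 / s2[j]
        A[o + 2, o + 3 + j] = -m2[j] / s2[j]
    if best is not None:
        best.x = A @ best.x
    if cov is not None:
        cov = A @ cov @ A.T

    return ModelFit(
        param_names=param_names,
        estimates=best.x.copy() if best is not None else x0,
        covariance=cov,
        loglik=-float(best.fun) if best is not None else float("nan"),
        converged=bool(any_ok),
        n_used=len(work),
        n_dropped=n_dropped,
        covariates1=covariates1,
        covariates2=covariates2,
        n_starts=max(1, multistart),
        message="" if best is None else str(best.message),
    )


def _numerical_hessian(f, x, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian on the transformed scale."""
    k = x.size
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def _safe_inverse(H: np.ndarray) -> np.ndarray | None:
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    cov = 0.5 * (cov + cov.T)
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None
    return cov


# ---------------------------------------------------------------------------
# inference and reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldCI:
    """Wald interval for one coefficient, on the beta and the S-HR scale."""

    name: str
    beta: float
    se: float
    level: float
    beta_lo: float
    beta_hi: float
    shr: float
    shr_lo: float
    shr_hi: float
    p: float


def wald_ci(fit: ModelFit, which: str, level: float) -> WaldCI:
    """Two-sided Wald interval; S-HR endpoints are exp of the beta endpoints."""
    if not fit.converged:
        raise ValueError("fit did not converge; no Wald inference available")
    if fit.covariance is None:
        raise ValueError("covariance unavailable; no Wald inference available")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    i = fit.index_of(which)
    b = float(fit.estimates[i])
    se = float(math.sqrt(fit.covariance[i, i]))
    z = stats.norm.ppf(0.5 * (1.0 + level))
    lo, hi = b - z * se, b + z * se
    zstat = b / se if se > 0 else math.inf
    p = 2.0 * stats.norm.sf(abs(zstat))
    return WaldCI(name=fit.param_names[i], beta=b, se=se, level=level,
                  beta_lo=lo, beta_hi=hi, shr=math.exp(b),
                  shr_lo=math.exp(lo), shr_hi=math.exp(hi), p=float(p))


def shr_table(fit: ModelFit, levels=(0.75, 0.90)) -> pd.DataFrame:
    """Sub-hazard-ratio table: one row per coefficient per cause.

    Columns: cause, variable, shr, p, and per requested level
    ``ci{pct}_lo`` / ``ci{pct}_hi`` on the S-HR scale.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    rows = []
    for cause, covs in ((1, fit.covariates1), (2, fit.covariates2)):
        for c in covs:
            name = f"cause{cause}:{c}"
            row = {"cause": cause, "variable": c}
            for lv in levels:
                ci = wald_ci(fit, name, lv)
                pct = int(round(lv * 100))
                row[f"ci{pct}_lo"] = ci.shr_lo
                row[f"ci{pct}_hi"] = ci.shr_hi
                row["shr"] = ci.shr
                row["p"] = ci.p
            rows.append(row)
    cols = ["cause", "variable", "shr"]
    for lv in levels:
        pct = int(round(lv * 100))
        cols += [f"ci{pct}_lo", f"ci{pct}_hi"]
    cols.append("p")
    return pd.DataFrame(rows, columns=cols)


def cif_curve(fit: ModelFit, x=None, times=None):
    """Model cumulative incidence of both causes on a time grid.

    ``x`` maps covariate names to values (missing names error; ``None``
    means the baseline profile).  Returns ``(F1, F2)`` arrays.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    cm1 = fit.cause_model(1)
    cm2 = fit.cause_model(2)
    x1 = _profile(x, cm1.covariates)
    x2 = _profile(x, cm2.covariates)
    F1 = cause_cdf(times, x1, cm1)
    F2 = cause_cdf(times, x2, cm2)
    if np.any(F1 + F2 > 1.0 + 1e-9):
        raise ValueError("F1 + F2 exceeds 1 on the requested grid: invalid profile")
    return F1, F2


def _profile(x, covariates) -> np.ndarray:
    if not covariates:
        return np.zeros(0)
    if x is None:
        return np.zeros(len(covariates))
    missing = [c for c in covariates if c not in x]
    if missing:
        raise KeyError(f"profile missing covariate(s): {missing}")
    return np.array([float(x[c]) for c in covariates])
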