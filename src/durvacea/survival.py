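"""Parametric survival distributions for extrapolating trial curves.

Six families are supported: exponential, Weibull, log-normal, log-logistic,
Gompertz and generalized gamma.  The generalized gamma uses the Prentice
(location/scale/signed-shape) parameterization

    w = (ln t - mu) / sigma,   gamma = Q**-2,   u = gamma * exp(Q * w)

    S(t) = P(gamma, u)      for Q < 0
         = 1 - P(gamma, u)  for Q > 0

with ``P`` the regularized lower incomplete gamma function.  This family
nests the Weibull (Q = 1) and, in the limit Q -> 0, the log-normal.  All
times are in months; calendar days convert at 30.4375 days per month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

DAYS_PER_MONTH = 30.4375

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz", "gengamma")

#: number of free parameters per family
N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
    "gengamma": 3,
}


class SurvivalModelError(ValueError):
    """Raised for invalid parameters or out-of-domain evaluations."""


@dataclass(frozen=True)
class SurvivalCurve:
    """A parametric survival curve.

    Parameters by family (all scales/times in months):

    - exponential: ``(rate,)``
    - weibull: ``(shape, scale)`` with S(t) = exp(-(t/scale)**shape)
    - lognormal: ``(mu, sigma)`` on the log-time scale
    - loglogistic: ``(shape, scale)`` with S(t) = 1/(1 + (t/scale)**shape)
    - gompertz: ``(shape, rate)`` with h(t) = rate * exp(shape * t); the
      shape may be negative (decreasing hazard, defective distribution)
    - gengamma: ``(mu, sigma, q)`` in the Prentice form described in the
      module docstring; ``q`` is the *signed* shape
    """

    family: str
    params: tuple
    time_unit: str = "months"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SurvivalModelError(f"unknown family {self.family!r}")
        if self.time_unit != "months":
            raise SurvivalModelError("months is the canonical time unit")
        p = tuple(float(x) for x in self.params)
        if len(p) != N_PARAMS[self.family]:
            raise SurvivalModelError(
                f"{self.family} takes {N_PARAMS[self.family]} parameters, got {len(p)}"
            )
        if not all(math.isfinite(x) for x in p):
            raise SurvivalModelError("non-finite parameters")
        if self.family == "exponential" and p[0] <= 0:
            raise SurvivalModelError("exponential rate must be > 0")
        if self.family in ("weibull", "loglogistic") and (p[0] <= 0 or p[1] <= 0):
            raise SurvivalModelError(f"{self.family} shape and scale must be > 0")
        if self.family == "lognormal" and p[1] <= 0:
            raise SurvivalModelError("lognormal sigma must be > 0")
        if self.family == "gompertz" and p[1] <= 0:
            raise SurvivalModelError("gompertz rate must be > 0")
        if self.family == "gengamma":
            if p[1] <= 0:
                raise SurvivalModelError("gengamma sigma must be > 0")
            if p[2] == 0:
                raise SurvivalModelError("gengamma q must be nonzero (q -> 0 is log-normal)")
        object.__setattr__(self, "params", p)


def _as_array(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise SurvivalModelError("negative time")
    return arr


def survival(curve: SurvivalCurve, t) -> np.ndarray | float:
    """S(t) for scalar or array ``t`` (months); S(0) = 1 for every family."""
    arr = _as_array(t)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.ones_like(arr)
    pos = arr > 0
    tp = arr[pos]
    p = curve.params
    if curve.family == "exponential":
        out[pos] = np.exp(-p[0] * tp)
    elif curve.family == "weibull":
        out[pos] = np.exp(-((tp / p[1]) ** p[0]))
    elif curve.family == "lognormal":
        out[pos] = stats.norm.sf((np.log(tp) - p[0]) / p[1])
    elif curve.family == "loglogistic":
        out[pos] = 1.0 / (1.0 + (tp / p[1]) ** p[0])
    elif curve.family == "gompertz":
        a, b = p
        if a == 0:
            out[pos] = np.exp(-b * tp)
        else:
            out[pos] = np.exp(-b / a * np.expm1(a * tp))
    elif curve.family == "gengamma":
        mu, sigma, q = p
        gam = q**-2
        u = gam * np.exp(q * (np.log(tp) - mu) / sigma)
        out[pos] = special.gammainc(gam, u) if q < 0 else special.gammaincc(gam, u)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def density(curve: SurvivalCurve, t) -> np.ndarray | float:
    """Probability density f(t); t must be > 0."""
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr <= 0):
        raise SurvivalModelError("density requires t > 0")
    ll = log_density(curve, arr)
    out = np.exp(ll)
    return float(out[0]) if np.ndim(t) == 0 else out


def log_density(curve: SurvivalCurve, t: np.ndarray) -> np.ndarray:
    tp = np.asarray(t, dtype=float)
    p = curve.params
    if curve.family == "exponential":
        return np.log(p[0]) - p[0] * tp
    if curve.family == "weibull":
        k, lam = p
        z = tp / lam
        return np.log(k / lam) + (k - 1) * np.log(z) - z**k
    if curve.family == "lognormal":
        mu, sig = p
        z = (np.log(tp) - mu) / sig
        return -np.log(tp * sig * math.sqrt(2 * math.pi)) - 0.5 * z**2
    if curve.family == "loglogistic":
        k, lam = p
        z = (tp / lam) ** k
        return np.log(k / lam) + (k - 1) * np.log(tp / lam) - 2 * np.log1p(z)
    if curve.family == "gompertz":
        a, b = p
        if a == 0:
            return np.log(b) - b * tp
        return np.log(b) + a * tp - b / a * np.expm1(a * tp)
    # gengamma (Prentice): density of w = (ln t - mu)/sigma transformed back
    mu, sig, q = p
    gam = q**-2
    w = (np.log(tp) - mu) / sig
    # log f(t) = log|q| + gam*log(gam) + gam*q*w - gam*exp(q*w) - lgamma(gam) - log(sigma*t)
    return (
        math.log(abs(q))
        + gam * math.log(gam)
        + gam * q * w
        - gam * np.exp(q * w)
        - special.gammaln(gam)
        - np.log(sig * tp)
    )


def hazard(curve: SurvivalCurve, t) -> np.ndarray | float:
    """Instantaneous hazard h(t) = f(t)/S(t); requires t > 0 and S(t) > 0."""
    s = survival(curve, t)
    if np.any(np.atleast_1d(s) <= 1e-300):
        raise SurvivalModelError("hazard undefined where S(t) = 0")
    return density(curve, t) / s


def conditional_transition_prob(curve: SurvivalCurve, t0: float, t1: float) -> float:
    """Probability of the event in (t0, t1] given survival to t0: 1 - S(t1)/S(t0)."""
    if not (0 <= t0 < t1):
        raise SurvivalModelError(f"need 0 <= t0 < t1, got {t0}, {t1}")
    s0 = survival(curve, t0)
    if s0 <= 0:
        import warnings

        warnings.warn("S(t0) = 0; conditional transition probability set to 1")
        return 1.0
    p = 1.0 - survival(curve, t1) / s0
    return float(min(max(p, 0.0), 1.0))


def median_survival(curve: SurvivalCurve, upper: float = 1e6) -> float:
    """Root of S(t) = 0.5 by bracketed root-finding; ``inf`` if never reached."""
    if survival(curve, upper) > 0.5:
        return math.inf
    lo, hi = 0.0, upper
    # shrink the bracket: find a finite lo with S(lo) > 0.5
    t = 1.0
    while t < upper and survival(curve, t) > 0.5:
        lo, t = t, t * 4
    hi = min(t, upper)
    return float(optimize.brentq(lambda x: survival(curve, x) - 0.5, lo, hi, rtol=1e-10))


# ---------------------------------------------------------------------------
# censored maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IPDRecord:
    """One individual patient datum: time in months, event flag (1) or censored (0)."""

    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise SurvivalModelError("time must be >= 0")
        if self.event not in (0, 1):
            raise SurvivalModelError("event must be 0 or 1")


@dataclass
class FitResult:
    curve: SurvivalCurve
    loglik: float
    aic: float
    bic: float
    n: int
    covariance: np.ndarray | None = None
    converged: bool = True
    message: str = ""
    #: data fingerprint (n, total time, events) used to guard select_best
    data_key: tuple = field(default=())

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.curve.family]

    def stderr(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        d = np.diag(self.covariance)
        if np.any(d < 0):
            return None
        return np.sqrt(d)


def _records_to_arrays(data: Iterable[IPDRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(data)
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=int)
    return t, e


# internal <-> natural parameter transforms for unconstrained optimization
def _to_internal(family: str, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float).copy()
    if family == "exponential":
        return np.log(p)
    if family in ("weibull", "loglogistic"):
        return np.log(p)
    if family == "lognormal":
        return np.array([p[0], math.log(p[1])])
    if family == "gompertz":
        return np.array([p[0], math.log(p[1])])
    return np.array([p[0], math.log(p[1]), p[2]])  # gengamma: q free


def _from_internal(family: str, x: np.ndarray) -> tuple:
    if family == "exponential":
        return (math.exp(x[0]),)
    if family in ("weibull", "loglogistic"):
        return (math.exp(x[0]), math.exp(x[1]))
    if family == "lognormal":
        return (x[0], math.exp(x[1]))
    if family == "gompertz":
        return (x[0], math.exp(x[1]))
    return (x[0], math.exp(x[1]), x[2])


def _initial_guess(family: str, t: np.ndarray, e: np.ndarray) -> np.ndarray:
    tt = np.maximum(t, 1e-6)
    logt = np.log(tt)
    mu0, sd0 = float(logt.mean()), float(max(logt.std(), 0.1))
    mean_t = float(tt.mean())
    rate0 = max(e.sum(), 1) / float(t.sum() + 1e-12)
    if family == "exponential":
        return np.array([rate0])
    if family == "weibull":
        return np.array([1.2 / sd0, math.exp(mu0)])
    if family == "lognormal":
        return np.array([mu0, sd0])
    if family == "loglogistic":
        return np.array([1.5 / sd0, math.exp(mu0)])
    if family == "gompertz":
        return np.array([0.01, rate0])
    return np.array([mu0, sd0, 1.0])


def _negloglik(family: str, x: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    try:
        curve = SurvivalCurve(family, _from_internal(family, x))
    except (SurvivalModelError, OverflowError):
        return 1e12
    with np.errstate(all="ignore"):
        tt = np.maximum(t, 1e-9)
        ll = np.where(
            e == 1,
            log_density(curve, tt),
            np.log(np.maximum(np.atleast_1d(survival(curve, tt)), 1e-300)),
        )
    total = float(np.sum(ll))
    if not math.isfinite(total):
        return 1e12
    return -total


def fit_parametric(
    data: Sequence[IPDRecord], family: str, n_starts: int = 5, seed: int = 0
) -> FitResult:
    """Fit one family to right-censored data by maximum likelihood.

    Uses multi-start Nelder-Mead/BFGS on log-transformed positive parameters;
    the covariance comes from the inverse observed information (finite-
    difference Hessian at the optimum).  Non-convergence is reported on the
    result, never silently.
    """
    if family not in FAMILIES:
        raise SurvivalModelError(f"unknown family {family!r}")
    t, e = _records_to_arrays(data)
    if len(t) < 10:
        raise SurvivalModelError("need at least 10 records")
    if e.sum() < 1:
        raise SurvivalModelError("all records censored; nothing to fit")

    x0 = _to_internal(family, _initial_guess(family, t, e))
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        start = x0 if k == 0 else x0 + rng.normal(scale=0.4, size=x0.shape)
        res = optimize.minimize(
            lambda x: _negloglik(family, x, t, e),
            start,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and best.fun < 1e11
    curve = SurvivalCurve(family, _from_internal(family, best.x))
    loglik = -float(best.fun)
    p = N_PARAMS[family]
    n = len(t)
    aic = 2 * p - 2 * loglik
    bic = p * math.log(n) - 2 * loglik

    cov = _covariance_natural(family, best.x, t, e)
    return FitResult(
        curve=curve,
        loglik=loglik,
        aic=aic,
        bic=bic,
        n=n,
        covariance=cov,
        converged=converged,
        message="" if converged else "optimizer did not converge",
        data_key=(n, round(float(t.sum()), 6), int(e.sum())),
    )


def _covariance_natural(family, x_opt, t, e) -> np.ndarray | None:
    """Covariance of the *natural* parameters via the delta method."""
    try:
        from statsmodels.tools.numdiff import approx_hess1

        hess = approx_hess1(x_opt, lambda x: _negloglik(family, x, t, e))
        cov_internal = np.linalg.inv(hess)
        # jacobian of natural w.r.t. internal params (diagonal by construction)
        nat = np.array(_from_internal(family, x_opt))
        jac = np.ones_like(nat)
        if family == "exponential":
            jac[0] = nat[0]
        elif family in ("weibull", "loglogistic"):
            jac[:] = nat
        elif family in ("lognormal", "gompertz"):
            jac[1] = nat[1]
        else:  # gengamma
            jac[1] = nat[1]
        cov = cov_internal * np.outer(jac, jac)
        if not np.all(np.isfinite(cov)):
            return None
        return cov
    except Exception:
        return None


def select_best(fits: Sequence[FitResult], criterion: str = "aic") -> FitResult:
    """Minimum-AIC/BIC fit; ties broken by fewer parameters then family order."""
    fits = list(fits)
    if not fits:
        raise SurvivalModelError("empty fit list")
    if criterion not in ("aic", "bic"):
        raise SurvivalModelError("criterion must be 'aic' or 'bic'")
    keys = {f.data_key for f in fits if f.data_key}
    if len(keys) > 1:
        raise SurvivalModelError("fits were computed on different datasets")
    return min(
        fits,
        key=lambda f: (
            round(getattr(f, criterion), 10),
            f.n_params,
            FAMILIES.index(f.curve.family),
        ),
    )


def read_ipd_csv(path) -> list[IPDRecord]:
    """Read `time,event` CSV (header required, times in months)."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"time", "event"}.issubset(df.columns):
        raise SurvivalModelError("IPD CSV must have columns time,event")
    return [IPDRecord(float(r.time), int(r.event)) for r in df.itertuples()]


def write_ipd_csv(records: Sequence[IPDRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"time": [r.time for r in records], "event": [r.event for r in records]}
    ).to_csv(path, index=False)
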