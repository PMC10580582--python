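"""Parametric survival distributions for extrapolating trial curves.

Six families are supported, in the parameterizations conventional for
health-economic survival extrapolation (time unit: months):

====================  =========================================  ==========
family                survival function S(t)                     parameters
====================  =========================================  ==========
``exponential``       ``exp(-lambda*t)``                         rate ``lambda``
``weibull_ph``        ``exp(-lambda*t**gamma)``                  rate ``lambda``, shape ``gamma``
``log_logistic``      ``1 / (1 + (t/lambda)**gamma)``            scale ``lambda``, shape ``gamma``
``log_normal``        ``1 - Phi((ln t - lambda)/gamma)``         log-location ``lambda``, log-sd ``gamma``
``gompertz``          ``exp(-(lambda/gamma)*(exp(gamma*t)-1))``  rate ``lambda``, shape ``gamma``
``gamma``             ``1 - P(gamma, lambda*t)``                 rate ``lambda``, shape ``gamma``
====================  =========================================  ==========

``weibull_ph`` is the proportional-hazards form of the Weibull (cumulative
hazard ``lambda * t**gamma``), not the accelerated-failure-time form.
``P`` is the regularized lower incomplete gamma function.

Maximum-likelihood fitting to right-censored data and AIC/BIC scoring live
here too (:func:`fit_mle`); model selection over all six families is in
:mod:`psmcea.reconstruct`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "FitResult",
    "fit_mle",
]

FAMILIES = (
    "exponential",
    "weibull_ph",
    "log_logistic",
    "log_normal",
    "gompertz",
    "gamma",
)

#: Families whose lambda parameter may be any real number (log-scale location).
_LAMBDA_FREE = frozenset({"log_normal"})

#: Shape below which a Gompertz collapses to an exponential to avoid overflow.
_GOMPERTZ_EPS = 1e-8


@dataclass(frozen=True)
class ParametricSurvival:
    """A fitted or asserted survival-time distribution in months.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    lambda_:
        Rate, scale or log-location parameter, depending on the family.
    gamma_:
        Shape (or log-sd) parameter; ignored for the exponential.
    """

    family: str
    lambda_: float
    gamma_: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        if self.family == "exponential":
            if self.gamma_ is not None:
                object.__setattr__(self, "gamma_", None)
            if not self.lambda_ > 0:
                raise ValueError("exponential requires lambda_ > 0")
            return
        if self.gamma_ is None or not self.gamma_ > 0:
            raise ValueError(f"{self.family} requires gamma_ > 0")
        if self.family not in _LAMBDA_FREE and not self.lambda_ > 0:
            raise ValueError(f"{self.family} requires lambda_ > 0")

    # -- evaluation -----------------------------------------------------

    def survival(self, t):
        """S(t); vectorized over ``t`` (months). Negative times are an error."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival is defined for t >= 0 only")
        lam, gam = self.lambda_, self.gamma_
        if self.family == "exponential":
            out = np.exp(-lam * t)
        elif self.family == "weibull_ph":
            out = np.exp(-lam * np.power(t, gam))
        elif self.family == "log_logistic":
            with np.errstate(divide="ignore"):
                out = 1.0 / (1.0 + np.power(t / lam, gam))
        elif self.family == "log_normal":
            with np.errstate(divide="ignore"):
                z = (np.log(np.where(t > 0, t, 1.0)) - lam) / gam
            out = np.where(t > 0, stats.norm.sf(z), 1.0)
        elif self.family == "gompertz":
            if abs(gam) < _GOMPERTZ_EPS:
                out = np.exp(-lam * t)
            else:
                out = np.exp(-(lam / gam) * np.expm1(gam * t))
        else:  # gamma
            out = special.gammaincc(gam, lam * t)
        return out if out.ndim else float(out)

    def hazard(self, t):
        """Instantaneous hazard h(t) = f(t)/S(t)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("hazard is defined for t >= 0 only")
        lam, gam = self.lambda_, self.gamma_
        if self.family == "exponential":
            out = np.full_like(t, lam)
        elif self.family == "weibull_ph":
            out = lam * gam * np.power(t, gam - 1.0)
        elif self.family == "log_logistic":
            out = (gam / lam) * np.power(t / lam, gam - 1.0) / (
                1.0 + np.power(t / lam, gam)
            )
        elif self.family == "log_normal":
            z = (np.log(t) - lam) / gam
            out = stats.norm.pdf(z) / (t * gam * stats.norm.sf(z))
        elif self.family == "gompertz":
            out = lam * np.exp(gam * t) if abs(gam) >= _GOMPERTZ_EPS else np.full_like(t, lam)
        else:  # gamma
            out = np.exp(self._log_pdf(t)) / special.gammaincc(gam, lam * t)
        out = np.asarray(out, dtype=float)
        return out if out.ndim else float(out)

    def _log_pdf(self, t):
        """log f(t) for event contributions to the likelihood."""
        t = np.asarray(t, dtype=float)
        lam, gam = self.lambda_, self.gamma_
        with np.errstate(divide="ignore"):
            logt = np.log(t)
        if self.family == "exponential":
            return math.log(lam) - lam * t
        if self.family == "weibull_ph":
            return math.log(lam * gam) + (gam - 1.0) * logt - lam * np.power(t, gam)
        if self.family == "log_logistic":
            # f = (g/l)(t/l)^(g-1) / (1+(t/l)^g)^2
            u = gam * (logt - math.log(lam))
            return (
                math.log(gam / lam)
                + (gam - 1.0) * (logt - math.log(lam))
                - 2.0 * np.logaddexp(0.0, u)
            )
        if self.family == "log_normal":
            z = (logt - lam) / gam
            return stats.norm.logpdf(z) - logt - math.log(gam)
        if self.family == "gompertz":
            if abs(gam) < _GOMPERTZ_EPS:
                return math.log(lam) - lam * t
            return math.log(lam) + gam * t - (lam / gam) * np.expm1(gam * t)
        # gamma
        return (
            gam * math.log(lam)
            + (gam - 1.0) * logt
            - lam * t
            - special.gammaln(gam)
        )

    def _log_sf(self, t):
        """log S(t) for censored contributions to the likelihood."""
        t = np.asarray(t, dtype=float)
        lam, gam = self.lambda_, self.gamma_
        if self.family == "exponential":
            return -lam * t
        if self.family == "weibull_ph":
            return -lam * np.power(t, gam)
        if self.family == "log_logistic":
            with np.errstate(divide="ignore"):
                u = gam * (np.log(t) - math.log(lam))
            return -np.logaddexp(0.0, u)
        if self.family == "log_normal":
            with np.errstate(divide="ignore"):
                z = (np.log(t) - lam) / gam
            return stats.norm.logsf(z)
        if self.family == "gompertz":
            if abs(gam) < _GOMPERTZ_EPS:
                return -lam * t
            return -(lam / gam) * np.expm1(gam * t)
        with np.errstate(divide="ignore"):
            return np.log(special.gammaincc(gam, lam * t))

    # -- summaries ------------------------------------------------------

    def median(self) -> float:
        """Time t with S(t) = 1/2, in months (closed form per family)."""
        lam, gam = self.lambda_, self.gamma_
        if self.family == "exponential":
            return math.log(2.0) / lam
        if self.family == "weibull_ph":
            return (math.log(2.0) / lam) ** (1.0 / gam)
        if self.family == "log_logistic":
            return lam
        if self.family == "log_normal":
            return math.exp(lam)
        if self.family == "gompertz":
            if abs(gam) < _GOMPERTZ_EPS:
                return math.log(2.0) / lam
            arg = 1.0 + gam * math.log(2.0) / lam
            if arg <= 0:  # plateau above 1/2: no finite median
                return math.inf
            return math.log(arg) / gam
        return float(special.gammaincinv(gam, 0.5)) / lam

    def ppf_survival(self, u):
        """Inverse survival: the time t with S(t) = u (for simulation)."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u > 1)):
            raise ValueError("survival quantile requires 0 < u <= 1")
        lam, gam = self.lambda_, self.gamma_
        if self.family == "exponential":
            out = -np.log(u) / lam
        elif self.family == "weibull_ph":
            out = np.power(-np.log(u) / lam, 1.0 / gam)
        elif self.family == "log_logistic":
            out = lam * np.power(1.0 / u - 1.0, 1.0 / gam)
        elif self.family == "log_normal":
            out = np.exp(lam + gam * stats.norm.isf(u))
        elif self.family == "gompertz":
            if abs(gam) < _GOMPERTZ_EPS:
                out = -np.log(u) / lam
            else:
                out = np.log1p(-(gam / lam) * np.log(u)) / gam
        else:  # gamma
            out = special.gammainccinv(gam, u) / lam
        return out if out.ndim else float(out)

    @property
    def n_params(self) -> int:
        return 1 if self.family == "exponential" else 2


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family, with information criteria."""

    distribution: ParametricSurvival
    log_likelihood: float
    k: int
    n: int
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "aic", 2.0 * self.k - 2.0 * self.log_likelihood)
        object.__setattr__(
            self, "bic", self.k * math.log(self.n) - 2.0 * self.log_likelihood
        )


class FittingError(RuntimeError):
    """Raised when maximum-likelihood fitting cannot proceed or converge."""


def _neg_loglik(theta, family, times, events):
    """Negative right-censored log-likelihood on the unconstrained scale."""
    if family == "exponential":
        lam = math.exp(theta[0])
        dist = ParametricSurvival("exponential", lam)
    elif family == "log_normal":
        dist = ParametricSurvival("log_normal", theta[0], math.exp(theta[1]))
    else:
        dist = ParametricSurvival(family, math.exp(theta[0]), math.exp(theta[1]))
    with np.errstate(over="ignore", invalid="ignore"):
        ll = np.sum(dist._log_pdf(times[events])) + np.sum(
            dist._log_sf(times[~events])
        )
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def _starts(family, times, events):
    """Method-of-moments style multi-start points (unconstrained scale)."""
    ev = times[events]
    rate = max(len(ev), 1) / max(times.sum(), 1e-9)
    log_rate = math.log(rate)
    med = float(np.median(ev))
    if family == "weibull_ph":
        return [(log_rate, math.log(g)) for g in (0.5, 1.0, 2.0)]
    if family == "log_logistic":
        return [(math.log(max(med, 1e-6)), math.log(g)) for g in (0.5, 1.0, 2.0)]
    if family == "log_normal":
        mu = float(np.mean(np.log(ev[ev > 0]))) if np.any(ev > 0) else 0.0
        sd = float(np.std(np.log(ev[ev > 0]))) if np.sum(ev > 0) > 1 else 1.0
        return [(mu, math.log(max(sd, 0.1))), (mu, 0.0)]
    if family == "gompertz":
        return [(log_rate, math.log(g)) for g in (0.001, 0.02, 0.1)]
    if family == "gamma":
        m, v = float(np.mean(ev)), float(np.var(ev))
        if v > 0 and m > 0:
            shape, rate_g = m * m / v, m / v
        else:
            shape, rate_g = 1.0, rate
        return [
            (math.log(max(rate_g, 1e-9)), math.log(max(shape, 1e-3))),
            (log_rate, 0.0),
        ]
    return [(log_rate,)]


def fit_mle(family: str, times, events) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    times:
        Observed times in months (event or censoring), all >= 0.
    events:
        Boolean event indicators (True = event, False = right-censored).

    Returns
    -------
    FitResult
        Fitted distribution with log-likelihood, AIC and BIC.

    Notes
    -----
    The exponential fit is the closed form ``events / total exposure``.
    Other families are maximized with L-BFGS-B on log-transformed
    parameters, multi-started from moment-based initial values, which
    makes the result deterministic for a given data set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have matching shapes")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    n = times.size
    n_events = int(events.sum())
    if n_events < 2:
        raise FittingError(f"need at least 2 events to fit, got {n_events}")
    # Zero event times break log-time families; nudge onto the grid edge.
    times = np.where(times <= 0, 1e-6, times)

    if family == "exponential":
        lam = n_events / float(times.sum())
        dist = ParametricSurvival("exponential", lam)
        ll = float(
            np.sum(dist._log_pdf(times[events])) + np.sum(dist._log_sf(times[~events]))
        )
        return FitResult(dist, ll, 1, n)

    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")

    best = None
    for theta0 in _starts(family, times, events):
        res = optimize.minimize(
            _neg_loglik,
            np.asarray(theta0, dtype=float),
            args=(family, times, events),
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FittingError(f"MLE for family {family!r} did not converge")
    theta = best.x
    if family == "log_normal":
        dist = ParametricSurvival("log_normal", float(theta[0]), math.exp(theta[1]))
    else:
        dist = ParametricSurvival(family, math.exp(theta[0]), math.exp(theta[1]))
    return FitResult(dist, -float(best.fun), dist.n_params, n)
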