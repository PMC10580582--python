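"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published trial curves are only available as figures; this module rebuilds
patient-level (time, event) records from digitized curve coordinates plus
the number-at-risk table printed under the figure, following the iterative
interval-matching algorithm of Guyot and colleagues: within each risk-table
interval, censoring is assumed uniform, events are allocated to the
digitized survival drops, and the censoring count is adjusted until the
implied number at risk at the next interval boundary matches the table.

The product-limit estimate of the reconstructed data and the six-family
parametric fitting/selection used for extrapolation live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import FAMILIES, FitResult, FittingError, fit_mle

logger = logging.getLogger("psmcea")

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "PseudoIPD",
    "KMEstimate",
    "ReconstructionError",
    "reconstruct_ipd",
    "km_estimate",
    "select_distribution",
]

_MAX_PASSES = 100


class ReconstructionError(RuntimeError):
    """Raised when curve and risk table cannot be reconciled."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized (time, survival) coordinates of a published KM curve."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.size < 1 or t.size != s.size:
            raise ValueError("curve needs matching, non-empty time/survival arrays")
        if t[0] != 0 or s[0] != 1.0:
            raise ValueError("digitized curve must start at (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12) or np.any((s < 0) | (s > 1)):
            raise ValueError("digitized survival must be non-increasing in [0, 1]")

    @classmethod
    def read(cls, path) -> "DigitizedCurve":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def write(self, path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class RiskTable:
    """Number-at-risk table printed under a published KM curve."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.size < 1 or t.size != n.size:
            raise ValueError("risk table needs matching, non-empty arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(n) > 0):
            raise ValueError("number at risk may not increase over time")
        if np.any(n < 0):
            raise ValueError("number at risk must be >= 0")

    @classmethod
    def read(cls, path) -> "RiskTable":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def write(self, path) -> None:
        pd.DataFrame({"time": self.times, "n_at_risk": self.n_at_risk}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed patient records: observed time and event flag."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=bool)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.size != e.size:
            raise ValueError("times and events must have matching lengths")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def read(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy().astype(bool))

    def write(self, path) -> None:
        pd.DataFrame(
            {"time": self.times, "event": self.events.astype(int)}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit step function with per-step risk/event counts."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t) -> np.ndarray:
        """Right-continuous step evaluation of S(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)


def km_estimate(ipd: PseudoIPD) -> KMEstimate:
    """Kaplan-Meier product-limit estimate of a pseudo-IPD set."""
    if len(ipd) == 0:
        raise ValueError("cannot estimate a survival curve from no records")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return KMEstimate(
        times=tab.index.to_numpy(dtype=float),
        survival=surv,
        n_at_risk=tab["at_risk"].to_numpy(dtype=int),
        n_events=tab["observed"].to_numpy(dtype=int),
    )


def reconstruct_ipd(
    curve: DigitizedCurve, risk: RiskTable | None, n0: int | None = None
) -> PseudoIPD:
    """Rebuild pseudo-IPD from a digitized curve and a number-at-risk table.

    Within each risk-table interval the censoring count is first guessed
    from the KM identity, censoring times are spread uniformly, events are
    allocated to the digitized survival drops, and the censoring count is
    iterated (at most 100 passes) until the implied number at risk at the
    next boundary equals the table entry.  Beyond the last risk-table time
    no censoring is assumed; patients still at risk at the end of the curve
    are censored there.

    When ``risk`` is None, the no-censoring variant is used: an initial arm
    size ``n0`` must be given, every drop is treated as events and survivors
    are censored at the last digitized time (logged as a warning).
    """
    t = curve.times
    s = curve.survival
    if risk is None:
        if n0 is None:
            raise ValueError(
                "reconstruction without a risk table requires the initial arm size n0"
            )
        logger.warning(
            "no risk table supplied: assuming no censoring before last follow-up"
        )
        risk = RiskTable(np.array([t[0]]), np.array([int(n0)]))
    if risk.times[0] > t[0]:
        raise ReconstructionError("risk table must cover the start of the curve")

    n0 = int(risk.n_at_risk[0])
    # Interval i spans the digitized points in (b_i, b_{i+1}]: the point
    # sitting exactly on a risk-table time carries the drops just before it,
    # so it is processed before comparing with that boundary's at-risk count
    # (at-risk is read as "still under observation just after the boundary").
    bounds = list(risk.times) + [t[-1] + 1.0]
    edges = [0] + [
        int(np.searchsorted(t, b, side="right")) for b in bounds[1:-1]
    ] + [t.size]

    event_times: list[float] = []
    censor_times: list[float] = []
    n_hat = float(n0)
    km_prev = 1.0          # reconstructed KM value at the last event so far
    s_prev = 1.0           # digitized survival at the last processed point

    for i in range(len(risk.times)):
        lo, hi = edges[i], edges[i + 1]
        if lo >= hi:
            continue
        last_interval = i == len(risk.times) - 1
        if last_interval:
            n_target = None
            n_censor = 0  # no censoring assumed beyond the last risk time
        else:
            n_target = int(risk.n_at_risk[i + 1])
            # first guess from the KM identity S_next/S_now ~ n_next/n_now
            ratio = s[hi - 1] / max(s_prev, 1e-12)
            n_censor = int(round(n_hat * ratio - n_target))
            n_censor = max(0, min(n_censor, int(n_hat)))

        t_start = bounds[i]
        t_end = bounds[i + 1]
        for _pass in range(_MAX_PASSES):
            ev_i: list[float] = []
            cen_i: list[float] = []
            n_run = n_hat
            km_run = km_prev
            s_run = s_prev
            if n_censor > 0:
                cen_t = t_start + (np.arange(1, n_censor + 1)) * (
                    t_end - t_start
                ) / (n_censor + 1)
            else:
                cen_t = np.empty(0)
            for k in range(lo, hi):
                if n_run < 0.5:
                    break
                # events at this digitized drop
                d_k = int(round(n_run * (1.0 - s[k] / max(km_run, 1e-12))))
                d_k = max(0, min(d_k, int(round(n_run))))
                if d_k > 0:
                    km_run *= 1.0 - d_k / n_run
                    ev_i.extend([float(t[k])] * d_k)
                # censoring allocated to this digitized step; the first step
                # also absorbs censor times before its grid point
                w_lo = t_start if k == lo else t[k]
                t_next = t[k + 1] if k + 1 < hi else np.inf
                in_step = (cen_t >= w_lo) & (cen_t < t_next)
                c_k = min(int(np.sum(in_step)), int(round(n_run)) - d_k)
                if c_k > 0:
                    cen_i.extend([float(c) for c in cen_t[in_step][:c_k]])
                n_run -= d_k + c_k
                s_run = s[k]
            if n_target is None:
                break
            diff = int(round(n_run)) - n_target
            if diff == 0:
                break
            n_censor += diff
            if n_censor < 0 or n_censor > n_hat:
                raise ReconstructionError(
                    f"interval {i} ({risk.times[i]:g} months): cannot reconcile "
                    f"curve with risk table (implied censor count {n_censor})"
                )
        else:
            raise ReconstructionError(
                f"interval {i} did not converge after {_MAX_PASSES} passes"
            )
        event_times.extend(ev_i)
        censor_times.extend(cen_i)
        n_hat = n_run
        km_prev = km_run
        s_prev = s_run

    # survivors at the end of follow-up are administratively censored there
    n_left = int(round(n_hat))
    censor_times.extend([float(t[-1])] * n_left)

    times = np.array(event_times + censor_times, dtype=float)
    events = np.array(
        [True] * len(event_times) + [False] * len(censor_times), dtype=bool
    )
    order = np.argsort(times, kind="stable")
    ipd = PseudoIPD(times[order], events[order])
    if len(ipd) != n0:
        raise ReconstructionError(
            f"reconstructed {len(ipd)} records for an initial arm size of {n0}"
        )
    return ipd


def select_distribution(ipd: PseudoIPD) -> list[FitResult]:
    """Fit all six parametric families and rank them by AIC.

    Ties are broken by BIC, then family name.  Families whose fit fails are
    excluded with a warning.  Raises :class:`~psmcea.survival.FittingError`
    when fewer than two events are available.
    """
    if ipd.n_events < 2:
        raise FittingError(
            f"model selection requires >= 2 events, got {ipd.n_events}"
        )
    results = []
    for family in FAMILIES:
        try:
            results.append(fit_mle(family, ipd.times, ipd.events))
        except (FittingError, ValueError) as exc:
            warnings.warn(f"family {family!r} excluded from ranking: {exc}", stacklevel=2)
    if not results:
        raise FittingError("no parametric family could be fitted")
    results.sort(key=lambda r: (r.aic, r.bic, r.distribution.family))
    return results
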