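"""One-way (tornado), threshold and probabilistic sensitivity analyses.

The one-way analysis re-runs the deterministic model at each parameter's
range extremes; the threshold search bisects a single price until the ICER
meets a willingness-to-pay target; the probabilistic analysis is a
second-order Monte Carlo over the economic parameters (survival-curve
parameters are held fixed, as their published ranges are not reported),
summarized as cost-effectiveness acceptability curves.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParamRange, RunConfig, get_param, set_param_inplace, with_param
from .model import run_cea

__all__ = [
    "TornadoRow",
    "NoCrossingError",
    "owsa",
    "threshold_price",
    "psa_run",
    "ceac",
]


@dataclass(frozen=True)
class TornadoRow:
    """ICER at a parameter's range extremes; spread orders the tornado."""

    param_id: str
    base: float
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


class NoCrossingError(RuntimeError):
    """The ICER does not cross the target anywhere in the search bracket."""


def owsa(
    cfg: RunConfig, population: str, ranges: tuple | None = None
) -> list[TornadoRow]:
    """One-way sensitivity analysis: vary each parameter to its extremes.

    Returns rows sorted by descending ICER spread (tornado order).
    Parameters whose range collapses to the base value yield zero spread.
    """
    rows = []
    for pr in ranges if ranges is not None else cfg.ranges:
        if not isinstance(pr, ParamRange):
            raise TypeError("ranges must contain ParamRange entries")
        icers = {}
        for label, value in (("low", pr.low), ("high", pr.high)):
            if value == pr.base:
                icers[label] = run_cea(cfg, population).icer
            else:
                icers[label] = run_cea(with_param(cfg, pr.param_id, value), population).icer
        rows.append(
            TornadoRow(pr.param_id, pr.base, pr.low, pr.high, icers["low"], icers["high"])
        )
    rows.sort(key=lambda r: -r.spread)
    return rows


def threshold_price(
    cfg: RunConfig,
    population: str,
    param_id: str,
    target_icer: float,
    tol: float = 1.0,
) -> float:
    """Price at which the ICER crosses ``target_icer``, by bisection.

    Searches ``[0, 4 x base]``, doubling the upper bound (up to 64 x base)
    until the ICER-minus-target changes sign, then bisects to
    ``|ICER - target| < tol`` (USD/QALY).  Raises :class:`NoCrossingError`
    when no sign change exists in the widest bracket.
    """
    base = get_param(cfg, param_id)

    def f(value: float) -> float:
        return run_cea(with_param(cfg, param_id, value), population).icer - target_icer

    lo, hi = 0.0, 4.0 * base if base > 0 else 1.0
    f_lo = f(lo)
    if abs(f_lo) < tol:
        return lo
    f_hi = f(hi)
    while f_lo * f_hi > 0 and hi < 64.0 * max(base, 1.0):
        hi *= 2.0
        f_hi = f(hi)
    if f_lo * f_hi > 0:
        raise NoCrossingError(
            f"ICER does not cross {target_icer:,.0f} for {param_id!r} in "
            f"[0, {hi:g}] (f({lo:g})={f_lo:,.0f}, f({hi:g})={f_hi:,.0f})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _sample_one(pr: ParamRange, rng: np.random.Generator) -> float:
    """Draw one parameter from its PSA family.

    Beta and gamma use method-of-moments with sd = (high - low)/3.92 (the
    range read as a 95% interval); uniform spans [low, high]; fixed returns
    the base value.
    """
    if pr.psa_family == "fixed" or pr.high == pr.low:
        return pr.base
    sd = (pr.high - pr.low) / 3.92
    m = pr.base
    if pr.psa_family == "uniform":
        return float(rng.uniform(pr.low, pr.high))
    if pr.psa_family == "beta":
        if m <= 0.0 or m >= 1.0:
            return m  # degenerate mean: nothing to sample
        nu = m * (1.0 - m) / sd**2 - 1.0
        if nu <= 0:
            return float(rng.uniform(pr.low, pr.high))
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if pr.psa_family == "gamma_dist":
        if m <= 0:
            return m
        shape = (m / sd) ** 2
        scale = sd**2 / m
        return float(rng.gamma(shape, scale))
    raise ValueError(f"unknown PSA family {pr.psa_family!r}")


def psa_run(
    cfg: RunConfig,
    population: str,
    n_iter: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Second-order Monte Carlo PSA: one row per iteration.

    Each iteration draws every non-fixed parameter from its PSA family,
    re-runs both arms deterministically, and records the incremental cost
    and QALYs.  A single RNG stream seeded from ``seed`` makes the run
    bit-reproducible.  Columns: ``iteration``, every sampled parameter id,
    ``delta_cost``, ``delta_qaly``.
    """
    n_iter = n_iter if n_iter is not None else cfg.psa_iterations
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    seed = seed if seed is not None else cfg.psa_seed
    rng = np.random.default_rng(seed)

    records = []
    for it in range(n_iter):
        draw = copy.deepcopy(cfg)
        row = {"iteration": it}
        for pr in cfg.ranges:
            value = _sample_one(pr, rng)
            row[pr.param_id] = value
            if value != pr.base:
                set_param_inplace(draw, pr.param_id, value)
        res = run_cea(draw, population)
        row["delta_cost"] = res.delta_cost
        row["delta_qaly"] = res.delta_qaly
        records.append(row)
    return pd.DataFrame.from_records(records)


def ceac(samples: pd.DataFrame, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA samples.

    At each willingness-to-pay value the probability is the fraction of
    iterations with positive incremental net monetary benefit
    (``wtp * delta_qaly - delta_cost > 0``).  Default grid: 0 to 400,000
    USD/QALY in 1,000-unit steps.
    """
    if len(samples) == 0:
        raise ValueError("CEAC requires at least one PSA sample")
    wtp = (
        np.asarray(wtp_grid, dtype=float)
        if wtp_grid is not None
        else np.arange(0.0, 400_001.0, 1000.0)
    )
    dq = samples["delta_qaly"].to_numpy()[:, None]
    dc = samples["delta_cost"].to_numpy()[:, None]
    nmb = wtp[None, :] * dq - dc
    prob = (nmb > 0).mean(axis=0)
    return pd.DataFrame({"wtp": wtp, "probability": prob})
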