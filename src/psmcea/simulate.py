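"""Synthetic trial arms with the statistical structure the analysis assumes.

No patient-level data from the underlying trial are available, so every
stage that consumes survival data (reconstruction, fitting, selection) is
exercised against simulated arms: event times drawn from the base-case
parametric curves by inverse transform, uniform accrual over an enrolment
window, and administrative censoring at a common data cut-off.  The default
window (18 months accrual, 36 months minimum follow-up) mirrors a phase-III
trial followed for at least three years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reconstruct import DigitizedCurve, PseudoIPD, RiskTable, km_estimate
from .survival import ParametricSurvival

__all__ = ["TrialSpec", "simulate_arm_ipd", "digitize_km", "make_checkmate_fixture"]

#: Arm sizes with OS curves in the published trial: (NI, C) per population.
ARM_SIZES = {"A": (303, 302), "E": (229, 226), "N": (74, 76)}


@dataclass(frozen=True)
class TrialSpec:
    """Design of the simulated trial used as the end-to-end test input."""

    arm_sizes: dict = field(default_factory=lambda: dict(ARM_SIZES))
    accrual_months: float = 18.0
    max_followup_months: float = 36.0
    seed: int = 743

    def __post_init__(self) -> None:
        if any(n < 1 for sizes in self.arm_sizes.values() for n in sizes):
            raise ValueError("arm sizes must be positive")
        if self.max_followup_months <= 0:
            raise ValueError("max follow-up must be positive")


def simulate_arm_ipd(
    dist: ParametricSurvival,
    n: int,
    accrual: float,
    max_followup: float,
    seed: int,
) -> PseudoIPD:
    """Simulate one arm's (time, event) records.

    Event times are drawn from ``dist`` by inverse transform; entry times
    are uniform over ``[0, accrual]``; a subject is administratively
    censored when the event falls beyond ``max_followup - entry``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    event_t = dist.ppf_survival(1.0 - u)  # S(t) ~ U(0,1) inverse transform
    entry = rng.uniform(0.0, accrual, size=n) if accrual > 0 else np.zeros(n)
    cens_t = np.maximum(max_followup - entry, 0.0)
    observed = np.minimum(event_t, cens_t)
    events = event_t <= cens_t
    return PseudoIPD(observed, events)


def digitize_km(
    ipd: PseudoIPD, grid_step: float = 1.0, risk_step: float = 3.0
):
    """Monthly digitization of an arm's KM curve plus a quarterly risk table.

    Emulates reading coordinates off a published figure at the resolution of
    the model's 1-month cycles.  Returns ``(DigitizedCurve, RiskTable)``.
    """
    km = km_estimate(ipd)
    t_max = float(ipd.times.max())
    grid = np.arange(0.0, t_max + grid_step, grid_step)
    curve = DigitizedCurve(grid, np.asarray(km.at(grid), dtype=float))
    risk_times = np.arange(0.0, t_max + 1e-9, risk_step)
    # at-risk just after each table time, matching the digitized curve level
    # at that time (which already includes the drops up to it)
    n_at_risk = np.array(
        [int(np.sum(ipd.times > rt)) for rt in risk_times], dtype=int
    )
    keep = n_at_risk > 0
    keep[0] = True
    return curve, RiskTable(risk_times[keep], n_at_risk[keep])


def make_checkmate_fixture(spec: TrialSpec, config=None) -> dict:
    """Simulate all six arm/population combinations from the base-case curves.

    Returns ``{(arm, population): {"ipd": PseudoIPD, "curve": DigitizedCurve,
    "risk": RiskTable, "truth": ParametricSurvival}}`` — the complete
    synthetic stand-in for the digitized trial figures.  OS curves are
    simulated per population; the shared PFS curves are keyed under
    population ``"PFS"``.
    """
    from .config import default_config

    cfg = config or default_config()
    out = {}
    sub = np.random.SeedSequence(spec.seed).spawn(8)
    idx = 0
    for arm_i, arm in enumerate(("NI", "C")):
        pfs, _ = cfg.arm_curves(arm, "A")
        n_pfs = spec.arm_sizes["A"][arm_i]
        out[(arm, "PFS")] = _one_arm(pfs, n_pfs, spec, sub[idx])
        idx += 1
        for pop in ("A", "E", "N"):
            _, os_ = cfg.arm_curves(arm, pop)
            n = spec.arm_sizes[pop][arm_i]
            out[(arm, pop)] = _one_arm(os_, n, spec, sub[idx])
            idx += 1
    return out


def _one_arm(dist, n, spec, seed_seq) -> dict:
    seed = int(seed_seq.generate_state(1)[0] % (2**31))
    ipd = simulate_arm_ipd(
        dist, n, spec.accrual_months, spec.max_followup_months, seed
    )
    curve, risk = digitize_km(ipd)
    return {"ipd": ipd, "curve": curve, "risk": risk, "truth": dist}
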