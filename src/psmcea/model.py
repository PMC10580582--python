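"""Run the full cost-effectiveness comparison for one population.

Glues the survival curves, the partitioned-survival trace and the cost
accruals together and reports per-arm totals plus the incremental
comparison (delta cost, delta QALY, ICER).
"""

from __future__ import annotations

from .config import RunConfig
from .costs import CostBreakdown, total_cost_trace
from .engine import ARMS, ArmModel, CEAResult, StateTrace, icer, run_trace

__all__ = ["run_arm", "run_cea"]


def run_arm(cfg: RunConfig, arm: str, population: str):
    """State trace and cost breakdown for one arm.

    Returns ``(ArmModel, StateTrace, CostBreakdown)``.
    """
    pfs, os_ = cfg.arm_curves(arm, population)
    model = ArmModel(arm, pfs, os_, population)
    trace = run_trace(model, cfg.engine, cfg.utilities)
    costs = total_cost_trace(
        model,
        trace,
        cfg.patient,
        cfg.prices,
        cfg.mix,
        cfg.engine,
        cfg.utilities.ae_incidences,
        cfg.first_line_durations,
    )
    return model, trace, costs


def run_cea(cfg: RunConfig, population: str) -> CEAResult:
    """Deterministic base-case comparison of NI vs C for one population."""
    ly, cost, qaly = {}, {}, {}
    for arm in ARMS:
        _, trace, costs = run_arm(cfg, arm, population)
        ly[arm] = trace.total_ly
        qaly[arm] = trace.total_qaly
        cost[arm] = costs.total
    delta_cost = cost["NI"] - cost["C"]
    delta_qaly = qaly["NI"] - qaly["C"]
    value, flag = icer(delta_cost, delta_qaly)
    return CEAResult(
        population=population,
        ly=ly,
        cost=cost,
        qaly=qaly,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=value,
        icer_flag=flag,
    )
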