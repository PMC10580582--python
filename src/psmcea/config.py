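"""Run configuration: every model parameter, with ranges, I/O and overrides.

The configuration is a machine-readable transcription of the model's
parameter table: survival-curve parameters per arm and population, drug
prices, fees, adverse-event incidences/costs/disutilities, utilities,
patient characteristics, mixture probabilities, discounting and the
willingness-to-pay threshold.  ``default_config()`` reproduces the base
case; YAML round-trips are lossless.

Every scalar that the sensitivity analyses vary is addressed by a dotted
parameter id (e.g. ``"price.pemetrexed"``, ``"utility.pfs"``); see
:data:`PARAM_TABLE` for ids, base values, ranges and the distribution family
used in probabilistic sensitivity analysis.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import asdict, dataclass, field

import yaml

from .costs import FIRST_LINE_DURATION_MONTHS, Patient, PriceList, SecondLineMix
from .engine import EngineConfig, HealthUtilities
from .survival import ParametricSurvival

logger = logging.getLogger("psmcea")

__all__ = [
    "RunConfig",
    "ParamRange",
    "PARAM_TABLE",
    "default_config",
    "load_config",
    "save_config",
    "get_param",
    "with_param",
    "set_param_inplace",
]

#: The shape digits of the non-epithelioid chemotherapy OS log-logistic are
#: corrupted in the source table; this least-edit reconstruction is the
#: default and is configurable like any other survival parameter.
C_N_OS_GAMMA_DEFAULT = 2.17796

_DEFAULT_SURVIVAL = {
    "pfs": {
        "NI": ("log_normal", 1.93843, 1.26135),
        "C": ("log_logistic", 7.53780, 2.29427),
    },
    "os": {
        "NI": {
            "A": ("weibull_ph", 0.0241553, 1.1284343),
            "E": ("log_logistic", 19.01452, 1.51241),
            "N": ("exponential", 0.0412831, None),
        },
        "C": {
            "A": ("log_logistic", 14.25065, 1.76236),
            "E": ("log_logistic", 16.70245, 1.70694),
            "N": ("log_logistic", 9.03382, C_N_OS_GAMMA_DEFAULT),
        },
    },
}


@dataclass(frozen=True)
class ParamRange:
    """One tunable parameter: dotted id, base, low/high, PSA family."""

    param_id: str
    base: float
    low: float
    high: float
    psa_family: str  # "beta", "gamma_dist", "uniform", "fixed"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.param_id}: range must satisfy low <= base <= high "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.psa_family not in ("beta", "gamma_dist", "uniform", "fixed"):
            raise ValueError(f"{self.param_id}: unknown PSA family {self.psa_family!r}")


def _pr(pid, base, low, high, fam):
    return ParamRange(pid, base, low, high, fam)


#: Base values and one-way ranges.  Price ranges are the published bid-price
#: extremes; incidence/utility ranges are the published intervals; mixture
#: probabilities span the full unit interval; the discount rate spans 0-8%.
PARAM_TABLE: tuple = (
    _pr("utility.pfs", 0.706, 0.565, 0.847, "beta"),
    _pr("utility.pd", 0.565, 0.452, 0.678, "beta"),
    _pr("disutility.asthenia", 0.07, 0.04, 0.11, "beta"),
    _pr("disutility.anemia", 0.073, 0.037, 0.110, "beta"),
    _pr("disutility.neutropenia", 0.20, 0.15, 0.25, "beta"),
    _pr("incidence.NI.anemia", 0.0033, 0.0027, 0.0040, "beta"),
    _pr("incidence.NI.neutropenia", 0.0067, 0.0053, 0.0080, "beta"),
    _pr("incidence.C.asthenia", 0.042, 0.0336, 0.0504, "beta"),
    _pr("incidence.C.anemia", 0.1127, 0.0902, 0.1352, "beta"),
    _pr("incidence.C.neutropenia", 0.1514, 0.1211, 0.1817, "beta"),
    _pr("price.nivolumab", 15.96, 6.44, 19.16, "gamma_dist"),
    _pr("price.ipilimumab", 77.96, 38.98, 93.55, "gamma_dist"),
    _pr("price.pemetrexed", 0.88, 0.05, 6.40, "gamma_dist"),
    _pr("price.cisplatin", 0.12, 0.01, 0.83, "gamma_dist"),
    _pr("price.carboplatin", 0.09, 0.02, 0.33, "gamma_dist"),
    _pr("price.vinorelbine", 1.52, 0.06, 5.61, "gamma_dist"),
    _pr("price.gemcitabine", 0.07, 0.005, 0.36, "gamma_dist"),
    _pr("fee.admin_iv_first_hour", 7.83, 6.27, 9.40, "gamma_dist"),
    _pr("fee.followup_per_cycle", 69.13, 51.85, 86.29, "gamma_dist"),
    _pr("ae_cost.asthenia", 96.05, 67.24, 124.87, "gamma_dist"),
    _pr("ae_cost.anemia", 500.78, 445.76, 545.54, "gamma_dist"),
    _pr("ae_cost.neutropenia", 434.57, 0.0, 1290.65, "gamma_dist"),
    _pr("patient.weight_kg", 65.0, 48.75, 81.25, "gamma_dist"),
    _pr("patient.bsa_m2", 1.72, 1.50, 1.90, "gamma_dist"),
    _pr("mix.p_carbo_vs_cis", 0.5, 0.0, 1.0, "uniform"),
    _pr("mix.p_immuno_in_c", 0.5, 0.0, 1.0, "uniform"),
    _pr("mix.p_nivo_mono_vs_combo", 0.5, 0.0, 1.0, "uniform"),
    _pr("mix.p_vinorelbine_vs_gemcitabine", 0.5, 0.0, 1.0, "uniform"),
    _pr("engine.discount_rate_annual", 0.05, 0.0, 0.08, "fixed"),
)


@dataclass
class RunConfig:
    """Everything needed to run the model for any population."""

    engine: EngineConfig = field(default_factory=EngineConfig)
    utilities: HealthUtilities = field(default_factory=HealthUtilities)
    prices: PriceList = field(default_factory=PriceList)
    patient: Patient = field(default_factory=Patient)
    mix: SecondLineMix = field(default_factory=SecondLineMix)
    survival: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_SURVIVAL))
    first_line_durations: dict = field(
        default_factory=lambda: dict(FIRST_LINE_DURATION_MONTHS)
    )
    ranges: tuple = PARAM_TABLE
    psa_iterations: int = 1000
    psa_seed: int = 743

    def arm_curves(self, arm: str, population: str):
        """(PFS, OS) distributions for an arm/population combination."""
        fam, lam, gam = self.survival["pfs"][arm]
        pfs = ParametricSurvival(fam, lam, gam)
        fam, lam, gam = self.survival["os"][arm][population]
        os_ = ParametricSurvival(fam, lam, gam)
        return pfs, os_

    def range_for(self, param_id: str) -> ParamRange:
        for r in self.ranges:
            if r.param_id == param_id:
                return r
        raise KeyError(f"no range defined for parameter {param_id!r}")


def default_config() -> RunConfig:
    """The bundled base case (5% discount, 120 cycles, WTP $33,819)."""
    cfg = RunConfig()
    logger.debug(
        "using reconstructed non-epithelioid chemo OS shape gamma=%.5f "
        "(source digits corrupted)",
        C_N_OS_GAMMA_DEFAULT,
    )
    return cfg


# ---------------------------------------------------------------------------
# parameter addressing (used by OWSA and PSA)
# ---------------------------------------------------------------------------


def get_param(cfg: RunConfig, param_id: str) -> float:
    """Read a scalar parameter by dotted id."""
    head, *rest = param_id.split(".")
    if head == "utility":
        return {"pfs": cfg.utilities.u_pfs, "pd": cfg.utilities.u_pd}[rest[0]]
    if head == "disutility":
        return cfg.utilities.ae_disutilities[rest[0]]
    if head == "incidence":
        return cfg.utilities.ae_incidences[rest[0]][rest[1]]
    if head == "price":
        return cfg.prices.usd_per_mg[rest[0]]
    if head == "fee":
        return getattr(cfg.prices, rest[0])
    if head == "ae_cost":
        return cfg.prices.ae_costs[rest[0]]
    if head == "patient":
        return getattr(cfg.patient, rest[0])
    if head == "mix":
        return getattr(cfg.mix, rest[0])
    if head == "engine":
        return getattr(cfg.engine, rest[0])
    raise KeyError(f"unknown parameter id {param_id!r}")


def with_param(cfg: RunConfig, param_id: str, value: float) -> RunConfig:
    """A deep copy of ``cfg`` with one scalar parameter replaced."""
    new = copy.deepcopy(cfg)
    set_param_inplace(new, param_id, value)
    return new


def set_param_inplace(new: RunConfig, param_id: str, value: float) -> None:
    """Overwrite one scalar parameter on ``new`` (no copying).

    Callers batching many overrides (the probabilistic sensitivity analysis)
    deep-copy once and then set each sampled value directly.
    """
    head, *rest = param_id.split(".")
    if head == "utility":
        attr = {"pfs": "u_pfs", "pd": "u_pd"}[rest[0]]
        object.__setattr__(new.utilities, attr, float(value))
    elif head == "disutility":
        new.utilities.ae_disutilities[rest[0]] = float(value)
    elif head == "incidence":
        new.utilities.ae_incidences[rest[0]][rest[1]] = float(value)
    elif head == "price":
        new.prices.usd_per_mg[rest[0]] = float(value)
    elif head == "fee":
        object.__setattr__(new.prices, rest[0], float(value))
    elif head == "ae_cost":
        new.prices.ae_costs[rest[0]] = float(value)
    elif head == "patient":
        object.__setattr__(new.patient, rest[0], float(value))
    elif head == "mix":
        object.__setattr__(new.mix, rest[0], float(value))
    elif head == "engine":
        object.__setattr__(new.engine, rest[0], float(value))
    else:
        raise KeyError(f"unknown parameter id {param_id!r}")


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------


def _to_dict(cfg: RunConfig) -> dict:
    d = {
        "engine": asdict(cfg.engine),
        "utilities": asdict(cfg.utilities),
        "prices": asdict(cfg.prices),
        "patient": asdict(cfg.patient),
        "mix": asdict(cfg.mix),
        "survival": {
            "pfs": {a: list(v) for a, v in cfg.survival["pfs"].items()},
            "os": {
                a: {p: list(v) for p, v in pops.items()}
                for a, pops in cfg.survival["os"].items()
            },
        },
        "first_line_durations": dict(cfg.first_line_durations),
        "ranges": [asdict(r) for r in cfg.ranges],
        "psa_iterations": cfg.psa_iterations,
        "psa_seed": cfg.psa_seed,
    }
    return d


def save_config(cfg: RunConfig, path) -> None:
    """Write a configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def _err(field_path: str, msg: str):
    raise ValueError(f"config field {field_path!r}: {msg}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration.

    Missing sections fall back to base-case defaults; invalid values raise
    ``ValueError`` naming the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config()
    try:
        if "engine" in raw:
            cfg.engine = EngineConfig(**raw["engine"])
    except (TypeError, ValueError) as exc:
        _err("engine", str(exc))
    try:
        if "utilities" in raw:
            cfg.utilities = HealthUtilities(**raw["utilities"])
        if "prices" in raw:
            cfg.prices = PriceList(**raw["prices"])
        if "patient" in raw:
            cfg.patient = Patient(**raw["patient"])
        if "mix" in raw:
            cfg.mix = SecondLineMix(**raw["mix"])
    except (TypeError, ValueError) as exc:
        _err("utilities/prices/patient/mix", str(exc))
    if "survival" in raw:
        surv = raw["survival"]
        try:
            cfg.survival = {
                "pfs": {a: tuple(v) for a, v in surv["pfs"].items()},
                "os": {
                    a: {p: tuple(v) for p, v in pops.items()}
                    for a, pops in surv["os"].items()
                },
            }
            for arm in ("NI", "C"):
                cfg.arm_curves(arm, "A")  # construct to validate
        except (KeyError, TypeError, ValueError) as exc:
            _err("survival", str(exc))
    if "first_line_durations" in raw:
        cfg.first_line_durations = dict(raw["first_line_durations"])
        if any(v < 0 for v in cfg.first_line_durations.values()):
            _err("first_line_durations", "durations must be >= 0")
    if "ranges" in raw:
        try:
            cfg.ranges = tuple(ParamRange(**r) for r in raw["ranges"])
        except (TypeError, ValueError) as exc:
            _err("ranges", str(exc))
    cfg.psa_iterations = int(raw.get("psa_iterations", cfg.psa_iterations))
    if cfg.psa_iterations < 1:
        _err("psa_iterations", "must be >= 1")
    cfg.psa_seed = int(raw.get("psa_seed", cfg.psa_seed))
    return cfg
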