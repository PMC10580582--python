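"""Direct medical costs: drug acquisition, administration, follow-up, AEs.

First-line drug cost accrues continuously against progression-free occupancy
up to the arm's median treatment duration (6 months for nivolumab+ipilimumab,
4 for chemotherapy).  Second-line therapy is charged as an expected
full-course lump sum to each newly progressed patient.  Follow-up is a flat
per-cycle fee for everyone alive; adverse-event management is a one-off,
undiscounted first-cycle charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import ArmModel, EngineConfig, StateTrace

__all__ = [
    "DAYS_PER_MONTH",
    "Patient",
    "Regimen",
    "PriceList",
    "SecondLineMix",
    "CostBreakdown",
    "dose_mg",
    "per_cycle_drug_cost",
    "ae_first_cycle_cost",
    "first_line_monthly_cost",
    "second_line_course_cost",
    "total_cost_trace",
]

DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375


@dataclass(frozen=True)
class Patient:
    """Reference patient for body-size-based dosing."""

    weight_kg: float = 65.0
    bsa_m2: float = 1.72
    crcl_ml_min: float = 60.0
    age_years: float = 69.0

    def __post_init__(self) -> None:
        for v in (self.weight_kg, self.bsa_m2, self.crcl_ml_min, self.age_years):
            if not v > 0:
                raise ValueError("patient characteristics must be positive")


@dataclass(frozen=True)
class Regimen:
    """One drug's dosing rule and schedule.

    ``dose_rule`` is ``per_kg`` (mg/kg), ``per_bsa`` (mg/m2), ``auc_calvert``
    (target AUC in mg.min/mL, dosed by the Calvert formula) or ``flat`` (mg).
    ``days_per_interval_dosed`` counts administration days per interval
    (e.g. day 1 + day 8 of a 21-day cycle -> 2).
    """

    drug: str
    dose_rule: str
    dose: float
    interval_days: float
    days_per_interval_dosed: int = 1

    def __post_init__(self) -> None:
        if self.dose_rule not in ("per_kg", "per_bsa", "auc_calvert", "flat"):
            raise ValueError(f"unknown dose rule {self.dose_rule!r}")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")

    @property
    def doses_per_month(self) -> float:
        return self.days_per_interval_dosed * DAYS_PER_MONTH / self.interval_days


# CheckMate 743 first-line schedules and the guideline second-line options.
NIVOLUMAB = Regimen("nivolumab", "per_kg", 3.0, 14.0)
IPILIMUMAB = Regimen("ipilimumab", "per_kg", 1.0, 42.0)
PEMETREXED = Regimen("pemetrexed", "per_bsa", 500.0, 21.0)
CISPLATIN = Regimen("cisplatin", "per_bsa", 75.0, 21.0)
CARBOPLATIN = Regimen("carboplatin", "auc_calvert", 5.0, 21.0)
VINORELBINE = Regimen("vinorelbine", "per_bsa", 25.0, 21.0, days_per_interval_dosed=2)
GEMCITABINE = Regimen("gemcitabine", "per_bsa", 1000.0, 21.0, days_per_interval_dosed=2)


@dataclass(frozen=True)
class PriceList:
    """Unit prices (USD/mg), fees and adverse-event management costs (USD)."""

    usd_per_mg: dict = field(
        default_factory=lambda: {
            "nivolumab": 15.96,
            "ipilimumab": 77.96,
            "pemetrexed": 0.88,
            "cisplatin": 0.12,
            "carboplatin": 0.09,
            "vinorelbine": 1.52,
            "gemcitabine": 0.07,
        }
    )
    admin_iv_first_hour: float = 7.83
    followup_per_cycle: float = 69.13
    ae_costs: dict = field(
        default_factory=lambda: {
            "asthenia": 96.05,
            "anemia": 500.78,
            "neutropenia": 434.57,
        }
    )

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.usd_per_mg.values()) or any(
            c < 0 for c in self.ae_costs.values()
        ):
            raise ValueError("prices and costs must be >= 0")
        if self.admin_iv_first_hour < 0 or self.followup_per_cycle < 0:
            raise ValueError("fees must be >= 0")

    def price(self, drug: str) -> float:
        try:
            return self.usd_per_mg[drug]
        except KeyError:
            raise ValueError(f"no unit price for drug {drug!r}") from None


@dataclass(frozen=True)
class SecondLineMix:
    """Mixture probabilities and durations of the second-line strategies.

    After progression the NI arm receives pemetrexed + platinum (cisplatin or
    carboplatin weighted by ``p_carbo_vs_cis``) for up to 5 months.  The
    chemotherapy arm receives immunotherapy with probability ``p_immuno_in_c``
    (nivolumab alone vs nivolumab+ipilimumab by ``p_nivo_mono_vs_combo``,
    3 months) and otherwise single-agent chemotherapy (vinorelbine vs
    gemcitabine by ``p_vinorelbine_vs_gemcitabine``, 16 months).
    """

    p_carbo_vs_cis: float = 0.5
    p_immuno_in_c: float = 0.5
    p_nivo_mono_vs_combo: float = 0.5
    p_vinorelbine_vs_gemcitabine: float = 0.5
    duration_ni_chemo_months: float = 5.0
    duration_c_immuno_months: float = 3.0
    duration_c_mono_chemo_months: float = 16.0

    def __post_init__(self) -> None:
        for p in (
            self.p_carbo_vs_cis,
            self.p_immuno_in_c,
            self.p_nivo_mono_vs_combo,
            self.p_vinorelbine_vs_gemcitabine,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mixture probabilities must lie in [0, 1]")


def dose_mg(regimen: Regimen, patient: Patient) -> float:
    """Administered dose in mg per administration day."""
    if regimen.dose_rule == "per_kg":
        return regimen.dose * patient.weight_kg
    if regimen.dose_rule == "per_bsa":
        return regimen.dose * patient.bsa_m2
    if regimen.dose_rule == "auc_calvert":
        # Calvert: dose (mg) = AUC x (GFR + 25), GFR taken as CrCl.
        return regimen.dose * (patient.crcl_ml_min + 25.0)
    return regimen.dose  # flat


def per_cycle_drug_cost(
    regimen: Regimen, patient: Patient, prices: PriceList
) -> float:
    """Drug acquisition cost per month of continuous treatment (no fees)."""
    return dose_mg(regimen, patient) * prices.price(regimen.drug) * regimen.doses_per_month


def _combo_monthly_cost(
    components: list, patient: Patient, prices: PriceList
) -> float:
    """Monthly cost of a weighted drug combination plus administration fees.

    ``components`` is a list of ``(regimen, weight)``.  All drugs in a
    combination here share infusion visits (the ipilimumab q6w schedule nests
    in the nivolumab q2w one; platinum is co-administered with pemetrexed),
    so one first-hour IV fee is charged per administration day: the densest
    component's schedule.
    """
    drug = sum(
        w * per_cycle_drug_cost(reg, patient, prices) for reg, w in components if w > 0
    )
    admin_days = max(reg.doses_per_month for reg, w in components if w > 0)
    return drug + prices.admin_iv_first_hour * admin_days


def first_line_monthly_cost(
    arm: str, patient: Patient, prices: PriceList, mix: SecondLineMix
) -> float:
    """Expected first-line drug + administration cost per treated month."""
    if arm == "NI":
        comps = [(NIVOLUMAB, 1.0), (IPILIMUMAB, 1.0)]
    elif arm == "C":
        comps = [
            (PEMETREXED, 1.0),
            (CARBOPLATIN, mix.p_carbo_vs_cis),
            (CISPLATIN, 1.0 - mix.p_carbo_vs_cis),
        ]
    else:
        raise ValueError(f"unknown arm {arm!r}")
    return _combo_monthly_cost(comps, patient, prices)


def ae_first_cycle_cost(arm: str, prices: PriceList, incidences: dict) -> float:
    """Expected adverse-event management cost, charged once in cycle 1."""
    inc = incidences[arm]
    if any(not 0.0 <= p <= 1.0 for p in inc.values()):
        raise ValueError("incidences must lie in [0, 1]")
    return sum(inc.get(name, 0.0) * c for name, c in prices.ae_costs.items())


def second_line_course_cost(
    arm: str, mix: SecondLineMix, patient: Patient, prices: PriceList
) -> float:
    """Expected full-course cost of the arm's second-line strategy."""
    if arm == "NI":
        monthly = _combo_monthly_cost(
            [
                (PEMETREXED, 1.0),
                (CARBOPLATIN, mix.p_carbo_vs_cis),
                (CISPLATIN, 1.0 - mix.p_carbo_vs_cis),
            ],
            patient,
            prices,
        )
        return monthly * mix.duration_ni_chemo_months
    if arm != "C":
        raise ValueError(f"unknown arm {arm!r}")
    mono = _combo_monthly_cost([(NIVOLUMAB, 1.0)], patient, prices)
    combo = _combo_monthly_cost([(NIVOLUMAB, 1.0), (IPILIMUMAB, 1.0)], patient, prices)
    immuno = (
        mix.p_nivo_mono_vs_combo * mono + (1.0 - mix.p_nivo_mono_vs_combo) * combo
    ) * mix.duration_c_immuno_months
    vin = _combo_monthly_cost([(VINORELBINE, 1.0)], patient, prices)
    gem = _combo_monthly_cost([(GEMCITABINE, 1.0)], patient, prices)
    chemo = (
        mix.p_vinorelbine_vs_gemcitabine * vin
        + (1.0 - mix.p_vinorelbine_vs_gemcitabine) * gem
    ) * mix.duration_c_mono_chemo_months
    return mix.p_immuno_in_c * immuno + (1.0 - mix.p_immuno_in_c) * chemo


#: First-line treatment durations in months (trial median medication time).
FIRST_LINE_DURATION_MONTHS = {"NI": 6.0, "C": 4.0}


@dataclass
class CostBreakdown:
    """Per-cycle discounted cost components and their totals (USD)."""

    times: np.ndarray
    first_line: np.ndarray
    second_line: np.ndarray
    followup: np.ndarray
    ae: np.ndarray

    @property
    def per_cycle(self) -> np.ndarray:
        return self.first_line + self.second_line + self.followup + self.ae

    @property
    def total(self) -> float:
        return float(self.per_cycle.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_months": self.times,
                "first_line": self.first_line,
                "second_line": self.second_line,
                "followup": self.followup,
                "ae": self.ae,
                "total": self.per_cycle,
            }
        )


def total_cost_trace(
    arm: ArmModel,
    trace: StateTrace,
    patient: Patient,
    prices: PriceList,
    mix: SecondLineMix,
    cfg: EngineConfig,
    incidences: dict,
    first_line_durations: dict | None = None,
) -> CostBreakdown:
    """Accrue all discounted direct medical costs along a state trace.

    Per cycle: first-line drug + administration cost times progression-free
    occupancy while within the first-line duration; follow-up fee times alive
    occupancy; the expected second-line course as a lump sum on newly
    progressed patients; and the adverse-event charge, undiscounted, in the
    first cycle.
    """
    if trace.times.shape[0] != cfg.horizon_cycles:
        raise ValueError("trace and engine config horizons do not match")
    durations = first_line_durations or FIRST_LINE_DURATION_MONTHS
    t, df = trace.times, trace.discount

    fl_monthly = first_line_monthly_cost(arm.name, patient, prices, mix)
    on_treatment = t < durations[arm.name]
    first_line = np.where(on_treatment, fl_monthly * trace.occ_pfs, 0.0) * df

    followup = prices.followup_per_cycle * (trace.occ_pfs + trace.occ_pd) * df

    course = second_line_course_cost(arm.name, mix, patient, prices)
    second_line = course * trace.new_progressors * df

    ae = np.zeros_like(t)
    ae[0] = ae_first_cycle_cost(arm.name, prices, incidences)

    return CostBreakdown(
        times=t, first_line=first_line, second_line=second_line, followup=followup, ae=ae
    )
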