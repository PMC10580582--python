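"""Dosing rules, per-cycle drug costs, AE charges and total cost accrual."""

import copy

import numpy as np
import pytest

from psmcea.config import default_config, with_param
from psmcea.costs import (
    CARBOPLATIN,
    IPILIMUMAB,
    NIVOLUMAB,
    PEMETREXED,
    VINORELBINE,
    Patient,
    PriceList,
    Regimen,
    SecondLineMix,
    ae_first_cycle_cost,
    dose_mg,
    per_cycle_drug_cost,
    second_line_course_cost,
    total_cost_trace,
)
from psmcea.model import run_arm, run_cea

PATIENT = Patient()
PRICES = PriceList()
MIX = SecondLineMix()


class TestDosing:
    @pytest.mark.parametrize(
        "regimen,expected_mg",
        [
            (NIVOLUMAB, 3 * 65.0),          # 195 mg per kg rule
            (PEMETREXED, 500 * 1.72),       # 860 mg per BSA rule
            (CARBOPLATIN, 5 * (60 + 25.0)), # 425 mg Calvert: AUC x (CrCl+25)
            (IPILIMUMAB, 65.0),
            (VINORELBINE, 25 * 1.72),       # 43 mg
        ],
    )
    def test_dose_rules(self, regimen, expected_mg):
        assert dose_mg(regimen, PATIENT) == pytest.approx(expected_mg)

    def test_flat_rule_and_validation(self):
        assert dose_mg(Regimen("x", "flat", 100.0, 21.0), PATIENT) == 100.0
        with pytest.raises(ValueError):
            Regimen("x", "per_pound", 1.0, 21.0)
        with pytest.raises(ValueError):
            Patient(weight_kg=-1)

    def test_per_dose_costs(self):
        # nivolumab 195 mg x 15.96 USD/mg per administration
        per_dose = dose_mg(NIVOLUMAB, PATIENT) * PRICES.price("nivolumab")
        assert per_dose == pytest.approx(3112.20)
        ipi_dose = dose_mg(IPILIMUMAB, PATIENT) * PRICES.price("ipilimumab")
        assert ipi_dose == pytest.approx(5067.40)
        assert IPILIMUMAB.doses_per_month == pytest.approx(0.72470, abs=1e-5)
        assert per_cycle_drug_cost(NIVOLUMAB, PATIENT, PRICES) == pytest.approx(
            3112.20 * 30.4375 / 14.0
        )

    def test_vinorelbine_day1_day8(self):
        assert dose_mg(VINORELBINE, PATIENT) * PRICES.price("vinorelbine") == (
            pytest.approx(65.36)
        )
        assert VINORELBINE.doses_per_month == pytest.approx(2 * 30.4375 / 21.0)

    def test_unknown_drug_price_rejected(self):
        with pytest.raises(ValueError):
            per_cycle_drug_cost(Regimen("madeupumab", "flat", 1.0, 21.0), PATIENT, PRICES)


class TestAECosts:
    def test_expected_first_cycle_charges(self):
        inc = {
            "NI": {"asthenia": 0.0, "anemia": 0.0033, "neutropenia": 0.0067},
            "C": {"asthenia": 0.042, "anemia": 0.1127, "neutropenia": 0.1514},
        }
        # oracle: plain expected-value arithmetic over the incidence table
        c_expected = 0.042 * 96.05 + 0.1127 * 500.78 + 0.1514 * 434.57
        ni_expected = 0.0033 * 500.78 + 0.0067 * 434.57
        assert ae_first_cycle_cost("C", PRICES, inc) == pytest.approx(c_expected)
        assert ae_first_cycle_cost("C", PRICES, inc) == pytest.approx(126.27, abs=0.01)
        assert ae_first_cycle_cost("NI", PRICES, inc) == pytest.approx(ni_expected)
        assert ae_first_cycle_cost("NI", PRICES, inc) == pytest.approx(4.56, abs=0.01)
        zero = {"C": {k: 0.0 for k in inc["C"]}}
        assert ae_first_cycle_cost("C", PRICES, zero) == 0.0


class TestSecondLine:
    def test_zero_prices_leave_admin_fees_only(self):
        free = PriceList(usd_per_mg={k: 0.0 for k in PRICES.usd_per_mg})
        cost = second_line_course_cost("NI", MIX, PATIENT, free)
        # 5 months of q3w visits at 7.83 per administration day
        assert cost == pytest.approx(7.83 * (30.4375 / 21.0) * 5.0)

    def test_immuno_only_branch(self):
        mix = SecondLineMix(p_immuno_in_c=1.0, p_nivo_mono_vs_combo=1.0)
        cost = second_line_course_cost("C", mix, PATIENT, PRICES)
        expected = (3112.20 + 7.83) * (30.4375 / 14.0) * 3.0
        assert cost == pytest.approx(expected)

    def test_chemo_only_vinorelbine_branch(self):
        mix = SecondLineMix(p_immuno_in_c=0.0, p_vinorelbine_vs_gemcitabine=1.0)
        cost = second_line_course_cost("C", mix, PATIENT, PRICES)
        expected = (65.36 + 7.83) * (2 * 30.4375 / 21.0) * 16.0
        assert cost == pytest.approx(expected)

    def test_mixture_probabilities_validated(self):
        with pytest.raises(ValueError):
            SecondLineMix(p_immuno_in_c=1.2)


class TestTotalCost:
    def test_price_linearity_of_drug_components(self, base_cfg):
        _, trace, costs = run_arm(base_cfg, "NI", "A")
        doubled = copy.deepcopy(base_cfg)
        doubled.prices = PriceList(
            usd_per_mg={k: 2 * v for k, v in base_cfg.prices.usd_per_mg.items()},
            admin_iv_first_hour=0.0,
            followup_per_cycle=base_cfg.prices.followup_per_cycle,
            ae_costs=base_cfg.prices.ae_costs,
        )
        zero_admin = copy.deepcopy(base_cfg)
        zero_admin.prices = PriceList(
            usd_per_mg=base_cfg.prices.usd_per_mg,
            admin_iv_first_hour=0.0,
            followup_per_cycle=base_cfg.prices.followup_per_cycle,
            ae_costs=base_cfg.prices.ae_costs,
        )
        _, _, c2 = run_arm(doubled, "NI", "A")
        _, _, c1 = run_arm(zero_admin, "NI", "A")
        # drug acquisition (first+second line, no admin) scales exactly x2
        np.testing.assert_allclose(
            c2.first_line + c2.second_line, 2 * (c1.first_line + c1.second_line)
        )

    @pytest.mark.parametrize(
        "param",
        ["price.nivolumab", "price.pemetrexed", "fee.followup_per_cycle"],
    )
    def test_total_cost_monotone_in_prices(self, base_cfg, param):
        from psmcea.config import get_param

        base = get_param(base_cfg, param)
        totals = []
        for scale in (0.5, 1.0, 2.0):
            _, _, c = run_arm(with_param(base_cfg, param, base * scale), "NI", "A")
            totals.append(c.total)
        assert totals[0] < totals[1] < totals[2]

    def test_total_cost_monotone_in_first_line_duration(self, base_cfg):
        totals = []
        for months in (2.0, 6.0, 12.0):
            cfg = copy.deepcopy(base_cfg)
            cfg.first_line_durations = {"NI": months, "C": 4.0}
            _, _, c = run_arm(cfg, "NI", "A")
            totals.append(c.total)
        assert totals[0] < totals[1] < totals[2]

    def test_identical_arms_give_zero_increments(self, base_cfg):
        cfg = copy.deepcopy(base_cfg)
        # same curves, free identical drugs, identical AE profiles
        cfg.survival["pfs"]["C"] = cfg.survival["pfs"]["NI"]
        cfg.survival["os"]["C"] = cfg.survival["os"]["NI"]
        cfg.prices = PriceList(
            usd_per_mg={k: 0.0 for k in cfg.prices.usd_per_mg},
            admin_iv_first_hour=0.0,
            followup_per_cycle=cfg.prices.followup_per_cycle,
            ae_costs={k: 0.0 for k in cfg.prices.ae_costs},
        )
        cfg.utilities.ae_incidences["C"] = dict(cfg.utilities.ae_incidences["NI"])
        cfg.first_line_durations = {"NI": 6.0, "C": 6.0}
        res = run_cea(cfg, "A")
        assert res.delta_qaly == 0.0
        assert res.delta_cost == 0.0
        assert res.icer_flag == "undefined"

    def test_horizon_mismatch_rejected(self, base_cfg):
        from psmcea.engine import EngineConfig

        model, trace, _ = run_arm(base_cfg, "NI", "A")
        short = EngineConfig(horizon_cycles=60)
        with pytest.raises(ValueError):
            total_cost_trace(
                model,
                trace,
                base_cfg.patient,
                base_cfg.prices,
                base_cfg.mix,
                short,
                base_cfg.utilities.ae_incidences,
            )
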