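"""Dose arithmetic, vial billing, AE costs, assistance tiers, arm costs."""

import numpy as np
import pytest

from psmcea import (
    AdverseEvent,
    CostInputs,
    EconParams,
    PAPSchedule,
    ParametricSurvival,
    PatientProfile,
    RegimenComponent,
    RegimenSpec,
    ae_cost_oneoff,
    arm_discounted_cost,
    cycle_drug_cost,
    occupancy_trace,
    pap_paid,
    vials_needed,
)
from psmcea.engine import cycle_weights

ECON = EconParams()
PROFILE = PatientProfile()

SUGEMALIMAB = RegimenComponent("sugemalimab", 1200, "flat", 1, 600, 1732.50,
                               max_cycles=24, pap_eligible=True)
CISPLATIN = RegimenComponent("cisplatin", 80, "per_m2", 1, 30, 2.68, max_cycles=4)
FLUOROURACIL = RegimenComponent("fluorouracil", 800, "per_m2", 4, 250, 20.44, max_cycles=4)


@pytest.mark.parametrize(
    "dose, vial, expected",
    [(1200, 600, 2), (137.6, 30, 5), (0, 30, 0), (600, 600, 1), (600.1, 600, 2)],
)
def test_vials_needed(dose, vial, expected):
    assert vials_needed(dose, vial) == expected


def test_component_cycle_costs():
    assert SUGEMALIMAB.cost_per_cycle(PROFILE) == pytest.approx(2 * 1732.50)
    assert CISPLATIN.cost_per_cycle(PROFILE) == pytest.approx(5 * 2.68)  # 137.6 mg -> 5 vials
    # 1376 mg/day -> 6 vials/day, 4 administration days per cycle
    assert FLUOROURACIL.cost_per_cycle(PROFILE) == pytest.approx(6 * 4 * 20.44)


def test_regimen_cycle_cost_sums_components():
    reg = RegimenSpec((SUGEMALIMAB, CISPLATIN, FLUOROURACIL))
    assert cycle_drug_cost(reg, PROFILE) == pytest.approx(3465.0 + 13.40 + 490.56)


def test_ae_cost_oneoff_dot_products():
    sc = (
        AdverseEvent("nausea", 0.037, 82.62),
        AdverseEvent("anemia", 0.167, 140.40),
        AdverseEvent("neutrophil", 0.204, 116.37),
        AdverseEvent("wbc", 0.088, 116.37),
        AdverseEvent("vomiting", 0.051, 82.62),
        AdverseEvent("platelet", 0.057, 1523.82),
        AdverseEvent("lymphocyte", 0.045, 149.60),
    )
    assert ae_cost_oneoff(sc) == pytest.approx(158.29, abs=0.01)
    chemo = (
        AdverseEvent("nausea", 0.049, 82.62),
        AdverseEvent("anemia", 0.143, 140.40),
        AdverseEvent("neutrophil", 0.209, 116.37),
        AdverseEvent("wbc", 0.104, 116.37),
        AdverseEvent("vomiting", 0.049, 82.62),
        AdverseEvent("platelet", 0.044, 1523.82),
        AdverseEvent("lymphocyte", 0.033, 149.60),
    )
    assert ae_cost_oneoff(chemo) == pytest.approx(136.58, abs=0.01)
    assert ae_cost_oneoff(()) == 0.0


class TestPAPSchedule:
    def test_tier_walk(self):
        s = PAPSchedule()
        # 2 paid + 2 free, 2 paid + 25 free, 1 paid + 3 free, free after
        assert pap_paid(s, 1) and pap_paid(s, 2)
        assert not pap_paid(s, 3) and not pap_paid(s, 4)
        assert pap_paid(s, 5) and pap_paid(s, 6)
        assert not any(pap_paid(s, j) for j in range(7, 32))
        assert pap_paid(s, 32)
        assert not any(pap_paid(s, j) for j in range(33, 200))

    def test_paid_cycles_total(self):
        s = PAPSchedule()
        assert sum(pap_paid(s, j) for j in range(1, 1000)) == 5

    def test_one_based_indexing(self):
        with pytest.raises(ValueError):
            pap_paid(PAPSchedule(), 0)


class TestArmCost:
    REGIMEN = RegimenSpec((SUGEMALIMAB, CISPLATIN, FLUOROURACIL))
    COSTS = CostInputs(753.49, 142.10, (AdverseEvent("nausea", 0.037, 82.62),))

    def trace(self):
        return occupancy_trace(
            ParametricSurvival("loglogistic", (9.06, 2.15)),
            ParametricSurvival("loglogistic", (20.92, 1.66)),
            ECON,
        )

    def test_matches_bruteforce_cycle_loop(self):
        """Vectorized arm cost agrees with an explicit python loop to 1e-9."""
        tr = self.trace()
        for pap in (None, PAPSchedule()):
            got = arm_discounted_cost(tr, self.REGIMEN, self.COSTS, ECON, pap=pap)
            expected = 0.037 * 82.62
            for i in range(1, ECON.n_cycles + 1):
                w_pfs = tr.p_pfs[i - 1]
                w_pd = tr.p_pd[i - 1]
                disc = (1 + ECON.discount_rate) ** (-(i - 1) * 21 / 365.25)
                drug = 0.0
                if i <= 24 and (pap is None or pap_paid(pap, i)):
                    drug += 2 * 1732.50
                if i <= 4:
                    drug += 5 * 2.68 + 6 * 4 * 20.44
                expected += (
                    drug * w_pfs + 142.10 * (w_pfs + w_pd) + 753.49 * w_pd
                ) * disc
            assert got == pytest.approx(expected, abs=1e-9)

    def test_cost_monotone_in_prices_and_incidence(self):
        tr = self.trace()
        base = arm_discounted_cost(tr, self.REGIMEN, self.COSTS, ECON)
        up_price = arm_discounted_cost(
            tr, self.REGIMEN, self.COSTS, ECON, price_overrides={"sugemalimab": 2000.0}
        )
        assert up_price > base
        worse_ae = CostInputs(753.49, 142.10, (AdverseEvent("nausea", 0.10, 82.62),))
        assert arm_discounted_cost(tr, self.REGIMEN, worse_ae, ECON) > base
        richer_pd = CostInputs(900.0, 142.10, self.COSTS.adverse_events)
        assert arm_discounted_cost(tr, self.REGIMEN, richer_pd, ECON) > base

    def test_pap_strictly_reduces_antibody_arm_cost(self):
        tr = self.trace()
        no_pap = arm_discounted_cost(tr, self.REGIMEN, self.COSTS, ECON)
        with_pap = arm_discounted_cost(tr, self.REGIMEN, self.COSTS, ECON, pap=PAPSchedule())
        assert with_pap < no_pap
        # arm without assistance-eligible components is untouched
        chemo = RegimenSpec((CISPLATIN, FLUOROURACIL))
        assert arm_discounted_cost(tr, chemo, self.COSTS, ECON, pap=PAPSchedule()) == (
            arm_discounted_cost(tr, chemo, self.COSTS, ECON)
        )

    def test_zero_prices_leave_only_ae_cost(self):
        tr = self.trace()
        free = RegimenSpec(
            (RegimenComponent("x", 100, "flat", 1, 100, 0.0),)
        )
        zero_costs = CostInputs(0.0, 0.0, ())
        assert arm_discounted_cost(tr, free, zero_costs, ECON) == 0.0

    def test_ledger_breakdown_sums_to_total(self):
        tr = self.trace()
        total, ledger = arm_discounted_cost(
            tr, self.REGIMEN, self.COSTS, ECON, return_ledger=True
        )
        parts = ledger[["drug", "hospitalization", "post_progression"]].to_numpy().sum()
        assert total == pytest.approx(parts + ae_cost_oneoff(self.COSTS.adverse_events))


def test_incremental_cost_decomposition():
    """The two-arm incremental cost is dominated by the antibody acquisition:
    it equals antibody price x discounted paid exposure plus the small
    AE/hospitalization/progression deltas, each verifiable separately."""
    sc_reg = RegimenSpec((SUGEMALIMAB, CISPLATIN, FLUOROURACIL))
    chemo_reg = RegimenSpec((CISPLATIN, FLUOROURACIL))
    costs = CostInputs(753.49, 142.10, ())
    tr_sc = occupancy_trace(
        ParametricSurvival("loglogistic", (9.06, 2.15)),
        ParametricSurvival("loglogistic", (20.92, 1.66)), ECON,
    )
    tr_c = occupancy_trace(
        ParametricSurvival("loglogistic", (6.61, 2.53)),
        ParametricSurvival("loglogistic", (16.12, 2.00)), ECON,
    )
    inc = arm_discounted_cost(tr_sc, sc_reg, costs, ECON) - arm_discounted_cost(
        tr_c, chemo_reg, costs, ECON
    )
    w_pfs, w_pd, disc = cycle_weights(tr_sc, ECON)
    cyc = np.arange(1, ECON.n_cycles + 1)
    sug = 2 * 1732.50 * float((w_pfs * disc * (cyc <= 24)).sum())
    w_pfs_c, w_pd_c, _ = cycle_weights(tr_c, ECON)
    chemo_delta = (5 * 2.68 + 24 * 20.44) * float(
        ((w_pfs - w_pfs_c) * disc * (cyc <= 4)).sum()
    )
    hosp_delta = 142.10 * float(((w_pfs + w_pd - w_pfs_c - w_pd_c) * disc).sum())
    pd_delta = 753.49 * float(((w_pd - w_pd_c) * disc).sum())
    assert inc == pytest.approx(sug + chemo_delta + hosp_delta + pd_delta, abs=1e-9)
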