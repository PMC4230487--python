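import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import pbpkdd as p
from pbpkdd.clearance import (
    clh_well_stirred,
    derive_clearances,
    fg,
    fh,
    induction_multiplier,
    induction_onset,
    scale_clint_gut,
    scale_clint_liver,
)


def test_liver_scaling_arithmetic_oracle(artemether, constants):
    """Hand unit conversion: CLint_rec * abundance * MPPGL * liver mass,
    uL/min -> L/h, divided by microsomal binding."""
    fum = 0.6994839081974413
    by_iso = scale_clint_liver(artemether, constants, 1800.0)
    for iso in ("CYP2B6", "CYP3A4"):
        expected = (
            artemether.clint_rec[iso]
            * constants.cyp_abundance_liver[iso]
            * constants.mppgl * 1800.0 * 6e-5 / fum
        )
        assert by_iso[iso] == pytest.approx(expected, rel=1e-9)


def test_liver_scaling_linear_in_liver_mass(artemether, constants):
    a = sum(scale_clint_liver(artemether, constants, 900.0).values())
    b = sum(scale_clint_liver(artemether, constants, 1800.0).values())
    assert b == pytest.approx(2 * a, rel=1e-12)


def test_zero_clint_drug_has_zero_clearance(artemether, constants):
    inert = dataclasses.replace(artemether, clint_rec={"CYP3A4": 0.0})
    assert sum(scale_clint_liver(inert, constants, 1800.0).values()) == 0.0
    assert scale_clint_gut(inert, constants) == 0.0
    assert fg(2.15, 1.0, 0.0) == 1.0


def test_unknown_isoform_raises(artemether, constants):
    odd = dataclasses.replace(artemether, clint_rec={"CYP99": 1.0})
    with pytest.raises(KeyError):
        scale_clint_liver(odd, constants, 1800.0)


def test_gut_scaling_linear_in_enzyme_content(artemether, constants):
    doubled = dataclasses.replace(constants, intestinal_cyp3a4_nmol=2 * constants.intestinal_cyp3a4_nmol)
    assert scale_clint_gut(artemether, doubled) == pytest.approx(
        2 * scale_clint_gut(artemether, constants), rel=1e-12
    )


def test_availability_algebra():
    assert fg(10.0, 1.0, 0.0) == 1.0
    assert fg(10.0, 1.0, 30.0) == pytest.approx(0.25)  # fu*CLint = 3*Qg
    assert fh(10.0, 0.5, 0.0) == 1.0
    assert clh_well_stirred(10.0, 1.0, 1e9) == pytest.approx(10.0, rel=1e-6)


def test_well_stirred_restrictive_limit():
    qh = 90.0
    x = 0.01 * qh  # fu*CLint far below flow
    assert clh_well_stirred(qh, 1.0, x) == pytest.approx(x, rel=0.01)


def test_well_stirred_bounded_by_flow():
    for clint in (1.0, 50.0, 1e4, 1e8):
        assert clh_well_stirred(86.0, 0.5, clint) < 86.0


def test_well_stirred_matches_liver_ode_oracle():
    """Steady-state elimination of a constantly perfused, well-mixed liver
    compartment reproduces the closed-form clearance within 0.5%."""
    q, fu, clint, kp, bp = 86.2, 0.05, 1150.0, 5.0, 1.0
    v_liver = 1.8
    c_in = 100.0  # inflowing blood concentration

    def rhs(t, y):
        c_out = y[0] / v_liver * bp / kp
        return [q * (c_in - c_out) - fu * clint * c_out]

    sol = solve_ivp(rhs, (0.0, 50.0), [0.0], method="LSODA", rtol=1e-10, atol=1e-10)
    c_out = sol.y[0, -1] / v_liver * bp / kp
    cl_sim = fu * clint * c_out / c_in
    assert cl_sim == pytest.approx(clh_well_stirred(q, fu, clint), rel=5e-3)


def test_induction_multiplier_identities():
    assert induction_multiplier(6.5, 3.9, 0.0) == 1.0
    assert induction_multiplier(6.5, 3.9, 3.9) == pytest.approx(1.0 + 6.5 / 2)  # 4.25
    assert induction_multiplier(6.5, 3.9, 1e12) == pytest.approx(7.5, rel=1e-6)
    assert induction_multiplier(5.7, 0.8, 0.8) == pytest.approx(1.0 + 5.7 / 2)


def test_induction_onset_ramp():
    assert induction_onset(0.0) == 0.0
    assert induction_onset(7 * 24.0) == pytest.approx(0.5)
    assert induction_onset(14 * 24.0) == 1.0
    assert induction_onset(30 * 24.0) == 1.0
    assert induction_onset(-5.0) == 0.0


def test_induction_raises_clearance_and_lowers_availability(artemether, constants, ref_subject):
    d = derive_clearances(
        artemether, constants, 1800.0,
        ref_subject.regional_flow["liver_total"],
        ref_subject.regional_flow["liver_portal"],
    )
    induced = d.induced_clint_h({"CYP2B6": 3.0, "CYP3A4": 3.0})
    assert induced > d.clint_h_total
    q = ref_subject.regional_flow["liver_total"]
    assert fh(q, artemether.fu_blood, induced) < d.fh
    assert clh_well_stirred(q, artemether.fu_blood, induced) > d.clh


def test_gut_availability_not_induced(ref_subject, artemether, efavirenz, constants):
    """Hepatic-only induction: Fg is identical with and without the inducer."""
    from pbpkdd.engine import build_model
    alone = build_model(ref_subject, [artemether], constants)
    both = build_model(ref_subject, [efavirenz, artemether], constants)
    assert both.blocks["artemether"].derived.fg == alone.blocks["artemether"].derived.fg


def test_first_pass_chain_reference_values(ref_subject, artemether, efavirenz, constants):
    """Baseline gut and hepatic availabilities of both shipped compounds."""
    q_t = ref_subject.regional_flow["liver_total"]
    q_p = ref_subject.regional_flow["liver_portal"]
    liver_g = ref_subject.organ_mass["liver"] * 1000.0
    d_art = derive_clearances(artemether, constants, liver_g, q_t, q_p)
    d_efv = derive_clearances(efavirenz, constants, liver_g, q_t, q_p)
    assert d_art.fg == pytest.approx(0.195, abs=0.005)
    assert d_art.fh == pytest.approx(0.600, abs=0.005)
    assert d_efv.fg == pytest.approx(0.954, abs=0.005)
    assert d_efv.fh == pytest.approx(0.954, abs=0.005)
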