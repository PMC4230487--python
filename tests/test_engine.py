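import dataclasses
import math

import numpy as np
import pytest

import pbpkdd as p
from pbpkdd.engine import (
    DoseEvent,
    DosingRegimen,
    N_COMPARTMENTS,
    _LinearSystem,
    build_model,
    rhs,
    simulate,
)


def inert_drug(**overrides):
    """A drug with no metabolism anywhere (for conservation oracles)."""
    base = dict(
        name="inert", molecular_weight=300.0, logP=2.0, fu_plasma=0.5,
        psa=60.0, hbd=1, dissolution_kd_per_h=5.0, clint_rec={},
        blood_plasma_ratio_measured=1.0,
    )
    base.update(overrides)
    return p.DrugParameters(**base)


def test_model_construction_sizes(ref_subject, artemether, efavirenz, constants):
    single = build_model(ref_subject, [artemether], constants)
    double = build_model(ref_subject, [efavirenz, artemether], constants)
    assert N_COMPARTMENTS == 16
    assert double.n_states == 2 * single.n_states


def test_flow_balance_verified_at_build(ref_subject, artemether, constants):
    broken = dataclasses.replace(ref_subject)
    broken.regional_flow = dict(ref_subject.regional_flow)
    broken.regional_flow["kidney"] *= 2.0
    with pytest.raises(ValueError, match="imbalance"):
        build_model(broken, [artemether], constants)


def test_matrix_system_equals_reference_rhs(ref_subject, artemether, efavirenz, constants):
    """The assembled linear operator and the hand-written derivative agree
    everywhere (the Jacobian path cannot drift from the reference model)."""
    model = build_model(ref_subject, [efavirenz, artemether], constants)
    model.inducer_start_h["efavirenz"] = 0.0
    system = _LinearSystem(model)
    rng = np.random.default_rng(11)
    for t in (0.0, 150.0, 500.0):
        y = rng.uniform(0.0, 1e7, model.n_states)
        a = rhs(t, y, model)
        b = system.rhs(t, y)
        assert np.allclose(a, b, rtol=1e-10, atol=1e-8)


def test_zero_state_zero_derivative(ref_subject, artemether, constants):
    model = build_model(ref_subject, [artemether], constants)
    assert np.all(rhs(0.0, np.zeros(model.n_states), model) == 0.0)


def test_zero_dose_gives_zero_profile(ref_subject, artemether, constants):
    model = build_model(ref_subject, [artemether], constants)
    regimen = DosingRegimen((), label="none")
    prof = simulate(model, regimen, t_end=12.0, grid_dt=0.5)
    assert np.all(prof.plasma["artemether"] == 0.0)


def test_iv_bolus_conservation_without_elimination(ref_subject, constants):
    """No clearance anywhere: an IV bolus stays in the body exactly."""
    drug = inert_drug()
    model = build_model(ref_subject, [drug], constants)
    regimen = DosingRegimen((DoseEvent(0.0, "inert", 100.0, route="iv"),))
    prof = simulate(model, regimen, t_end=48.0, grid_dt=0.5, atol=1e-6)
    body = prof.y[:N_COMPARTMENTS].sum(axis=0)
    assert np.max(np.abs(body - 100e6)) / 100e6 < 1e-4


def test_global_mass_balance_oral_dose(ref_subject, artemether, constants):
    """Dose = body + gut + eliminated + gut-wall + transited, within 0.1%."""
    model = build_model(ref_subject, [artemether], constants)
    regimen = DosingRegimen((DoseEvent(0.0, "artemether", 80.0),))
    prof = simulate(model, regimen, t_end=48.0, grid_dt=0.2, atol=1e-6)
    b = model.blocks["artemether"]
    body = prof.y[:N_COMPARTMENTS].sum(axis=0)
    elim = prof.y[N_COMPARTMENTS]
    gutmet = prof.y[N_COMPARTMENTS + 1]
    gut = prof.y[N_COMPARTMENTS + 2: b.n_states]
    total = body + elim + gutmet + gut[:-2].sum(axis=0) + gut[-1]
    assert np.max(np.abs(total - 80e6)) / 80e6 < 1e-3
    assert prof.mass_balance_error("artemether") < 1e-3


def test_state_non_negative(ref_subject, artemether, constants):
    model = build_model(ref_subject, [artemether], constants)
    regimen = DosingRegimen((DoseEvent(0.0, "artemether", 80.0),))
    prof = simulate(model, regimen, t_end=24.0, grid_dt=0.2, atol=1e-6)
    assert prof.y.min() > -1.0  # ng; tiny solver undershoot only


def test_dose_linearity(ref_subject, artemether, constants):
    """First-order model: doubling the dose doubles every concentration."""
    model = build_model(ref_subject, [artemether], constants)
    r1 = DosingRegimen((DoseEvent(0.0, "artemether", 80.0),))
    r2 = DosingRegimen((DoseEvent(0.0, "artemether", 160.0),))
    p1 = simulate(model, r1, t_end=24.0, grid_dt=0.2, atol=1e-7)
    p2 = simulate(build_model(ref_subject, [artemether], constants), r2,
                  t_end=24.0, grid_dt=0.2, atol=1e-7)
    c1, c2 = p1.plasma["artemether"], p2.plasma["artemether"]
    mask = c1 > 1e-3
    assert np.max(np.abs(c2[mask] / c1[mask] - 2.0)) < 2e-3


def test_superposition_of_repeated_doses(ref_subject, artemether, constants):
    """q12h dosing equals the sum of time-shifted single-dose profiles."""
    t_end, dt = 48.0, 0.2
    multi = simulate(
        build_model(ref_subject, [artemether], constants),
        DosingRegimen(tuple(DoseEvent(t, "artemether", 80.0) for t in (0.0, 12.0, 24.0))),
        t_end=t_end, grid_dt=dt, atol=1e-7,
    )
    single = simulate(
        build_model(ref_subject, [artemether], constants),
        DosingRegimen((DoseEvent(0.0, "artemether", 80.0),)),
        t_end=t_end, grid_dt=dt, atol=1e-7,
    )
    t = multi.t
    c_single = single.plasma["artemether"]
    expected = np.zeros_like(t)
    for shift in (0.0, 12.0, 24.0):
        expected += np.interp(t - shift, single.t, c_single, left=0.0)
    c_multi = multi.plasma["artemether"]
    mask = expected > 0.01 * expected.max()
    assert np.max(np.abs(c_multi[mask] - expected[mask]) / expected.max()) < 5e-3


def test_one_compartment_halflife_oracle(ref_subject, constants):
    """Homogeneous limit (all Kp = 1, flows cranked): terminal half-life
    matches ln2 * V / CL within 0.5%."""
    drug = inert_drug(clint_rec={"CYP3A4": 0.05})
    ind = dataclasses.replace(ref_subject)
    ind.regional_flow = {k: v * 50.0 for k, v in ref_subject.regional_flow.items()}
    ind.cardiac_output = ref_subject.cardiac_output * 50.0
    model = build_model(ind, [drug], constants)
    block = model.blocks["inert"]
    block.kp[:] = 1.0
    clint = block.derived.clint_h_total
    regimen = DosingRegimen((DoseEvent(0.0, "inert", 100.0, route="iv"),))
    prof = simulate(model, regimen, t_end=200.0, grid_dt=0.5, atol=1e-6)
    v_total = model.v_art + model.v_ven + model.v_tissues.sum()
    cl = p.clh_well_stirred(ind.regional_flow["liver_total"], drug.fu_blood, clint)
    expected_thalf = math.log(2.0) * v_total / cl
    c = prof.plasma["inert"]
    sel = prof.t > 50.0
    slope = np.polyfit(prof.t[sel], np.log(c[sel]), 1)[0]
    assert -math.log(2.0) / slope == pytest.approx(expected_thalf, rel=5e-3)


def test_simulation_restart_continuity(ref_subject, artemether, constants):
    """Splitting a simulation at an arbitrary time reproduces the one-shot
    run (the lead-in/co-dosing handover is exact)."""
    model = build_model(ref_subject, [artemether], constants)
    regimen = DosingRegimen(tuple(DoseEvent(t, "artemether", 80.0) for t in (0.0, 12.0)))
    full = simulate(model, regimen, t_end=24.0, grid_dt=0.5, atol=1e-8)
    m2 = build_model(ref_subject, [artemether], constants)
    first = simulate(m2, regimen, t_end=7.0, grid_dt=0.5, atol=1e-8)
    second = simulate(m2, regimen, t_end=24.0, t0=7.0, y0=first.y_final,
                      grid_start=7.0, grid_dt=0.5, atol=1e-8)
    c_full = np.interp(second.t, full.t, full.plasma["artemether"])
    assert np.allclose(second.plasma["artemether"], c_full, rtol=2e-4, atol=1e-3)


def test_invalid_dose_events_rejected():
    with pytest.raises(ValueError):
        DoseEvent(0.0, "x", -5.0)
    with pytest.raises(ValueError):
        DoseEvent(0.0, "x", 5.0, route="intrathecal")
    with pytest.raises(ValueError):
        DosingRegimen((DoseEvent(5.0, "x", 1.0), DoseEvent(1.0, "x", 1.0)))
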