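"""Shared fixtures.

The expensive simulations (the 50-subject paired trial, the efavirenz
steady-state run, the per-seed artemether-alone arms) are session-scoped so
the whole suite pays for them once.
"""
from __future__ import annotations

import numpy as np
import pytest

import pbpkdd as p
from pbpkdd.engine import build_model, simulate
from pbpkdd.trial import artemether_regimen, efavirenz_regimen, pk_metrics, run_population_trial, run_subject_arms


@pytest.fixture(scope="session")
def constants():
    return p.load_system_constants()


@pytest.fixture(scope="session")
def artemether():
    return p.builtin_drug("artemether")


@pytest.fixture(scope="session")
def efavirenz():
    return p.builtin_drug("efavirenz")


@pytest.fixture(scope="session")
def ref_subject():
    return p.reference_subject()


@pytest.fixture(scope="session")
def reference_arms(ref_subject, artemether, efavirenz, constants):
    """Reference-subject arms at 80/160/240 mg artemether."""
    return run_subject_arms(
        ref_subject, artemether, efavirenz, constants,
        art_doses_mg=(80.0, 160.0, 240.0),
    )


@pytest.fixture(scope="session")
def population_trial(artemether, efavirenz, constants):
    """The standard 50-subject paired trial, all scanned dose levels."""
    spec = p.PopulationSpec(
        n_subjects=50, age_range=(20.0, 50.0), proportion_female=0.5,
        random_seed=1,
    )
    return run_population_trial(
        spec, artemether, efavirenz, constants,
        art_doses_mg=(80.0, 160.0, 240.0),
    )


@pytest.fixture(scope="session")
def efv_steady_state(ref_subject, efavirenz, constants):
    """Efavirenz 600 mg once daily to steady state, reference subject."""
    model = build_model(ref_subject, [efavirenz], constants)
    regimen = efavirenz_regimen(21)
    profile = simulate(
        model, regimen, t_end=21 * 24.0, grid_start=18 * 24.0,
        grid_dt=0.1, atol=1e-6,
    )
    return pk_metrics(profile, regimen, "efavirenz", tau_h=24.0)


def artemether_alone_medians(seed, artemether, efavirenz, constants):
    """Median Cmax / windowed AUC of the artemether-alone arm for one seed."""
    spec = p.PopulationSpec(50, (20.0, 50.0), 0.5, random_seed=seed)
    subjects = p.sample_population(spec)
    regimen = artemether_regimen()
    cmax, auc = [], []
    for ind in subjects:
        model = build_model(ind, [artemether], constants)
        prof = simulate(model, regimen, t_end=68.0, grid_dt=0.05, atol=1e-6)
        met = pk_metrics(prof, regimen, "artemether", tau_h=12.0)
        cmax.append(met.cmax)
        auc.append(met.auc_window)
    return float(np.median(cmax)), float(np.median(auc))


@pytest.fixture(scope="session")
def alone_arm_medians_by_seed(artemether, efavirenz, constants):
    return {
        seed: artemether_alone_medians(seed, artemether, efavirenz, constants)
        for seed in (1, 2, 3)
    }
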