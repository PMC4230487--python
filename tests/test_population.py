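import math

import numpy as np
import pytest

import pbpkdd as p
from pbpkdd.population import FLOW_FRACTIONS, ORGANS, compute_organ_masses


def test_bsa_dubois_value():
    assert p.compute_bsa(70.0, 170.0) == pytest.approx(1.8097, abs=5e-4)


def test_bsa_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        p.compute_bsa(0.0, 170.0)
    with pytest.raises(ValueError):
        p.compute_bsa(70.0, -1.0)


def test_bsa_power_law_scaling():
    base = p.compute_bsa(70.0, 170.0)
    assert p.compute_bsa(140.0, 340.0) == pytest.approx(base * 2 ** 1.15, rel=1e-12)


def test_reference_subject_organ_masses_pinned(ref_subject):
    """Variability off: the reference male carries the anchored organ set."""
    m = ref_subject.organ_mass
    assert m["liver"] == pytest.approx(1.800, abs=1e-3)
    assert m["blood"] == pytest.approx(5.530, abs=1e-3)
    assert m["skin"] == pytest.approx(3.295, abs=1e-3)
    assert m["brain"] == pytest.approx(1.450, abs=1e-3)
    assert m["adipose"] == pytest.approx(15.352, abs=1e-3)
    assert m["bones"] == pytest.approx(10.5, abs=1e-6)
    assert set(m) == set(ORGANS)


def test_organ_masses_deterministic_without_variability():
    a = compute_organ_masses("male", 35.0, 176.0, 74.34, 24.0, 1.904, variability=False)
    b = compute_organ_masses("male", 35.0, 176.0, 74.34, 24.0, 1.904, variability=False)
    assert a == b


def test_mass_closure_is_exact(ref_subject):
    assert sum(ref_subject.organ_mass.values()) == pytest.approx(
        ref_subject.body_weight, rel=1e-12
    )


def test_brain_mass_age_dependence():
    """Brain mass follows the saturating growth / slow atrophy curve."""
    def factor(age):
        return (3.68 - 2.68 * math.exp(-age / 0.89)) * math.exp(-age / 629.0)

    m20 = compute_organ_masses("male", 20.0, 176.0, 74.34, 24.0, 1.904, variability=False)
    m50 = compute_organ_masses("male", 50.0, 176.0, 74.34, 24.0, 1.904, variability=False)
    assert m20["brain"] / m50["brain"] == pytest.approx(factor(20.0) / factor(50.0), rel=1e-9)


def test_allometric_masses_increase_with_height():
    short = compute_organ_masses("male", 35.0, 160.0, 61.4, 24.0, 1.76, variability=False)
    tall = compute_organ_masses("male", 35.0, 190.0, 86.6, 24.0, 2.05, variability=False)
    for organ in ("liver", "kidney", "heart", "lungs", "spleen", "bones"):
        assert tall[organ] > short[organ]


def test_cardiac_output_allometry():
    co81, _ = p.compute_flows(81.0)
    co16, _ = p.compute_flows(16.0)
    assert co81 / co16 == pytest.approx((81.0 / 16.0) ** 0.75, rel=1e-12)


def test_flow_fractions(ref_subject):
    co = ref_subject.cardiac_output
    f = ref_subject.regional_flow
    assert f["liver_total"] / co == pytest.approx(0.227, rel=1e-12)
    assert f["liver_portal"] / co == pytest.approx(0.181, rel=1e-12)
    assert f["liver_arterial"] == pytest.approx((0.227 - 0.181) * co, rel=1e-12)
    # splanchnic organs jointly carry the portal flow
    splanchnic = f["stomach"] + f["intestine"] + f["spleen"] + f["pancreas"]
    assert splanchnic == pytest.approx(f["liver_portal"], rel=1e-12)
    # arterial allocation closes exactly on cardiac output
    allocated = sum(
        f[k] for k in ("adipose", "bones", "brain", "kidney", "liver_total",
                       "muscle", "skin", "heart", "remaining")
    )
    assert allocated == pytest.approx(co, rel=1e-12)
    assert f["liver_portal"] < f["liver_total"]


def test_listed_fraction_sum_leaves_positive_residual():
    listed = sum(
        FLOW_FRACTIONS[k]
        for k in ("adipose", "bones", "brain", "kidney", "liver_total", "muscle", "skin")
    )
    assert listed == pytest.approx(0.859, abs=1e-9)
    assert listed < 1.0


def test_sampling_is_seed_deterministic():
    spec = p.PopulationSpec(5, (20, 50), 0.5, random_seed=42)
    a = p.sample_population(spec)
    b = p.sample_population(spec)
    for x, y in zip(a, b):
        assert x.sex == y.sex
        assert x.height_cm == y.height_cm
        assert x.organ_mass == y.organ_mass
        assert x.regional_flow == y.regional_flow


def test_population_size_and_sex_balance():
    spec = p.PopulationSpec(50, (20, 50), 0.5, random_seed=1)
    pop = p.sample_population(spec)
    assert len(pop) == 50
    n_female = sum(1 for s in pop if s.sex == "female")
    assert 15 <= n_female <= 35
    for s in pop:
        assert 20.0 <= s.age <= 50.0


def test_sex_proportion_converges_at_large_n():
    """Empirical sex split at n=1000 stays inside the binomial 99% band."""
    spec = p.PopulationSpec(1000, (20, 50), 0.5, random_seed=7)
    pop = p.sample_population(spec)
    frac = np.mean([s.sex == "female" for s in pop])
    assert 0.45 <= frac <= 0.55


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        p.PopulationSpec(0, (20, 50), 0.5, 1)
    with pytest.raises(ValueError):
        p.PopulationSpec(5, (50, 20), 0.5, 1)
    with pytest.raises(ValueError):
        p.PopulationSpec(5, (20, 50), 1.5, 1)


def test_sampled_individuals_satisfy_invariants():
    spec = p.PopulationSpec(200, (20, 50), 0.5, random_seed=3)
    for s in p.sample_population(spec):
        assert all(v > 0 for v in s.organ_mass.values())
        assert all(v > 0 for v in s.regional_flow.values())
        assert sum(s.organ_mass.values()) == pytest.approx(s.body_weight, rel=0.05)
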