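"""Virtual population physiology.

Generates virtual subjects — anthropometry, organ masses, cardiac output and
regional blood flows — with inter-individual variability, for use as the
"system" half of a PBPK model.  Organ masses follow log-linear allometric
scaling on height (slopes from a published population-physiology regression
set), anchored so that a 176-cm reference male carries standard reference
organ masses (liver 1.80 kg, brain 1.45 kg, ...).  Random variation is
applied as 10**eps with eps ~ Normal(0, SD) on each organ, SDs sex-specific
where the source reports them.  Skeletal muscle is the mass-balance
remainder, so organ masses always close exactly on body weight.

Cardiac output scales allometrically with body weight (CO = QCC * BW^0.75)
and is distributed over organs by fixed fractions; the splanchnic organs
(stomach, intestine, spleen, pancreas) jointly receive the portal fraction
and drain into the liver, which additionally receives a hepatic-artery
fraction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationSpec",
    "IndividualPhysiology",
    "compute_bsa",
    "compute_organ_masses",
    "compute_flows",
    "sample_population",
    "reference_subject",
    "ORGANS",
]

#: Organs carried in every individual's organ-mass map (kg).
ORGANS = (
    "blood", "lungs", "heart", "bones", "kidney", "stomach", "intestine",
    "spleen", "pancreas", "liver", "brain", "skin", "adipose", "muscle",
    "remaining",
)

# Allometric reference masses (kg) at the 176-cm reference male and
# height slopes b: mass = ref * (H / 1.76 m)^b * 10^eps.
# Slopes are the published log10(mass)-on-log10(height) regression slopes;
# reference masses are standard adult reference-man values.
_ALLOMETRIC = {
    #         ref_kg  slope   SD(log10) male, female
    "lungs":     (1.00, 2.10, 0.195, 0.195),
    "heart":     (0.33, 2.13, 0.069, 0.069),
    "bones":     (10.50, 2.67, 0.116, 0.083),
    "kidney":    (0.31, 1.93, 0.140, 0.140),
    "stomach":   (0.15, 2.45, 0.0965, 0.0425),
    "intestine": (1.20, 2.47, 0.049, 0.049),
    "spleen":    (0.15, 2.16, 0.156, 0.156),
    "pancreas":  (0.14, 2.43, 0.245, 0.087),
    "liver":     (1.80, 1.98, 0.028, 0.048),
    "remaining": (4.00, 1.95, 0.049, 0.049),
}

_REF_HEIGHT_CM = 176.0

# Brain: B * (3.68 - 2.68*exp(-age/0.89)) * exp(-age/629), age in years.
# B anchors brain mass to 1.45 kg for the 35-year-old reference adult.
_BRAIN_B = 1.45 / ((3.68 - 2.68 * math.exp(-35.0 / 0.89)) * math.exp(-35.0 / 629.0))
_BRAIN_SD = 0.084

_BLOOD_SD = 0.10
_SKIN_SD = 0.049

#: Cardiac output coefficient, L/h per kg^0.75 (standard PBPK reference).
QCC = 15.0

#: Regional blood flows as fractions of cardiac output.  The splanchnic
#: organs sum to the portal fraction 0.181; liver total = portal + arterial.
FLOW_FRACTIONS = {
    "adipose": 0.052,
    "bones": 0.042,
    "brain": 0.114,
    "kidney": 0.175,
    "liver_total": 0.227,
    "liver_portal": 0.181,
    "muscle": 0.191,
    "skin": 0.058,
    "heart": 0.040,
}
# Splanchnic split of the portal fraction (relative weights renormalised
# to 0.181): stomach 1 : intestine 15 : spleen 3 : pancreas 1.
_SPLANCHNIC_WEIGHTS = {"stomach": 1.0, "intestine": 15.0, "spleen": 3.0, "pancreas": 1.0}

#: Minimum admissible skeletal-muscle remainder (kg); a draw below this
#: triggers resampling of the whole individual.
MUSCLE_FLOOR_KG = 5.0

_MAX_RESAMPLES = 100

# Sex-conditional anthropometry: height ~ Normal, BMI ~ log-normal.
ANTHROPOMETRY = {
    "male": {"height_mean_cm": 176.0, "height_sd_cm": 7.0},
    "female": {"height_mean_cm": 163.0, "height_sd_cm": 6.0},
    "bmi_median": 24.0,
    "bmi_gsd": 1.15,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual cohort."""

    n_subjects: int
    age_range: tuple[float, float] = (20.0, 50.0)
    proportion_female: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if lo > hi:
            raise ValueError("age_range min must be <= max")
        if not 0.0 <= self.proportion_female <= 1.0:
            raise ValueError("proportion_female must be in [0, 1]")


@dataclass
class IndividualPhysiology:
    """One virtual subject's anatomy and haemodynamics."""

    sex: str
    age: float
    height_cm: float
    body_weight: float          # kg
    bmi: float                  # kg/m^2
    bsa: float                  # m^2
    organ_mass: dict[str, float] = field(default_factory=dict)   # kg
    cardiac_output: float = 0.0  # L/h
    regional_flow: dict[str, float] = field(default_factory=dict)  # L/h

    def validate(self) -> None:
        for organ, m in self.organ_mass.items():
            if not (m > 0 and math.isfinite(m)):
                raise ValueError(f"non-positive organ mass for {organ}: {m}")
        for organ, q in self.regional_flow.items():
            if not (q > 0 and math.isfinite(q)):
                raise ValueError(f"non-positive regional flow for {organ}: {q}")
        total = sum(self.organ_mass.values())
        if abs(total - self.body_weight) > 0.05 * self.body_weight:
            raise ValueError("organ masses do not close on body weight")
        # Arterial allocation (liver_total subsumes the splanchnic organs).
        allocated = sum(
            self.regional_flow[k]
            for k in ("adipose", "bones", "brain", "kidney", "liver_total",
                      "muscle", "skin", "heart", "remaining")
        )
        if allocated > self.cardiac_output * (1 + 1e-9):
            raise ValueError("regional flows exceed cardiac output")
        if not self.regional_flow["liver_portal"] < self.regional_flow["liver_total"]:
            raise ValueError("portal flow must be below total hepatic flow")


def compute_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m^2) by the DuBois formula.

    BSA = 0.007184 * BW^0.425 * H^0.725, weight in kg and height in cm.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg ** 0.425 * height_cm ** 0.725


def _percent_body_fat(bmi: float, age: float, sex: str) -> float:
    # Deurenberg body-fat equation; male coded 1.
    male = 1.0 if sex == "male" else 0.0
    return 1.2 * bmi + 0.23 * age - 10.8 * male - 5.4


def compute_organ_masses(
    sex: str,
    age: float,
    height_cm: float,
    body_weight: float,
    bmi: float,
    bsa: float,
    rng: np.random.Generator | None = None,
    variability: bool = True,
) -> dict[str, float]:
    """Organ-mass map (kg) for one subject.

    Allometric organs scale with height; blood and skin scale with BSA;
    adipose follows the body-fat-percent equation on BMI/age/sex; muscle is
    the remainder against body weight.  With ``variability`` each organ mass
    is multiplied by 10**eps, eps ~ N(0, SD).  Raises ``ValueError`` if the
    muscle remainder falls below the configured floor (caller resamples).
    """
    if rng is None or not variability:
        draw = lambda sd: 0.0  # noqa: E731
    else:
        draw = lambda sd: rng.normal(0.0, sd)  # noqa: E731

    col = 0 if sex == "male" else 1
    h_rel = height_cm / _REF_HEIGHT_CM
    masses: dict[str, float] = {}
    for organ, (ref, slope, sd_m, sd_f) in _ALLOMETRIC.items():
        sd = (sd_m, sd_f)[col]
        masses[organ] = ref * h_rel ** slope * 10.0 ** draw(sd)

    if sex == "male":
        blood = 3.33 * bsa - 0.81
    else:
        blood = 2.66 * bsa - 0.46
    masses["blood"] = blood * 10.0 ** draw(_BLOOD_SD)

    masses["skin"] = math.exp(1.64 * bsa - 1.93) * 10.0 ** draw(_SKIN_SD)

    brain = _BRAIN_B * (3.68 - 2.68 * math.exp(-age / 0.89)) * math.exp(-age / 629.0)
    masses["brain"] = brain * 10.0 ** draw(_BRAIN_SD)

    fat_pct = _percent_body_fat(bmi, age, sex)
    masses["adipose"] = max(fat_pct, 3.0) / 100.0 * body_weight

    other = sum(masses.values())
    muscle = body_weight - other
    if muscle < MUSCLE_FLOOR_KG:
        raise ValueError(
            f"muscle remainder {muscle:.2f} kg below floor {MUSCLE_FLOOR_KG} kg"
        )
    masses["muscle"] = muscle
    return masses


def compute_flows(body_weight: float, qcc: float = QCC) -> tuple[float, dict[str, float]]:
    """Cardiac output (L/h) and regional flow map for a body weight.

    CO = QCC * BW^0.75.  Fractions follow :data:`FLOW_FRACTIONS`; the
    splanchnic organs split the portal fraction; ``remaining`` absorbs the
    unallocated residual so that arterial allocations sum exactly to CO.
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    co = qcc * body_weight ** 0.75
    f = FLOW_FRACTIONS
    flows = {
        "adipose": co * f["adipose"],
        "bones": co * f["bones"],
        "brain": co * f["brain"],
        "kidney": co * f["kidney"],
        "muscle": co * f["muscle"],
        "skin": co * f["skin"],
        "heart": co * f["heart"],
        "liver_total": co * f["liver_total"],
        "liver_portal": co * f["liver_portal"],
        "liver_arterial": co * (f["liver_total"] - f["liver_portal"]),
    }
    wsum = sum(_SPLANCHNIC_WEIGHTS.values())
    for organ, w in _SPLANCHNIC_WEIGHTS.items():
        flows[organ] = co * f["liver_portal"] * w / wsum
    allocated = (
        f["adipose"] + f["bones"] + f["brain"] + f["kidney"] + f["muscle"]
        + f["skin"] + f["heart"] + f["liver_total"]
    )
    residual = 1.0 - allocated
    if residual < 0:
        raise ValueError("flow fractions exceed unity")
    flows["remaining"] = co * residual
    flows["lungs"] = co  # in series with the systemic circulation
    return co, flows


def _build_individual(
    sex: str, age: float, height_cm: float, bmi: float,
    rng: np.random.Generator | None, variability: bool,
) -> IndividualPhysiology:
    body_weight = bmi * (height_cm / 100.0) ** 2
    bsa = compute_bsa(body_weight, height_cm)
    masses = compute_organ_masses(
        sex, age, height_cm, body_weight, bmi, bsa, rng=rng, variability=variability
    )
    co, flows = compute_flows(body_weight)
    ind = IndividualPhysiology(
        sex=sex, age=age, height_cm=height_cm, body_weight=body_weight,
        bmi=bmi, bsa=bsa, organ_mass=masses, cardiac_output=co,
        regional_flow=flows,
    )
    ind.validate()
    return ind


def sample_population(spec: PopulationSpec) -> list[IndividualPhysiology]:
    """Draw ``spec.n_subjects`` virtual subjects, deterministically per seed.

    Sex ~ Bernoulli(proportion_female), age ~ Uniform(age_range), height
    sex-conditional Normal, BMI log-normal; an individual violating the
    physiological invariants is redrawn (up to 100 times, then the run
    aborts).  The number of resamples is recorded on the function attribute
    ``sample_population.last_resample_count``.
    """
    rng = np.random.default_rng(spec.random_seed)
    subjects: list[IndividualPhysiology] = []
    resamples = 0
    mu_bmi = math.log(ANTHROPOMETRY["bmi_median"])
    sd_bmi = math.log(ANTHROPOMETRY["bmi_gsd"])
    for _ in range(spec.n_subjects):
        for attempt in range(_MAX_RESAMPLES + 1):
            sex = "female" if rng.random() < spec.proportion_female else "male"
            age = rng.uniform(*spec.age_range)
            a = ANTHROPOMETRY[sex]
            height = rng.normal(a["height_mean_cm"], a["height_sd_cm"])
            bmi = math.exp(rng.normal(mu_bmi, sd_bmi))
            if not (height > 120.0 and math.isfinite(bmi)):
                resamples += 1
                continue
            try:
                subjects.append(_build_individual(sex, age, height, bmi, rng, True))
                break
            except ValueError:
                resamples += 1
        else:
            raise RuntimeError(
                "could not draw a physiologically valid subject after "
                f"{_MAX_RESAMPLES} resamples"
            )
    sample_population.last_resample_count = resamples  # type: ignore[attr-defined]
    return subjects


def reference_subject() -> IndividualPhysiology:
    """The deterministic reference adult: male, 35 y, 176 cm, BMI 24.

    All variability factors are unity; used for first-pass calibration,
    oracle tests and the deterministic acceptance chain.
    """
    return _build_individual("male", 35.0, 176.0, 24.0, rng=None, variability=False)
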