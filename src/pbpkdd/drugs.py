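"""Per-compound parameters and IVIVE system constants.

A :class:`DrugParameters` carries everything the simulator needs to know
about one compound: physicochemistry (logP, MW), plasma binding,
permeability input (either a Caco-2 Papp or a PSA/HBD pair), formulation
(first-order dissolution constant, optional dissolvable-fraction cap and
solubility), recombinant-isoform intrinsic clearances and, for inducers,
Emax/EC50 induction parameters per isoform.  :class:`SystemConstants`
carries the drug-independent scaling constants (CYP abundances, MPPGL,
intestinal CYP3A4 content, transit times, permeability regressions, tissue
composition).  Both load from human-readable YAML with validation; fixtures
for efavirenz and artemether ship with the package.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "DrugParameters",
    "InductionParams",
    "SystemConstants",
    "load_drug",
    "save_drug",
    "load_system_constants",
    "builtin_drug",
    "predict_fu_mic",
]


def _data_path(name: str):
    return importlib.resources.files("pbpkdd.data") / name


@dataclass(frozen=True)
class InductionParams:
    emax: float       # maximum fold-increase over baseline expression
    ec50_um: float    # driver concentration at half-maximal induction, uM

    def __post_init__(self) -> None:
        if self.emax < 0:
            raise ValueError("Emax must be >= 0")
        if self.ec50_um <= 0:
            raise ValueError("EC50 must be > 0")


@dataclass(frozen=True)
class DrugParameters:
    name: str
    molecular_weight: float           # g/mol
    logP: float
    fu_plasma: float                  # fraction unbound in plasma
    caco2_papp: float | None = None   # 1e-6 cm/s
    psa: float | None = None          # A^2
    hbd: int | None = None
    solubility_mg_l: float | None = None
    dissolution_kd_per_h: float | None = None
    dissolvable_fraction: float = 1.0
    clint_rec: dict[str, float] = field(default_factory=dict)  # uL/min/pmol
    clint_additional_hepatic_lh: float = 0.0  # unbound L/h at reference liver
    induction: dict[str, InductionParams] = field(default_factory=dict)
    fu_mic_measured: float | None = None
    blood_plasma_ratio_measured: float | None = None
    #: Empirical scalar applied to every tissue:plasma partition
    #: coefficient; the standard way of matching a composition-based Kp set
    #: to an observed in vivo volume of distribution.
    kp_scalar: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fu_plasma <= 1.0:
            raise ValueError(f"{self.name}: fu_plasma must be in (0, 1]")
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be positive")
        has_caco2 = self.caco2_papp is not None
        has_psa = self.psa is not None and self.hbd is not None
        if has_caco2 == has_psa:
            raise ValueError(
                f"{self.name}: exactly one permeability route required "
                "(caco2_papp or psa+hbd)"
            )
        for iso, cl in self.clint_rec.items():
            if cl < 0:
                raise ValueError(f"{self.name}: CLint for {iso} must be >= 0")
        if self.kp_scalar <= 0:
            raise ValueError(f"{self.name}: kp_scalar must be positive")
        if not 0.0 <= self.dissolvable_fraction <= 1.0:
            raise ValueError(f"{self.name}: dissolvable_fraction must be in [0, 1]")

    @property
    def blood_plasma_ratio(self) -> float:
        """Blood:plasma ratio; measured value, else 0.55 + 0.45*fu.

        The default assumes plasma-restricted distribution (no erythrocyte
        partitioning beyond water), conservative for highly bound drugs.
        """
        if self.blood_plasma_ratio_measured is not None:
            return self.blood_plasma_ratio_measured
        return 0.55 + 0.45 * self.fu_plasma

    @property
    def fu_blood(self) -> float:
        return self.fu_plasma / self.blood_plasma_ratio

    def ng_per_ml_to_um(self, conc_ng_ml: float) -> float:
        return conc_ng_ml / self.molecular_weight


def predict_fu_mic(logP: float, protein_mg_ml: float) -> float:
    """Fraction unbound in the microsomal incubation.

    Lipophilicity-based nonspecific-binding prediction
    (Hallifax & Houston form):

        log10 K = 0.072*logP^2 + 0.067*logP - 1.126
        fu_mic  = 1 / (1 + C * K)

    with C the microsomal protein concentration in mg/mL.  Always in (0, 1];
    tends to 1 for very hydrophilic compounds.
    """
    if protein_mg_ml <= 0:
        raise ValueError("protein concentration must be positive")
    k = 10.0 ** (0.072 * logP**2 + 0.067 * logP - 1.126)
    return 1.0 / (1.0 + protein_mg_ml * k)


def fu_mic(drug: DrugParameters, protein_mg_ml: float) -> float:
    """Measured fu_mic if configured, otherwise the logP-based prediction."""
    if drug.fu_mic_measured is not None:
        return drug.fu_mic_measured
    return predict_fu_mic(drug.logP, protein_mg_ml)


@dataclass(frozen=True)
class SystemConstants:
    """Drug-independent IVIVE/absorption/distribution constants."""

    cyp_abundance_liver: dict[str, float]        # pmol/mg microsomal protein
    mppgl: float                                 # mg/g liver
    intestinal_cyp3a4_nmol: float
    enterocyte_blood_flow_lh: float
    fu_gut: float
    microsomal_protein_conc_mg_ml: float
    small_intestine_radius_cm: float
    peff_caco2_regression: dict[str, float]
    peff_psa_hbd_regression: dict[str, float]
    stomach_transit_h: float
    small_intestine_transit_h: float
    n_intestinal_segments: int
    luminal_volumes_l: list[float]
    induction_onset_days: float
    induction_driver: str
    organ_density: dict[str, float]
    arterial_blood_fraction: float
    hematocrit: float
    tissue_composition: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, val in (
            ("mppgl", self.mppgl),
            ("intestinal_cyp3a4_nmol", self.intestinal_cyp3a4_nmol),
            ("enterocyte_blood_flow_lh", self.enterocyte_blood_flow_lh),
            ("stomach_transit_h", self.stomach_transit_h),
            ("small_intestine_transit_h", self.small_intestine_transit_h),
            ("small_intestine_radius_cm", self.small_intestine_radius_cm),
        ):
            if val <= 0:
                raise ValueError(f"system constant {name} must be positive")
        if self.n_intestinal_segments < 1:
            raise ValueError("n_intestinal_segments must be >= 1")
        if self.induction_driver not in ("liver_blood", "liver_total", "liver_unbound"):
            raise ValueError(f"unknown induction_driver {self.induction_driver!r}")

    def density(self, organ: str) -> float:
        return self.organ_density.get(organ, self.organ_density["default"])


# ---------------------------------------------------------------------------
# Loading / saving

_DRUG_KEYS = {
    "name", "molecular_weight", "logP", "fu_plasma", "permeability",
    "solubility_mg_l", "dissolution_kd_per_h", "dissolvable_fraction",
    "clint_rec", "clint_additional_hepatic_lh", "induction",
    "fu_mic_measured", "blood_plasma_ratio", "kp_scalar",
}


def _drug_from_dict(doc: dict[str, Any]) -> DrugParameters:
    unknown = set(doc) - _DRUG_KEYS
    if unknown:
        raise ValueError(f"unknown drug-config keys: {sorted(unknown)}")
    for key in ("name", "molecular_weight", "logP", "fu_plasma", "permeability"):
        if key not in doc:
            raise ValueError(f"drug config missing mandatory field {key!r}")
    perm = doc["permeability"] or {}
    induction = {
        iso: InductionParams(emax=float(p["emax"]), ec50_um=float(p["ec50_um"]))
        for iso, p in (doc.get("induction") or {}).items()
    }
    return DrugParameters(
        name=str(doc["name"]),
        molecular_weight=float(doc["molecular_weight"]),
        logP=float(doc["logP"]),
        fu_plasma=float(doc["fu_plasma"]),
        caco2_papp=perm.get("caco2_papp"),
        psa=perm.get("psa"),
        hbd=perm.get("hbd"),
        solubility_mg_l=doc.get("solubility_mg_l"),
        dissolution_kd_per_h=doc.get("dissolution_kd_per_h"),
        dissolvable_fraction=float(doc.get("dissolvable_fraction", 1.0)),
        clint_rec={k: float(v) for k, v in (doc.get("clint_rec") or {}).items()},
        clint_additional_hepatic_lh=float(doc.get("clint_additional_hepatic_lh", 0.0)),
        induction=induction,
        fu_mic_measured=doc.get("fu_mic_measured"),
        blood_plasma_ratio_measured=doc.get("blood_plasma_ratio"),
        kp_scalar=float(doc.get("kp_scalar", 1.0)),
    )


def load_drug(path: str | Path) -> DrugParameters:
    """Load and validate a drug definition from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: drug config must be a mapping")
    return _drug_from_dict(doc)


def save_drug(drug: DrugParameters, path: str | Path) -> None:
    """Write a drug definition back to YAML (round-trips with load_drug)."""
    perm: dict[str, Any]
    if drug.caco2_papp is not None:
        perm = {"caco2_papp": drug.caco2_papp}
    else:
        perm = {"psa": drug.psa, "hbd": drug.hbd}
    doc: dict[str, Any] = {
        "name": drug.name,
        "molecular_weight": drug.molecular_weight,
        "logP": drug.logP,
        "fu_plasma": drug.fu_plasma,
        "permeability": perm,
        "dissolvable_fraction": drug.dissolvable_fraction,
        "clint_rec": dict(drug.clint_rec),
        "clint_additional_hepatic_lh": drug.clint_additional_hepatic_lh,
        "kp_scalar": drug.kp_scalar,
        "induction": {
            iso: {"emax": p.emax, "ec50_um": p.ec50_um}
            for iso, p in drug.induction.items()
        },
    }
    for key, val in (
        ("solubility_mg_l", drug.solubility_mg_l),
        ("dissolution_kd_per_h", drug.dissolution_kd_per_h),
        ("fu_mic_measured", drug.fu_mic_measured),
        ("blood_plasma_ratio", drug.blood_plasma_ratio_measured),
    ):
        if val is not None:
            doc[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def builtin_drug(name: str) -> DrugParameters:
    """Load one of the shipped compound fixtures ('efavirenz', 'artemether')."""
    path = _data_path(f"{name}.yaml")
    if not path.is_file():
        raise ValueError(f"no builtin drug fixture named {name!r}")
    with path.open() as fh:
        return _drug_from_dict(yaml.safe_load(fh))


def load_system_constants(path: str | Path | None = None) -> SystemConstants:
    """Load system constants; defaults to the shipped constants file."""
    if path is None:
        with _data_path("system_constants.yaml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return SystemConstants(
        cyp_abundance_liver={k: float(v) for k, v in doc["cyp_abundance_liver"].items()},
        mppgl=float(doc["mppgl"]),
        intestinal_cyp3a4_nmol=float(doc["intestinal_cyp3a4_nmol"]),
        enterocyte_blood_flow_lh=float(doc["enterocyte_blood_flow_lh"]),
        fu_gut=float(doc["fu_gut"]),
        microsomal_protein_conc_mg_ml=float(doc["microsomal_protein_conc_mg_ml"]),
        small_intestine_radius_cm=float(doc["small_intestine_radius_cm"]),
        peff_caco2_regression=doc["peff_caco2_regression"],
        peff_psa_hbd_regression=doc["peff_psa_hbd_regression"],
        stomach_transit_h=float(doc["transit_times_h"]["stomach"]),
        small_intestine_transit_h=float(doc["transit_times_h"]["small_intestine"]),
        n_intestinal_segments=int(doc["n_intestinal_segments"]),
        luminal_volumes_l=[float(v) for v in doc["luminal_volumes_l"]],
        induction_onset_days=float(doc["induction_onset_days"]),
        induction_driver=str(doc["induction_driver"]),
        organ_density={k: float(v) for k, v in doc["organ_density"].items()},
        arterial_blood_fraction=float(doc["arterial_blood_fraction"]),
        hematocrit=float(doc["hematocrit"]),
        tissue_composition=doc["tissue_composition"],
    )
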