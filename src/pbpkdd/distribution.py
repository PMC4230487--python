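"""Tissue:plasma partition coefficients and volume of distribution.

Partitioning follows the tissue-composition model of Poulin & Theil: each
tissue is a mixture of neutral lipid, phospholipid and water, the drug
partitions into the lipid fractions according to its octanol-water
coefficient (vegetable-oil-water for adipose), and the tissue:plasma ratio
is corrected by the plasma/tissue unbound-fraction ratio.  Both shipped
compounds are treated as neutral at physiological pH (no pKa correction).
"""
from __future__ import annotations

import math

from .drugs import DrugParameters, SystemConstants
from .population import IndividualPhysiology

__all__ = ["kp_poulin_theil", "kp_map", "vss", "tissue_volume", "fu_tissue"]

#: Engine tissues that require a partition coefficient.
PERFUSED_TISSUES = (
    "lungs", "heart", "brain", "kidney", "liver", "stomach", "intestine",
    "spleen", "pancreas", "skin", "adipose", "muscle", "bones", "remaining",
)


def fu_tissue(fu_plasma: float, tissue: str) -> float:
    """Fraction unbound in tissue under the macro-binding assumption.

    Non-adipose tissues are assumed to carry half the binding-protein
    concentration of plasma: fu_t = 1 / (1 + 0.5*(1 - fu_p)/fu_p).
    Adipose binding proteins are negligible: fu_t = 1.
    """
    if tissue == "adipose":
        return 1.0
    return 1.0 / (1.0 + 0.5 * (1.0 - fu_plasma) / fu_plasma)


def _mixture(p: float, comp: dict[str, float]) -> float:
    # lipid-water mixture solubility weight: P*(Vnl + 0.3*Vph) + (Vw + 0.7*Vph)
    return (
        p * (comp["neutral_lipid"] + 0.3 * comp["phospholipid"])
        + comp["water"] + 0.7 * comp["phospholipid"]
    )


def kp_poulin_theil(
    drug: DrugParameters, tissue: str, constants: SystemConstants
) -> float:
    """Tissue:plasma partition coefficient for one tissue.

    Kp = mixture(tissue) / mixture(plasma) * fu_p / fu_t with the
    octanol-water partition P = 10**logP for all tissues except adipose,
    which uses the vegetable-oil-water partition
    log Pvo:w = 1.115*logP - 1.35.
    """
    comps = constants.tissue_composition
    if tissue not in comps:
        raise KeyError(f"no tissue composition configured for {tissue!r}")
    if tissue == "adipose":
        p = 10.0 ** (1.115 * drug.logP - 1.35)
    else:
        p = 10.0 ** drug.logP
    ratio = _mixture(p, comps[tissue]) / _mixture(p, comps["plasma"])
    return ratio * drug.fu_plasma / fu_tissue(drug.fu_plasma, tissue) * drug.kp_scalar


def kp_map(drug: DrugParameters, constants: SystemConstants) -> dict[str, float]:
    """Partition coefficients for every perfused tissue."""
    return {t: kp_poulin_theil(drug, t, constants) for t in PERFUSED_TISSUES}


def tissue_volume(
    individual: IndividualPhysiology, organ: str, constants: SystemConstants
) -> float:
    """Organ volume in litres from mass and density."""
    return individual.organ_mass[organ] / constants.density(organ)


def vss(
    kps: dict[str, float],
    individual: IndividualPhysiology,
    constants: SystemConstants,
) -> float:
    """Steady-state volume of distribution (L), plasma-referenced.

    Vss = V_plasma + sum_t Kp_t * V_t over perfused tissues.
    """
    v_plasma = (
        tissue_volume(individual, "blood", constants) * (1.0 - constants.hematocrit)
    )
    total = v_plasma
    for tissue, kp in kps.items():
        total += kp * tissue_volume(individual, tissue, constants)
    return total
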