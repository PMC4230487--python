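"""IVIVE clearance scaling, first-pass availability and enzyme induction.

Recombinant-isoform intrinsic clearances (uL/min/pmol) are scaled to
whole-organ intrinsic clearance with isoform abundance (pmol/mg microsomal
protein), microsomal protein per gram liver (MPPGL) and liver mass — or,
for the gut wall, the total intestinal CYP3A4 content — and corrected for
nonspecific binding in the incubation (fu_mic).  Availability and
clearance follow the well-stirred liver model:

    Fg  = Qg / (Qg + fu_gut * CLint_gut)
    Fh  = Qh / (Qh + fu_b * CLint_h)        (Qh = total hepatic blood flow)
    CLh = Qh * fu_b * CLint_h / (Qh + fu_b * CLint_h)

with fu_b the fraction unbound in blood.  An inducer raises hepatic
per-isoform expression by the saturable factor E = 1 + Emax*I/(EC50 + I),
ramping linearly from nothing to full effect over a fixed onset period
(default 14 days); gut-wall expression is deliberately left uninduced.
"""
from __future__ import annotations

from dataclasses import dataclass

from .drugs import DrugParameters, SystemConstants, fu_mic

__all__ = [
    "scale_clint_liver",
    "scale_clint_gut",
    "fg",
    "fh",
    "clh_well_stirred",
    "induction_multiplier",
    "induction_onset",
    "DerivedClearances",
    "derive_clearances",
]

_REFERENCE_LIVER_G = 1800.0  # anchors the per-drug additional CLint term

# 1 uL/min = 1e-6 L/min = 6e-5 L/h
_UL_MIN_TO_L_H = 6e-5


def scale_clint_liver(
    drug: DrugParameters, constants: SystemConstants, liver_mass_g: float
) -> dict[str, float]:
    """Unbound hepatic intrinsic clearance per isoform, L/h.

    CLint_iso = clint_rec (uL/min/pmol) * abundance (pmol/mg) * MPPGL (mg/g)
    * liver mass (g) / fu_mic, converted to L/h.  Any additional (non-CYP)
    hepatic clearance configured on the drug is returned under the key
    ``"other"``, scaled linearly with liver mass from the reference liver.
    The per-isoform split is retained because induction acts per isoform.
    """
    if liver_mass_g <= 0:
        raise ValueError("liver mass must be positive")
    fum = fu_mic(drug, constants.microsomal_protein_conc_mg_ml)
    scale = constants.mppgl * liver_mass_g
    out: dict[str, float] = {}
    for iso, clint in drug.clint_rec.items():
        if iso not in constants.cyp_abundance_liver:
            raise KeyError(
                f"{drug.name}: no hepatic abundance configured for {iso}"
            )
        abundance = constants.cyp_abundance_liver[iso]
        out[iso] = clint * abundance * scale * _UL_MIN_TO_L_H / fum
    if drug.clint_additional_hepatic_lh:
        out["other"] = (
            drug.clint_additional_hepatic_lh * liver_mass_g / _REFERENCE_LIVER_G
        )
    return out


def scale_clint_gut(drug: DrugParameters, constants: SystemConstants) -> float:
    """Unbound gut-wall intrinsic clearance, L/h (CYP3A4 only)."""
    clint = drug.clint_rec.get("CYP3A4", 0.0)
    fum = fu_mic(drug, constants.microsomal_protein_conc_mg_ml)
    # uL/min/pmol * nmol -> (x1000 pmol) uL/min
    return clint * constants.intestinal_cyp3a4_nmol * 1000.0 * _UL_MIN_TO_L_H / fum


def fg(qg: float, fu_gut: float, clint_gut: float) -> float:
    """Fraction escaping gut-wall metabolism."""
    if qg <= 0:
        raise ValueError("enterocyte blood flow must be positive")
    return qg / (qg + fu_gut * clint_gut)


def fh(q_hepatic: float, fu_blood: float, clint_h: float) -> float:
    """Fraction escaping hepatic first pass (1 - hepatic extraction).

    Evaluated with total hepatic blood flow (portal + arterial), the flow
    actually perfusing the organ during first pass, which keeps Fh and the
    well-stirred clearance mutually consistent (CLh = Qh * (1 - Fh)).
    """
    if q_hepatic <= 0:
        raise ValueError("hepatic flow must be positive")
    return q_hepatic / (q_hepatic + fu_blood * clint_h)


def clh_well_stirred(qh: float, fu_blood: float, clint_h: float) -> float:
    """Well-stirred hepatic blood clearance, L/h; always below Qh."""
    if qh <= 0:
        raise ValueError("hepatic blood flow must be positive")
    x = fu_blood * clint_h
    return qh * x / (qh + x)


def induction_multiplier(emax: float, ec50_um: float, i_um: float) -> float:
    """Saturable fold-increase in enzyme expression: 1 + Emax*I/(EC50 + I)."""
    if ec50_um <= 0:
        raise ValueError("EC50 must be positive")
    if i_um < 0:
        raise ValueError("inducer concentration must be non-negative")
    return 1.0 + emax * i_um / (ec50_um + i_um)


def induction_onset(t_since_start_h: float, onset_days: float = 14.0) -> float:
    """Linear onset ramp: 0 at inducer start, 1 from ``onset_days`` onward."""
    if t_since_start_h < 0:
        return 0.0
    return min(t_since_start_h / (onset_days * 24.0), 1.0)


@dataclass(frozen=True)
class DerivedClearances:
    """Per-subject, per-drug first-pass and clearance report (baseline)."""

    clint_h_by_isoform: dict[str, float]   # unbound, L/h
    clint_h_total: float                   # unbound, L/h
    clint_gut: float                       # unbound, L/h
    fu_blood: float
    fg: float
    fh: float
    clh: float                             # blood clearance, L/h

    def induced_clint_h(self, multipliers: dict[str, float]) -> float:
        """Total hepatic CLint with per-isoform expression multipliers."""
        total = 0.0
        for iso, cl in self.clint_h_by_isoform.items():
            total += cl * multipliers.get(iso, 1.0)
        return total


def derive_clearances(
    drug: DrugParameters,
    constants: SystemConstants,
    liver_mass_g: float,
    q_hepatic_total: float,
    q_hepatic_portal: float,
) -> DerivedClearances:
    """Assemble the baseline clearance chain for one subject and drug."""
    by_iso = scale_clint_liver(drug, constants, liver_mass_g)
    total = sum(by_iso.values())
    cl_gut = scale_clint_gut(drug, constants)
    fub = drug.fu_blood
    return DerivedClearances(
        clint_h_by_isoform=by_iso,
        clint_h_total=total,
        clint_gut=cl_gut,
        fu_blood=fub,
        fg=fg(constants.enterocyte_blood_flow_lh, constants.fu_gut, cl_gut),
        fh=fh(q_hepatic_total, fub, total),
        clh=clh_well_stirred(q_hepatic_total, fub, total),
    )
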