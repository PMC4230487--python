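"""Oral absorption: compartmental absorption and transit (CAT) model.

A stomach plus a chain of small-intestine segments with first-order
transit.  Solid drug dissolves with a first-order dissolution constant
(optionally capped by luminal solubility); dissolved drug in the intestinal
segments is absorbed with a first-order constant ka derived from the human
effective jejunal permeability, ka = 2*Peff/r (cylindrical tube).  Peff
comes from either a Caco-2 log-log correlation or a PSA/HBD regression.
Drug exiting the last segment — including any never-dissolvable fraction of
a poorly soluble dose — counts as unabsorbed.

The gut state block is shared with the whole-body engine; it can also be
integrated standalone to study Fa in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .drugs import DrugParameters, SystemConstants

__all__ = [
    "peff_from_caco2",
    "peff_from_psa_hbd",
    "peff_for_drug",
    "ka_from_peff",
    "GutParams",
    "gut_params_for_drug",
    "gut_rhs",
    "simulate_gut",
    "compute_fa",
]


def peff_from_caco2(papp: float, constants: SystemConstants) -> float:
    """Human jejunal Peff (1e-4 cm/s) from Caco-2 Papp (1e-6 cm/s)."""
    if papp <= 0:
        raise ValueError("Caco-2 Papp must be positive")
    reg = constants.peff_caco2_regression
    return 10.0 ** (reg["slope"] * np.log10(papp) + reg["intercept"])


def peff_from_psa_hbd(psa: float, hbd: int, constants: SystemConstants) -> float:
    """Human jejunal Peff (1e-4 cm/s) from polar surface area and H-bond donors.

    Peff decreases in both PSA and HBD.
    """
    if psa < 0 or hbd < 0:
        raise ValueError("PSA and HBD must be non-negative")
    reg = constants.peff_psa_hbd_regression
    return 10.0 ** (reg["intercept"] + reg["psa_coeff"] * psa + reg["hbd_coeff"] * hbd)


def peff_for_drug(drug: DrugParameters, constants: SystemConstants) -> float:
    if drug.caco2_papp is not None:
        return peff_from_caco2(drug.caco2_papp, constants)
    return peff_from_psa_hbd(drug.psa, drug.hbd, constants)


def ka_from_peff(peff_1e4_cm_s: float, radius_cm: float) -> float:
    """First-order absorption constant (1/h) from Peff and tube radius.

    ka = 2 * Peff / r for absorption across the wall of a cylinder.
    """
    if peff_1e4_cm_s <= 0 or radius_cm <= 0:
        raise ValueError("Peff and radius must be positive")
    return 2.0 * peff_1e4_cm_s * 1e-4 / radius_cm * 3600.0


@dataclass(frozen=True)
class GutParams:
    """Resolved kinetic constants of the CAT model for one drug."""

    ka: float              # 1/h, per intestinal segment
    kd: float              # 1/h, first-order dissolution
    ks: float              # 1/h, gastric emptying
    kt: float              # 1/h, segment-to-segment transit
    n_segments: int
    dissolvable_fraction: float
    solubility_ng_l: float | None
    luminal_volumes_l: tuple[float, ...]   # stomach first, then segments

    @property
    def n_states(self) -> int:
        # stomach (solid, inert, dissolved) + per-segment triple
        # + cumulative absorbed + cumulative exited
        return 3 + 3 * self.n_segments + 2


def gut_params_for_drug(drug: DrugParameters, constants: SystemConstants) -> GutParams:
    peff = peff_for_drug(drug, constants)
    ka = ka_from_peff(peff, constants.small_intestine_radius_cm)
    kd = drug.dissolution_kd_per_h
    if kd is None:
        kd = 1e6  # effectively instantaneous dissolution
    sol = None
    if drug.solubility_mg_l is not None:
        sol = drug.solubility_mg_l * 1e6  # mg/L -> ng/L
    return GutParams(
        ka=ka,
        kd=kd,
        ks=1.0 / constants.stomach_transit_h,
        kt=constants.n_intestinal_segments / constants.small_intestine_transit_h,
        n_segments=constants.n_intestinal_segments,
        dissolvable_fraction=drug.dissolvable_fraction,
        solubility_ng_l=sol,
        luminal_volumes_l=tuple(constants.luminal_volumes_l),
    )


def gut_rhs(y: np.ndarray, gp: GutParams) -> tuple[np.ndarray, float]:
    """Time derivative of a gut state block and the lumen-absorption flux.

    ``y`` layout: [stomach_solid, stomach_inert, stomach_dissolved,
    seg_solid[n], seg_inert[n], seg_dissolved[n], cum_absorbed, cum_exited],
    amounts in ng.  Returns (dy, absorbed_flux_ng_per_h); the flux is the
    drug leaving the lumen across the gut wall (before gut-wall metabolism).
    """
    n = gp.n_segments
    dy = np.zeros_like(y)
    st_sol, st_in, st_dis = y[0], y[1], y[2]
    seg_sol = y[3:3 + n]
    seg_in = y[3 + n:3 + 2 * n]
    seg_dis = y[3 + 2 * n:3 + 3 * n]

    # dissolution rates, optionally solubility-capped per compartment
    if gp.solubility_ng_l is None:
        r_st = gp.kd * st_sol
        r_seg = gp.kd * seg_sol
    else:
        vols = np.asarray(gp.luminal_volumes_l)
        cap_st = max(0.0, 1.0 - (st_dis / vols[0]) / gp.solubility_ng_l)
        cap_seg = np.clip(1.0 - (seg_dis / vols[1:]) / gp.solubility_ng_l, 0.0, 1.0)
        r_st = gp.kd * st_sol * cap_st
        r_seg = gp.kd * seg_sol * cap_seg

    dy[0] = -r_st - gp.ks * st_sol
    dy[1] = -gp.ks * st_in
    dy[2] = r_st - gp.ks * st_dis

    # solids
    dy[3] = gp.ks * st_sol - gp.kt * seg_sol[0] - r_seg[0]
    dy[4:3 + n] = gp.kt * seg_sol[:-1] - gp.kt * seg_sol[1:] - r_seg[1:]
    # inert (never-dissolvable) fraction just transits
    dy[3 + n] = gp.ks * st_in - gp.kt * seg_in[0]
    dy[4 + n:3 + 2 * n] = gp.kt * seg_in[:-1] - gp.kt * seg_in[1:]
    # dissolved: dissolution + inflow - transit - absorption
    absorbed = gp.ka * seg_dis
    dy[3 + 2 * n] = r_seg[0] + gp.ks * st_dis - gp.kt * seg_dis[0] - absorbed[0]
    dy[4 + 2 * n:3 + 3 * n] = (
        r_seg[1:] + gp.kt * seg_dis[:-1] - gp.kt * seg_dis[1:] - absorbed[1:]
    )
    flux = float(absorbed.sum())
    dy[3 + 3 * n] = flux
    dy[3 + 3 * n + 1] = gp.kt * (seg_sol[-1] + seg_in[-1] + seg_dis[-1])
    return dy, flux


def apply_oral_dose(y: np.ndarray, gp: GutParams, dose_ng: float) -> None:
    """Add an oral dose to the stomach pools in place."""
    y[0] += gp.dissolvable_fraction * dose_ng
    y[1] += (1.0 - gp.dissolvable_fraction) * dose_ng


def simulate_gut(
    drug: DrugParameters,
    constants: SystemConstants,
    dose_mg: float,
    t_end_h: float = 24.0,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> dict:
    """Integrate the gut submodel alone for a single oral dose.

    Returns a dict with times, the state matrix, the administered dose (ng)
    and the terminal cumulative amounts.
    """
    gp = gut_params_for_drug(drug, constants)
    dose_ng = dose_mg * 1e6
    y0 = np.zeros(gp.n_states)
    apply_oral_dose(y0, gp, dose_ng)

    def rhs(t, y):
        return gut_rhs(y, gp)[0]

    t_eval = np.linspace(0.0, t_end_h, 481)
    sol = solve_ivp(rhs, (0.0, t_end_h), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"gut integration failed: {sol.message}")
    return {
        "t": sol.t,
        "y": sol.y,
        "dose_ng": dose_ng,
        "params": gp,
        "absorbed_ng": float(sol.y[-2, -1]),
        "exited_ng": float(sol.y[-1, -1]),
    }


def compute_fa(gut_result: dict, mass_balance_tol: float = 0.005) -> float:
    """Fraction of dose absorbed from the lumen.

    Requires the simulation to have run to >= 95% dose disposition
    (absorbed + transited out); raises on a lumen mass-balance violation
    beyond ``mass_balance_tol``.
    """
    dose = gut_result["dose_ng"]
    y_end = gut_result["y"][:, -1]
    absorbed, exited = y_end[-2], y_end[-1]
    lumen = float(y_end[:-2].sum())
    balance = (lumen + absorbed + exited - dose) / dose
    if abs(balance) > mass_balance_tol:
        raise ValueError(f"gut mass balance violated by {balance:.2%}")
    if (absorbed + exited) / dose < 0.95:
        raise ValueError("absorption window too short: <95% of dose disposed")
    return absorbed / dose
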