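"""Virtual clinical trial runner.

Builds the standard efavirenz/artemether interaction study — efavirenz
600 mg once daily for 14 days, then artemether 80 mg at 0 and 8 h followed
by 80 mg twice daily for two more days (six doses), with efavirenz
continued — runs it over a virtual population with paired arms (the same
subjects with and without the inducer), extracts per-subject PK metrics and
population summaries, and scans artemether dose levels to find the dose
restoring exposure under the interaction.

Two AUC readouts are computed for every final dosing interval: the full
interval AUC (used for CL/F = dose/AUC_tau) and an AUC truncated 8 h after
the last dose, which matches the sampling window of the clinical studies
this trial design mirrors and is the exposure metric reported by
:func:`summarise`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .absorption import compute_fa, simulate_gut
from .clearance import fh as fh_eq
from .clearance import induction_multiplier
from .drugs import DrugParameters, SystemConstants
from .engine import (
    ConcentrationProfile,
    DoseEvent,
    DosingRegimen,
    ModelInstance,
    build_model,
    simulate,
)
from .population import IndividualPhysiology, PopulationSpec, sample_population

__all__ = [
    "DoseEvent",
    "DosingRegimen",
    "PKMetrics",
    "PopulationSummary",
    "artemether_regimen",
    "efavirenz_regimen",
    "standard_trial",
    "pk_metrics",
    "run_subject_arms",
    "run_population_trial",
    "dose_scan",
    "summarise",
    "TrialResult",
]

EFV_LEAD_IN_DAYS = 14
EFV_DOSE_MG = 600.0
ART_DOSE_MG = 80.0
#: Artemether schedule relative to its first dose: two doses 8 h apart,
#: then twice daily for two days (six doses over three days).
ART_SCHEDULE_H = (0.0, 8.0, 20.0, 32.0, 44.0, 56.0)
ART_TAU_H = 12.0
AUC_WINDOW_H = 8.0  # clinical-comparator sampling window


def artemether_regimen(
    dose_mg: float = ART_DOSE_MG, start_h: float = 0.0, label: str = "ART"
) -> DosingRegimen:
    events = tuple(
        DoseEvent(start_h + t, "artemether", dose_mg) for t in ART_SCHEDULE_H
    )
    return DosingRegimen(events, label=label)


def efavirenz_regimen(
    n_doses: int, dose_mg: float = EFV_DOSE_MG, label: str = "EFV"
) -> DosingRegimen:
    events = tuple(
        DoseEvent(24.0 * i, "efavirenz", dose_mg) for i in range(n_doses)
    )
    return DosingRegimen(events, label=label)


def standard_trial(
    art_dose_mg: float = ART_DOSE_MG,
) -> tuple[DosingRegimen, DosingRegimen, DosingRegimen]:
    """(EFV lead-in, artemether-alone, artemether+EFV) regimens.

    The lead-in covers days 1-14 (14 doses); in the combination arm
    efavirenz continues daily while artemether is dosed from day 15.
    """
    art_start = EFV_LEAD_IN_DAYS * 24.0
    lead_in = efavirenz_regimen(EFV_LEAD_IN_DAYS, label="EFV lead-in")
    art_alone = artemether_regimen(art_dose_mg, start_h=0.0, label="ART")
    n_efv = EFV_LEAD_IN_DAYS + 3  # continued through the artemether days
    combined_events = tuple(sorted(
        efavirenz_regimen(n_efv).events
        + artemether_regimen(art_dose_mg, start_h=art_start).events,
        key=lambda e: e.time_h,
    ))
    combined = DosingRegimen(combined_events, label="ART+EFV")
    return lead_in, art_alone, combined


@dataclass
class PKMetrics:
    """Per-subject, per-drug pharmacokinetic readouts (final interval)."""

    cmax: float            # ng/mL
    tmax: float            # h after last dose
    ctrough: float         # ng/mL
    auc_tau: float         # ng*h/mL over the full final interval
    auc_window: float      # ng*h/mL over the first AUC_WINDOW_H of it
    cl_over_f: float       # L/h, dose / auc_tau
    v_over_f: float        # L, CL/F * t_half / ln 2 (nan if slope >= 0)
    t_half: float          # h, terminal, from the last quartile
    fa: float = math.nan
    fg: float = math.nan
    fh: float = math.nan
    foral: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def pk_metrics(
    profile: ConcentrationProfile,
    regimen: DosingRegimen,
    drug: str,
    tau_h: float | None = None,
    window_h: float = AUC_WINDOW_H,
) -> PKMetrics:
    """Extract PK metrics over the final dosing interval of ``drug``.

    The profile must span the final interval at <=0.1 h resolution.  The
    terminal slope is fitted by log-linear regression over the last quartile
    of the post-final-dose curve; a non-negative slope leaves V/F missing.
    """
    doses = regimen.for_drug(drug)
    if not doses:
        raise ValueError(f"regimen contains no doses of {drug}")
    t_last = doses[-1].time_h
    if tau_h is None:
        if len(doses) >= 2:
            tau_h = t_last - doses[-2].time_h
        else:
            tau_h = profile.t[-1] - t_last
    t_end = t_last + tau_h
    if profile.t[-1] < t_end - 1e-9:
        raise ValueError("profile does not span the final dosing interval")

    t = profile.t
    c = profile.plasma[drug]
    sel = (t >= t_last - 1e-9) & (t <= t_end + 1e-9)
    ti, ci = t[sel], c[sel]

    cmax = float(ci.max())
    tmax = float(ti[int(ci.argmax())] - t_last)
    ctrough = float(np.interp(t_end, ti, ci))
    auc_tau = float(np.trapezoid(ci, ti))
    w_end = t_last + min(window_h, tau_h)
    selw = ti <= w_end + 1e-9
    auc_window = float(np.trapezoid(ci[selw], ti[selw]))

    dose_ng = doses[-1].dose_mg * 1e6
    cl_over_f = dose_ng / auc_tau / 1000.0 if auc_tau > 0 else math.nan

    # terminal slope over the last quartile of the post-dose curve
    fit_start = t_last + 0.75 * tau_h
    fsel = (ti >= fit_start) & (ci > 0)
    t_half = math.nan
    v_over_f = math.nan
    if fsel.sum() >= 3:
        slope = np.polyfit(ti[fsel], np.log(ci[fsel]), 1)[0]
        if slope < 0:
            t_half = float(-math.log(2.0) / slope)
            v_over_f = cl_over_f * t_half / math.log(2.0)
    return PKMetrics(
        cmax=cmax, tmax=tmax, ctrough=ctrough, auc_tau=auc_tau,
        auc_window=auc_window, cl_over_f=cl_over_f, v_over_f=v_over_f,
        t_half=t_half,
    )


@dataclass
class PopulationSummary:
    """Across-subject summary of one metric."""

    n: int
    median: float
    minimum: float
    maximum: float
    mean: float
    sd: float

    @classmethod
    def of(cls, values: "pd.Series | np.ndarray") -> "PopulationSummary":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        return cls(
            n=int(v.size), median=float(np.median(v)), minimum=float(v.min()),
            maximum=float(v.max()), mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        )


def _first_pass_chain(
    drug: DrugParameters,
    constants: SystemConstants,
    model: ModelInstance,
    dose_mg: float,
) -> tuple[float, float, float]:
    """(Fa, Fg, Fh) for one subject at baseline expression."""
    gut = simulate_gut(drug, constants, dose_mg, t_end_h=24.0)
    fa = compute_fa(gut)
    d = model.blocks[drug.name].derived
    return fa, d.fg, d.fh


def induced_fh(
    model: ModelInstance,
    victim: str,
    inducer: str,
    inducer_blood_um: float,
) -> float:
    """Hepatic availability of the victim at a given inducer exposure,
    full induction onset."""
    v = model.blocks[victim]
    ind = model.blocks[inducer].drug.induction
    mult = {
        iso: induction_multiplier(p.emax, p.ec50_um, inducer_blood_um)
        for iso, p in ind.items()
    }
    clint = v.derived.induced_clint_h(mult)
    return fh_eq(
        model.individual.regional_flow["liver_total"], v.fu_blood, clint
    )


# ---------------------------------------------------------------------------
# Arm execution


@dataclass
class SubjectArmResult:
    subject_id: int
    arm: str
    drug: str
    metrics: PKMetrics


def run_subject_arms(
    individual: IndividualPhysiology,
    art: DrugParameters,
    efv: DrugParameters,
    constants: SystemConstants,
    art_doses_mg: tuple[float, ...] = (ART_DOSE_MG,),
    grid_dt: float = 0.05,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    compute_first_pass: bool = True,
) -> dict[str, PKMetrics]:
    """All arms for one subject; keys 'ART', 'ART+EFV@<dose>', 'EFV'.

    The efavirenz lead-in is integrated once (single-drug system — the
    victim block is identically zero before its first dose) and its final
    state seeds every combination arm, which co-integrates both drugs.
    """
    lead_in, art_alone, _ = standard_trial()
    art_start = EFV_LEAD_IN_DAYS * 24.0
    t_alone_end = ART_SCHEDULE_H[-1] + ART_TAU_H

    out: dict[str, PKMetrics] = {}

    # artemether alone
    m_art = build_model(individual, [art], constants)
    prof = simulate(m_art, art_alone, t_end=t_alone_end,
                    grid_dt=grid_dt, rtol=rtol, atol=atol)
    met = pk_metrics(prof, art_alone, "artemether", tau_h=ART_TAU_H)
    if compute_first_pass:
        met.fa, met.fg, met.fh = _first_pass_chain(art, constants, m_art, ART_DOSE_MG)
        met.foral = met.fa * met.fg * met.fh
    out["ART"] = met

    # efavirenz lead-in (single-drug), coarse grid
    m_efv = build_model(individual, [efv], constants)
    lead = simulate(m_efv, lead_in, t_end=art_start,
                    grid_dt=1.0, rtol=rtol, atol=atol)
    efv_trough = float(lead.plasma["efavirenz"][-1])

    # combination arms: seed the two-drug system with the lead-in state
    for dose in art_doses_mg:
        _, _, combined = standard_trial(art_dose_mg=dose)
        m_both = build_model(individual, [efv, art], constants)
        m_both.inducer_start_h["efavirenz"] = 0.0
        n_efv_states = m_both.blocks["efavirenz"].n_states
        y0 = np.zeros(m_both.n_states)
        y0[:n_efv_states] = lead.y_final
        prof = simulate(
            m_both, combined, t_end=art_start + t_alone_end, t0=art_start,
            y0=y0, grid_start=art_start, grid_dt=grid_dt, rtol=rtol, atol=atol,
        )
        met = pk_metrics(prof, combined, "artemether", tau_h=ART_TAU_H)
        if compute_first_pass:
            fa, fg_b, _ = _first_pass_chain(art, constants, m_both, dose)
            # hepatic availability at the subject's actual inducer exposure
            efv_block = m_both.blocks["efavirenz"]
            css_blood_um = (
                float(np.mean(prof.plasma["efavirenz"])) * efv_block.bp
                / efv.molecular_weight
            )
            fh_i = induced_fh(m_both, "artemether", "efavirenz", css_blood_um)
            met.fa, met.fg, met.fh = fa, fg_b, fh_i
            met.foral = fa * fg_b * fh_i
        out[f"ART+EFV@{dose:g}"] = met

    # efavirenz steady-state metrics from the lead-in (trough at day 14)
    out["EFV"] = PKMetrics(
        cmax=float(lead.plasma["efavirenz"].max()), tmax=math.nan,
        ctrough=efv_trough, auc_tau=math.nan, auc_window=math.nan,
        cl_over_f=math.nan, v_over_f=math.nan, t_half=math.nan,
    )
    return out


@dataclass
class TrialResult:
    per_subject: pd.DataFrame
    summaries: dict[str, dict[str, PopulationSummary]]
    n_failed: int
    failed_subjects: list[int]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for arm, metrics in self.summaries.items():
            for metric, s in metrics.items():
                rows.append({
                    "arm": arm, "metric": metric, "n": s.n, "median": s.median,
                    "min": s.minimum, "max": s.maximum, "mean": s.mean, "sd": s.sd,
                })
        return pd.DataFrame(rows)


_SUMMARY_METRICS = (
    "cmax", "ctrough", "auc_tau", "auc_window", "cl_over_f", "v_over_f",
    "fa", "fg", "fh", "foral",
)


def summarise(per_subject: pd.DataFrame) -> dict[str, dict[str, PopulationSummary]]:
    out: dict[str, dict[str, PopulationSummary]] = {}
    for arm, grp in per_subject.groupby("arm", sort=True):
        out[arm] = {
            m: PopulationSummary.of(grp[m])
            for m in _SUMMARY_METRICS
            if m in grp and np.isfinite(grp[m]).any()
        }
    return out


def run_population_trial(
    spec: PopulationSpec,
    art: DrugParameters,
    efv: DrugParameters,
    constants: SystemConstants,
    art_doses_mg: tuple[float, ...] = (ART_DOSE_MG,),
    max_failure_fraction: float = 0.10,
    compute_first_pass: bool = True,
) -> TrialResult:
    """Paired-arm virtual trial over a sampled population.

    The same virtual subjects are reused across arms; per-subject
    interaction ratios (combination / alone) are computed before
    summarising.  A subject whose integration fails is recorded and
    excluded; more than ``max_failure_fraction`` failures aborts.
    """
    subjects = sample_population(spec)
    rows = []
    failed: list[int] = []
    for sid, ind in enumerate(subjects):
        try:
            arms = run_subject_arms(
                ind, art, efv, constants, art_doses_mg=art_doses_mg,
                compute_first_pass=compute_first_pass,
            )
        except (RuntimeError, FloatingPointError, ValueError):
            failed.append(sid)
            if len(failed) > max_failure_fraction * spec.n_subjects:
                raise RuntimeError(
                    f"more than {max_failure_fraction:.0%} of subjects failed "
                    f"to integrate ({len(failed)}/{spec.n_subjects})"
                )
            continue
        base = arms["ART"]
        for arm_name, met in arms.items():
            row = {"subject": sid, "arm": arm_name, "sex": ind.sex,
                   "body_weight": ind.body_weight, **met.as_dict()}
            if arm_name.startswith("ART+EFV") and base.auc_window > 0:
                row["auc_ratio"] = met.auc_window / base.auc_window
                row["cmax_ratio"] = met.cmax / base.cmax
            rows.append(row)
    per_subject = pd.DataFrame(rows)
    return TrialResult(
        per_subject=per_subject,
        summaries=summarise(per_subject),
        n_failed=len(failed),
        failed_subjects=failed,
    )


def dose_scan(
    spec: PopulationSpec,
    art: DrugParameters,
    efv: DrugParameters,
    constants: SystemConstants,
    doses_mg: tuple[float, ...] = (80.0, 160.0, 240.0),
    target_fraction: float = 2.0 / 3.0,
    result: TrialResult | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Rerun the combination arm at several artemether doses.

    Returns the per-dose summary table and the smallest dose whose median
    exposure (8-h window AUC) under the inducer reaches ``target_fraction``
    of the inducer-free median.  ``result`` may carry a previously computed
    trial covering all requested dose levels; pass None to run one.
    """
    res = result if result is not None else run_population_trial(
        spec, art, efv, constants, art_doses_mg=tuple(doses_mg),
        compute_first_pass=False,
    )
    ref = res.summaries["ART"]["auc_window"].median
    rows = []
    chosen: float | None = None
    for dose in doses_mg:
        s = res.summaries[f"ART+EFV@{dose:g}"]["auc_window"]
        rows.append({
            "dose_mg": dose, "median_auc": s.median, "min_auc": s.minimum,
            "max_auc": s.maximum, "target_auc": target_fraction * ref,
            "reaches_target": s.median >= target_fraction * ref,
        })
        if chosen is None and s.median >= target_fraction * ref:
            chosen = dose
    return pd.DataFrame(rows), chosen
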