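# pbpkdd

Whole-body PBPK/IVIVE simulation of enzyme-induction drug-drug
interactions, with a virtual clinical trial engine.

HIV-malaria co-infected patients commonly receive artemether (an
artemisinin combination therapy component) together with efavirenz, which
induces the very enzymes — CYP3A4 and CYP2B6 — that clear artemether.
The induction deepens artemether's already extensive first pass and can
push exposure below therapeutic levels.  `pbpkdd` builds the whole chain
bottom-up from in vitro data and asks the clinical "what-if" questions in
silico: how big is the interaction, and what artemether dose restores
exposure?

The model stack, for each virtual subject:

- **population**: anthropometry, allometric organ masses, cardiac output
  and regional flows with inter-individual variability;
- **absorption**: a compartmental absorption and transit (CAT) gut —
  stomach plus seven intestinal segments, first-order dissolution,
  permeability-derived absorption (`ka = 2·Peff/r`), giving the fraction
  absorbed `Fa`;
- **distribution**: tissue-composition (Poulin-Theil-type)
  tissue:plasma partition coefficients and volumes of distribution;
- **clearance**: IVIVE scaling of recombinant-CYP intrinsic clearances
  (abundance × MPPGL × liver mass, microsomal-binding-corrected) into the
  well-stirred liver model,

      Fg = Qg/(Qg + fu·CLint,g),   Fh = Qh/(Qh + fu·CLint,h),
      CLh = Qh·fu·CLint,h/(Qh + fu·CLint,h),   Foral = Fa·Fg·Fh;

- **induction**: E = 1 + Emax·I/(EC50 + I) on hepatic CYP3A4/CYP2B6
  expression, ramping to full effect over 14 days of inducer dosing;
- **engine**: the 16-compartment flow-limited ODE system
  `V·dC/dt = Q·(C_art − C·B:P/Kp)` per tissue, both drugs co-integrated,
  dose events as solver restarts;
- **trial**: paired-arm virtual studies, per-subject PK metrics (Cmax,
  Ctrough, AUC, CL/F, V/F), population summaries and dose scans.

## Worked example

```python
import pbpkdd as p
from pbpkdd.trial import run_population_trial

const = p.load_system_constants()
art, efv = p.builtin_drug("artemether"), p.builtin_drug("efavirenz")

spec = p.PopulationSpec(n_subjects=50, age_range=(20, 50),
                        proportion_female=0.5, random_seed=1)
res = run_population_trial(spec, art, efv, const, art_doses_mg=(80.0, 240.0))

for arm in ("ART", "ART+EFV@80", "ART+EFV@240"):
    s = res.summaries[arm]
    print(arm, round(s["cmax"].median, 1), round(s["auc_window"].median, 1))
```

prints (seed 1):

```
ART 37.5 203.0
ART+EFV@80 8.7 38.0
ART+EFV@240 26.0 114.0
```

Read: without the inducer the median artemether peak is 37.5 ng/mL with a
203 ng·h/mL exposure over the 8-h sampling window of the final interval.
Fourteen days of efavirenz cut exposure by ~81% (38.0 ng·h/mL) — the
induced liver lets only a fifth of the absorbed dose through — and
tripling the artemether dose to 240 mg recovers a large part of it
(114 ng·h/mL) without changing the induced kinetics, because disposition
stays first-order.

The same study is available from the shell:

```sh
pbpkdd simulate-trial --config examples/paper_trial.yaml --out results/
pbpkdd dose-scan --config examples/paper_trial.yaml --doses 80,160,240
```

which writes `subjects.csv`, `pk_per_subject.csv`, `summary.csv` and a
checksummed `manifest.json`.

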