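# Efavirenz: physicochemical, binding, permeability, recombinant-CYP
# intrinsic clearance and CYP-induction parameters.
name: efavirenz
molecular_weight: 315.67      # g/mol
logP: 4.6
fu_plasma: 0.01
permeability:
  caco2_papp: 2.5             # 1e-6 cm/s
dissolution_kd_per_h: 3.0
# Fraction of the dose that can dissolve at all (solubility-limited
# absorption); calibrated once so the reference subject absorbs 45% of a
# 600 mg dose.  See docs/methods.md.
dissolvable_fraction: 0.5434
clint_rec:                    # uL/min/pmol recombinant isoform
  CYP2B6: 0.55
  CYP1A2: 0.07
  CYP2A6: 0.08
  CYP3A4: 0.007
  CYP3A5: 0.03
# UGT2B7 glucuronidation, expressed directly as unbound hepatic intrinsic
# clearance (L/h) for the reference liver; scaled with liver mass.
# Calibrated so total oral clearance matches the observed 9.7 L/h.
clint_additional_hepatic_lh: 216.5
# Blood and plasma treated as equivalent matrices (see artemether fixture).
blood_plasma_ratio: 1.0
# Empirical partition-coefficient scalar matching the composition-based Kp
# set to the observed apparent volume of distribution (~150 L at F ~ 0.41);
# lipophilicity-based partitioning grossly overpredicts for this compound.
kp_scalar: 0.1511
induction:                    # Emax (fold over baseline), EC50 (uM)
  CYP2B6: {emax: 5.7, ec50_um: 0.8}
  CYP3A4: {emax: 6.5, ec50_um: 3.9}
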