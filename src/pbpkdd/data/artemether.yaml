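# Artemether: physicochemical, binding, permeability, recombinant-CYP
# intrinsic clearance and formulation parameters.
name: artemether
molecular_weight: 298.37      # g/mol
logP: 3.4
fu_plasma: 0.05
permeability:
  psa: 46.15                  # polar surface area, A^2
  hbd: 0                      # hydrogen-bond donors
# First-order tablet dissolution constant, 1/h.  Calibrated once against
# the reported slow-release/poor-solubility behaviour so that the reference
# subject absorbs 86% of an 80 mg oral dose; see docs/methods.md.
dissolution_kd_per_h: 4.4992
dissolvable_fraction: 1.0
clint_rec:                    # uL/min/pmol recombinant isoform
  CYP2B6: 9.31
  CYP3A4: 1.47
# Blood and plasma treated as equivalent matrices (the source kinetic
# chain is only self-consistent under B:P = 1).
blood_plasma_ratio: 1.0
kp_scalar: 1.0
induction: {}
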