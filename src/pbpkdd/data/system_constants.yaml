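# System (drug-independent) constants for IVIVE scaling, oral absorption
# and tissue distribution.  All values are editable; entries marked
# "calibrated" were fixed once so that the reference 176-cm male reproduces
# the observed first-pass chain of the two shipped compounds, and are not
# meant to be tuned per run.

# Hepatic CYP abundances, pmol isoform per mg liver microsomal protein.
# Chosen within the range of published LC-MS/MS proteomic quantifications
# (which run far below older immunoquantification values for CYP2B6);
# jointly calibrated against the shipped compounds' in vivo first pass.
cyp_abundance_liver:
  CYP3A4: 64.0
  CYP2B6: 9.9
  CYP1A2: 52.0
  CYP2A6: 42.0
  CYP3A5: 10.0

# Microsomal protein per gram liver, mg/g.
mppgl: 40.0

# Total small-intestinal CYP3A4 content, nmol.
intestinal_cyp3a4_nmol: 70.5

# Blood flow perfusing the enterocytes (the "Q-gut" flow), L/h.
# Calibrated: reproduces the gut availability of both shipped compounds
# from their recombinant CYP3A4 clearances with fu_gut = 1, anchored so
# the population-median exposures land on the observed values.
enterocyte_blood_flow_lh: 2.15

# Fraction unbound inside the enterocyte used in the gut-availability
# equation (standard Q-gut assumption).
fu_gut: 1.0

# Protein concentration of the in vitro microsomal incubation, mg/mL,
# used by the nonspecific-binding (fu_mic) prediction.
microsomal_protein_conc_mg_ml: 0.5

# Effective small-intestine radius, cm, for ka = 2*Peff/r.  Calibrated
# (effective absorptive radius, not the anatomical lumen radius).
small_intestine_radius_cm: 1.25

# Caco-2 -> human jejunal Peff log-log regression:
# log10(Peff / 1e-4 cm/s) = slope * log10(Papp / 1e-6 cm/s) + intercept
peff_caco2_regression:
  slope: 0.4926
  intercept: -0.1454

# PSA/HBD -> Peff regression (Winiwarter-type):
# log10(Peff / 1e-4 cm/s) = intercept + psa_coeff*PSA + hbd_coeff*HBD
peff_psa_hbd_regression:
  intercept: 0.4926
  psa_coeff: -0.0087
  hbd_coeff: -0.43

# Compartmental absorption and transit model.
transit_times_h:
  stomach: 0.5
  small_intestine: 3.3
n_intestinal_segments: 7
# Luminal water volumes, L: stomach then the 7 intestinal segments.
luminal_volumes_l: [0.25, 0.12, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04]

# Enzyme-induction onset: linear ramp reaching 100% induction at this many
# days after the first inducer dose.
induction_onset_days: 14.0
# Driver concentration for the induction Emax model: one of
# liver_blood (blood leaving the liver), liver_total (total tissue),
# liver_unbound (unbound tissue).
induction_driver: liver_blood

# Organ densities, g/mL (volume = mass / density).
organ_density:
  default: 1.0
  adipose: 0.92
  bones: 1.30
  blood: 1.06

# Split of blood volume between the arterial and venous pools.
arterial_blood_fraction: 0.3333333333333333
hematocrit: 0.45

# Tissue composition: fractional volumes of neutral lipid, phospholipid
# and water, for the tissue:plasma partition model.  "remaining" uses
# muscle composition; stomach uses gut composition.
tissue_composition:
  plasma:    {neutral_lipid: 0.0023, phospholipid: 0.0013, water: 0.945}
  adipose:   {neutral_lipid: 0.79,   phospholipid: 0.002,  water: 0.18}
  bones:     {neutral_lipid: 0.074,  phospholipid: 0.0011, water: 0.439}
  brain:     {neutral_lipid: 0.051,  phospholipid: 0.0565, water: 0.77}
  intestine: {neutral_lipid: 0.0487, phospholipid: 0.0163, water: 0.718}
  stomach:   {neutral_lipid: 0.0487, phospholipid: 0.0163, water: 0.718}
  heart:     {neutral_lipid: 0.0115, phospholipid: 0.0166, water: 0.758}
  kidney:    {neutral_lipid: 0.0207, phospholipid: 0.0162, water: 0.783}
  liver:     {neutral_lipid: 0.0348, phospholipid: 0.0252, water: 0.751}
  lungs:     {neutral_lipid: 0.003,  phospholipid: 0.009,  water: 0.811}
  muscle:    {neutral_lipid: 0.0238, phospholipid: 0.0072, water: 0.76}
  pancreas:  {neutral_lipid: 0.0403, phospholipid: 0.009,  water: 0.664}
  skin:      {neutral_lipid: 0.0284, phospholipid: 0.0111, water: 0.718}
  spleen:    {neutral_lipid: 0.0201, phospholipid: 0.0198, water: 0.788}
  remaining: {neutral_lipid: 0.0238, phospholipid: 0.0072, water: 0.76}
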