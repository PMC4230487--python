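# The standard virtual interaction study: efavirenz 600 mg once daily for
# 14 days in 50 virtual adults (20-50 years, half female), then artemether
# 80 mg at 0 and 8 h followed by 80 mg twice daily for two more days, with
# the same subjects run with and without the inducer (paired arms).
seed: 1
population:
  n_subjects: 50
  age_min: 20
  age_max: 50
  proportion_female: 0.5
drugs:
  artemether: builtin
  efavirenz: builtin
constants: builtin
art_doses_mg: [80]
output_dir: results
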