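# Constituent registry used by the exposure stage.
#
# emission_factor_ug_per_mg: µg exhaled per mg e-liquid consumed (EVP source,
#   reference product; pipeline runs replace these with freshly estimated
#   values from the breath-statistics stage).
# sidestream_ug_per_cigarette: sidestream emission of a reference cigarette
#   (null where no data exist -> NA in reports).
# exposure_limit_ug_m3: 8-h reference limit (OSHA PEL where listed; propylene
#   glycol uses the 10,000 µg/m³ AIHA-style guideline since it has no PEL).
# saturation_ug_m3: saturation mass concentration C*; null = treated as fully
#   volatile (the default for all EVP constituents modeled here).
constituents:
  - name: nicotine
    emission_factor_ug_per_mg: 4.22
    sidestream_ug_per_cigarette: 5600
    exposure_limit_ug_m3: 500
    saturation_ug_m3: null
    below_mdl: false
  - name: propylene_glycol
    emission_factor_ug_per_mg: 83.86
    sidestream_ug_per_cigarette: null
    exposure_limit_ug_m3: 10000
    saturation_ug_m3: null
    below_mdl: false
  - name: glycerin
    emission_factor_ug_per_mg: 162.12
    sidestream_ug_per_cigarette: null
    exposure_limit_ug_m3: 10000
    saturation_ug_m3: null
    below_mdl: false
  - name: formaldehyde
    emission_factor_ug_per_mg: 0.0083
    sidestream_ug_per_cigarette: 700
    exposure_limit_ug_m3: 920
    saturation_ug_m3: null
    below_mdl: false
  - name: acetaldehyde
    emission_factor_ug_per_mg: 0.0
    sidestream_ug_per_cigarette: 4200
    exposure_limit_ug_m3: 360000
    saturation_ug_m3: null
    below_mdl: true
  - name: acrolein
    emission_factor_ug_per_mg: 0.0
    sidestream_ug_per_cigarette: 1300
    exposure_limit_ug_m3: 250
    saturation_ug_m3: null
    below_mdl: true
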