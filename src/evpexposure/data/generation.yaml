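# Default generator parameters.
#
# true_mean_ug: per-analyte, per-product true exhaled masses (µg per 10-puff
#   session) on the sham-corrected scale.
# cv_between / cv_within: between-subject and session-residual coefficients
#   of variation of the lognormal measurement model.
# sham_mean_ug: background in sham sessions (only formaldehyde has an
#   endogenous-breath background of note).
# mdl_ug: assay minimum detectable levels; below-MDL draws are substituted
#   and flagged.
# consumption_mg: session e-liquid consumption [mean, sd] per product per
#   collection type (normal truncated at zero).
cv_between: 0.6
cv_within: 0.6
true_mean_ug:
  nicotine:         {tp1: 89.44,  tp2: 195.70, tp3: 168.83, tp4: 182.65}
  propylene_glycol: {tp1: 1678.4, tp2: 1199.7, tp3: 3354.5, tp4: 2511.0}
  glycerin:         {tp1: 5972.3, tp2: 6099.5, tp3: 6484.7, tp4: 5366.8}
  menthol:          {tp1: 0.17,   tp2: 0.35,   tp3: 21.11,  tp4: 31.01}
  formaldehyde:     {tp1: 0.25,   tp2: 0.25,   tp3: 0.34,   tp4: 0.30}
  acetaldehyde:     {tp1: 0.0,    tp2: 0.0,    tp3: 0.0,    tp4: 0.0}
  acrolein:         {tp1: 0.0,    tp2: 0.0,    tp3: 0.0,    tp4: 0.0}
sham_mean_ug:
  nicotine: 0.0
  propylene_glycol: 0.0
  glycerin: 0.0
  menthol: 0.0
  formaldehyde: 0.2
  acetaldehyde: 0.0
  acrolein: 0.0
mdl_ug:
  nicotine: 1.0
  propylene_glycol: 10.0
  glycerin: 10.0
  menthol: 1.0
  formaldehyde: 0.1
  acetaldehyde: 0.5
  acrolein: 0.5
consumption_mg:
  tp1: {collection1: [35.2, 8.70],  collection2: [35.6, 11.53]}
  tp2: {collection1: [33.7, 11.37], collection2: [36.3, 11.94]}
  tp3: {collection1: [40.2, 12.6],  collection2: [41.2, 14.58]}
  tp4: {collection1: [36.7, 12.32], collection2: [37.9, 12.4]}
seed: 0
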