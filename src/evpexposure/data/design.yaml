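# Default crossover layout: 32 subjects, four product-order sequences,
# eight subjects per sequence, two trapping-container collection types.
n_subjects: 32
subjects_per_sequence: 8
sequences: [ABDC, BCAD, CDBA, DACB]
products:
  - {id: tp1, nicotine_by_weight: 0.025, mentholated: false}
  - {id: tp2, nicotine_by_weight: 0.040, mentholated: false}
  - {id: tp3, nicotine_by_weight: 0.035, mentholated: true}
  - {id: tp4, nicotine_by_weight: 0.040, mentholated: true}
collections:
  nicotine: 1
  propylene_glycol: 1
  glycerin: 1
  menthol: 1
  formaldehyde: 2
  acetaldehyde: 2
  acrolein: 2
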