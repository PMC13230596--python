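# Default normalization rules for LLPS experimental-condition extraction.
# Alias keys are matched case-insensitively after whitespace folding.

temperature_aliases:
  rt: 25.0
  r.t.: 25.0
  room temperature: 25.0
  room temp: 25.0
  ambient: 25.0
  ambient temperature: 25.0
  on ice: 4.0

# multiplier taking a value in the given unit to µM
molar_unit_factors:
  M: 1.0e6
  mM: 1.0e3
  µM: 1.0
  μM: 1.0      # Greek mu variant
  uM: 1.0
  nM: 1.0e-3
  pM: 1.0e-6

# units kept as-is (value + unit preserved, flagged non-convertible):
# converting these to molar needs molecular weight or solvent volume.
non_convertible_units:
  - mg/mL
  - mg/ml
  - µg/mL
  - ug/mL
  - µg/µL
  - ng/µL
  - ng/uL
  - "%"
  - "% w/v"
  - "% (w/v)"
  - wt%

# protein synonym map: alias -> canonical notation.
# Ships empty; projects supply their own dictionary.
protein_synonyms: {}

phase_vocab:
  # phase separation observed
  droplet: 1
  droplets: 1
  droplet formation: 1
  llps: 1
  phase separation: 1
  phase separated: 1
  phase-separated: 1
  two-phase: 1
  two phase: 1
  two phases: 1
  condensate: 1
  condensates: 1
  demixed: 1
  demixing: 1
  ps: 1
  "yes": 1
  "1": 1
  # no phase separation
  soluble: 0
  one phase: 0
  one-phase: 0
  single phase: 0
  no llps: 0
  no phase separation: 0
  homogeneous: 0
  mixed: 0
  dispersed: 0
  no droplets: 0
  "no": 0
  "0": 0
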