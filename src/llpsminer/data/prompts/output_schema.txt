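Answer with a JSON array only, one object per experiment, using exactly
these keys (omit a key when the condition is not stated):
protein_name (string), protein_conc (string with unit), rna_conc (string
with unit), ph (string), temperature (string), phase_status (string),
sequence_region (string), modification_state (string).
Do not add any text outside the JSON array.
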