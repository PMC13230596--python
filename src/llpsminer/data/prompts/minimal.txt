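You are given material from a scientific publication on liquid-liquid phase
separation (LLPS). Extract every LLPS experiment reported in the provided
material. For each experiment, report the following experimental conditions:
the protein studied, the protein concentration, the RNA concentration, the
buffer pH, the temperature, and whether phase separation was observed.
Also report the protein sequence region and modification state when stated.
Report one entry per experiment. If a condition is not stated for an
experiment, leave it out rather than guessing.
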