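Background knowledge for this task. Liquid-liquid phase separation (LLPS) is
the demixing of a protein (often with RNA) solution into a dense condensed
phase - droplets or condensates - and a dilute phase. About each item:
- Protein: the macromolecule driving the phase behaviour; papers may name it
  by gene symbol, full name, or construct; prefer the name as written.
- Protein / RNA concentration: the total concentration in the assay, usually
  in molar units (nM, uM, mM) or mass units (mg/mL); keep the unit written.
- pH: the buffer pH of the assay solution.
- Temperature: the assay temperature; "RT" or "room temperature" count.
- Phase outcome: whether droplets/condensates formed (phase separation) or
  the solution stayed in one phase (no phase separation). In phase diagrams,
  filled and open markers typically distinguish the two outcomes.
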