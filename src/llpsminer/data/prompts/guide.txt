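Follow this procedure step by step:
1. Identify the kind of evidence shown (phase diagram / scatter plot,
   micrograph panel, turbidity curve) and locate the target figure or panel.
2. For scatter plots, treat each plotted point as one experiment; read its
   coordinates against the axis labels, tick values, and units to obtain the
   concentrations, and use the legend or marker style for the phase outcome.
3. For micrographs, treat each image or labelled condition as one
   experiment; take the conditions from the panel labels and caption.
4. Search the caption and methods text for conditions that apply to the
   whole figure (buffer pH, temperature, fixed component concentrations).
5. Write one entry per experiment with every condition you located, then
   re-check each entry against the figure before answering.
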