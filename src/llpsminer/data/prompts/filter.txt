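Only extract experiments meeting all of the following criteria:
1. the experiment directly observes LLPS (droplet or condensate formation);
2. it uses a single type of protein and a single type of RNA at most;
3. the experimental conditions are stated or readable from a figure;
4. the outcome (phase separation or not) is reported for that condition.
Skip experiments that do not meet every criterion.
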