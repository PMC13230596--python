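# Methods

This note documents the models, conventions and numerical choices behind
`llpsminer`: what the evaluation engine computes, what the synthetic
benchmark emulates, and where the design was genuinely open.

## Scope of the problem

An LLPS experiment is characterized here by six conditions: protein name,
protein concentration, RNA concentration, buffer pH, temperature, and a
strictly binary phase status (phase separation observed / not). Auxiliary
protein annotations (sequence region, modification state) are carried but
not scored. Extraction operates per figure (figure-by-figure mode, one
model call per figure, the figure named in the prompt) or per paper
(single-shot mode, one call over the whole document with filter criteria in
the prompt); evaluation scopes follow the same split — per figure for
figure-by-figure runs, per paper for single-shot.

## Normalization

Raw model output is free text; scoring requires canonical scales.

* **Temperature** → °C. Room-temperature aliases ("RT", "r.t.", "room
  temperature", "ambient") collapse to 25 °C; Kelvin and Fahrenheit are
  converted arithmetically (a harmless superset — the alias and unit tables
  are configuration). Bare numbers are read as Celsius.
* **Concentration** → µM via a positive-factor unit table (M, mM, µM, nM,
  pM). Units that cannot be converted without molecular weight or solvent
  volume — mg/mL and other mass/volume or percentage units — are passed
  through unchanged with `convertible=False`. No molecular-weight lookup is
  attempted.
* **Protein names** are casefolded, whitespace-collapsed, and resolved
  through a synonym map. The map ships empty: there is no universal protein
  dictionary, so canonicalization vocabulary is per-project configuration.
* **Phase status** maps through a binary vocabulary ("droplets",
  "phase separation", "condensates" → 1; "soluble", "one phase",
  "no phase separation" → 0; …). Unknown tokens are a normalization error,
  never silently coerced.
* **pH** strips a leading "pH" token and must lie in [0, 14].

`normalize_record` is idempotent; per-field failures flag the field
non-convertible instead of aborting the record.

## Evaluation engine

### Distances

All per-field distances lie in [0, 1].

* **Numeric** (both concentrations, pH, temperature):
  `|x_pred − x_true| / (x_max − x_min)`, where the range is the min/max of
  the **label** data within the evaluated scope. Two edge conventions:
  a degenerate range (`x_max == x_min`) preserves exact-match semantics
  (0 if equal, else 1), and values beyond the range are clamped so the
  distance never exceeds 1 (keeping the record cost a mean of unit-interval
  terms). Quantities compare numerically only on a common unit class —
  canonical µM/°C, or the *same* non-convertible unit after case folding;
  any unit mismatch scores 1, since e.g. mg/mL and µM values are not
  commensurable.
* **Text** (protein name): `1 − s` with `s` the Ratcliff–Obershelp gestalt
  similarity, `s = 2M/(|a|+|b|)` over recursively found longest matching
  blocks (`difflib.SequenceMatcher`, junk heuristic off). Two wrapper
  choices: inputs are casefolded (normalization casefolds extracted names;
  a pure case difference is not an extraction error) and argument order is
  canonicalized, because the gestalt ratio is order-dependent in rare cases
  and a distance must be symmetric.
* **Phase** (binary): 0 on agreement, 1 on mismatch.
* **Missing fields**: missing-vs-missing contributes 0, missing-vs-present
  contributes 1. The record cost averages over exactly six fields, so
  omissions and hallucinations are penalized symmetrically. (Whether the
  average should instead run over label-present fields only is an open
  convention; the six-field choice is recorded in the report metadata.)

### Matching

The |E|×|L| cost matrix is solved as a rectangular assignment problem
(`scipy.optimize.linear_sum_assignment`), matching min(|E|, |L|) pairs; no
square padding is used (padding with unit-cost dummies would be equivalent).
Exact cost ties are broken deterministically toward the lowest (row, column)
indices by adding an infinitesimal bias with geometrically decaying row
weights (scale 1e-12) before solving; a plain row-major bias would not work,
since any bias separable as f(row)+g(column) sums to a constant over every
complete assignment. Reported totals always come from the unbiased matrix.
The tie bias only resolves ties closer than ~1e-10 in total cost.

### Thresholding and metrics

A matched field counts as a true positive when its distance is strictly
below the threshold (default τ = 0.2, chosen to absorb curation noise in
ground truth), otherwise a false positive. Two deliberate options, both off
by default: `inclusive` switches the comparison to ≤ (a threshold of 0 is
only meaningful if exact matches survive it), and `strict_recall`
additionally counts an above-threshold matched field as a false negative
(the default follows the literal rule that thresholding affects precision
only). Unmatched extracted fields are false positives; unmatched label
fields are false negatives. This yields the invariant
TP + FP = number of extracted records with the field present.

Precision, recall and F1 are undefined on zero denominators and are
**excluded** from aggregation rather than imputed as 0; the count of
defined scopes is reported alongside each mean. Cross-scope aggregates use
the population SD (a single scope has SD 0). The overall Average is the
mean of the six per-field means; its SD is taken across the per-scope
averages.

Threshold sweeps reuse one matching per scope (costs do not involve the
threshold), so per-field F1 is non-decreasing in τ by construction.

Method comparison across scopes uses the two-sided paired Wilcoxon
signed-rank test on per-scope average F1, zero differences dropped; if all
differences are zero the test degenerates to p = 1 with a warning. SciPy
computes the p-value (exact where its conditions allow, otherwise the
tie-corrected normal approximation); the test suite checks the significance
verdict against full 2^n sign enumeration.

## Synthetic benchmark

The generator emulates the structure of a curated LLPS figure corpus, not
its content. Defaults: 49 figures across 20 papers; per figure, one protein
(from an 8-name pool), one pH, one temperature (25 °C over-represented, as
"RT" is in practice), and an exact log-spaced protein × RNA concentration
grid of 2–6 × 2–7 points (3–40 experiments per figure, ≈18 on average,
≈880 experiments in total — the scale of a realistic benchmark). Phase
status is 1 at or above the geometric-mean concentration-product cutoff, so
the rule is monotone and both outcomes appear in every figure that
straddles it. Protein concentrations span 0.1–100 µM and RNA 0.01–50 µM,
typical ranges for in-vitro reconstitution assays.

Corruption emulates the error modes observed in real extractions: dropped
records (missed experiments), per-field omissions, relative Gaussian noise
on concentrations (coordinate-reading error; pH/temperature errors in real
extractions are categorical, so their default noise is 0 and configurable),
single-character protein-name typos, re-expression of µM values in mM/nM in
the raw (pre-normalization) form, and spurious records. Rates default to
0.05 (noise SD 0.05, 0.5 spurious records per figure), producing mid-range
scores; rates of 0 and 0.2 bracket the regime in the test suite.

### Exact expected tallies

Each scenario carries the exact per-figure TP/FP/FN counts the evaluator
must produce, computed during generation **without running the assignment
solver** — only the distance and threshold rules are replayed on the known
true correspondence. Exactness rests on conditions checked per figure:

* **Row dominance.** Every corrupted record's cost to its true label is its
  row minimum, strictly below (by an absolute margin, default 1e-6) every
  label outside its exact tie set. Ties are tolerated only when
  tally-invariant: the per-field distance vector must be bit-identical
  across the tie set, which happens precisely because the grids are exact —
  a record that omitted its one discriminating field is equally distant
  from every label on the shared grid line, and scores the same against any
  of them. All labels being complete, whichever label ends up unmatched
  contributes the same six false negatives. Under these conditions every
  optimal assignment yields the same tallies (an exchange argument: any
  deviation either costs strictly more or permutes within tie sets).
* **Constant-cost spurious rows.** Spurious records are constructed so each
  present field is at distance exactly 1 from *every* label in the figure —
  an alien-alphabet protein name (gestalt similarity 0), concentrations two
  range-widths beyond the label maximum (clamped to 1), off-grid pH and
  temperature — and fields without such a guarantee (always phase status)
  are omitted, which also scores exactly 1 against complete labels. Their
  record cost is therefore exactly 1 everywhere, so which dropped labels
  they absorb cannot change the tallies.

Figures violating the conditions are regenerated with a fresh corruption
sub-seed and counted in the manifest (at the default and tested rates the
count is 0). Mild log-spaced grids make violations rare by construction:
grid lines are separated by factors ≳3.4 while the noise SD is a few
percent, so noise never moves a value closer to a neighbouring line.

What passing these tests shows — and does not. They verify the evaluator
(matching, distances, thresholding, aggregation) exactly, and the pipeline's
parsing/normalization byte-for-byte, under LLPS-like record structure. They
do not exercise vision: no scatter-plot or micrograph images are rendered,
and no claim is made about any live model's extraction quality. Scenario
records are also cleaner than real extractions in one respect: corruption
events are independent, whereas real model errors correlate within a figure.

## Problem sizes

The shipped test suite and `scripts/acceptance.py` use 3-figure scenarios
for the 100-scenario exactness sweeps, 4–10 figures for pipeline and
fixed-point checks, and the full 49-figure default for the corpus-scale F1
quantities; assignment optimality is checked against exhaustive permutation
enumeration up to 7×7 matrices. These sizes keep the whole suite under a
minute on one CPU while covering every code path; all are trivially
increased via `GeneratorConfig`.

## Known limitations

* Expected-tally exactness requires complete labels (all six fields); the
  generator guarantees this, but `corrupt()` applied to user-supplied
  incomplete labels may regenerate indefinitely and then raise.
* The mg/mL ↔ µM divide is absolute: no molecular-weight table is consulted.
* Multi-protein complexes are stored as free-text names; complex-aware
  matching would need a richer name model than gestalt similarity.
* The Wilcoxon p-value uses SciPy's tie handling; for heavily tied score
  vectors at small n it is approximate (the significance flag, not the
  exact p, is the contract).
* Token counts are logged when a backend reports them, but no cost model is
  provided.
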