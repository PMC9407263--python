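# Methods

## Model and procedure

`coevmi` treats two alignment columns as categorical random variables
observed once per species and measures their dependence with mutual
information. The pipeline is:

1. **Pairing.** Two aligned FASTA files are matched by exact full-header
   equality; species present in only one file are dropped. At least 100
   common species are required by default (`min_common`) so that per-column
   frequencies are estimated from a reasonable sample; the threshold is a
   parameter so small fixtures can exercise the code. A user-chosen
   reference species defines the coordinate system: columns where the
   reference row carries a gap are excluded, and all reported positions are
   1-based indices into the ungapped reference sequence (the numbering a
   biologist uses for that protein).
2. **Scoring.** For every cross-protein pair of reference positions, the MI
   of the two columns is computed by summing partial terms
   `p_XY·log(p_XY/(p_X·p_Y))` over residue combinations. Species with a gap
   or non-standard symbol (anything outside the 20 amino acids) at either
   column are excluded from that pair's counts and frequencies are taken
   over the remaining species: a gap is the absence of a residue, not a
   coevolving state. Intra-protein pairs are never scored.
3. **Filtering.** Each partial term must individually pass two thresholds:
   both marginals at least τ, and the joint frequency at least
   `(1 + r/100)·p_X·p_Y`. Finite-sample joint frequencies fluctuate around
   the independence product and those fluctuations, summed over hundreds of
   terms, produce spurious positive MI; the percent-above-random filter
   keeps only combinations that beat their independence expectation by a
   margin, which also makes every retained term — and hence the filtered
   score — non-negative. A column pair whose every term is filtered scores
   exactly 0.
4. **Normalization.** Raw scores are divided by the mean raw score of the
   entire comparison (all cells, zeros included) and multiplied by 10,000.
   This average-based correction removes comparison-wide background (long
   proteins, compositional bias) and makes scores comparable across
   analyses; the ×10,000 is readability only. The normalized matrix has
   mean exactly 10,000 whenever any raw score is positive; if all raw
   scores are zero the comparison is flagged "no signal" and all normalized
   scores are 0.
5. **Probability.** The comparison's top normalized score is looked up in a
   calibration table — a step function from descending score thresholds to
   percent chance of true interaction. Lookups are boundary-inclusive;
   scores above the highest threshold return the top percent (tables are
   open-ended upward) and scores below the lowest return the 50% baseline,
   i.e. no better than random.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| τ (`min_px`) | marginal frequency floor per term | 0.17 (vertebrate), 0.29 (bacteria) | dimensionless frequency in [0, 1] |
| r (`pct_above_random`) | required % excess of `p_XY` over `p_X·p_Y` | 35 (vertebrate), 22 (bacteria) | percent in [0, 100) |
| `min_common` | minimum shared species | 100 | CLI default enforces it; library callers may lower it |
| log base | base of the MI logarithm | natural log | cancels under normalization (asserted by test); chosen as the conventional base |
| `n_bins` | calibration bins | 20 | equal-width over `[0, max score]` |

The presets are the combinations that maximized precision (subject to ≥ 20%
recall) in a 36 × 40 grid search over τ = 0–0.35 (step 0.01) and r = 10–49%
(step 1%) on labeled vertebrate and bacterial interaction sets; the grid,
the evaluation statistics (Welch t-test by default with a Student option,
pooled-SD Cohen's D, Mann–Whitney-rank AUC with half-credit ties, best
precision at ≥ 20% recall with ties broken toward higher recall) and the
selection rule (max precision, then AUC, then smaller (τ, r)) are all
implemented in `coevmi.tuning` so the search can be rerun on any labeled
corpus. Endpoint arithmetic uses exact decimal steps so the default grid has
exactly 1440 combinations rather than drifting to 35 τ values through
floating-point accumulation.

## Embedded calibration tables

The vertebrate and bacteria tables ship as packaged TSVs exactly as
published. The bacteria table contains one cell (score threshold 23.93 →
75.58%) that breaks monotonicity between its neighbours (96.56 and 95.09)
and is almost certainly an erratum; it is kept as published — fidelity
first — with a `NonMonotonicTableWarning` at load time, and
`ProbabilityTable.monotonized()` offers an explicit opt-in that replaces the
cell by the mean of its neighbours. Whether published thresholds are bin
lower edges or midpoints is not documented; they are treated as inclusive
lower edges, which is also the convention `build_probability_table` emits.

`build_probability_table` rebuilds such a table from labeled top-score
sets: 20 equal-width bins over `[0, max score]`, per-bin probability
`known/(known+unknown)`, and the contiguous bottom run of bins at ≤ 50% (or
empty) merged into the baseline region — the labeling of "not known to
interact" is far more likely to hide true interactions (false negatives)
than to invent them, so at-or-below-random bins carry no usable evidence.
Empty bins above the merged region extend the step below them. A ≤ 50% bin
sitting *above* an informative bin is emitted as computed rather than
silently repaired, matching the as-published handling of the bacteria table.

## Synthetic data: what it emulates and what it does not

`coevmi.synthetic` generates paired alignments in which every species'
residue is drawn independently — background columns from a background
profile (uniform over the 20 amino acids by default; a Dirichlet-skewed
option exercises the τ filter), and each planted coevolving pair as a noisy
bijection: column-1 residues are drawn from a constrained-site profile
(three residues at frequencies 0.5/0.3/0.2), pushed through a fixed random
bijection of the alphabet into column 2, and a fraction ε of species have
their column-2 state resampled independently. The bijection gives an
analytically known ceiling — at ε = 0 the pair's MI equals the empirical
entropy of column 1 — and ε interpolates continuously to full independence
at ε = 1. Planted columns use a low-cardinality profile because real
covarying sites are functionally constrained to a few residue states; a
uniformly drawn 20-letter column has every marginal near 0.05 and could
never pass a realistic τ, so "coevolution among unconstrained columns" is
not a regime the method (or biology) admits. Gaps are inserted
independently at `gap_rate` in every species except the first, which acts
as the gap-free reference so planted columns always keep a reference
coordinate.

The simulator deliberately omits phylogenetic correlation, indel processes,
rate heterogeneity and alignment error. Shared ancestry is the most
important omission: real species are not independent draws, so background
MI in real alignments is inflated relative to this null. Passing tests
therefore demonstrate the engine's correctness and its behavior under the
stated generative model, not field performance on real ortholog sets — the
filters' defaults, tuned on real labeled data, are what carries that
burden.

## Numerical choices

* MI terms are evaluated from integer contingency counts, with the ratio
  computed as `(n_xy·n)/(n_x·n_y)`; exactly independent counts give a ratio
  of exactly 1.0 and hence an MI of exactly 0, so the independence null is
  exact rather than approximate.
* The joint filter is optional at the API level: `pair_mi(..., filters=None)`
  computes plain textbook MI including negative-term cancellation, which is
  the quantity cross-checked against an independent implementation in the
  tests. With `FilterParams`, even `r = 0` keeps only terms at or above the
  independence product (the filter is a one-sided predicate, not a no-op).
* The top cell is chosen by row-major argmax, so ties break deterministically
  toward the smallest protein-1 position, then protein-2 position — the
  summary file must be reproducible across runs.
* Degenerate inputs: all-gap columns score 0; a comparison whose raw matrix
  is all zeros is flagged "no signal" instead of dividing by zero; zero
  variance in both tuning classes reports a NaN p-value rather than failing.
* Simulation problem sizes used by the test suite and the acceptance script
  (150 species, 30 × 30 columns, 10 seeds for recovery; 1000+ random column
  pairs for oracle agreement; 500 scores per class for calibration) were
  chosen to make each property statistically unambiguous while keeping a
  full run in the order of seconds.

## Design choices where the design was open

* **Header matching** is exact full-header string equality — no tokenizing
  of accession formats; users control their headers.
* **Duplicate headers** within one file keep the first occurrence with a
  logged warning.
* **t-test variant**: Welch by default (group sizes and variances of labeled
  score sets generally differ), Student's pooled test available as an
  option. Cohen's D uses the classic pooled-SD definition.
* **"Percent above random"** is read as the multiplicative predicate
  `p_XY ≥ (1 + r/100)·p_X·p_Y` — the most direct interpretation of an
  excess-over-independence percentage.

## Known limitations

* Phylogeny-blind: shared ancestry masquerades as covariation; scores on
  closely related species sets should be interpreted cautiously.
* MI needs deep sampling; the 100-species floor is a lower bound, not a
  guarantee, and columns dominated by one residue carry little information.
* Calibration tables transfer only as far as their training regime
  (taxon, alignment depth, ortholog selection) resembles the query's.
* The method detects statistical coupling, not physical contact; high
  scores prioritize candidates for validation rather than proving
  interaction.
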