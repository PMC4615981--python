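# Methods

## Sequence model and set resolution

Sequences are strings over the 20 canonical residues plus the tolerated
ambiguity letters X, B, Z, U, O, upper-cased on ingest and never silently
edited. Identifier lists resolve against the sequence universe by exact
protein accession first, then by case-insensitive gene symbol; a gene
symbol pulls **all** of its isoforms by default (`isoforms: longest`
selects the single longest), mirroring the several-isoforms-per-gene
structure of a full human proteome. Duplicate resolutions are
deduplicated with a warning; unresolvable identifiers abort with the full
missing list. An optional `dedupe_identical_sequences` step collapses
byte-identical sequences; it is off by default because redundancy
conventions differ between proteome releases and we prefer not to guess.

## Propensity scales

A scale assigns each canonical residue one number; ambiguity letters are
explicitly unscored. All bundled scales are oriented so that higher
means more of the feature (two published membrane insertion free-energy
scales are stored negated for this reason, which their registry citations
state). The bundled registry carries at least three scales per feature
class — e.g. TOP-IDP, the averaged normalized crystallographic B-factor
scale and the Bhaskaran–Ponnuswamy flexibility indices for disorder;
Kyte–Doolittle, Eisenberg and Fauchère–Pliska for hydrophobicity;
Chou–Fasman, Deléage–Roux and Levitt for helix and sheet; Janin, Chothia
and Rose for burial; AGGRESCAN for aggregation; GES, Wimley–White and the
Hessa biological scale for membrane propensity. Where no classical
single-residue table is established we bundle package-derived composites,
labelled as such in their citation fields: two aggregation composites
(z-scored hydrophobicity + z-scored β-propensity − |charge|, following
the classical sequence determinants of amyloid aggregation) and three
nucleic-acid interface composition propensities encoding the canonical
enrichment of basic/amide (and, for RNA, aromatic) residues at
protein–nucleic-acid interfaces. Users can extend any class to the
ten-predictor layout of the original web battery through the TSV plug-in
(`residue<TAB>value`). Scale values are literature constants, not fitted
quantities; the enrichment statistics are deliberately invariant to any
monotone re-expression of a scale, so moderate disagreement between
printed variants of the same scale does not change calls.

### Profiles and scores

Profiles are window means (default window 7, an odd number of residues —
common disorder-profiling practice; configurable). At the termini the
window is clipped rather than padded, so position 0 of a window-3 profile
averages positions {0, 1}. Unscored residues are dropped from every
window mean they fall in; a position is missing only when its entire
window is unscorable. Protein scores are profile means over non-missing
positions, which for window 1 reduces exactly to the plain per-residue
mean (a tested equivalence).

The **B-value disorder score** used by the onset stage is deliberately
unwindowed: the mean of a flexibility scale linearly normalised to
[0, 1], restricted to residues whose value strictly exceeds a floor of
0.2. The floor is interpreted as a per-residue filter on which residues
enter the mean; filtering whole proteins by their mean score instead is a
defensible alternative reading and is available to callers by
thresholding the returned scores. The bundled `bvalue` scale is the
normalised averaged-B-factor scale and is swappable; any [0, 1] scale
flagged `normalized` is accepted.

The **DisEMBL-style** summary is the fraction of non-missing profile
positions strictly above a threshold, averaged unweighted over a set's
proteins.

## Enrichment testing

Per scale, both sets' protein scores are pooled and split at the pooled
median; counts of strictly-above vs. at-or-below median per set form a
2×2 table (ties go low — scores are means of hundreds of residues, so
ties essentially occur only in degenerate inputs; a fully constant pool
is flagged and reported non-significant). The original web tool's exact
discretisation of score distributions is not published; the median split
is our explicit stand-in: scale-free, deterministic, and invariant under
monotone transforms of the scale.

The two-sided Fisher exact test is computed in-package with exact integer
arithmetic: the probability of a margin-fixed table is proportional to
`C(c1, n11)·C(c2, n12)`, and the p-value sums the probabilities of all
tables no more probable than the observed one ("no more probable" rule;
mid-p is not used). Integer weights make probability ties exact, which a
floating-point implementation can only approximate with a tolerance;
the suite verifies agreement with an independent exhaustive enumeration
oracle to 1e-10 over every table with margins ≤ 30, and cross-checks
`scipy.stats.fisher_exact` at a looser tolerance. Margin-family weight
vectors are memoised, so grids of comparisons and calibration loops cost
little beyond the first table of each family.

A comparison is called enriched for a side only when `p < α`
(default 10⁻⁵, the stringent threshold appropriate to thousands of grid
cells; no multiple-testing correction is applied beyond it, though the
report includes all raw p-values) **and** that side holds the larger
above-median fraction. Sets smaller than 10 proteins are computed but
annotated `low_n`. Swapping the sets mirrors every call and preserves
p-values exactly (tested).

## Comparison matrices and signal strength

Every (signal set × negative set) pair is compared on every scale of a
feature class. The signed signal strength of N calls with k significant
in the majority direction is ±k/N, rounded half-up to two decimals at
reporting time (full precision kept internally), positive when the signal
side dominates. Non-significant calls count toward N only. An exact tie
between directions is reported `MIXED` with a positive sign by
convention. Counts may be grouped per set-pair for a single scale or per
set-pair × scale when aggregating a class; reports state the grouping
used (the package default aggregates pair × scale).

`agreement_score` compares an up-regulation matrix with a down-regulation
matrix slot by slot: slots significant in opposite directions (enriched
up, depleted down — the single-hypothesis pattern) accumulate toward a
negative score, slots significant in the same direction toward a positive
one, with the same ±k/N arithmetic.

**Null calibration.** Replicates draw two disjoint subsets (without
replacement) from a background pool and re-run the comparison; the
empirical fraction of significant calls estimates the procedure's
false-positive rate. Background scores are computed once per scale, so
1000 replicates are cheap. The default group size is 150 proteins per
subset over a 2000-protein background: the exact test on a median split
is discrete, and its realized size at nominal α = 0.05 depends on the
margin family — computed analytically, it is 0.019 at n = 30 per group,
0.027 at 50, 0.034 at 100 and 0.049 at 150. At 150 the achievable
p-values are dense enough that the realized size essentially matches the
nominal level, which is what a calibration check should exercise; at the
pipeline's working threshold of 10⁻⁵ the null fraction is ~0 regardless.
These sizes are also of the order of the disease gene lists this pipeline
is meant for.

## Abundance comparison

Abundances must be positive and are log₁₀-transformed on ingest (zeros
rejected with a clear error). Set members are matched by protein id,
then gene symbol, and the unmatched count is always reported — silent
dropout would bias the comparison. The two-sample KS test uses the exact
D statistic and the asymptotic p-value with the `sqrt(nm/(n+m))`
effective-sample correction (an exact-p switch exists for small sets).
Direction (LOWER/HIGHER) is the sign of the median difference, reported
only when p < α (default 0.05 for this stage).

## Age-of-onset analysis

Substitutions of the form `A53T` are validated against the sequence
(reference-residue mismatch aborts unless forced). Disorder is scored on
the **mutant** sequence by default — the analysis concerns mutation
effects — with a wild-type mode available since either reading is
defensible. Pairs are binned by onset age into half-open 2.5-year
windows anchored at the minimum observed age; each bin contributes its
mean disorder, mean age and occupancy, and occupancies sum to the input
size. The disorder axis is Z-normalised across bins (sample sd, n−1).

The sigmoid is the four-parameter logistic
`AGE(z) = A + (B−A)/(1+exp(k(z−m)))`, the canonical sigmoid; the specific
parameterisation is pluggable and the analysis' conclusions rest on
parameter recovery and the correlation sign, not the parameter names.
Fitting is least squares with five seeded multi-starts spanning the data
range (steepness sign initialised from the raw correlation); the best
residual wins, non-convergence is flagged rather than raised, and the
asymptotes are re-ordered A ≤ B via the (A,B,k,m) ↔ (B,A,−k,m) symmetry.
Two correlations are reported: `pearson_r`, between Z-scored disorder and
age over the fitted points (model-independent), and `model_r`, between
fitted and observed ages signed by the data trend — the quantity that can
differ between the sigmoid and linear models and lets the better model
show a stronger (more negative, for decreasing data) association.
Correlations are computed on binned points by default, matching the
binned presentation of this analysis; a per-mutation mode is available
and reports state which was used.

## Synthetic-data generators

All generators take one explicit seed (`numpy.random.default_rng`; no
global state), are bit-reproducible, and emit their ground truth (the
CLI writes it to `*.meta.json` sidecars).

* **Composition sets.** Sequences are sampled i.i.d. per residue.
  The `disordered` preset up-weights P, E, S, K, Q, G and down-weights
  W, F, I, Y, V, L, C by a multiplicative effect size (default 0.25,
  i.e. ±25% on those residues before renormalisation); `ordered` is the
  mirror image; `uniform` is the flat background. Lengths are uniform in
  100–400 residues, the bulk of a typical proteome's length range. The
  ±25% composition bias yields mean per-protein disorder-score shifts of
  several within-set standard deviations — a strong, clearly separable
  signal in the spirit of the disorder contrast this pipeline targets,
  not an estimate of any particular disease set's effect size.
* **Abundance.** Background log₁₀-abundances are normal with mean 1.5
  and sd 0.8 (≈ 4 orders of magnitude dynamic range, typical of deep
  proteome quantifications, units arbitrary); the focal set is drawn
  with a configurable median log₁₀ shift.
* **Onset.** Disorder values uniform in [0.30, 0.70] (the mid-range of
  B-value scores); ages follow the logistic with A = 40, B = 85 years
  (juvenile-to-late onset span), k = 3 per Z-unit, midpoint m = 0.5,
  plus Gaussian noise (default sd 2 years), truncated below at 0;
  428 observations by default, the scale of a combined mutation-database
  export for these diseases.
* **Fixtures.** Comparison-outcome grids with a requested number of
  significant concordant calls, for exercising the signal-strength
  arithmetic in isolation.

What the generators deliberately do **not** emulate: real proteome
composition beyond the stated biases (no domain structure, no repeats,
no signal peptides), correlations between feature classes as they occur
in real proteins, matching-by-annotation noise in abundance tables, or
gene-level clustering of mutations. Passing tests therefore demonstrate
that the statistics and fits recover known ground truth under the
assumed data model — they are not evidence about any particular real
disease dataset.

## Numerical choices and degenerate inputs

* Fisher p-values and tie handling are exact (integers/fractions);
  conversion to float happens once at the end.
* Median-split ties go to the low cell; a fully degenerate (constant)
  score pool is flagged and reported non-significant rather than tested.
* Signal-strength rounding is half-up (0.875 → 0.88), applied once at
  reporting.
* Profiles mark missingness as NaN; scoring a fully unscorable protein
  raises an error naming it, and a B-value score with no residue above
  the floor returns NaN (the missing marker) so callers can filter.
* Z-normalisation of a constant vector, empty sets/vectors, even or
  oversized windows, negative table entries and invalid substitutions
  all raise immediately with context rather than propagating NaNs.
* Sigmoid non-convergence returns `converged=False` with NaN parameters;
  degenerate spread (constant disorder or age) raises.

## Known limitations

* The bundled scales are three-per-class stand-ins for the original
  ten-predictor battery; absolute profile values depend on the chosen
  scales even though enrichment calls are robust to monotone changes.
* The median-split contingency construction is a documented surrogate
  for the original web tool's unpublished discretisation.
* The printed correlations of the original onset analysis (−0.90
  sigmoid, −0.87 linear) depend on its real mutation set and exact
  B-value table, neither of which is redistributable here; the package
  validates the machinery by parameter recovery on synthetic ground
  truth instead.
* Pooled fits only: no gene-stratified onset modelling, no clinical
  covariates.
* Problem sizes used by the validation suite (e.g. 200-protein sets for
  discrimination, 2000-protein backgrounds with 1000 calibration
  replicates, 100 onset replicates) were chosen as the smallest rounds
  that make the binomial/Monte-Carlo error bars decisively smaller than
  the effects being checked.
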