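# Methods

## Problem and model

Within a protein superfamily, pairs of homologous domains differ both in
sequence (amino-acid substitutions, insertions/deletions) and in structure
(superposition RMSD, structure-alignment Z-score). `strucdiv` quantifies
how much of the accumulated structural divergence is explained jointly by
substitutions and indels, treating the two as separate predictors of a
bilinear regression fitted independently within each superfamily:

```
Group 1:              RMSD    = b0 + b1·PNI + b2·SNG  + u
Group 2:              Z-score = b0 + b1·PNS + b2·LSNG + u
PC-corrected Group 1: RMSD    = b0 + b1·PC  + b2·SNG  + u
```

The substitution variables are the percent sequence non-identity
(PNI = (1 − N_iden/N_algn)·100), the percent sequence non-similarity
(PNS = 100·N_ns/N_algn, counting aligned columns whose residue pair scores
zero or negative in BLOSUM45), and the Poisson-corrected distance
PC = −ln(1 − PNI/100) (substitutions per site, correcting for multiple
hits). The indel variables are the standardized number of gaps
(SNG = 100·N_gap/N_algn, one count per maximal gap run irrespective of
length) and its length-weighted form LSNG = (100/N_algn)·Σ_i N_i·a_i.
N_algn counts alignment columns holding residues in both rows; gap columns
never contribute to it.

The absolute coefficients |b1| and |b2| are reported as the structural
substitution sensitivity (SSS) and structural indel sensitivity (SIDS).
Because higher divergence lowers the Z-score, the raw group-2 coefficients
are negative; the sensitivities are magnitudes by definition.

## Indel-length weights

The weight a_L of a gap of length L comes from an asymptotic-growth model
of the structural shift that an indel imposes on its flanking regions:

```
f(L) = c1·exp(−L/c2) + c3        (c1 ≤ 0, c2 > 0)
a_L  = f(L) / f(1)               (a_1 = 1 exactly)
```

c1 (Å) sets the depth below the asymptote at short lengths, c2 (residues)
the saturation rate, c3 (Å) the limiting shift of very long indels. The
increasing form is enforced as a bound constraint in the least-squares fit
(scipy `curve_fit`, trust-region reflective). The starting point is
deterministic and scale-aware: c3⁰ = the largest per-length mean shift,
c1⁰ = (mean shift at the smallest observed length) − c3⁰, c2⁰ = 2
residues. Weights are evaluated on the fitted curve at integer L, one term
per gap occurrence (not per binned length class), and are therefore
non-decreasing with 1 = a_1 ≤ a_L ≤ c3/f(1). No default (c1, c2, c3) is
hard-coded: the model used for LSNG is always fitted to the supplied (or
generated) flank samples.

## Per-superfamily statistics

All fits are ordinary least squares (statsmodels). Around each bilinear
fit the package reports:

* R = +√R² (multiple correlation, reported in [0, 1]);
* adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1) with k = 2;
* the overall F-test of R = 0 with (k, n − k − 1) degrees of freedom;
* adequacy = adjR²(bilinear)/adjR²(one-predictor linear fit), computed
  against the substitution-only and the indel-only comparator; recorded as
  NaN when the comparator's adjusted R² is not positive, since the ratio
  is then meaningless;
* first-order partial correlations
  r(y, x1·x2) = (r_y1 − r_y2·r_12)/√((1 − r_y2²)(1 − r_12²)), tested
  two-sided with t = r_p·√((n − 3)/(1 − r_p²)) on n − 3 df;
* the two-predictor variance inflation factor VIF = 1/(1 − r_12²);
* product-measure contributions C_i = β_i·r_i, where β_i is the
  standardized coefficient (sample SDs with n − 1 denominator) and r_i the
  zero-order predictor–response correlation. C_1 + C_2 = R² identically;
  this decomposition apportions the explained variance between
  substitutions and indels even when the predictors are correlated.

Significance is by conventional F/t machinery; no multiple-testing
correction is applied across superfamilies (raw p thresholds are how such
analyses are reported). When the response is exactly collinear with one
predictor the partial correlations are undefined and stored as NaN while
the fit itself is returned.

## Selection, filtering, aggregation

Ancient superfamilies are those present in strictly more than 90% of
model eukaryote genomes, 90% of bacteria and 90% of archaea (each domain
of life separately), restricted to the five main SCOP classes (a: all-α,
b: all-β, c: α/β, d: α+β, e: α&β) and to superfamilies with at least 20
X-ray-determined non-redundant domains. Alignments with fewer than 50
aligned residues are removed; the "relatively accurate" subset further
requires a strictly positive P-score. Each unordered domain pair is
analyzed once (reciprocal duplicates are dropped, first occurrence kept).
A cross-family subset (family_a ≠ family_b) is available to reduce the
phylogenetic non-independence of intra-family pairs; no explicit
phylogenetic correction is attempted.

Aggregation reports the median and quartiles of R per variable group and
alignment subset (quartiles by linear interpolation between order
statistics, the "type 7" convention), an α/β-class (SCOP class c) versus
others comparison, and — over the superfamilies whose group-2 R exceeds a
threshold (default 0.75) — the pooled contribution shares
Σ C_indel / Σ (C_sub + C_indel). Pooling is an unweighted sum of raw
contributions across superfamilies; an alignment-count-weighted pooling
would be equally defensible, and the choice matters only when superfamily
sizes are very unequal.

## Synthetic data

The generators produce every input kind with a known ground truth,
because the real inputs (structure-alignment service output, genome
annotation databases, an indel-flank database) carry none.

* **Aligned pairs** are built backwards from exact counts: an ancestor
  sequence over the 20 standard residues, exactly `n_substitutions`
  identity-breaking substitutions of which exactly `n_nonsimilar` score
  ≤ 0 in BLOSUM45 (partners drawn from qualifying matrix cells; residues
  such as G, C and P, which have no positively scoring exchange partner in
  BLOSUM45, are re-drawn at similar-substitution sites), and gap runs of
  requested lengths at distinct internal slots so the realized run count
  equals the request. The metrics recomputed from the emitted pair equal
  the planted counts exactly; sums entering LSNG are taken in sorted
  length order precisely so this equality and row-swap symmetry are exact
  in floating point.
* **Bilinear cohorts** draw divergence targets from the stated predictor
  distributions — PNS uniform on [5, 60] percent, LSNG gamma(shape 2,
  scale 1.5), with uniform [10, 35] extra percentage points of similar
  substitutions on top of PNS and gap lengths geometric with mean 3 —
  discretize them to integer counts over 200 aligned residues, and
  compute the response from the REALIZED (discretized) predictors plus
  Gaussian noise on the response only, clamped at zero. A noiseless
  cohort is therefore fitted back exactly. The discretization granularity
  is 100/N_algn = 0.5 percentage points. Default group-2 coefficients
  (b0, b1, b2, σ) = (25, −0.15, −0.7, 2.0) keep the Z response far from
  the zero clamp and give per-superfamily R ≈ 0.8, in the realistic range
  for strongly structured superfamilies; an indel-dominant template
  (25, −0.08, −1.5, 2.0) is available for cohorts where indels drive most
  of the explained variance. The complementary response (RMSD for a
  group-2 cohort) is filled from documented default coefficients
  (0.5, 0.025, 0.10, σ = 0.35) so one cohort supports all three fits, and
  the P-score is the Z-score centred on its realized 40th percentile so
  the positive-P subset keeps ~60% of records.
* **Presence matrices** are Bernoulli draws per genome; the "ancient"
  truth labels are computed from the realization, not the probabilities,
  so they agree with the selection operation by construction of the data,
  not of the test.
* **Flank samples** are f(L) plus Gaussian noise truncated at zero.

What the generators do not emulate: real alignments have correlated
predictor errors (the same alignment produces both the metrics and the
structural scores), non-Gaussian and heteroscedastic responses,
phylogenetically correlated pairs, and empirical predictor distributions
that differ by superfamily. Passing tests therefore demonstrate that the
machinery is correct and well-calibrated under the assumed statistical
model, not that the model describes any particular real superfamily.

## Numerical choices and limitations

* Identifier comparison is exact and case-sensitive (SCOP sids are
  case-significant). Tables are UTF-8 TSV; floats are written with
  `repr`, the shortest string that round-trips exactly.
* Terminal gap runs count like internal ones: the alignments cover only
  the matched region of two domains and no exclusion rule is defensible
  from the data. Whether an upstream aligner's own gap count would agree
  is unknowable from the files; the definition here is self-consistent.
* Columns containing ambiguous residues (B, Z, X, U, O, J) count toward
  N_algn and are classified non-identical and non-similar — a
  deterministic, conservative rule.
* "Non-similar" means BLOSUM45 score ≤ 0 in the published half-bit
  integer matrix; the matrix is configurable (any NCBI-format file) but
  BLOSUM45 is the documented default.
* PC is returned in natural units (substitutions/site); the regression
  standardizes internally, so its scale is immaterial. PNI = 100 makes PC
  infinite and is rejected as saturated.
* The curve fit requires ≥ 3 distinct indel lengths (three parameters);
  constant samples drive c1 → 0 and yield a flat, valid model.
* Bilinear fits require n ≥ 4, non-zero variances and |r_12| < 1; each
  violation raises a named error rather than returning garbage.
* Problem sizes used by the shipped verification runs: the end-to-end
  cohort is 40 superfamilies × 500 alignments of 200 residues; parameter
  recovery uses 200 replicates at n = 1000; metric round trips use 1000
  random requests. These sizes give Monte-Carlo errors comfortably inside
  the asserted tolerances.
* Absolute LSNG values depend on the fitted (c1, c2, c3), for which no
  published reference values exist; only the procedure, not a specific
  weight table, is reproducible.
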