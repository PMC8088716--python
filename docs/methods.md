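# Methods

## Fold-change quantification (`pepquant`)

The protein fold change between two groups is a two-level rollup. For each
peptide, every combination of replicate abundances across the two groups is
turned into a ratio (|A|·|B| ratios for a peptide observed in |A| replicates
of group A and |B| of group B), and the peptide group ratio is the geometric
median of those ratios. The protein ratio is then the geometric median of
its peptide group ratios.

"Geometric median" of scalars is interpreted as the median in log space: for
vectors the geometric median is the L1-minimising point, and in one
dimension that is the ordinary median, applied to log-ratios because the
objects are multiplicative. An even number of values resolves to the
geometric mean of the two central values (the unique-minimiser convention,
and continuous in the data). Consequences that the tests verify: exact
antisymmetry FC(A,B)·FC(B,A) = 1, scale equivariance, and invariance to
replicate ordering.

Missing and non-positive abundances contribute no ratios — no imputation,
since imputing would manufacture signal in exactly the quantity being
estimated. A peptide with no valid cross-group pair is excluded and counted;
a protein observed in only one group is reported with a +inf/0 sentinel and
an `a_only`/`b_only` flag rather than a number, keeping single-group
detections in the detection-set logic where they belong. No cap is placed on
the number of ratio combinations.

## Differential signatures (`diffsig`)

Columns are normalized by total-sum scaling before any cohort comparison
(each sample's abundances sum to 1). This is the standard treatment for
compositional MS intensities; one consequence worth knowing is that a strong
shift in a few proteins induces small opposite shifts in the rest of the
column — visible in small synthetic examples as "background" proteins
acquiring a weak anti-correlated signal.

The per-protein statistic is the two-sample Student *t* with pooled
variance, two-sided p (a t-test is what the source workflow used; Welch's
variant is available via `equal_var=False`). Degenerate rows are handled
explicitly: zero variance with equal means gives t = 0, p = 1; zero variance
with unequal means gives a ±inf sentinel with p = 0. Raw p-values are the
primary output; Benjamini–Hochberg q-values are emitted alongside as a
clearly-labelled extension because a 5-vs-5 proteome-wide screen demands
multiplicity awareness.

Heatmap cells are log2((x + ε)/(reference mean + ε)) with the reference mean
taken over the good-responder cohort's columns, so that cohort's mean
profile maps to zero; rows are ordered by descending t-score with ties
broken by protein id. ε defaults to 1e-9 of the matrix mean — small enough
not to distort nonzero cells, large enough to keep zeros finite.

Detection (Venn) regions treat a protein as present in a group when it is
observed (> 0) in at least one replicate (configurable via
`min_replicates`); 2- and 3-set layouts are supported and the regions
partition the union by construction. The ortholog filter retains strictly
more than 99% amino-acid similarity, matching the stated retention rule's
exclusive boundary.

Gene-set enrichment is the displayed statistic of the original analysis
reconstructed directly: a 2×2 table per set over an explicit background,
the sample odds ratio with a Haldane–Anscombe 0.5 correction when any cell
is zero, and a one-sided hypergeometric tail p-value. It deliberately does
not reproduce any external web tool's gene-set libraries or ranking extras.

## Prognosis score (`prognosis`)

The source figures show per-sample "net prediction score" contributions
split into features positively and negatively correlated with good outcome,
and a straight decision boundary — but not the construction. This module
formalises the minimal linear model consistent with those axes:

* features: proteins with t-test p < 0.05 (cutoff and a max-feature cap are
  exposed), weight = training t-score (good − poor);
* per-feature contribution = weight × standardized normalized abundance
  (standardization fitted on the training samples);
* `contrib_positive` sums contributions of positive-weight features,
  `contrib_negative` those of negative-weight features (sign-flipped so both
  plotted axes grow with their own evidence); net = negative − positive, so
  lower net means better predicted prognosis;
* boundary: midpoint of the two training cohorts' mean net scores (with
  balanced cohorts and all-sample standardization this lands at 0, but it is
  data-driven in general); samples exactly on the boundary are called poor —
  the conservative clinical default.

Leave-one-out validation retrains normalization, selection, standardization
and the boundary inside every fold; a fold that selects nothing counts its
held-out sample as misclassified and flags it.

Two behaviours are worth stating precisely:

* **Duplication invariance is classifier-level, not weight-level.** Any
  t-statistic depends on n, so duplicating every training sample rescales
  the weights and the boundary together; the selected features, weight signs
  and every prediction are unchanged, and that is what the tests assert.
* **Null LOO accuracy sits slightly *below* chance.** With no true signal,
  honest leave-one-out of a centroid-style scorer is pessimistically biased
  (≈ 0.38 here over many null replicates): removing a sample shifts its own
  cohort's training mean away from it. The property the tests guard is the
  absence of *optimistic* leakage — accuracy clearly above chance under the
  null would mean information crossing fold boundaries — so the null check
  is a band at-or-below chance, not a two-sided band at 0.5.

The validation here is on synthetic cohorts; nothing is claimed about the
original sera beyond consistency of the formalisation.

## Assay math (`assays`)

Generation time is t = H·ln2/ln(c₂/c₁); c₂ ≤ c₁ raises an explicit
non-growth error rather than producing a negative or complex time. MTS
absorbances are divided by the vehicle-control mean (controls then average
exactly 1; idempotent). The 4PL model is
v(d) = lower + (upper − lower)/(1 + (d/IC50)^hill); the reported IC50 is the
curve inflection (relative IC50, the Prism-style convention). IC50 and hill
are optimised on a log scale — both positive by construction — with the
asymptotes free unless fixed; starts are upper = max v, lower = min v,
IC50 = the dose nearest the half-range crossing, and three hill seeds
(0.5, 1, 2) against local minima. Zero-dose wells enter the residuals and
anchor the upper asymptote only (log 0 being undefined on the dose axis).
The `converged` flag is honest — optimiser success, finite parameters and
lower < upper — and `ic50_in_range` reports whether the inflection lies
inside the tested dose range; monotone non-inhibition data therefore come
back flagged instead of with a fabricated IC50.

Cohort assignment uses strict inequalities (DFI > 300 days good, < 100 days
poor), everything else — including missing DFI — unclassified and counted,
never imputed.

## Synthetic data (`synthio`)

Abundances are lognormal: per-protein baselines ~ Normal(20, 2) on the log2
scale (typical MS dynamic range), measurement noise with
σ_ln = √ln(1 + cv²), and discriminating proteins shifted by `effect_log2`
multiplicatively in the non-reference group. Peptides inherit their
protein's effect exactly (no peptide-level interaction), keeping the
quantifier's truth well defined; per-peptide offsets emulate ionisation
efficiency. Missingness is MCAR by default, with an optional
intensity-biased mode (drop probability decreasing in abundance rank, mean
rate preserved) because real MS missingness is abundance-dependent; the
default stays MCAR so tests read simply.

Default study conditions: three cell-line groups in triplicate for the
peptide table; two serum cohorts of five subjects, 500 proteins with 4%
(20) discriminating at a 2-log2 shift and cv = 0.2 (`serum_config()`); the
MTS dose panel 0 (control), 0.5, 1, 2.5, 4, 6, 8, 10 µM in triplicate. The
cell-line replicate count is not fixed by the source design and defaults to
3. Simulated DFIs are drawn consistent with each cohort's definition so the
cohort-assignment stage can run on simulated sheets.

What the generator does **not** emulate: correlated protein co-expression,
batch effects, heavy-tailed or structured (non-lognormal) noise, shared
peptides between proteins, and instrument-level artefacts. Passing tests
therefore demonstrate correctness of the computations and honest validation
under the stated stochastic model, not performance on real sera.

## Problem sizes and numerics

The test suite and the acceptance script run at the scales the analyses
were designed around — 5-vs-5 cohorts with 500–2000 proteins, 1000 random
small instances for the quantifier oracle, 10 000 Monte-Carlo draws for
enrichment calibration, 20 null replicates for the leakage check — all of
which complete in well under a minute each. Fold-change oracle agreement is
asserted to 1e-12 relative; 4PL recovery on noise-free curves to 1e-6
relative (IC50 within 1% is the acceptance bar); the growth round trip to
1e-9 relative.
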