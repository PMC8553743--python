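# Methods

## Model and procedure

The pipeline treats a resting-state connectome study as a mass-univariate
regression problem followed by a second-level test.

1. **Connectivity panel.** For each subject, the pairwise Pearson
   correlations of m ROI mean time signals are vectorized over the strict
   upper triangle (row-major; this single canonical ordering is shared by
   every module) and mapped to the Fisher-Z scale, z = atanh(r). With the
   default 212-node annotation (79 DMN, 78 ASN, 55 LECN nodes) the panel
   has 22,366 columns. Correlations with |r| ≥ 1 − 1e−7 are clamped and
   logged rather than erroring, so degenerate inputs degrade loudly but
   gracefully.
2. **Edge-wise regression.** Every edge gets the same OLS model: Fisher-Z
   connectivity on the PSWQ worry score plus age, sex, race, education,
   CIRS-G, MADRS (dichotomized at ≥ 14 because its distribution is highly
   skewed; the boundary maps to "high" and the threshold is configurable),
   HARS, PSS, RSQ and NEO-FFI. Categoricals use treatment coding with the
   modal level as reference (stable under the 88/10/1% race split); with
   all levels present k = 13, so n = 77 gives 64 residual df. Because the
   design is shared, all fits reduce to one QR factorization and two matrix
   products; p-values are two-sided from the t distribution (at 64 df the
   distinction between t and z is negligible, but t keeps the synthetic
   null exactly calibrated). Reported effects are β (per PSWQ point) and
   β·sd(PSWQ) (per SD of worry); dividing by the outcome SD as well is
   available as an option. No multiple-testing correction is applied here
   by design — that is the next stage's job.
3. **Higher criticism.** HCᵢ = √n(i/n − p₍ᵢ₎)/√((i/n)(1 − i/n)) over ranks
   1..n−1 (the variance vanishes at i = n). The global null is rejected iff
   max HC > 2 (strict), and the i\* smallest p-values form the selected
   set. Sorting is stable; tied maxima resolve to the smallest rank; exact
   zero p-values are floored at 1e−300 with a warning. The standard
   stabilized variants (restricting to i/n ≤ α₀, or ignoring p₍ᵢ₎ < 1/n)
   are implemented but off by default: the plain statistic over the full
   range is the primary object.
4. **Bootstrap prevalence.** Subjects are resampled with replacement; the
   design is rebuilt per resample (categorical encodings re-derived;
   resamples that leave the design rank-deficient are redrawn and counted,
   with an abort if redraws exceed max(10, B/2)); all edges are refit and
   HC applied. Iterations with max HC below the threshold tally nothing;
   otherwise each selected edge is tallied. Tallying uses ≥ (the
   complement of "below the threshold, tally nothing"), which differs from
   the strict > of the single global decision; both are configurable.
   Prevalence = tally/B ranks edges by stability. This is not a
   significance test, and the output says so (`is_significance_test:
   false`); under the null some edges of any fixed dataset are stably
   re-selected, because the bootstrap conditions on the realized sample —
   the null signature is that those edges do not replicate across
   datasets, which is what the test suite checks.
5. **Summaries.** Selected edges are counted in the six network categories
   (three within, three between, labels fixed to DMN-ASN / ASN-LECN /
   LECN-DMN regardless of endpoint order) split by sign of β, and
   aggregated into signed weighted degree centrality: each selected edge
   adds β·sd(PSWQ) to both endpoints' positive or negative stratum. The
   two strata are kept separate to avoid cancellation, matching how
   sign-specific brain maps are drawn. Exports use canonical row order and
   6-significant-digit floats so identical inputs re-export byte-identically.

## Synthetic-data generator

The generator exists so the full pipeline is testable without restricted
imaging data; it emulates the study *design*, not brains.

- **Subjects.** Marginals follow the cohort summary: age 61.8 ± 8.2,
  education 16.0 ± 2.3, CIRS-G 3.7 ± 3.5, MADRS 7.4 ± 7.9, HARS 7.4 ± 5.7,
  PSWQ 48.2 ± 14.6 (range 16–80), RSQ 37.0 ± 12.9, NEO-FFI 19.2 ± 9.9,
  62% female, race 68/8/1 in 77. PSS has no published summary in this
  cohort; its default (13 ± 7 on the 0–40 PSS-10 scale) is a typical
  community older-adult value, chosen once and documented here. Bounded
  continuous scores use *moment-matched truncated normals* — the latent
  mean/SD are solved so the post-truncation moments equal the configured
  values — and the nonnegative, right-skewed clinical scores (MADRS, HARS,
  CIRS-G) use moment-matched gammas. Covariates are independent by
  default (only marginals are published); an optional Gaussian-copula
  block imposes correlations among the psychometric scales for users who
  want to stress confound adjustment.
- **Edges.** Panels are generated directly on the Fisher-Z scale:
  z[s,e] = baseline + β[e]·(pswq_s − mean)/sd + covariate terms +
  N(0, noise_sd), with β nonzero only on a sparse planted set. Worry
  enters standardized so planted slopes are per-SD effects, the scale on
  which design-stage effect sizes are stated. Defaults: baseline 0.25
  (typical within-network mean Fisher-Z), noise 0.3 (across-subject edge
  SD), 100 planted edges with about half negative, mirroring the roughly
  even positive/negative split of the observed selected set.
- **Time series.** Optionally the same edge model is materialized as
  band-limited Gaussian series: each subject's target correlation matrix
  is tanh of their Fisher-Z edge values (the noise draw acting as
  between-subject variability), repaired to the nearest correlation matrix
  by eigenvalue clipping at 1e−8 and diagonal rescaling, then imposed by
  Cholesky mixing on independently band-passed (frequency-domain masked,
  0.008–0.15 Hz at TR = 1 s; `band=None` gives white noise), unit-variance
  columns — so the population correlation equals the target regardless of
  the filter. Defaults T = 360, TR = 1 s reflect a 6-minute scan.

What the generator does **not** model: hemodynamics, head motion, scanner
noise and preprocessing artifacts, spatial autocorrelation of neighboring
ROIs, and any anatomical meaning of the region groups (these are assigned
from configured proportions by a seeded rule). Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated generative model — not that real scans would yield any particular
selected set.

## Power analysis

The design-stage calculation asks: with F = 22,366 candidate features of
which k = 100 carry a population correlation of 0.1 with the (standardized)
worry score, at what n does the max-HC threshold-2 rule reject in ≥ 80% of
simulations? Per simulation the worry vector and feature outcomes are
drawn, two-sided p-values come from the simple-regression t statistic
(covariates are orthogonal noise at design stage), and the HC decision is
applied. The grid search uses common random numbers — each simulation
draws once at the largest grid n and smaller n reuse the leading rows — so
the power-vs-n curve is smooth. Defaults: 200 simulations per point
(±0.028 SE at power 0.8), a `--fast` 50-sim mode.

Two calibration facts matter for interpretation and are computed, not
assumed, by the test suite:

- the threshold-2 rule applied to the full index range is
  **anticonservative** under the global null at this ensemble size (the
  decision takes a maximum over thousands of correlated ranks; the
  empirical null rejection rate at F = 22,366 is about 0.6, far above the
  nominal 5% a single HCᵢ would suggest);
- with effect 0.1, n = 81 places the per-feature noncentrality
  0.1·√(n−2) ≈ 0.89 exactly at the rare/weak asymptotic detection boundary
  √(2ρ·log F) for this sparsity (ρ = β_sparsity − ½ ≈ 0.04). At the
  boundary, finite-sample power sits near 0.7 and approaches 1 only
  asymptotically; in these simulations 80% empirical power is reached
  around n ≈ 160–320 depending on seed. The "detectable with 81
  participants" design figure should therefore be read as a
  boundary-crossing statement, not a finite-sample 80%-power guarantee.

## Numerical and design choices

- Edge ordering: row-major strict upper triangle everywhere; edge id
  recoverable from (i, j) in closed form, and m from E = m(m−1)/2.
- OLS via QR; per-edge variances from the R-inverse row norms; t-based
  two-sided p.
- HC evaluated at ranks 1..n−1; decision strict >; bootstrap tally ≥.
- Fisher clamp 1 − 1e−7; p-value floor 1e−300; nearest-PD eigenvalue floor
  1e−8; all logged when triggered.
- Bootstrap child RNGs seeded as (master, iteration) so iterations are
  order-independent and individually reproducible.
- Pipeline randomness funnels through one master seed with fixed stage
  offsets; manifests carry no timestamps, so identical configs reproduce
  identical bytes.
- Simulation sizes in the test suite (e.g. 30-node connectomes for
  calibration checks, full 212-node panels for recovery checks, 100–500
  Monte-Carlo replicates) were chosen as the smallest giving stable
  verdicts for the property under test.

## Known limitations

- No robust/heteroskedastic SEs, mixed models, partial correlations,
  regularized covariance or dynamic connectivity.
- No analytic max-HC critical values (Donoho–Jin asymptotics); the
  threshold-2 rule is taken as given and its null behavior reported
  empirically.
- The bootstrap ranking has no inferential guarantee by construction.
- Real-data quantities from restricted datasets cannot be reproduced here;
  the acceptance machinery validates the method on synthetic ground truth
  at the same problem sizes instead.
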