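# Methods

## The analysis

The package implements a structural-connectome centrality analysis for
temporal lobe epilepsy (TLE) cohorts. The input per subject is an n x n
asymmetric matrix of probabilistic-tractography streamline counts (entry
[i, j]: streamlines seeded in parcel i reaching parcel j) together with a
per-parcel *waytotal* (total streamlines propagated from that seed), plus a
clinical table (drug-resistance status, epilepsy duration, age at MRI, sex,
TLE laterality, MRI-lesion coding, onset age, surgical-outcome labels).

Processing per subject:

1. **Waytotal normalization.** Row i is divided by waytotal_i, converting
   counts into per-seed connection probabilities and removing seed-size
   bias.
2. **Symmetrization.** W <- (W + W^T) / 2. The arithmetic mean is the
   standard convention for probabilistic tractography matrices and is
   order-independent; the available description lists normalization before
   symmetrization and the implementation follows that order (the reverse
   order would distribute seed-size bias across both directions and is not
   offered).
3. **Proportional thresholding.** For each integer density d% in a sweep
   (default 20-40% in 1% steps, i.e. 21 levels), the k = round(d/100 *
   n(n-1)/2) strongest undirected connections are kept and binarized.
   Rounding is half-away-from-zero; ties at the cutoff weight are broken
   deterministically by ascending (row, column) index, so thresholding is
   exactly reproducible. The 20% floor reflects the observation that
   empirical networks may fragment at lower densities, which degenerates
   path-based metrics; fragmentation *within* the sweep is detected (a
   connected-components check at each level) and reported as a per-subject
   diagnostic, not an exclusion.
4. **Centrality.** On each binary graph: node degree (number of incident
   edges) and betweenness centrality, BC(v) = sum over unordered pairs
   {s,t}, s,t != v of sigma_st(v)/sigma_st, computed with Brandes'
   dependency-accumulation algorithm on the unweighted graph. Pairs without
   a connecting path contribute zero. BC is left unnormalized: at fixed
   node count the normalization is a constant and cancels from group
   comparisons and rank correlations. Metrics are computed on binarized,
   not weighted, graphs, matching the definition of degree as a connection
   count under density thresholding; weighted variants are out of scope.
5. **Density integration.** Each metric is summed across the 21 densities
   ("area under the curve" over the sweep; a plain sum, not a trapezoid),
   giving one threshold-independent value per node per subject.

Because proportional thresholds nest under the deterministic tie-break, the
implementation sorts each subject's edges once and adds them incrementally
across the sweep; a test verifies this equals thresholding every density
independently.

## Inference

* **Group tests.** Two-sample permutation t-tests (drug-resistant vs
  drug-sensitive) on integrated centrality. The observed statistic is the
  pooled-variance t; group labels are permuted preserving group sizes;
  the two-tailed Monte-Carlo p uses add-one smoothing, p = (1 + #{|t*| >=
  |t|}) / (N + 1), which can never reach 0 and keeps the test valid.
  When C(n, n_a) <= N the sampler switches to exhaustive enumeration and
  reports the exact p. Default N = 100,000. Effect sizes are Cohen's d
  with the pooled sample SD and no small-sample correction, so
  t = d * sqrt(n_a n_b / n) holds as an identity.
* **Families.** The primary family is 2 piriform ROIs x 2 metrics = 4
  tests at Bonferroni alpha 0.05/4 = 0.0125. The surgery family is
  corrected for 10 comparisons, alpha 0.05/10 = 0.005. The exploratory
  whole-network scan (every node, both metrics) reports raw permutation p
  and Benjamini-Hochberg adjusted p across the n nodes.
* **Correlations.** Spearman's rho (Pearson correlation of mid-ranks,
  two-tailed p from the t-approximation) between piriform centrality and
  epilepsy duration; a control correlation against age at MRI guards
  against an age confound. Subjects missing a covariate are dropped
  listwise and counted.
* **Regression.** OLS of left-piriform integrated degree on resistance +
  duration, then additionally on sex, laterality (dummy-coded, "left"
  reference; absent levels dropped to preserve full rank), the MRI-lesion
  dummy and onset age. Rank-deficient designs raise rather than silently
  pseudo-inverting.
* **Surgery subanalysis.** Among operated subjects with >= 1 year
  follow-up, ILAE class 1 (seizure-free) vs the rest, permutation t-tests
  at candidate nodes; a negative d means smaller centrality in the
  seizure-free group. With fewer than 2 subjects in either outcome group
  the section is reported as not evaluable.
* **Seeding.** One global seed expands to per-test seeds via a BLAKE2
  hash of (seed, section, node, metric) truncated below 2^31 — tests never
  share a permutation stream, and any reported p can be reproduced by
  re-running the single test with its logged seed. Reports are
  byte-deterministic given config + input files.

## Synthetic cohorts

Patient MRI data cannot be shared, so a generator produces cohorts with the
statistical structure the inference assumes. It is a simulation of
streamline-count *matrices*, not of diffusion signal or tractography.

* **Anatomy template.** One symmetric weight template per cohort: edges
  present with probability `base_density` (default 0.6) on a connected
  random graph (bounded regeneration otherwise), weights log-normal with
  log-scale sigma = 1.5 and mean `weight_scale` (default 5000 streamlines)
  — heavy-tailed counts spanning several orders of magnitude, as
  probabilistic tractography yields. `base_density` must exceed 0.4 so the
  20% proportional threshold cannot disconnect subjects; a per-subject
  connectivity guard regenerates noise (bounded retries) if it ever does.
* **Subjects.** Each subject applies independent multiplicative log-normal
  noise per *direction* (CV `noise_cv`, default 0.3) to the template and
  rounds to integers (present edges floor at 1 streamline), yielding
  asymmetric integer matrices with the template as shared anatomy.
* **Waytotals.** waytotal_i = c_i * rowsum_i with a per-region seeding
  factor c_i ~ Uniform(1.2, 2.5) drawn once per cohort. Waytotals are
  deliberately *not* equal to row sums (streamlines that reach no target
  are still seeded), so the normalization step is genuinely exercised.
* **Planted group effect.** Drug-resistant subjects have one node's row
  and column counts scaled by s_i = 1 + gamma * u_i (u_i log-normal,
  sigma 0.35), the affected row's waytotal rescaled accordingly; gamma is
  found by bisection so that the *realized* Cohen's d of the node's
  integrated degree equals the target (default d = 0.85, the effect size
  the pipeline is designed to detect; tolerance 0.02). Scaling below 1
  (negative targets) uses s_i = 1/(1 + |gamma| u_i).
* **Duration coupling.** Epilepsy durations are rank-coupled to the
  realized effect-node integrated degree across all subjects through a
  Gaussian copula with latent Pearson correlation 2 sin(pi rho / 6), so
  the population Spearman correlation equals the target rho (default
  0.39); marginals are log-normal (median 14 years, log-SD 0.6),
  right-skewed as real duration distributions are. The coupling targets
  the realized centrality rather than the planted scales because scales
  exist only in one group while the duration correlation is defined over
  the whole cohort.
* **Clinical marginals.** Sex (58.1% female), laterality (59.7 / 32.2 /
  6.5 / 1.6 % left/right/bilateral/unclear), an MRI-lesion dummy
  (P = 0.25), onset age ~ Normal(18, 9) truncated at 1 year, age at MRI =
  onset + duration + Uniform(0, 2). Defaults mirror the cohort the
  analysis is designed for: 43 resistant vs 19 sensitive subjects plus 2
  with unknown resistance status (included only in the surgery
  subanalysis), and one labeled subject with missing duration.
* **Surgical outcome.** ~42% of subjects operated (the unknown-resistance
  subjects always); P(ILAE 1) = logistic(intercept - slope * z) in the
  standardized effect-node centrality (defaults 0 and 1.5), follow-up ~
  Uniform(0.5, 8) years. This gives the surgery subanalysis a generative
  analog in which seizure freedom is likelier at low centrality.

What the generator does **not** emulate: spatial anatomy (labels are just
names), distance- or geometry-dependent connection strength, hemispheric
asymmetries, site/scanner effects, or any tractography biases beyond
seed-size (waytotal) variation. Raw streamline-count marginals are a
modeling choice (no empirical distributional reference was available) —
passing tests show the *pipeline* behaves correctly under a plausible
generative model, not that the model matches real tractography output.

## Numerical and design choices

* Densities are carried as exact integer percents; k is computed per
  density from the closed form, never accumulated in floating point.
* |t| comparisons in permutation counting use a relative 1e-12 tolerance
  so exact ties (including the identity permutation) count as at least as
  extreme.
* Degenerate group test: if all observations are identical the null is
  degenerate and p = 1 (t = 0); zero pooled variance with unequal means
  raises.
* Spearman p-values use the t-approximation (the behavior of standard
  statistical packages at these sample sizes), not an exact permutation
  null.
* The exploratory scan derives an independent seed per node; permutation
  sets are not reused across nodes.
* Finer parcellations need no dedicated code path: all components are
  node-count agnostic, and a robustness test splits the effect node into
  two half-nodes sharing its counts and re-detects the effect.

## Problem sizes in the test suite

Statistical validation in the suite runs at sizes chosen to keep the whole
run in the tens of minutes on one CPU: the null-calibration experiment uses
2000 replicate cohorts with 2000-permutation tests; recovery experiments
use 100 cohorts at the default 43 + 19 + 2 subjects with 4000-permutation
tests; Brandes-vs-enumeration equivalence uses 500 random graphs with
n <= 7 plus spot checks at n = 15. The analysis itself defaults to 100,000
permutations.

## Known limitations

* Betweenness is computed per density level from scratch; the sweep does
  not reuse shortest-path information across levels.
* The permutation test permutes raw observations (simple exchangeability),
  not residualized values; covariate-adjusted inference is delegated to
  the OLS layer.
* The generator's effect mechanism (uniform incident-count scaling) raises
  degree and betweenness together; it cannot plant dissociated effects in
  the two metrics.
* Realized per-seed duration correlations inherit sampling noise of order
  1/sqrt(n); only their multi-seed mean is pinned near the target.
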