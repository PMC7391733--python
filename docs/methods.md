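# Methods

## Model

A local community is N individuals under death–immigration–reproduction
dynamics: each event removes one uniformly chosen individual and replaces it
with an immigrant drawn from the regional species pool (probability m) or with
the offspring of a surviving local individual (probability 1 − m). In Sloan's
continuous approximation the stationary relative abundance of a taxon with
pool abundance p is Beta(N m p, N m (1 − p)); only the product N·m is
identified by occurrence-frequency data, so N is fixed by convention and m is
the single fitted parameter.

Assumptions inherited from the model: all taxa disperse and reproduce
equivalently; local communities are independent given the pool; the pool is
static over the sampling window. Taxa whose prevalence sits above or below the
fitted curve are candidates for positive or negative local selection, with the
usual caveat that selection shared between pool and local communities is
invisible to this contrast.

## Regional species pool

Default `pooled_counts`: sum read counts over samples, then normalise. The
alternative `mean_of_proportions` (average of per-sample relative abundances)
weights samples equally regardless of depth; both are exposed and the choice
is recorded in outputs. Taxa with zero pooled count get p = 0 and are excluded
from fitting (p = 0 is outside the Beta parameterisation); they remain in
tables and in bootstrap bookkeeping.

## Detection and the two predicted-frequency curves

A taxon is called present at ≥ `min_reads_detect` reads (default 1).

* `detection="threshold"` (default, the classical form): predicted prevalence
  is the Beta tail above a hard detection limit d. Defaults follow field
  convention: N = mean read depth of the fitted samples, d = 1/N. A
  `half_detect` choice, d = 1 − 2^(−1/depth) ≈ ln 2/depth (the abundance at
  which one read is seen with probability ½), centres the threshold on the
  soft multinomial detection curve and is preferable when depth is known.
* `detection="reads"`: the exact probability of seeing ≥ k reads when `depth`
  reads are drawn multinomially from the Beta-distributed composition — a
  beta-binomial tail. Still a one-parameter least-squares fit of m; no
  likelihood is involved.

Why both exist: the hard threshold ignores read-sampling dispersion. We
measured the asymptotic least-squares bias of the threshold fit against the
exact beta-binomial detection curve: negligible while N·m ≪ depth, but ≈ −24%
when N·m equals the read depth, and no fixed d removes it (it is a shape, not
a location, mismatch). For analyses of real tables at typical depths the
threshold form matches the literature and its bias is small; for simulation
studies and parameter recovery, where N is known and N·m can approach the
depth, the read-level curve is the correct choice and is what the validation
battery uses. When communities are literal collections of N discrete
individuals (the agent simulator) and sequencing is deep, presence is a
beta-binomial over N, so the read-level curve evaluated at size N is exact.

## Fitting

m is estimated by bounded least squares (`scipy.optimize.least_squares`,
m ∈ [1e−9, 1]) initialised from the best of 25 log-spaced N·m values in
[0.1, 10^6]; the objective is smooth but can be nearly flat far from the
optimum, and the grid avoids stalls. Noiseless self-consistency recovers m to
< 0.1% relative error; with multinomial reads and 50 subjects the median
relative error of the read-level fit is 2–5% across m ∈ {0.05, 0.2, 0.5}
(depth 5000, N = 10^4). If the refinement fails to converge the best grid
point is kept and flagged (`converged=False`). RMSE between observed and
predicted prevalences is the goodness-of-fit statistic.

## Classification band

Each taxon's observed prevalence is compared against an acceptance band around
its prediction with nominal level set by `confidence_z` (default two-sided
95%). The band is the score-test acceptance region
predicted ± z·sqrt(predicted(1 − predicted)/n), n being the number of samples;
by the Wilson duality, the observed frequency falls inside it exactly when the
prediction lies inside the Wilson score interval of the observed frequency.
A Wilson interval *centred on the prediction* is not calibrated here: near
saturation its upper limit is strictly below 1 while observed prevalence has an
atom at exactly 1, so every saturated taxon would be called "above"
(P(50/50 | 0.999) ≈ 0.97 is no evidence of selection). With the acceptance
band, fully neutral simulations yield ~0% above/below and ~88% consistently
neutral labels. Boundary ties classify as "within" (conservative toward
neutrality). `wilson_interval` itself is the standard closed form and is used
directly where a proportion CI is meant.

## One-per-subject bootstrap

Longitudinal samples are not independent communities, so the fit is
bootstrapped: each permutation draws one sample per subject uniformly,
rebuilds the pool, occurrence frequencies, N and d from the resampled set
(a fixed-pool mode exists for sensitivity analysis), refits, and classifies.
Aggregates: RMSE mean ± sd, the m distribution, and per-taxon classification
fractions. Consistency labels use the spec of "at least 90% of permutations"
(inclusive threshold) with fit-eligible permutations as the denominator;
fractions over all permutations are also reported (their shortfall from 1 is
the fraction of permutations in which the taxon had pool abundance 0).
Permutations with fewer than five fit-eligible taxa are skipped and counted;
more than 20% skipped is an error. RNG streams are spawned per permutation
index from one root seed, so results are reproducible and independent of
execution order. The Welch t comparison of two bootstrap RMSE distributions
mirrors common practice but carries an explicit caveat: bootstrap replicates
are not independent observations, so its p-value is descriptive.

## Partitions

Samples are assigned to country × age-bin partitions by the age in whole
months (floor) falling in half-open bins (default edges 1, 4, 7, 10, 13
months). Each partition is refit with its own pool, N (mean depth) and d.
The primary CI on m is a percentile bootstrap over subject-level resamples
(subjects drawn with replacement, then one sample per drawn subject). A Wilson
interval treating m as a proportion with n = partition sample count is
reported alongside, clearly labelled: Wilson intervals apply to proportions,
not fitted rates, so this is a compatibility output, not the recommended one.
Classification sets are compared across partitions by Jaccard distance and
embedded with classical (Torgerson) MDS; axes with non-positive eigenvalues
are dropped and the full eigenvalue spectrum is returned.

## Dyad sharing

"Shared within a dyad" means present in the infant sample and in at least one
of the mother's same-site samples (maternal time points aggregated). Source
attribution flags, per infant-carried taxon: mother same site, mother other
site, same-village non-mother adults (same site); the exclusive decomposition
mother-any / village-only / unobserved sums to 1. If the mother lacks same-site
samples the same-site fraction is reported as missing, not zero. Sharing rate
per taxon is the conditional probability that a carrying infant's mother also
carries it; maternal abundance bins default to >0.1%, 0.01–0.1%, ≤0.01%.
Mother–mother overlap uses |A∩B|/min(|A|,|B|) by default (Jaccard available)
and compares within- vs between-village pairs by rank-sum test. Abundance
contrasts between shared and non-shared taxa are tested per age window
(0–6, 6–12, 12–18 months) with two-sided Wilcoxon rank-sum tests.

## Simulator

The default generator draws stationary compositions directly:
x ~ Dirichlet(N m p), sampled through gammas so extreme drift (tiny
concentrations) stays numerically safe. It is fast and analytically tied to
the fitted model — each marginal is the model's Beta — which makes it the
oracle for end-to-end tests. Reads are multinomial at a fixed or lognormal
depth (mean-preserving parameterisation).

The individual-based path runs the literal dynamics (default 50·N events,
i.e. 50 generations; replacement draws exclude the just-removed individual;
a midpoint/end composition-correlation diagnostic is logged at DEBUG level).
Its exact stationary law is Dirichlet-multinomial with concentration
θ = m(N − 1)/(1 − m) — the (N − 1)/(1 − m) factor comes from death preceding
reproduction — and the test suite verifies agent occupancy against that law.

Metacommunities default to lognormal abundances (σ = 2, the
several-orders-of-magnitude spread typical of 16S surveys); a geometric series
is available. Cohorts are independent subject-time point assemblies sharing
p and m. Dyads: village pools are Dirichlet perturbations of the metacommunity
(concentration 500 by default); mothers assemble from their village pool; each
infant's immigration source is α·mother + (1 − α)·village pool, so α = 0 makes
infants exchangeable with unrelated village infants and sharing statistics
rise monotonically with α (Spearman ρ ≈ 0.98 across α = 0.1…0.9 at 20 dyads).

Selection. Constant per-taxon reproductive weights implement directional
selection. Its occurrence-frequency signature deserves a warning: a constant
multiplicative advantage *amplifies* founder and arrival randomness, so across
communities it increases abundance variance at matched mean abundance — the
advantaged taxon ends up high-abundance but patchy, i.e. at or *below* the
neutral curve, never above it. (In the sweep regime the advantaged class fixes
at a deterministic share and which taxon wins locally is a founder lottery; in
the immigration-balance regime the birth/death ratio is near-critical and the
count distribution is strongly overdispersed.) Elevated prevalence at modest
abundance — the "above" signature — requires selection that stabilises a taxon
at a preferred frequency. The simulator therefore also offers stabilizing
(niche) selection via `niche_targets`: a weighted taxon reproduces with weight
w below its target frequency and 1/w above it, pinning it near the target in
every community; the classifier detects such taxa as "above" at many times
the matched-neutral rate. Validation uses both: constant weights to show
deviation from neutrality is flagged (as below/variable), niche targets to
show the "above" direction has power.

## Problem sizes used in validation

Recovery: 50 subjects, 300 taxa, N = 10^4, depth 5000, 20 seeds per m.
Calibration: 50 subjects × 3 samples, 100 bootstrap permutations, 5 seeds.
Selection: 30 subjects × 2 samples, N = 800 (constant weights) or 25–40
communities, N = 1500–2000 (niche targets), individual-based runs of 20–30
generations. Bootstrap-vs-exhaustive: 3 subjects × 2 samples, 10,000
permutations against the 8-fold enumeration. These sizes give stable
statistics at interactive runtimes; all are configurable.

## Limitations

* Occurrence-frequency data identify only N·m; reported m inherits the N
  convention, and comparisons across datasets must hold the convention fixed.
* The threshold detection model is biased low when N·m approaches the read
  depth; use the read-level curve there (see above).
* The pool is estimated from the same samples that are fit; strong, coherent
  selection therefore distorts the pool and can partially mask itself.
* Bootstrap permutations share the underlying samples, so consistency labels
  and the RMSE comparison are not formal tests.
* The simulator omits several features of real surveys: taxonomic correlation
  between villages beyond a single Dirichlet perturbation, time-varying pools
  and age-dependent m within a subject, compositional sequencing artefacts
  (chimeras, contamination), and any phylogenetic structure. Passing its tests
  demonstrates internal consistency of the method, not field accuracy.
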