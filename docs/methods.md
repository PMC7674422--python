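# Methods

## The clade-age calibration model

A clade originates as one lineage and diversifies under a time-homogeneous
birth–death process with speciation rate λ and extinction rate μ,
parameterized by the net diversification rate d = λ − μ and the turnover
ε = μ/λ (so λ = d/(1−ε), μ = εd/(1−ε)). Fossils are preserved and
discovered at rate ψ per lineage per Myr. Conditional on the clade having
at least one living species at the time its first fossil formed, the
probability density that the clade originated t Myr before that fossil is

    f(t) = E[ ψ N e^(−ψ S(t)) | N ≥ 1 ]

with N the number of extant species at fossilization and S(t) the total
lineage duration accumulated by the clade over [0, t]. S counts *every*
lineage alive at any point during the interval, including side branches
that went extinct before the fossilization time — a fossil can be sampled
from a lineage that later died out. Consequently S(t) ≥ t, with equality
exactly when the clade stayed a single lineage throughout.

### Monte-Carlo evaluation

The expectation has no closed form for general (λ, μ, ψ), so it is
estimated by exact Gillespie simulation of the lineage-count process
(exponential waiting times at total rate N(λ+μ); no time discretization).
Each replicate runs one unconditioned history forward and records the
integrand ψ N e^(−ψS) at every requested grid age while the history is
alive; histories extinct by a grid age are excluded from that age's average,
which is precisely the N ≥ 1 conditioning. Amortizing one history across
the whole age grid makes the estimator's values correlated across grid
points — harmless for a density table — and reduces the cost by roughly
the grid size relative to per-age rejection sampling.

Uncertainty in the fossil's age (a uniform stratigraphic interval
[age_min, age_max]) and in the rates (uniform ranges for d, ε, ψ) is
marginalized by drawing each quantity uniformly per replicate. The
marginal density is defined as the expectation of the integrand jointly
over parameter draws and histories, conditioned on survival; parameter
values with higher survival probability therefore carry proportionally
more weight, and the definition reduces exactly to the display above when
all parameters are points. Grid ages that precede a replicate's drawn
fossil age contribute zero density but stay in the denominator (the clade
cannot predate its record under that draw).

Two numerical safeguards bound the work per replicate:

- once ψS exceeds 70 the integrand is below e⁻⁷⁰ of any attainable value;
  the history is counted as alive-with-zero-density for the remaining grid
  ages (a by-then-enormous clade's total extinction has negligible
  probability), capping the event count at about (λ+μ)·70/ψ per replicate;
- a rejection-sampling cap of 10⁷ attempts guards the separately exposed
  conditioned-history sampler against parameter regimes whose survival
  probability is effectively zero.

The simulation kernel is jit-compiled and seeded per call: identical seed
and inputs give bit-identical densities.

### Grid construction

Densities are tabulated on 1000 equally spaced ages from the (younger)
fossil's minimum age to an adaptive upper bound: a pilot run extends the
grid geometrically until the raw density falls below 10⁻⁶ of its maximum,
capped at 10× the 0.999 quantile. The tabulated density is renormalized to
integrate to 1 by the trapezoid rule; evaluation interpolates linearly, is
zero outside the support, and the CDF/quantile pair are exact inverses of
the interpolated table. Sampling is by inverse CDF.

### Two-fossil mixtures

For an ambiguous first record the two candidate fossils carry assignment
probabilities p_younger + p_older = 1 ("twice the weight" on one fossil
means probabilities 2/3 vs 1/3, since the mixture must normalize). Each
component density is normalized individually on a shared grid and the
mixture is their weighted sum; the older component vanishes below the older
fossil's age, so the mixture is p_y f_y below t_older and
p_y f_y + p_o f_o above — by construction, not approximation. Fossils are
ordered by interval midpoint; overlapping intervals are accepted with a
warning (ordering by midpoint), though the intended use is disjoint
stratigraphic intervals.

## Node-age prior on a fixed topology

Conditioned on the root age T, the ages of the remaining internal nodes of
a complete-sampled reconstructed birth–death tree are iid with kernel

    g(t) ∝ r² e^(−rt) / (λ − μ e^(−rt))²,   r = λ − μ > 0

truncated at T (for μ = 0 this is the familiar truncated exponential of
the pure-birth process). On a *fixed labeled topology* the joint density of
node ages is the product of kernels restricted to the topology's partial
order (each assignment of distinct ages consistent with parent-older-
than-child corresponds to one equally weighted ranked history). The root
age carries its own prior — a configuration choice (uniform, normal, or
improper flat). This conditional construction was verified against forward
simulation of exactly-3- and exactly-4-tip pure-birth trees (KS < 0.02).
When the tree prior's d is a range, the sampler uses the range midpoint.

## The Metropolis–Hastings sampler

State: the vector of internal-node ages (plus log clock rate for posterior
runs). Operators:

- **node slide** (weight 3): a uniform draw for one non-root internal node
  within (oldest child age, parent age); symmetric.
- **subtree scale** (weight 1): multiply all internal ages within a random
  subtree by s ~ U(κ, 1/κ), κ = 0.75; Hastings factor s^(m−2) for m scaled
  ages.
- **root scale** (weight 1): the same move on the root age alone
  (Hastings 1/s).
- **root slide** (weight 1): a symmetric uniform-window move on the root
  age. Multiplicative root moves cannot cross the deep inter-mode valley of
  a well-separated bimodal calibration (intermediate states have ~zero
  density), so this window move — wide enough to reach the other mode in
  one jump — is what makes mode switching possible. The window defaults to
  half the starting root age and can be set per run; optional tuning
  adjusts it during burn-in only.
- **rate scale** and a joint **up/down move** (ages × s, rate / s; Hastings
  s^(m−2)) when the clock rate is sampled. The up/down move travels along
  the rate–time ridge that the strict-clock likelihood cannot resolve and
  is the difference between root-age effective sample sizes of ~10 and
  ~300 in the recovery experiment.

Proposals that violate the age partial order or leave a calibration
density's support are rejected (log density −∞). Calibration densities are
precomputed tables evaluated by interpolation; the chain multiplies
constraint densities independently (no joint correction for nested
calibrated clades — a documented limitation). Burn-in defaults to 10% of
the chain; the trace retains every `thinning`-th iteration from the start,
and summaries drop the burn-in fraction. Initial ages set each calibrated
node to its density median, then raise ancestors minimally to restore
ordering.

The clock rate gets an improper log-uniform prior bounded to
[10⁻⁸, 10²] substitutions per site per Myr — effectively uninformative for
any realistic molecular rate.

### Trace summaries

ESS uses Geyer's initial monotone sequence estimator (FFT autocovariances,
paired sums truncated at the first non-positive pair, monotonized); it was
cross-checked against an independent library implementation on AR(1)
series. A constant series reports ESS = length with a warning. The HPD
interval is the shortest window containing ⌈level·n⌉ sorted samples. A
mode switch is a crossing of the density minimum between the two component
modes, counted on the thinned trace.

## Sequence likelihood

GTR with the six exchangeabilities and four base frequencies, rate matrix
scaled to one expected substitution per unit branch length; branch lengths
are clock_rate × duration (Myr). Discrete-Γ rate variation uses the
mean-of-bin discretization into equal-probability categories; shape None
disables it, and one category or a very large shape collapse to the
rate-homogeneous model. Likelihoods use the pruning algorithm over
compressed site patterns with per-node rescaling and a log-sum-exp over
categories; N, -, ? are missing data (partial vectors of one). The
eigendecomposition uses the π-symmetrization of the reversible generator
and is computed once per model. Partitioning, codon handling and
third-position exclusion are the caller's responsibility; the module sees
plain nucleotide alignments.

## Marker-filter cascade

Filters run in a fixed order because counts depend on it: (1) drop
sequences below 90% of the best ingroup bitscore for their exon, (2) drop
sequences with dN/dS strictly above 0.25 (exactly 0.25 is retained), (3)
drop exons with more than 10 missing species, (4) mask whole codons with a
site above 20% missing data or a codon entropy score above 0.5 (masking
removes triplets only; inputs must be in frame), (5) drop alignments
shorter than 150 bp after masking, (6) drop alignments with among-sequence
GC standard deviation (sample SD, ddof = 1) above 0.04, (7) drop all exons
of genes with fewer than 3 surviving exons or exons spanning more than
100,000 bp on the reference genome (0-based half-open coordinates,
span = max end − min start), (8, optional) drop exons flagged discordant by
an externally supplied boolean table, re-applying the minimum-exon rule,
(9, optional) drop manually excluded genes. Each step logs
(unit, before, removed, after) with after = before − removed; the cascade
is deterministic and idempotent. Gene-set selection: *permissive* = minimum
ESS > 100, substitution rate < 1.6×10⁻⁹ per year and site, rate CV < 0.7;
*strict* = ESS > 200, rate < 1.4×10⁻⁹, CV < 0.6; strict is nested in
permissive by construction. External tools (TBLASTN, codeml, BMGE, tree
concordance) are consumed as table columns, never re-run.

## Synthetic data and what the tests show

The fixture generators produce (i) exon metric tables with exactly planted
rule violations — one violation per exon so cascade steps cannot interact,
clean sequences at bitscore 100 / dN/dS 0.1, a species panel of 15 — and
return the audit report the cascade must produce (self-verifying); and
(ii) the bimodality experiment: two simulated point-age fossils with equal
weights at separations of 30/60/90/120 Myr (younger fossil at 50 Ma),
rate parameters at the midpoints of the published teleost ranges
(d = 0.061, ε = 0.1856, ψ = 0.01233 per lineage per Myr), calibrating the
root of a two-tip tree with a flat root prior so the sampled ages must
reproduce the mixture density exactly.

These generators emulate the *structure* of real inputs (stratigraphic
intervals, rate ranges, metric tables), not their messiness: real exon
tables have correlated violations across filters, real fossil ages are not
uniform draws, and real alignments violate the strict clock. Passing tests
therefore demonstrate correctness of the model arithmetic, the samplers
and the cascade bookkeeping — not robustness to model misspecification.

Validation problem sizes: densities use 10⁵ Monte-Carlo replicates (10⁶
for the analytic-limit check); prior-recovery and bimodality chains run
1.12 million iterations thinned by 10 (≈10⁵ retained after burn-in); the
simulate-then-date study uses 20 replicates of 10⁴ sites on a 6-tip tree
with 15,000-iteration chains. The age grid holds 1000 points.

## Known limitations

- At most two candidate first records per clade; the mixture model is
  explicitly two-fossil.
- No fossilized-birth–death tip dating, no incomplete extant-sampling
  correction, no time-varying rates.
- Whether the original calibration tool additionally conditions on clade
  survival to the present is not settled here; the density implements the
  N ≥ 1-at-fossilization conditioning literally.
- Multiple constraints multiply independently; nested calibrated clades
  receive no joint correction.
- Strict clock only; no partitioned or relaxed-clock models.
- The tree prior assumes complete species sampling of the clade.
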