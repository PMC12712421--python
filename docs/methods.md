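# Methods

`fluctsel` estimates time-varying selection from temporal allele-frequency
data and provides the forward simulation machinery to study when such
estimation works. This note records the models, the defaults and why they
were chosen, the numerical decisions, and the limits of what the test
suite demonstrates.

## Selection model and the logit connection

The deterministic core is the standard one-locus diploid viability model
with fitnesses `w_aa = 1`, `w_Aa = 1 + hs`, `w_AA = 1 + s`. One
generation of selection changes the frequency `p` of the selected allele
by

    dp = s p (1-p) [p + h(1-2p)] / w_bar,
    w_bar = 1 + s p^2 + 2 h s p (1-p).

Writing `dp = S p (1-p)` defines the effective (haploid-equivalent)
selection coefficient `S = s [p + h(1-2p)] / w_bar`. On the logit scale
the haploid recursion is approximately linear in time with slope `S`, so
a binomial logistic regression of allele counts on time estimates `S`.
Under additive dominance (`h = 0.5`) the bracket is exactly 1/2 at every
frequency and the slope estimates `s/2` up to the `1/w_bar` factor; away
from additivity the `S -> s` mapping depends on frequency, which is why
the inversion `s_from_S(S, h, p)` takes a reference frequency. Mean
fitness is always computed exactly; the familiar rare/intermediate/
near-fixation limits (`S ~ sh`, `s/2`, `s(1-h)`) are treated as
asymptotic approximations and verified as such (2% after removing the
`w_bar` factor).

Because `S` is a linear-fractional function of `s` at fixed `(h, p)`, the
inversion has a closed form, `s = S / (a - S b)` with
`a = p + h(1-2p)`, `b = p^2 + 2hp(1-p)`; the implementation uses it
directly (with admissibility checks for positive genotype fitnesses)
rather than iterative root-finding.

The linear-logit approximation degrades when `|s|` is large: even at
`h = 0.5`, `S = s/(2 w_bar)` declines slightly as `p` (and hence
`w_bar`) grows, so a fitted logit slope under-states `s/2` by roughly
`s * p_bar / 2` (about 5% at `s = 0.1`). The consistency tests bound the
error at 5% for `|s| <= 0.1` over the frequency window [0.1, 0.9]; the
approximation should not be trusted for much stronger selection.

## Forward simulator

`simulate` implements a panmictic diploid Wright–Fisher population of
`N` individuals carrying a recombining region of `L` bp:

* **mutation** — Poisson(`mu*L`) new sites per gamete, each at a uniform
  position; a fraction `prop_selected` of new mutations is selected.
* **fitness effects** — a selected locus draws a non-negative relative
  effect once, `base_effect ~ Exponential(mean 1)`. The selection regime
  is a list of periods tiling the post-burn-in timeline, each with a
  signed mean effect; the locus's realized coefficient during a period
  is `base_effect * mean_s`. The same loci therefore flip effect sign
  across regimes — fluctuating selection acting on the same variants —
  and a period with negative mean is a negated exponential (all effects
  deleterious). Per-period effects have expectation equal to the
  period's mean.
* **selection** — multiplicative fitness across loci with per-locus
  genotype fitnesses `1, 1 + h s_t, 1 + s_t`.
* **reproduction** — parents drawn proportional to fitness (selfing
  allowed), one recombinant gamete per parent with Poisson(`r*L`)
  crossovers per meiosis.
* **standing variation** — either an explicit neutral burn-in, or (the
  desk-scale default) direct seeding from the neutral mutation–drift
  equilibrium site-frequency spectrum: Poisson(`theta * H_{2N-1}`)
  segregating sites with derived-allele counts drawn proportional to
  `1/i` and copies placed on haplotypes at random. Seeding bypasses the
  burn-in that otherwise dominates runtime; its known simplification is
  that the initial state carries no linkage disequilibrium, which builds
  up subsequently through drift and selection.

Selected effects are dormant during burn-in. "Known selected loci" are
the selected loci segregating at the first post-burn-in generation;
their true frequency paths over the sampled window are what the
simulator records and the estimators consume.

A light-weight single-locus path (deterministic recursion + binomial
resampling of `2N` allele copies) backs the drift oracles in the tests
and the focused experiments below; its neutral variance after `t`
generations matches the closed form `p0 q0 (1 - (1 - 1/2N)^t)`.

## Observation designs

* **Museum/herbarium (continuous)** — one potential time point per
  generation across the window; per-generation sample sizes follow a
  geometric ramp ending at the present, rounded by largest remainder to
  sum exactly to the design total, with zero-sample generations dropped.
  The default density growth factor is 1.01: at 200 individuals over 150
  generations this keeps at least one specimen per generation while the
  density still roughly doubles toward the present. This choice is
  deliberate: a steeper ramp (e.g. 1.02) rounds the first ~25
  generations to zero specimens, and a shift in the selection regime
  that occurs before essentially any data exist is unidentifiable in
  principle — no estimator choice can recover it. Real natural-history
  series retain sparse early coverage, and the power study assumes the
  first regime shift is at least observable.
* **Discrete** — `steps` equally spaced time points straddling a known
  shift (default six points, ten generations apart, centred on the
  shift), each with the same number of individuals.

Sampling is binomial: each diploid contributes two allele copies drawn
with replacement from the population frequency (`N >> n` in all
scenarios, so the hypergeometric correction is negligible).

## Joint segmented inference

The estimator is a binomial-response logistic regression shared across
loci: for locus `j` at time `t`,

    logit p_j(t) = alpha_j + f(t),

with locus-specific intercepts and a continuous piecewise-linear `f`
whose slopes are the per-segment effective selection coefficients and
whose knots are the regime-shift times. Under a distribution of fitness
effects the loci are heterogeneous, so the shared slope estimates an
information-weighted *mean* `S` across loci; per-period `s` estimates
are obtained by inverting each segment slope at the allele-weighted mean
observed frequency of that segment (assumed dominance supplied by the
analyst, default additive).

Numerics. For fixed breakpoints the log-likelihood is concave in
`(alpha, beta)` and is maximized by full Newton iteration; the Hessian
is diagonal in the intercepts, so each step solves only a small system
in the slope parameters via the Schur complement (cost linear in the
number of observations), with step-halving and a convergence rule that
requires a full accepted Newton step — halved steps near-stationarity
indicate the iterate is still far from the optimum. Loci whose counts
are zero (or maximal) at *every* time point have no finite intercept and
are excluded and flagged; individual time points at observed frequency 0
or 1 are informative and retained.

Breakpoint search. Candidate breakpoints are the observed time points
(integer-generation resolution) with at least three time points per
segment. Truly exhaustive search over all `C(~110, k)` placements is
not affordable for `k >= 3`, so the search is a deterministic
coarse-to-fine scheme: a scan of a uniformly subsampled candidate grid
(capped at ~1500 placements, each ranked by a few warm-started Newton
steps with the leaders refit to convergence), plus candidates formed by
adding one breakpoint to the best `(k-1)`-breakpoint solution, followed
by coordinate-descent refinement at full resolution. Warm starts carry
the previous optimum between neighbouring candidates, and any
non-converged warm fit is retried cold. The seeded candidates make the
maximized log-likelihood provably non-decreasing in `k` (the enlarged
model nests the smaller one at fixed knots). Ties in the grid search
break toward the earlier breakpoint. Reported breakpoint intervals are
95% profile-likelihood bounds over the grid, holding the other
breakpoints fixed.

Model selection. `select_breakpoints` fits `k = 0..k_max` and minimizes
the BIC with effective sample size equal to the total number of sampled
allele copies and parameter count `J + (k+1) + k` (intercepts, slopes,
knots). The BIC is intentionally conservative; genetic drift makes the
binomial likelihood overdispersed, so likelihood-ratio-style selection
would overfit the breakpoint count.

The instantaneous estimator for discrete designs is
`S_t = (p_after - p_before) / (p_before (1 - p_before)) / dt`, with the
*pre-shift* frequency in the denominator (the defining ratio does not
specify which; this choice is fixed and documented) and an optional
`dt` to place the estimate on a per-generation scale. Its standard
error is the binomial delta method given the two allele sample sizes.

Environmental covariates. `fit_with_environment` models the
per-generation slope as `S(t) = f'(t) + gamma * env(t)` by adding a
cumulative-exposure column `E(t) = sum_{u<t} env(u) du` to the design —
the coefficient `gamma` is the per-unit-env change in `S`. (A raw
`env * t` product column would not correspond to any generative model of
selection switching with the environment.) A constant environment makes
exposure proportional to time; the fit then falls back to the plain
model with a zero interaction and flag `constant`. An environment
itself (near-)linear in time is flagged `collinear` and the interaction
is not estimated.

No multiple-testing correction is applied in the joint model — it
performs one shared test. Per-locus scans, where a user runs
`logit_slope` locus by locus, should be corrected by the user
(Benjamini–Hochberg is the community default).

## Scenario harness and study conditions

The desk-scale study conditions are: `N = 1000` diploids, `L = 10` kb,
`mu = 5e-6` per site per generation, region map length `r*L = 2.3`
crossovers per meiosis, `prop_selected = 0.05` (giving ~80–95 known
selected loci per replicate), equilibrium-SFS initialization, and three
selective periods with mean effects +0.05, −0.025 and +0.10 over
generations 0–50, 50–100 and 100–150, so the true regime shifts sit at
generations 50 and 100 of a 150-generation sampled window. Twenty
replicates per scenario. Scenarios cross continuous (200 or 70
individuals) and discrete (6 × 40 or 6 × 15) designs with dominance 0.5
or 0.15; analysis always assumes additivity, which is the point of the
dominance scenarios.

Two desk-scaling decisions deserve emphasis:

* **Recombination.** The full-scale design is a 100 kb region at
  `r = 2.3e-5` per site — 2.3 crossovers per meiosis. Shrinking the
  region to 10 kb at the same per-site rate would cut the region map
  length tenfold, pushing the tracked loci into a near-clonal linkage
  regime in which the joint estimator resolves haplotype-block dynamics
  rather than the selection regime. The desk default therefore
  preserves the *region* map length (`r = 2.3e-4` per site at 10 kb),
  which is the quantity that governs locus independence in a joint
  multi-locus fit.
* **Standing variation.** Equilibrium-SFS seeding replaces the explicit
  multi-thousand-generation neutral burn-in; the paper-scale
  configuration (N = 5000, 100 kb, burn-in 2000 generations,
  `prop_selected = 0.002`) remains available behind the `scale` flag of
  the `figure1` command.

Metrics follow the conditioning rule of the power study: the
breakpoint-count success rate uses all replicates; selection-coefficient
and breakpoint-timing biases are computed only over replicates whose
selected breakpoint count equals the truth. Bias is signed
(estimate minus true period mean), summarized by median, interquartile
range and min–max; success rates carry Clopper–Pearson intervals.

For the discrete design the harness pools counts across loci within
each time point (the mean-frequency estimate of all known selected
loci) and forms one instantaneous estimate per adjacent pair of time
points, scored against the mean effect of the period containing the
pair's midpoint.

Focused experiments back the remaining properties at low cost using the
single-locus path with SFS-drawn starting frequencies: the neutral
type-I control (50 replicates of 50 unlinked neutral loci under the
museum design; the selected breakpoint count should be 0 in ≥90% of
them), the matched-effort design contrast (the instantaneous estimator's
between-replicate variance exceeds the continuous logit-slope
estimator's), and the dominance-bias experiment (rare alleles simulated
at `h = 0.15`, analyzed assuming additivity, give systematically
negative `s` bias — rare partially-recessive alleles have `S` well below
`s/2`).

## What the synthetic data do and do not show

The generator emulates the study design: fluctuating directional
selection on standing variation in a closed, panmictic population, with
binomial observation noise. It does not emulate spatial structure (the
full-scale study population lives in 2D space; spatially spreading
sweeps produce more nearly linear global frequency trajectories than
panmictic logistic growth, so the desk-scale replication is, if
anything, the harder problem), population-size change, migration,
sequencing error, or reference/orientation error. Passing tests
demonstrate internal consistency of estimator and generator under the
stated conditions — not robustness to structure shifts or ascertainment,
both of which are known to bias selection estimates from real time
series and are out of scope here (kinship-matrix corrections and
drift-explicit likelihoods are the appropriate tools).

Known limitations:

* The shared-slope model estimates a weighted mean `S`; under a heavy-
  tailed DFE the weighting favours loci near frequency 0.5, and late in
  a strong-selection period the weighted mean declines as large-effect
  loci approach fixation. With sparse early sampling this can make a
  spurious within-period knot compete with a true early regime shift.
  The desk-scale conditions (early sampling coverage, preserved map
  length) keep this in check; analysts of real data should inspect
  per-segment fits and the model-score table, not just the selected k.
* Breakpoint timing is reported in generations since the start of the
  sampled window; calendar conversion is left to the user.
* `s_hat_from_fit` inverts at a single reference frequency per segment;
  when frequencies span a wide range within a segment and dominance is
  far from additive, no single reference is fully adequate.
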