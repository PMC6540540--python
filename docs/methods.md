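# Methods

## Model

A tumor sample with purity φ contains S subclones with cell fractions
η₁,…,η_S (so φ = Σ η_s) related by a rooted phylogeny. Under the
infinite-sites assumption each subclone inherits all mutations of its parent,
so a mutation arising in subclone s is carried by s and its descendants; the
indicator of that set over subclones is the mutation's allocation vector
q. We additionally assume a single founder clone, at most two descendant
subclones per ancestor, and clonal copy-number events. The last assumption
is what makes multiplicity tractable: a subclonal mutation necessarily
post-dates every copy-number event and sits on one allele copy (m = 1), while
a clonal mutation may pre-date the event and carry m ∈ unique positive of
{1, C₁, C₂} for allele-specific copy numbers C₁ ≤ C₂.

Writing ϑ_s = η_s/φ for the subclone proportions among cancer cells, a
combination d = (q_d, m_d) at a locus with state (C₁, C₂) implies binomial
success probability

p_d = m_d φ ϑᵀq_d / ((C₁+C₂) φ + 2(1−φ)),

the expected variant allele frequency of a mutation with cellular prevalence
ϑᵀq_d. Alternate read counts are modeled per unique copy state w by an
ε-contaminated binomial mixture over the D_w = |M| + S − 1 combinations (the
clonal allocation with every multiplicity, each subclonal allocation with
m = 1); the ε term is a discrete uniform on {0..T}-scale density 1/T per
locus, absorbing artifacts and mis-modeled loci.

ITH is summarized by Shannon entropy E = −Σ ϑ_s log ϑ_s, which is invariant
to purity, increases with the number of subclones, and discounts negligible
subclones continuously — the property that makes it a better association
covariate than a raw or thresholded subclone count.

## Enumeration

All non-isomorphic rooted trees with 1..s_max nodes and out-degree ≤ 2 are
generated recursively (a tree is a root plus an unordered pair or singleton
of subtrees) and labeled breadth-first with children ordered by canonical
subtree form, making configuration indices reproducible. The counts are 1,
1, 2, 3, 6 for S = 1..5 (13 configurations at the default s_max = 5), and
are verified in the test suite against a brute-force enumerator that
generates all parent vectors and dedupes by rooted isomorphism. Isomorphic
relabelings are collapsed because the likelihood explores all proportion
vectors, making labelings redundant.

## Fitting

Each configuration is fitted by EM over latent (allocation, multiplicity)
assignments:

* E-step: posterior responsibilities of the noise term and each combination,
  computed in log space.
* M-step, closed form: ε is the mean noise responsibility, clamped to
  [1e−6, 0.25] (an unbounded ε can absorb genuine clusters); each π_w is the
  normalized responsibility tally of its state. A state with no non-noise
  responsibility resets π_w to uniform with a warning.
* M-step, ϑ: quasi-Newton (BFGS family; the limited-memory L-BFGS-B
  implementation is used for speed on this ≤ 4-dimensional problem) on the
  expected complete-data log-likelihood, in a softmax parameterization with
  the last coordinate pinned so the optimization is unconstrained. The
  update is skipped when the gradient at the current ϑ is negligible, and
  the previous ϑ is kept whenever the optimizer fails to improve the
  objective, preserving the generalized-EM ascent guarantee. Because the
  expected complete-data log-likelihood is additively separable in (ε, π)
  and ϑ given responsibilities, the split M-step is exact.

Initialization: ε = 1e−3, π_w uniform, ϑ ~ Dirichlet(1,…,1). Restarts are
staged: n_inits (default 5) starts run 3 iterations, the best two continue
to 12, and the single best continues until the relative change in observed
log-likelihood falls below 1e−6 or 500 total iterations. Observed
log-likelihood monotonicity along the returned path is asserted in tests at
tolerance 1e−8. S = 1 uses a single start (ϑ is fixed).

Numerical safeguards: binomial success probabilities are clipped to
[1e−9, 1 − 1e−9]; a combination whose unclipped probability reaches 1
(possible only in degenerate purity/state corners) is dropped from the
mixture with a warning rather than failing the fit.

## Model averaging and metrics

Each fit b is scored by BIC_b = 2L_b − m_b log(L), with L the number of
mutations and the model size counting free parameters under simplex
constraints: m_b = 1 (ε) + (S − 1) (ϑ) + Σ_w (D_w − 1) (π). Posterior
configuration weights are softmax(0.5 · BIC), computed via log-sum-exp.

Before averaging, a support filter removes configurations in which any
non-root subclone is the maximum-a-posteriori origin of fewer than
min_support = 2 mutations (MAP over combination responsibilities, noise
excluded); weights are renormalized over the retained set, and both entropy
metrics are computed after filtering (filter-then-weight is the default; the
unfiltered order is available via `apply_support_filter=False`). The
single-clone configuration is never removed, so the retained set cannot be
empty when it was fitted.

* E_o averages entropy over configurations whose BIC ties the maximum within
  1e−6 (a tolerance for float noise in "equal BIC").
* E_w averages entropy over all retained configurations by weight.
* S is the subclone count of the best-BIC retained configuration; the
  high-ITH indicator is I(S > κ) with κ = 3 in the simulation convention, or
  I(S ≥ 3) in the application convention (both exposed).
* Per-mutation cellular prevalence is the weight-averaged ϑᵀq of each
  configuration's MAP allocation.

## Simulator

The generator reproduces the benchmark's study conditions; its defaults are
the baseline grid point and all knobs are exposed on `SimConfig`.

* Subclone structure: S uniform on {1..5} (the distribution over S is not
  otherwise pinned down; uniform exercises every stratum), tree uniform
  among configurations with S subclones, U_s ~ Uniform(−3, 1),
  η_s = exp(U_s)/(1 + Σ exp(U_s')), φ = Σ η_s. Draws are rejected until
  min ϑ_s > 0.05 and all pairwise cellular-prevalence gaps exceed 0.05, so
  simulated clusters are identifiable in principle.
* Reads: depth T ~ NegBin with mean μ ∈ {100, 500, 1000} and dispersion
  δ = 2 in the variance-μ + μ²/δ parameterization (moment-tested), truncated
  below at 1; copy states uniform over {(1,1), (0,1), (1,2)} by default,
  mirroring mutations spread evenly across common clonal states;
  (allocation, multiplicity) uniform over the state's valid combinations;
  A ~ Binom(T, p_d). 100 mutations per sample by default.
* Covariates: Z₁ ~ Bernoulli(0.5) (sex-like), Z₂ ~ N(0,1) (age-like),
  Z₃–Z₅ one-hot stage indicators from a four-category equal-probability
  multinomial with the reference dropped. These are synthetic stand-ins
  shaped like typical clinical covariates, not a reconstruction of any
  particular cohort.
* Survival: constant baseline hazard λ₀ = exp(−7.0), hazard
  λ₀·exp(β·ITH + γᵀZ) with β = 0.5 and γ = (0.55, 0.15, 0.8, 1.7, 2.7), so
  event times are exponential; censoring ~ Uniform(0, τ).
* τ tuning: a pilot population of subjects (default 10⁵) is drawn once; for
  candidate τ the expected censoring fraction is the pilot mean of the exact
  per-subject probability (1 − e^{−rτ})/(rτ), a smooth monotone function
  bisected to within 0.005 of the target. Targets outside [0.01, 0.9] are
  rejected as degenerate.

What the simulator does not emulate: subclonal copy-number alterations,
mutation-calling errors beyond the ε channel, multi-region sampling, and
real covariate correlation structure. Passing benchmarks therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to their violation.

## Benchmark harness

Replicated cohorts are simulated; an ITH covariate (true E, true H, or
estimated E_o/E_w/H from full read-count inference via a pluggable
estimator) enters a Cox proportional-hazards model (lifelines) with the five
baseline covariates. Per scenario the harness reports mean coefficient,
bias, empirical SE, power at α = 0.05 (Wald), 95% CI coverage of the
generating coefficient, and the Spearman correlation (average-rank ties)
between estimated and true subclone counts. Replicate seeds derive from a
master seed by counter, so results are reproducible bit-for-bit.

Problem sizes: the acceptance script uses 50 replicates of 400 subjects for
the true-covariate targets and 100,000 fresh subjects for the censoring
check, matching the benchmark design; the estimated-entropy coverage target
runs 20 replicates of 50 subjects at mean depth 500, a reduced scale chosen
so the full per-sample mixture inference (13 configurations × 5 restarts per
sample) stays tractable on a single CPU. The package's own tests verify
recovery at the full per-sample size (100 mutations, depth 500).

## Known limitations

* Clonal-SCNA assumption: mutations inside subclonal copy-number regions are
  liable to be explained as extra subclones.
* Two subclones with near-equal cellular prevalence are unidentifiable from
  one bulk sample; the simulator's separation constraints deliberately avoid
  this regime.
* BIC weights are a large-sample approximation; with few mutations the
  posterior over configurations is diffuse and E_w correspondingly shrinks
  toward the average entropy of competing trees.
* Beta-binomial overdispersion and joint multi-sample fitting are out of
  scope.
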