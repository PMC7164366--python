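# Methods

`cetdate` implements a Bayesian divergence-dating workflow for
phylogenomic coding data: dataset-assembly QC, rate-binned gene
partitioning, relaxed-clock model selection by stepping-stone marginal
likelihoods, and fossil-calibrated MCMC dating under a birth–death
node-age prior with exact or Hessian-approximate likelihood, together
with infinite-sites diagnostics and a synthetic-data generator that makes
the whole chain testable without any sequence download. This note
documents the models, the numerical choices, and what the synthetic
experiments do and do not establish.

## Time and rate units

Internally 1 time unit = 100 Ma; substitution rates are in
substitutions/site/unit, so the Γ(2, 20) rate prior has mean 0.1
subs/site per 100 Ma — a mammal-like magnitude. All I/O (trees,
calibration tables, posterior summaries) is in Ma; conversion happens
only at the sampler boundary.

## Priors

**Node ages.** Non-root interior ages are i.i.d. draws from the
birth–death kernel conditional on the root age, with birth rate λ, death
rate μ and sampling fraction ρ (defaults λ = μ = 1, ρ = 0.1 per unit,
which make the kernel nearly uniform: the endpoint-density ratio is
(1+ρλt₁)² = 1.21 at t₁ = 1). For λ = μ the kernel has the closed form
g(t) = (1+ρλt₁)/(t₁(1+ρλt)²); the general case uses the standard
P(0,t)/v_t expressions, and both CDF and quantile function are closed
form (used for simulation and for prior-only checks).

**Fossil calibrations.** A calibration is a uniform core on [t_L, t_U]
carrying mass 1−p_L−p_U, with an exponential upper tail and a power-law
lower tail matched continuously to the core height; a zero tail
probability makes the bound hard (true zero density — not a tiny tail).
Calibrated nodes *replace* their birth–death kernel term; truncation by
the parent-older-than-child constraint is implicit in the sampler. The
effective marginal prior at a node can therefore differ from the
specified calibration density — which is why `DivergenceTimeModel`
exposes `fit_prior()` and the recommended practice is to run it before
every dating run. A root calibration is mandatory.

**Branch rates.** Three clock models. STR: all branches share one rate
μ_p per partition. IR: branch rates i.i.d. lognormal with expectation μ_p
and log-variance σ²_p. AR: geometric Brownian motion along the tree —
a child branch's log rate is Normal(log parent rate − σ²Δt/2, σ²Δt),
where Δt is the time between branch midpoints and the root's child
branches diffuse from a lognormal with expectation μ_p over their
distance from the root. The −σ²Δt/2 drift makes the rate process a
martingale (E[child rate | parent rate] = parent rate), which the
generator's tests verify by simulation. The midpoint-to-midpoint
discretization is one of several possible choices for an autocorrelated
clock; only its stated properties (martingale, degenerate limit at
σ² → 0) are relied on.

**Hyperpriors.** μ ~ Γ(2, 20) and σ² ~ Γ(2, 2), as diffuse defaults on
the unit scale. With several partitions, the *average* of the partition
mean rates carries the gamma prior and the proportions a symmetric
Dirichlet (concentration 1, configurable); the density includes the
change-of-variables Jacobian and is verified to integrate to 1.

## Likelihood

Exact likelihood is Felsenstein pruning under HKY85 with discrete-gamma
rate heterogeneity (5 equal-probability categories, category means from
incomplete-gamma conditional expectations). Site patterns are compressed
once; per-pattern scaling guards underflow. Because the model is
reversible, only unrooted branch lengths are identified: the two branches
meeting at the root are merged into one parameter (b = r₁t₁ + r₂t₂ when
mapped back to times and rates).

The approximate likelihood is the second-order Taylor expansion of the
log likelihood in untransformed branch lengths around their MLEs,
per partition. MLEs come from L-BFGS-B with batched central-difference
gradients (branches bounded in [10⁻⁹, 10] subs/site, boundary solutions
snapped to zero); the Hessian from central finite differences with step
h = max(10⁻⁴, 10⁻² b), one-sided at zero-length branches so the quadratic
form still penalizes negative excursions. On a 16-taxon, 2-kb simulated
gene, the surface deviates from the exact likelihood by well under 0.5
log units across ±5% branch-length perturbations. No branch-length
transform (e.g. arcsine) is applied before expansion.

## MCMC

Random-scan Metropolis–Hastings over internal-node ages, per-partition
branch rates (IR/AR), and hyperparameters (μ_p, σ²_p). Kernels:

* bounded sliding window on each non-root age (reflected between the
  oldest child and the parent);
* multiplier moves on the root age, branch rates and hyperparameters;
* a whole-tree **mixing move** scaling all ages by c and all rates by
  1/c with its Jacobian — branch lengths are invariant, so the likelihood
  is not re-evaluated;
* a **joint age–rate move** that slides one node age while rescaling the
  three adjacent branch rates to hold branch lengths fixed (Jacobian
  included). This is likelihood-invariant and traverses the strong
  age–rate ridge of relaxed clocks cheaply; it markedly improves mixing
  of mid-depth node ages.

Step sizes tune toward a 20–40% acceptance window during burn-in only,
keeping the post-burn-in chain Markovian. In exact-likelihood mode,
per-node conditional likelihoods and per-branch contributions are cached
so single-branch updates only recompute the path to the root (~4× faster
on 20 taxa). Hyperparameter moves never touch the likelihood (the data
depend on rates × durations only). Prior-only chains (and the β = 0 stone
of power posteriors) skip likelihood bookkeeping entirely and evaluate
the log likelihood lazily at recording times.

Default desk-scale settings are 2×10⁵ elementary updates sampled every
20 with 50% burn-in and two chains — an explicit scale-down of the
reference protocol (10⁷ iterations, sampling every 500, run twice).
ESS uses the autocorrelation sum truncated by the initial-positive-
sequence rule; parameters with ESS < 100 are flagged in every summary.

## Model selection

Power posteriors p(θ)L(θ)^β are sampled at β_k = (k/K)^{1/a} (default
K = 8, a = 0.3 — front-loaded near the prior) and combined by the
stepping-stone identity, with per-stone delta-method standard errors
(autocorrelation-adjusted sample sizes) summed in quadrature. The
approximate likelihood cannot be used for evidence, so selection runs
exact pruning and is guarded to small subsets (default ≤ 4×10⁵
taxa×sites); the root age is fixed by a narrow uniform (0.999–1.001
units) and no other calibrations are applied, mirroring the selection
protocol the package emulates. Posterior model probabilities are the
softmax of log evidences under equal priors; an SE-aware mode averages
the softmax over Gaussian resamples of each estimate. The published
log-mL table bundled with the package reproduces its printed
probabilities at three decimals for every subset except the
20-gene/20-species row, where the printed 0.998/0.002 requires the
SE-aware computation or unrounded inputs (plug-in softmax gives
0.9998/0.0002).

## Synthetic data

The generator emulates: birth–death node ages conditional on a fixed
root age attached to a ranked random topology (only the age density
matters downstream, so no forward simulation with extinct lineages);
STR/IR/AR branch rates; per-gene lognormal rate multipliers (log-sd 0.7
by default, spanning slow to fast genes); HKY85+Γ₅ site evolution with
codon-position multipliers (default 1, 0.5, 2.5 — third positions
fastest); and artifact injection (internal stops, frameshift gaps of
length ≢ 0 mod 3, per-taxon dropout) with a ground-truth log. The
nucleotide-level simulator is codon-agnostic, so gene sets destined for
QC are sanitized by recoding chance in-frame stops (third base → C);
`simulate_alignment` itself stays a pure HKY process for likelihood
tests. No indel evolution is modelled — gaps only arise from injected
artifacts.

What passing synthetic tests show: the estimator machinery is internally
consistent (correct priors, correct likelihood, calibrated posteriors
under the assumed model). What they do not show: robustness to alignment
error, model misspecification (e.g. codon-level selection,
lineage-specific composition), or fossil-calibration misplacement in
real data.

## Validation experiments and problem sizes

The validation battery (`cetdate.validation`, also driven by
`scripts/acceptance.py`) uses these desk-scale sizes, chosen so the whole
battery runs in minutes on one CPU:

* clock-model recovery: 20 taxa, 1 gene of 333 codons, 10 replicates per
  generating model, 5 stones × 3600 updates per stone;
* coverage: 20 datasets, 16 taxa, 3 partitions × 200 codons, independent
  AR rate realizations per partition (matching the fitted model's
  independence assumption), 10⁵ updates per fit;
* complete-vs-reduced: 10 replicates, 8 taxa, 60 genes × 60 codons,
  full data at 3/6/10 partitions plus the 10 most clocklike genes.

Two findings deserve note. First, dating coverage is a well-specified
check: when the generator shares a single rate realization across
partitions (which the independence-assuming model cannot represent),
coverage drops by about ten points — a real caveat for real data.
Second, the infinite-sites slope is *not* reliably non-increasing across
3 → 6 → 10 partitions at these sizes: the between-scheme slope
differences (~0.01–0.03 Ma/Ma) are smaller than replicate noise, and the
codon-position split (6p) captures the generator's dominant rate
structure better than the rate-only 10-bin scheme, so the 10p slope is
not systematically below 6p. The published trend arises in a regime —
megabases per partition — where finite-data error is negligible; the
corresponding check is reported as measured rather than forced. The
reduced-vs-full precision result (clocklike-subset CIs wider than
full-data CIs) is robust at every scale tried.

## Known limitations

* Topology is fixed; no tree moves, no tip dating.
* Nucleotide models only (HKY85+Γ); no codon or amino-acid likelihoods.
* Minimum-only (no-maximum) calibrations are not supported.
* The pipeline's resumability re-derives in-memory state
  deterministically and skips re-writing stamped artifacts; it does not
  checkpoint MCMC chains mid-run.
* Mixing of deep AR node ages is the slowest part of the sampler;
  summaries flag low-ESS parameters and two-chain agreement should be
  checked via `DivergenceTimeResults.convergence()`.
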