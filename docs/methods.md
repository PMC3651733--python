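# Methods

## Models

**GTR (M0).** The general time-reversible model is parameterized by five
free exchangeabilities (pairs AC, AG, AT, CG, CT; the sixth pair GT is
the scale reference, fixed at 1) and a point on the base-frequency
4-simplex.  The rate matrix is rescaled to one expected substitution per
site per unit time at stationarity, so branch lengths are expected
substitution counts.  Transition matrices come from the spectral
decomposition of the similarity-symmetrized rate matrix (real
eigenvalues, clamped at their exact upper bound 0 against round-off).

**Context-dependent model (M1).** ψ(x→z | w y) is the probability that
base x mutates to z within one unit of time given immediate neighbors
w (left) and y (right); the no-substitution probability is the
completion 1 − Σ_{z≠x} ψ.  Each of the 16 neighbor contexts carries its
own frequency vector f_wxy, and ψ is scaled per context so that
Σ_x Σ_{z≠x} f_wxy ψ(x→z|wy) = 1 — one expected change per base per unit
time in every context.  (The sum is read over z ≠ x: including z = x
would make the constraint vacuous, since the completion forces each row
to total 1.)  Gap rule: whenever any of w, x, y, z is a gap the factor
is 1; this also covers the two sequence ends, which are treated as
gap-neighbored, so edge sites carry no substitution factor.  Under
strand symmetry, ψ(x→z|wy) = ψ(x^c→z^c | y^c w^c); the 16 contexts fall
into 6 complement-orbit pairs plus 4 self-complementary contexts
((A,T), (T,A), (C,G), (G,C)), giving 6·12 + 4·6 = 96 free entries
instead of 192.  The context frequencies are tied the same way, a
consistency choice the symmetry assumption does not force but strongly
suggests.

**Branch transition.** ψ is a per-unit-time probability and branches
are not partitioned into discrete time slices (parameter estimates are
insensitive to such partitioning); neighbors are read from the branch's
parent sequence and held fixed across the branch.  Across a branch of
length t the off-diagonal probability is t·ψ, with the row rescaled to
1 − 10⁻¹² whenever the summed substitution probability would exceed 1
(a truncation that only engages for extreme branch lengths, where the
one-event-per-branch reading has already lost meaning).

**Root distributions.** The root sequence follows a Markov chain along
the sequence of order 0, 1 or 2.  Leading positions with incomplete
history use explicit lower-order initial distributions (each with a flat
Dirichlet prior); the chain is otherwise a table of conditional
4-simplices.  Gaps in the focal or any conditioning base contribute
factor 1.

**Priors.** Branch lengths are i.i.d. Exponential with mean μ given the
hyperparameter μ, which carries an inverse-gamma(shape 2.1, scale 1.1)
hyperprior; the density used is the proper inverse-gamma
b^a/Γ(a) · μ^−(a+1) e^(−b/μ).  Every probability simplex (base
frequencies, root-chain rows, each context's ψ block and f vector)
carries a flat Dirichlet of matching dimension, whose density is the
constant Γ(dim).  The five free GTR exchangeabilities take i.i.d.
Exponential(mean 1) priors — a proper, weakly informative choice for
nonnegative relative rates.

## The joint path

The two models live on one concatenated parameter space: GTR block,
context block (ψ, f, root chain), shared branch lengths and μ, and the
augmented ancestral sequences A (one gapped sequence per internal node;
a site is gapped at an internal node iff all descendant tips are gapped
there, and gapped sites are never resampled).  Both kernels share the
full prior over all blocks, so the prior cancels in the potential U.
Crucially, *both models are evaluated on the same augmented complete
data*: M1 through its complete-data likelihood f(Y, A | θ₁), M0 through
the GTR complete-data likelihood (stationary-frequency root term times
per-branch transition factors).  Summing the GTR complete-data
likelihood over all ancestral assignments reproduces the pruned
marginal exactly (verified in the tests by enumeration), so

    c₀ = Z₀(GTR),   c₁ = Z₁(context),

and the path integral is the log Bayes factor.  This construction also
keeps U = log f₁(Y,A|θ₁) − log f₀(Y,A|θ₀) at a modest scale (a model
fit difference, not an augmentation penalty), which is what makes
desk-scale grids usable.

## Sampler

One update cycle touches every model parameter, every branch length and
every ancestral site exactly once:

- simplex blocks (frequencies, root rows, ψ and f blocks, proposed in
  the free coordinates under symmetry): Dirichlet-perturbation proposal
  α = c·x + ε with concentration c = 200 and pseudocount ε = 0.05, with
  the exact Hastings correction;
- branch lengths, μ, free GTR rates: log-scale multiplier with window
  0.6;
- ancestral sites: uniform single-site resampling, vectorized in three
  interleaved site classes (stride 3).  A site at node v enters factors
  at positions i−1, i, i+1 of v's outgoing branches, position i of its
  parent branch, and root-chain positions i..i+order, so sites three
  apart touch disjoint factors and a whole stride class can be accepted
  or rejected elementwise in one vector operation — this is what makes
  thousand-site augmented updates cheap in pure numpy.

Cached per-branch tables and per-branch log-likelihood sums are updated
incrementally; a test asserts the cached potential equals a from-scratch
evaluation after arbitrary update cycles for all root orders and both
symmetry settings.

The traversal protocol equilibrates at the starting endpoint (default
10·Q cycles), then runs Q cycles at every grid value of β, saving the
potential just before each β update (classic sample).  In mean/ss modes
a sample is additionally collected every `save_interval` cycles
(default 10); when Q > 2·save_interval the first save_interval cycles at
each new β are discarded as per-step burn-in.  Melting runs traverse the
reversed grid; identical seeds give bit-identical traces.

## Estimators and error theory

- **PS (classic / mean):** trapezoid rule Σ (β_{k+1}−β_k)·½(U_k+U_{k+1})
  over the saved potentials, or over per-β sample means.  Exact for
  potentials linear in β on any grid.
- **SS:** per-step importance ratios estimated from the samples at the
  step's lower endpoint (upper endpoint with inverted exponent for
  melting runs), always factoring out the largest sampled term.  The
  natural-scale product is unbiased; the log transform's bias shrinks
  as K grows.
- **Discretization error:** σ_d = |Σ ½(β_{k+1}−β_k)(E_{k+1}[U] − E_k[U])|,
  the area between the piecewise-linear interpolant of E_β[U] and the
  step functions built from it (E_β[U] estimated by the per-β sample
  mean; by the single saved U in classic mode).
- **PS sampling variance:** ¼[Σ d_k²(V_k+V_{k+1}) + 2Σ d_k d_{k−1} V_k],
  scaled by the decorrelation time τ = K/K_eff for correlated samples.
  The ¼ multiplies both sums — re-deriving the variance of the
  trapezoid weights (¼, ½, …, ½, ¼ on a constant grid) fixes the
  bracket placement, and the worked value for K = 2, unit variances,
  V[(U₀+2U₁+U₂)/4] = 6/16 = 0.375, is pinned in the tests.  For
  mean-sample traces each V_k enters as (sample variance)·τ_k/n_k.
- **SS variance:** delta method, Σ_k Var̂(r̂_k)/r̂_k² with
  Var̂(r̂_k) = (1/n²) Σᵢ (wᵢ − w̄)², computed stably from log moments;
  an optional τ factor accounts for autocorrelated per-step samples
  (the printed formula assumes independent draws).
- **Variance comparison:** the direct-path and ratio-structure
  variances differ exactly by the covariance term
  2·Cov(powered kernel 1, powered kernel 0)/(means), estimable from a
  single run because the direct trace stores per-sample component log
  kernels.  The unobservable normalizing-constant ratios in the
  analytic expressions are replaced by their per-step sample means —
  the same large-n approximation the delta-method derivation already
  makes.
- **Bidirectional summary:** the final estimate is the mean of the
  annealing and melting estimates; BDE = Σ_splits |contribution
  difference| is a repeatability error; the thermic-lag flag records
  whether annealing < melting, the direction implied by
  d²log c_β/dβ² = Var_β(U) ≥ 0 (E_β[U] is nondecreasing, so a lagging
  chain underestimates on the way up and overestimates on the way
  down).
- **HME / sHME:** log N − logsumexp(−ℓ), and the stabilized δ-mixture
  fixed point (δ = 0.01, tolerance 10⁻¹⁰, max 1000 iterations) iterated
  in log space; it reduces to the HME as δ → 0.
- **Effective sample size:** Geyer's initial monotone positive sequence
  on FFT autocorrelations; constant series report τ = 1 with a warning.
  Cross-checked against arviz.ess in the tests.

Schedules: the sigmoid grid is β_k = (g(k/K) − g(0))/(g(1) − g(0)) with
g(u) = 1/(1 + e^{−α(2u−1)}) — the shape maps step index to β (exposing
the grid for inspection), is exactly symmetric by construction, and
concentrates steps near both endpoints for large α, where one model is
raised to a vanishing power and the integrand changes fastest.  Split
boundaries default to equal step-index groups (equal work per node) and
must lie on the grid; split contributions are exactly additive for all
three estimators.  Flexible-increment grids take user-supplied
boundaries and per-interval step counts.

## Synthetic data

The simulators invert the likelihood definitions: GTR draws the root
from the stationary frequencies and evolves each branch with exp(Qt);
the context simulator draws the root from the root chain and evolves
each site with the per-branch table conditioned on the *parent's*
neighbors — the same within-branch approximation the likelihood makes,
so simulation and inference are exactly matched.  Sites whose factor
involves a gap (including sequence ends) copy the parent.  A column gap
mask is propagated unchanged.  What the synthetic data do **not**
emulate: real context effects such as CpG hypermutability (no
context-dependent generating process is used in the acceptance
experiments — that is deliberate, the experiment tests the penalty
direction), indel processes, among-site rate variation, or
lineage-specific effects.  Passing experiments therefore demonstrate
estimator correctness and calibration, not biological realism.

## Study conditions of the bundled experiments

- *Toy oracle:* beta-binomial pair Beta(1,1) vs Beta(2,2), data 14/20;
  sigmoid α = 10, K = 50, Q = 200, samples every 2 cycles (≈ 99 per
  step); bidirectional SS and mean-PS compared to the analytic value at
  3 τ-corrected Monte Carlo SEs.
- *Unbiasedness:* 500 independent K = 1 runs (Q = 100, every 10th
  cycle); mean of exp(log r̂) vs the analytic Bayes factor at 3
  replicate SEs.
- *HME bias:* conjugate-normal spec (prior N(0,1), σ = 1, 10
  observations), 20 replicates of 50,000 exact posterior draws.
- *Variance ordering:* two conjugate-normal models sharing the N(0,1)
  prior with σ = 1.0 vs 1.5 (the shared-prior regime of the variance
  identity), 100 replicates, K = 10, Q = 20.
- *Thermic lag:* Beta(1,1) vs Beta(150,50) (strong prior separation —
  the lag scales with ∫Var_β(U)dβ), K = 5, Q = 5, sticky random walk
  (step 0.3), mean-PS over 20 annealing/melting pairs.  These choices
  make the systematic lag dominate Monte Carlo noise at the mandated
  tiny Q.
- *Phylogenetic sign experiment:* 10 alignments of 2000 columns
  simulated under GTR (transition-biased rates, frequencies
  0.3/0.2/0.2/0.3) on the five-taxon tree
  ((((cow,sheep),muntjak),pig),horse) with all branches 0.1; annealing
  SS with sigmoid α = 10, K = 30, Q = 10.  These problem sizes are the
  package's desk-scale defaults; the estimate's magnitude at such
  coarse grids is biased, but its sign — the context model penalized on
  context-free data — is robust, and that sign is what the experiment
  asserts.

## Design decisions and limitations

- Split intervals run as independent chains with their own
  equilibration (matching distribution across compute nodes); resuming
  from checkpoints is exactly reproducible because each interval's
  random stream derives from (seed, direction, interval).
- N in input FASTA is treated as a gap; gaps are never resampled and
  always contribute factor 1.
- The per-context normalization is applied independently per context,
  as defined; no joint rescaling across contexts sharing sites is
  attempted.
- Melting starts from a prior-drawn state equilibrated at β = 1; for
  large phylogenetic problems this equilibration is the dominant
  transient and should be lengthened via the `equilibration` argument.
- Tree topology is always fixed; no topology inference, no
  branch-partitioned context models, no generalized stepping stones
  with working priors.
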