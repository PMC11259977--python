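# Methods

This note documents the model implemented by `wgdchronos`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's numerical
conventions. All ages are stored internally in units of 100 Myr (user
I/O is in Ma); rates are substitutions/site per 100 Myr.

## The dating model

**Topology.** Dating happens on a fixed, rooted, binary "duplicated"
topology: the species tree with the subtree of the duplicated clade
appearing twice as sister copies under the WGD node. Mirrored speciation
nodes (e.g. the crown of the duplicated clade in each copy) are distinct
parameters dated independently; agreement between the two copies is an
internal consistency check, and reports also carry their average for
comparison against single printed values.

**Age prior.** The root must carry a calibration, because the
birth–death kernel conditions on the root age. Each calibrated node has
a hard-minimum / soft-maximum density: mass p_body = 0.975 uniform on
[t_L, t_U], zero below t_L, and an exponential tail above t_U with rate
θ = p_body / (p_tail (t_U − t_L)), which makes the density continuous at
t_U and gives the tail exactly p_tail = 0.025. (Some dating software
uses a heavier power tail; the exponential tail is this package's
dialect — continuity plus exact mass in closed form.) The hard minimum
is exact (no left tail). Uncalibrated internal nodes follow the
birth–death-with-species-sampling kernel conditional on the root age
(Yang–Rannala construction), with the critical closed form used when
|birth − death| < 1e−8; defaults birth = 1, death = 1, sampling = 0.1.
Calibrations on mirrored nodes are applied to each copy independently.
The joint age prior is the product of these densities restricted to the
parent-older-than-child region.

**Clocks.** Per locus, either ILN — branch rates iid log-normal with
E[r_b] = μ (mean-corrected: log r_b ~ N(log μ − σ²/2, σ²)) — or GBM —
node rates evolving by geometric Brownian motion, the child's log rate
normal around the parent's with variance σ²Δt and the −σ²Δt/2 mean
correction, where Δt is the midpoint-to-midpoint separation of the two
branches (the root "midpoint" is the root's age). A branch's expected
length is r_b·Δt (ILN) or the arithmetic mean of the endpoint node rates
times Δt (GBM); the geometric-mean alternative would differ only at
second order in σ²Δt. μ (per locus) has a Gamma(α_r = 2, β_r = 40) prior
(mean 0.05 substitutions/site/100 Myr, a typical vertebrate protein
rate); σ² (per locus, shared across that locus's branches) has
Gamma(α_σ = 1, β_σ = 10) (mean 0.1). Under GBM the locus-rate prior
prices the root node rate directly and there is no separate μ parameter.

**Likelihood.** The sequence likelihood enters only through its
second-order expansion per locus: ℓ(b) − ℓ(b̂) ≈ gᵀd + ½dᵀHd, d = b − b̂,
with b̂ the MLE branch lengths of the duplicated topology under the
locus's substitution model, g the gradient (≈0 at an interior MLE) and H
the Hessian. Branch order is the tree's canonical post-order (children
visited by smallest descendant leaf label); a branch is named
`<smallest-descendant-leaf>+<clade size>`, which is unique and stable,
and BV files record this ordering so mismatches against the dating tree
are detected by name. Genes missing from a locus are represented as
all-missing rows on the full topology, which simply leaves the affected
tip branches likelihood-uninformed.

**Sampler.** Metropolis–Hastings sweeps over: per-node sliding-window
age moves (rejected outside the parent/child window), per-branch (ILN)
or per-node (GBM) multiplicative log-rate moves vectorized across loci
(loci are conditionally independent given ages), multiplicative moves on
μ and σ², and one whole-tree mixing move per sweep (ages ×c, rates and μ
÷c) with acceptance Jacobian c^(n_ages − n_rates), which travels along
the time–rate ridge the calibrations are needed to resolve. Step sizes
tune toward 20–40% acceptance during burn-in only, then freeze, so
detailed balance holds in the sampling phase. A single seed drives one
`numpy` Generator in a fixed draw order: output is bit-reproducible.
Defaults: burn-in 25% of sweeps, thinning chosen to retain at most
10,000 draws.

**Summaries.** Per-node posterior mean, 95% HPD by the
shortest-order-statistic interval, ESS via the autocorrelation-based
estimator (arviz). Convergence between two runs uses classic split-R̂
(two chains halved into four), with the degenerate conventions R̂ = 1
for bitwise-identical runs or zero within-chain variance, plus a flag
when the two runs' means differ by more than half a pooled (ESS-based)
standard error, and a mean-vs-mean regression across node ages.

## The synthetic-data generator

`StudyDesign` defaults emulate a real concatenated-ohnologue WGD study:
12 ray-finned-fish taxa (6 teleosts with two ohnologue copies each, 6
non-duplicated actinopterygian outgroups → 18 expected sequences per
locus), 30 loci with lengths 100 + Gamma(4, 122) columns (mean ≈ 590),
exactly 3 genes deleted from 3 distinct loci (so the default fixture has
537 sequences and 27 complete loci), a Permian WGD (t = 2.77) on a
~380-Ma-root Devonian-to-Neogene scale, ILN rate heterogeneity with
per-locus (μ, σ²) drawn from the gamma hyperpriors, and four soft-bound
calibrations (root, one backbone node, both mirrored crowns).

**Chronograms are drawn from exactly the prior the sampler uses**:
calibrated nodes from their calibration densities, free nodes iid from
the birth–death kernel restricted to the order constraints. The
restriction is sampled exactly — free nodes are partitioned into
connected components, each drawn from the kernel truncated to its
enclosing fixed-node ages and rejected until the component's internal
order holds. This matters: assigning kernel draws to nodes by rank would
systematically misplace shallow-but-old clades and break posterior
coverage, since truth would no longer come from the inference prior.
The WGD age itself is a design constant, not a prior draw — it is the
estimand, and coverage experiments treat it like any other node.

**Loci** come in two modes. `alignment` evolves sequences site-wise down
the tree under the chosen substitution model (this is what the on-disk
fixtures contain, and what the end-to-end tests push through the real
estimation path). `brlen_approx` short-cuts the sequence layer: it
computes the true b from the drawn rates, measures the curvature H of
the exact pruning log-likelihood at b as the empirical Fisher
information (negative outer product of per-site score vectors) on an
alignment of `n_sites` simulated at b, adds a small ridge
(1e−3 × mean diagonal) so fully-missing rows cannot make H singular,
and returns b̂ = b + ε with ε ~ N(0, −H⁻¹), g = 0. The noise is **not**
truncated at zero: a slightly negative b̂ on a near-zero branch is what
an unconstrained MLE would give, and censoring it measurably biases the
noise model (it cost ~5 Ma of systematic young bias at the WGD node in
development experiments). Because the inference model sees exactly the
(b̂, H) pair the generator used, generator and sampler are consistent by
construction; what passing recovery tests shows is therefore the
correctness of prior + sampler + bookkeeping, not robustness to
model misspecification — alignment-mode studies, where H is estimated
from data rather than shared, cover the latter more honestly but at
smaller scale.

**Rediploidization.** The tetrasomic-phase simulator draws, per site,
gene-conversion events at rate c during (t_r, t_wgd]; the site's
effective divergence age is the age of the most recent conversion (t_r
plus a truncated-exponential residual) or t_wgd if none occurred, after
which the two copies diverge independently under the Poisson model.
Conversion is symmetric and neutral; there is no biased conversion, no
selection, no rate shift between tetrasomic and disomic phases. The
simulator exposes t_wgd, t_r and c as free parameters rather than
asserting values for any real WGD.

## Estimation details

* MLE branch lengths: multi-start L-BFGS-B (starts 0.1 and 0.5
  substitutions/site on every branch) with analytic gradients from a
  post-order + pre-order pruning pass; box bound b ≥ 1e−6 keeps the
  optimum interior so the quadratic expansion is valid. Non-convergence
  (‖g‖∞ > 1e−3 per site at an interior point) raises an error carrying
  the best point found.
* Hessians: `fd` — central finite differences of the analytic gradient
  with per-coordinate step max(1e−4, 1e−2·b̂_i); `outer` — empirical
  Fisher (negative score outer product), which is the fast choice at
  study scale and agrees with `fd` to within sampling error. On a rooted
  tree with a reversible model the split of the root edge between its
  two child branches is unidentifiable, so H has a null direction there;
  the quadratic likelihood handles it, and consumers that need a
  covariance should use the pseudo-inverse.
* Transition matrices by symmetric eigendecomposition of the
  π-similarity transform of Q (Q scaled to one expected substitution per
  site at stationarity); discrete gamma uses 4 categories by default
  with median-of-category rates renormalized to mean 1. Partial
  likelihoods are per-site rescaled at every internal node, and scores
  are formed from identically-scaled inside/outside passes so the
  scalers cancel exactly.
* Empirical exchangeabilities (WAG/LG/JTT) ship as plain-text
  lower-triangle files in the standard PAML layout.

## Problem sizes in the test suite

The suite runs the study-scale checks at sizes chosen to keep the whole
run comfortably interactive while leaving the statistics meaningful:
coverage uses 20 studies × 30 approximation-mode loci × 500 sites with
2,500-sweep chains (the 0.90 coverage threshold tolerates the per-study
correlation that the time–rate ridge induces: all 17 nodes of a study
move together, so the effective replication is the number of studies);
the infinite-sites monotonicity check uses one study at subset sizes
0/1/6/12/30; the end-to-end alignment-based study uses 8 loci of mean
~300 columns. The effective-prior check runs a no-data chain of 10^5
sweeps against the analytic calibration CDF (KS < 0.02).

## Known limitations

* The quadratic likelihood is trusted wherever the sampler wanders; no
  guard re-evaluates the exact likelihood for proposals far from b̂
  (the standard trade-off of the normal-approximation method).
* Calibrated nodes combine their calibration density with the order
  constraints by simple truncation-in-product; the joint prior on a
  calibrated node therefore deviates from its marginal calibration
  wherever neighbouring constraints bind (the usual "effective prior vs
  user prior" phenomenon — inspect it with a no-data run).
* σ² is per locus and shared across branches within a locus;
  per-branch σ² and mixture clocks are out of scope, as are codon and
  nucleotide models, model selection, alignment and homology inference.
* The paired clock-model comparison uses all internal nodes by default;
  restricting to a subset is the caller's choice.
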