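# Methods

## The estimation problem

A closed population of unknown size N is observed through repeated
captures over a fixed window. For each of the n observed individuals we
know only the number of times it was captured; the N − n never-captured
individuals are invisible. The data reduce to the frequency-of-
frequencies table {n_k : k ≥ 1}, where n_k is the number of individuals
captured exactly k times. Inference about N amounts to inference about
the missing zero class n_0.

Many real capture processes — arrest records, treatment registries,
administrative complaint data — show an **excess of singletons**: far
more individuals observed exactly once than any simple count
distribution predicts, typically because the first capture changes
behavior (avoidance, incarceration, treatment entry). Ignoring this
*one-inflation* inflates n̂_0 severely, because the singleton excess is
read as evidence of a large, lightly sampled population.

## Model

Let Y* be the latent capture count an individual would have without the
behavioral effect, with base pmf f(·|θ):

* Poisson(λ),
* geometric with P(Y* = k) = (1 − p)^k p on k ≥ 0, or
* negative binomial P(Y* = k) = Γ(k+r)/(Γ(r) k!) · p^r (1 − p)^k
  (r = 1 recovers the geometric).

With probability ω, an individual whose Y* > 1 is observed as a
singleton instead; zeros and genuine singletons are unchanged. The
observed count Y then has pmf

    P(Y=0) = f(0|θ)
    P(Y=1) = (1 − ω) f(1|θ) + ω (1 − f(0|θ))
    P(Y=j) = (1 − ω) f(j|θ),  j > 1.

ω is restricted to [0, 1): at ω = 1 no count above one is observable
and the base parameters lose identifiability, so that corner is
rejected at validation.

Priors: λ ~ Gamma(α_λ, β_λ), p ~ Beta(α_p, β_p), ω ~ Beta(α_ω, β_ω),
and for the NB size either r ~ Gamma(α_r, β_r) or r ~ InvGamma(α_r,
β_r) — the inverse-gamma tail turns out to matter for the boundary
problem (below). The package defaults are the weakly informative
choices used for the shipped case studies: Gamma(0.1, 0.1) for λ,
Beta(1, 1) for p and ω, InvGamma(0.1, 0.1) for r. For N the default is
the scale-invariant improper p(N) ∝ 1/N; the other power priors N^l,
l ∈ {−2, −1/2, 0}, and Rissanen's universal prior
p(N) ∝ 2^(−log*(N)) are available (`PriorConfig.n_prior`).

## Posterior computation

The sampler augments the data with (i) the unknown n_0, (ii) indicators
of which singletons are inflated (their total nz), and (iii) the latent
counts of those inflated units. All state is kept at the *frequency*
level: the per-unit augmentation steps aggregate exactly into

1. nz ~ Binomial(n_1, ω(1−F(1))/(f(1) + ω(1−F(1)))), plus one
   multinomial over the base pmf truncated below 2 for the latent
   counts — giving completed frequencies n*_k;
2. ω ~ Beta(α_ω + nz, β_ω + Σ_{k>1} n_k) — the second argument uses
   the observed multi-capture count, since those units are certainly
   uninflated;
3. n_0 ~ NegBinomial(n, 1 − f(0|θ)) exactly under p(N) ∝ 1/N; under
   any other N prior, a symmetric integer random-walk Metropolis step
   (fixed half-width, reflected at N = n) on
   p(N|−) ∝ C(N, n) f(0)^{N−n} p(N);
4. the θ block: λ ~ Gamma(α_λ + s*, β_λ + N) or
   p ~ Beta(α_p + N[r], β_p + s*), with s* = Σ k·n*_k; the NB size r by
   either (a) random-walk Metropolis — by default on log r with the
   Jacobian included and the step adapted during burn-in toward ~35%
   acceptance, with a plain-scale variant retained — or (b) the exact
   two-stage CRT (Chinese-restaurant-table) augmentation, which is a
   pure Gibbs step but requires the Gamma prior on r. The CRT Bernoulli
   trials are pooled per depth j into Binomials over the m_j units with
   y* ≥ j, so the step is O(kmax) like everything else. A
   moment-matched Gaussian approximation to Σ l_i is available and is
   switched on automatically when the total capture count exceeds
   10,000.

One sweep runs latents → ω → N → θ (any fixed scan order is valid;
fixing one makes runs reproducible) and costs O(kmax) independent of n,
so the default 10^6 sweeps with thinning 20 (the chain sizes used for
the shipped case studies) take minutes on one core. Initialization is
deterministic: θ mean-matched to the truncated sample mean, r = 1,
ω = 0.1, N = ⌈n / (1 − f(0|θ_0))⌉.

Numerical guards worth knowing about: all pmfs are computed in log
space; the truncated-tail support for step 1 is found adaptively
(smallest K whose residual tail, bounded by a geometric series computed
from the terms themselves, is below 10^−12 of the tail mass) so no
rejection loops occur; when θ wanders into a corner where the tail mass
beyond one is numerically zero, inflation is treated as impossible for
that sweep (the exact limit of the conditional); and the n_0 draw is
capped at 2^53 so that data with a divergent N posterior (e.g. all
singletons, which make the 1/N posterior improper) cannot overflow
int64 — such data are a misuse of the model, and the cap only affects
astronomically divergent chains.

N is summarized by the mode of its integer draw frequencies (the
argmax of the draw histogram — the convention used for the reported
case-study values), along with mean, median, HPD (default, via arviz)
and equal-tailed intervals; θ and ω by posterior means.

## Marginal likelihoods and model choice

Under p(N) = c/N the sum over N collapses analytically and

    p(y|M) = (c/n) ∫ Π_i [f(y_i|θ)/(1 − f(0|θ))] p(θ) dθ,

i.e. model comparison depends only on the fit of the zero-truncated
distribution, and c cancels from posterior model probabilities as long
as every compared model uses the same 1/N prior (comparisons under
other N priors are refused with an explanatory error). The remaining
integral is estimated by Chib's identity at θ* = the posterior mean:

    log p̂(y|M) = −log n + log L_trunc(θ*) + log p(θ*) − log p̂(θ*|y),

with the posterior ordinate factored block by block: block 1 is the
base parameter (λ; p; or p then r for the NB), block 2 is ω. The
first-block ordinate is Rao-Blackwellized over the main run's latent
draws; each later block comes from a reduced run with the earlier
blocks pinned at their starred values. The Metropolis-updated r block
uses the Chib–Jeliazkov two-run ordinate (numerator from the reduced
posterior run, denominator from a run with r fixed at r*); with a
Gamma prior and the CRT updater the r ordinate is Rao-Blackwellized
instead. The block order and reduced-run structure are this package's
design choice, certified against tensor-grid Gauss–Legendre quadrature
of the truncated-likelihood integral on small instances (agreement
within 0.005 in log on all six families in the shipped tests, against
a 0.05 test tolerance).

Posterior model probabilities are the softmax of log-marginal-
likelihoods plus log prior probabilities; the model-averaged population
size is N̄ = Σ_i N̂_i P(M_i|y) with N̂_i the per-model posterior mean.

## Classical benchmarks

Chao's lower bound n + n1²/(2 n2) and Zelterman's truncated-Poisson
estimator (λ̂ = 2 n2/n1, N̂ = n/(1 − e^{−λ̂})) are included as the
singleton-based references that one-inflation corrupts. The modified
(singleton-free) Chao estimators are reconstructed from the moment
identity E[n_2]/E[n_3] of the assumed base family: Poisson base
λ̂ = 3 n3/n2, n̂0 = 2 n2/λ̂² = 2 n2³/(9 n3²); geometric base
1 − p̂ = n3/n2, n̂0 = n2/(1 − p̂)² = n2³/n3². Both reproduce the
published Vancouver values (1005 and 1421) exactly after rounding.
Interval estimates for these closed-form estimators are not part of
the reconstruction; the package attaches only a log-normal
approximation to Chao's estimator, explicitly labeled as such.

## Synthetic data and the replication harness

`simulate_counts` draws exactly true_N latent counts from the base
family, thins each count > 1 to 1 with probability ω, discards the
zeros (recording their number as the realized n_0), and tabulates the
rest. This reproduces the generative scheme of the simulation study the
models were evaluated under; what it deliberately does **not** emulate
is anything the model itself omits — unit-level heterogeneity in
capture rates, open populations, record-linkage error — so passing
recovery tests demonstrates correctness of the inference machinery
under the stated model, not robustness to real-data violations of it.

`run_replications` fits a list of models to each replicate and
aggregates: percent relative bias of n̂_0 (posterior mean against the
realized n_0 of that replicate; the expected n_0 = N f(0) is recorded
alongside), percent MSE defined as 100 · mean(((n̂0 − n0)/n0)²) (the
convention that matches the magnitudes of the published tables),
empirical HPD coverage, and the NB boundary flags. Per-replicate RNG
substreams are spawned from (seed, replicate index) so individual
replicates are reproducible in isolation; replicate-level sampler
failures are recorded and excluded rather than fatal.

### Boundary problem

NB-based population estimates diverge as r → 0 (the Horvitz–Thompson
factor 1/(1 − p^r) blows up). Following the source convention the
package flags r̂ < 0.25, and in simulations N̂ > 5·true_N, both strict
inequalities; fits warn but never abort. The shipped boundary study
(OINB data with N = 5000, p = 0.35, r = 0.5, ω = 0.5, fitted with
r ~ InvGamma(0.1, 0.1)) reproduces the headline finding that the
inverse-gamma prior suppresses boundary cases entirely, at 20
replications with 10^5-sweep chains — roughly 20× smaller than the
original 100 × 2·10^6 design, a problem size chosen so the whole
study runs in a couple of minutes. Note that at these settings the
per-replicate posterior of N is genuinely heavy-tailed (r = 0.5 is
inside the regime where the OINB itself begins to destabilize), so
posterior-mean estimates fluctuate across replicates even though none
approaches the 5N threshold.

## Known limitations

* The posterior mean of n_0 is right-skewed in weakly informative
  designs (low rates, strong inflation): in the scaled-down replication
  of the hardest scenario (OIP, λ = 1, ω = 0.5) it overshoots the truth
  by on the order of +10–20% even though the posterior itself is exact
  (verified against direct quadrature of E[n_0|y]). This is a property
  of the estimator under those conditions, not a sampler defect.
* All-singleton data (no counts above 1) leave N with an improper
  posterior under p(N) ∝ 1/N; chains on such data drift and should not
  be summarized.
* Chao-type interval estimates from the primary literature are not
  reproduced (their variance formulas are outside this package's
  scope); the attached log-normal intervals are labeled approximations.
* Model comparison is fixed-dimension (one marginal likelihood per
  model); no trans-model or reversible-jump sampler is provided.
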