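# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `mitopop`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Time and rate scaling

All single-population demographic quantities are expressed in
*mutational units*: one unit equals 1/(2u) generations, with u the
per-locus per-generation mutation rate. Under this convention a pair of
lineages accumulates differences as a Poisson process of rate 1, so

* the expansion age τ = 2ut is read directly off the mismatch spectrum
  (its mode sits near τ),
* at equilibrium E[pairwise differences] = θ = 2N_e u and
  E[S] = θ·a1 with a1 = Σ_{i<n} 1/i,
* E[pairwise TMRCA] = θ in these units.

The isolation-with-migration (IM) model instead follows the MDIV
convention: time in units of N_e generations (within-population pairwise
coalescence rate 1), per-locus θ = 2N_e u, per-lineage migration rate
M/2, populations merging into an equal-sized ancestral population at
time T. The two scales are related by a factor θ (one N_e-generation
unit = θ mutational units); the simulator converts internally.

Calendar conversions treat a "1.1% per Myr" mtDNA divergence rate as a
per-lineage per-site rate of 1.1e-8/site/year (the usual arthropod
convention); a `pairwise_rate` flag halves it for users who read such
rates as pairwise. Defaults: L = 596 bp, generation time 1.5 years.
With these, τ converts as t = τ/(2u) generations, u = L × rate × g.

## Site handling and haplotype collapsing

Columns containing `-` or `N` are removed before all statistics
(complete deletion, the DnaSP convention); a `strict` policy treating
the full strings as-is is available. Two sequences share a haplotype iff
they are identical at all retained sites; labels are assigned
H01, H02, … in first-appearance order. Haplogroup membership is consumed
from the population map per individual — clade inference is out of scope
— and the same haplotype label may therefore legitimately occur in more
than one haplogroup.

The bundled *D. armandi* COI frequency table carries a declared
per-locality sample size. Two source rows (Wd and Ld) declare one fewer
individual than their haplotype tokens sum to; the declared column is
the one consistent with the survey's overall totals (255 individuals;
17/149/29/60 per haplogroup), so the parser's lenient mode treats the
declared n as authoritative for totals and records both rows in
`HaplotypeTable.inconsistencies`. The strict mode (library default for
user tables) raises instead. Relatedly, recomputing MSM haplotype
diversity from the table's own counts gives Hd = 0.912, while the
source survey printed 0.943 for that group; count-derived quantities
are therefore what the acceptance checks anchor on, not Hd.

## Neutrality tests

* **Tajima's D** uses the 1989 constants computed from n, with S and the
  mean pairwise difference k.
* **Fu & Li's D/D\*** use the total mutation count η (minimum changes
  summed per column) with the corrected constants (including the d_n
  term of the errata). D requires an outgroup to polarise external
  mutations (derived singletons); without one, D* uses unpolarised
  singletons — the default, matching the common DnaSP path. Both
  variants ship because surveys rarely state which was used.
* **Fu's Fs** computes S′ = P(K ≥ N_hap | θ = k) from the Ewens sampling
  formula. Unsigned Stirling numbers of the first kind are built by the
  exact integer recurrence and both tails of the distribution are summed
  in log space, so Fs = log Σ_{k≥K} − log Σ_{k<K} is stable up to
  n ≥ 255 with no special-precision arithmetic and no catastrophic
  1 − S′ cancellation. A single haplotype gives S′ = 1 (Fs undefined,
  flagged, never silently 0).
* **R2** is √[(1/n) Σ_i (U_i − k/2)²]/S with U_i the singletons carried
  by sequence i.

Significance comes from coalescent simulation under neutrality and
constant size, by default *conditional on the observed S* (mutations
placed multinomially on branches, infinite sites); conditioning on the
Watterson θ̂ (Poisson mutations) is available. All p-values are
one-tailed on the expansion-sensitive (lower) tail, with stars at
0.05/0.01/0.001. Ties between simulated and observed values count as
extreme, which makes the tests very slightly conservative at small
simulation counts. Default 10,000 simulations; tests and the acceptance
script run scaled-down counts (documented per run in the report header)
with correspondingly coarser Monte-Carlo resolution.

## Mismatch analysis

The expected spectrum under stepwise growth is Li's transient solution

F_i(τ) = F̂_i(θ1) + e^{−τ(θ1+1)/θ1} Σ_{j≤i} τ^{i−j}/(i−j)! (F̂_j(θ0) − F̂_j(θ1)),

with F̂_i(θ) = θ^i/(θ+1)^{i+1}, evaluated on 0..(observed max + 10) and
renormalised (tail mass at fitted parameters is negligible; the pad
keeps the fit from being truncation-limited). (τ, θ0, θ1) minimise the
SSD between observed and expected relative spectra by bounded
Nelder–Mead from eight starts (τ ∈ {1, spectrum mode},
θ0 ∈ {0, k/2}, θ1 ∈ {k, 5k}), parameterised as (τ, θ0, θ1−θ0) to
enforce θ1 ≥ θ0, ties broken toward the smallest τ. Bootstrap refits
use two starts and a looser tolerance; 10,000 replicates by default
(scaled down in tests). p_SSD and p_rg are the fraction of
parametric-bootstrap replicates (data re-simulated under the fitted
model by coalescent simulation, spectra re-fit) with statistic ≥
observed; CIs are percentile. Raggedness follows the Arlequin
convention rg = Σ_{i=1}^{d+1} (x_i − x_{i−1})², x_{d+1} = 0.

A spectrum entirely at zero differences returns the boundary fit
(τ = θ0 = θ1 = 0) flagged as degenerate rather than an error.

## Isolation-with-migration sampler

The posterior is over (G, θ, M, T) where G is a genealogy with explicit
backward-in-time migration events on its branches. Priors are uniform:
M on [0, M_max] (default 10), T on [0, T_max] (default 5), θ on
[0, θ_max] (default 5× the pooled Watterson estimate). The likelihood is
Felsenstein pruning under HKY with empirical base frequencies and κ
fixed by method-of-moments from pooled pairwise transition/transversion
counts (κ̂ = (ts/tv)·π_Rπ_Y/(π_Aπ_G + π_Cπ_T), clipped to [0.5, 100]);
branch lengths enter as Δt·(θ/2)/L substitutions per site. Site
patterns are compressed once; partials are rescaled every ten nodes to
prevent underflow on large trees.

Moves, chosen at random each iteration:

* **Lineage re-simulation** (55%): detach a uniformly chosen lineage and
  redraw its migration path and coalescence point from the conditional
  structured coalescent given the rest of the genealogy (migration M/2,
  coalescence rate 1 per contemporaneous same-label lineage below T,
  1 per lineage above). Above the rest-root both remaining free
  lineages are co-simulated, including the rest-root lineage's own
  migration back-fill when the detached lineage starts above it. The
  proposal density is exactly the prior's conditional, so acceptance is
  the likelihood ratio alone. This single move updates topology, node
  times and migration paths and is irreducible.
* **Node-time slide** (20%): uniform within the window allowed by
  neighbouring nodes, migration events and label consistency;
  Metropolis on prior × likelihood.
* **θ multiplicative walk** (5%): log-normal proposal with its Hastings
  correction; likelihood ratio only.
* **Rescale** (5%): θ ← sθ with all node times, migration-event times and
  T divided by s. Branch lengths in substitutions are invariant, so the
  move slides along the (θ, tree-scale) likelihood ridge and accepts on
  the prior ratio times the Jacobian s^(1−m), m = number of scaled time
  variables; this is what decorrelates θ from the genealogy.
* **M Gibbs** (8%): the full conditional of M is
  Gamma(n_mig + 1, exposure/2) truncated to [0, M_max], with exposure
  the total lineage-time below T; sampled exactly by inverse CDF.
* **T Gibbs** (7%): log p(T) given the labelled genealogy is piecewise
  linear with slope k0·k1 − (M/2)(k0+k1) between events (flat above the
  root), supported between the latest migration event and the earliest
  label-inconsistent coalescence; sampled exactly as a piecewise
  exponential.

The two Gibbs moves remove most of the autocorrelation that plain
random-walk updates leave in M and T; remaining mixing time is set by
genealogy turnover. Correctness checks: prior-only runs (likelihood
switched off, unconstrained model) recover uniform M and T marginals;
genealogy-move-only chains at fixed (M, T) reproduce the migration-count
and TMRCA distributions of direct structured-coalescent simulation; and
for the one-sequence-per-population case the full sampler's posterior
moments match an exactly integrated three-dimensional reference
posterior (see the exact-posterior audit test).

By default the prior support is additionally restricted to genealogies
whose root is at least T ("ancestral coalescence precedes population
divergence"), which guarantees TMRCA ≥ T in every posterior sample; with
M = 0 this is vacuous (cross-population coalescence below T is
impossible anyway). The flag `constrain_root_above_split=False` gives
the standard unrestricted IM model, which is also what the prior
uniformity checks use, since only there does ∫P(G|M,T) dG = 1 make the
uniform-marginal property exact.

Posterior summaries follow the gridded-histogram convention: modes from
100-bin histograms over each prior range (ties toward the smaller
value), boundary modes flagged. Replicate chains (default 3, per common
practice with this sampler family; scaled down in tests) are pooled for
the histograms, with per-chain modes kept as a convergence diagnostic.

Conversions echo every factor: Ne♀ = θ/(2Lμ_gen) and
T_pop = [(T·θ)/2L]·(1/μ) generations (× generation time for years),
applied identically to TMRCA. Note the bundled study's printed
per-pair divergence table cannot be reproduced from its own θ, T and
this formula under any standard reading of the rate (hand evaluation
differs by roughly five-fold); the package implements the formula as
stated and reports all factors so users can audit any conversion.

## Synthetic data

The generator draws Hudson-style coalescent genealogies (constant size;
stepwise expansion with instantaneous θ1 → θ0 change at τ, a star-like
burst when θ0 = 0; two-population IM) and evolves sequences site-by-site
with the HKY transition matrices obtained from one eigendecomposition —
finite sites, multiple hits included, so the estimators are exercised
honestly. An infinite-sites mode (each mutation its own column) exists
for exact oracles. Defaults mirror the target data type: L = 596,
κ = 10 and AT-rich base frequencies (0.31, 0.13, 0.15, 0.41) as a
generic insect-mtDNA composition. What the simulator does **not**
emulate: rate heterogeneity across sites, selection, recombination
(irrelevant for mtDNA), sequencing error, nuclear pseudogenes, and
geographic substructure within haplogroups — so green tests demonstrate
estimator correctness under the assumed models, not robustness to those
violations.

## Problem sizes used in tests and acceptance runs

Simulation-based checks use deliberately scaled problem sizes chosen as
the package's own test policy: 2000 replicates for estimator
calibration (θ = 5, n = 30, L = 596); 800–1000 outer replicates with
200-simulation p-values for rejection-rate calibration; 100 replicates
at n = 149 for expansion recovery; 20 seeded IM runs at n = 10+10 with
24,000-step chains; 300,000-step prior-only chains. Defaults
in the library remain at the full survey-practice scales (10,000 null
simulations and bootstrap replicates; 5,000,000-step chains with
1,000,000-step burn-in and three replicates).

## Known limitations

* Single locus, single κ, no site-rate heterogeneity (no Γ model).
* The IM model assumes equal θ in both daughter and the ancestral
  population, as in MDIV.
* Fu & Li's D with an outgroup treats every singleton differing from
  the outgroup state as external; ancestral-state ambiguity at
  multi-hit sites is not modelled.
* The mismatch bootstrap re-fits every replicate with the fast (two-start)
  optimiser rather than the full multi-start used for the observed data; a
  replicate occasionally landing in a worse local optimum makes the SSD
  p-value very slightly conservative.
* T and M are weakly identified from one locus when data are close to
  panmixia; the posterior T mode then tracks the first cross-population
  coalescence time rather than a sharply resolved split time. This is a
  property of the model class, not of the implementation.
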