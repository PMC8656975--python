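# Methods

`sarmap` implements the standard small-area disease-mapping chain for
hospital-admission counts aggregated to census tracts: indirect
standardization, Bayesian smoothing of relative risks with conditional
autoregressive (CAR) priors, a shared-component joint model for the two
sexes, and spatial cluster detection with global and local Moran
statistics. This note records the models, the defaults and why, the
numerical choices, and what the synthetic generator does and does not
emulate.

## Indirect standardization

For tract *i*, sex *s* and age group *g* (five groups: 0–14, 15–39, 40–64,
65–84, 85+), area-wide reference rates are derived internally,

    r_{g,s} = Σ_i O_{i,g,s} / Σ_i n_{i,g,s},

expected counts are E_{i,s} = Σ_g n_{i,g,s} r_{g,s}, and the standardized
admission ratio is SAR_{i,s} = 100 · O_{i,s} / E_{i,s}. With internal
rates the method conserves totals (Σ E = Σ O per sex), which the tests
assert at 1e-8 relative tolerance. Population is treated as constant over
the study period and rates as period-cumulative risks; because the same
period underlies counts and rates, the time scale cancels in SAR. Tracts
with E = 0 get an undefined SAR: they are flagged and excluded from maps
rather than imputed, the conservative option. Reports round to 2 decimals
(half-up); full precision is kept internally and in JSON.

## CAR smoothing

Counts are modelled as O_i ~ Poisson(E_i θ_i) with four priors on
log θ_i = α + (random effects):

- **bym** (default): u + v with u ~ ICAR(τ_u) (precision τ_u·Q, Q = D − W
  the contiguity Laplacian) and v iid N(0, 1/τ_v). The classic
  unscaled-ICAR-plus-iid parameterisation, not the rescaled BYM2 variant.
- **icar**: u only.
- **leroux**: a single effect with precision τ[(1−λ)I + λQ], λ ∈ [0, 1]
  interpolating between independence and the intrinsic CAR; λ may be fixed
  (the λ=0 and λ=1 limits reproduce the iid and icar fits, a tested
  equivalence) or sampled.
- **iid**: unstructured only — the no-spatial baseline for model
  comparison.

Hyperpriors: gamma(1, 0.0005) on every precision (the classical default of
the WinBUGS/GeoBUGS family for these models), uniform(0,1) on λ,
N(0, 10³) on α. All overridable.

**Inference** is Metropolis-within-Gibbs MCMC. Precisions have conjugate
gamma full conditionals. The fields use single-site random-walk
Metropolis, vectorised by graph colouring: a greedy colouring partitions
tracts into independent sets, and within a set the single-site full
conditionals are mutually independent, so a whole colour class is proposed
and accepted element-wise in one vectorised step (2–4 colours on lattice
geometries). Per-site step sizes adapt during burn-in (Robbins–Monro on
the log step, target acceptance 0.44, adaptation frozen afterwards). λ is
updated by random walk on the logit scale; its acceptance ratio needs
log det[(1−λ)I + λQ], evaluated from the precomputed eigenvalues of Q.

The ICAR prior is improper (rank n − c for c connected components); the
field is re-centred after every sweep and the intercept absorbs the level.
This is exact for connected geometries (all shipped lattices); for
multi-component graphs the field is centred per component while the
intercept absorbs the global mean. Isolated tracts are refused (the ICAR
prior is undefined on them) unless explicitly allowed, in which case they
carry only unstructured variation. Tracts with E = 0 are dropped from the
likelihood but retained in the output with undefined SRR.

**Summaries.** SRR_i is the posterior mean of 100·θ_i (the posterior
median is reported alongside, since either convention appears in
practice); 95% equal-tail credible intervals; PP_i = P(θ_i > 1 | data)
with PP ≥ 0.8 flagging a significant admission excess and PP < 0.2 a
significant deficit. DIC uses p_D = mean deviance minus deviance at the
posterior mean of θ; WAIC uses the variance form of the penalty with the
sample (n−1) variance, both on the deviance scale with the Poisson
likelihood and E offsets. Split-chain R-hat and effective sample sizes are
computed with arviz; R-hat > 1.1 raises a warning, not a failure. Fixed
seed + fixed settings give bit-identical results (chains are seeded by
spawning a SeedSequence and run sequentially).

Defaults: 4 chains, 5000 iterations, burn-in half, thin 1. The
experiments in the test suite use 2 chains × 1500–2500 iterations on 5×5
to 15×15 lattices and 2 × 2000 on the 558-tract preset — sizes at which
the recovery and equivalence checks are comfortably stable.

## Shared-component joint model

The two sexes are modelled jointly with one spatial field δ ~ ICAR(τ_δ)
common to both, scaled antisymmetrically by a sharing parameter κ:

    log θ_{i,m} = α_m + κ δ_i + v_{i,m},
    log θ_{i,f} = α_f + δ_i / κ + v_{i,f},

with sex-specific iid effects and log κ ~ N(0, 0.5²) (log-normal, median
1: a priori neither sex loads more on the shared geography; sd 0.5 allows
roughly a factor-e asymmetry). This is the simplest member of the
shared-component family for joint disease mapping, chosen over a general
multivariate CAR with free cross-covariance because the goal is to borrow
strength across sexes through a common risk geography, and it is
documented as such a stand-in rather than a replica of any particular
multivariate-CAR software variant. κ is identified through the sum-to-zero
constraint on δ plus its prior; it can be fixed at 1 as a sensitivity
check. The reported cross-sex correlation is the posterior mean of the
per-draw Pearson correlation over tracts between the two log-risk fields;
on data with a genuinely shared field it recovers values above 0.5 and a
κ interval covering 1, while on independent unstructured risks it stays
near zero (both tested).

## Moran statistics and LISA

Weights are row-standardised by default (the GeoDa convention for LISA);
binary weights are available. Global Moran's I uses the standard
cross-product form; inference is by random relabelling (999 permutations
default), two-sided on |I| with the +1 pseudo-p correction, plus an
analytic normal approximation under randomization moments as an
alternative. Cluster statistics run on the *smoothed* relative risks: SAR
in small tracts is noise-dominated and would drive spurious local
extremes.

Local Moran I_i = (z_i/m2) Σ_j w_ij z_j with the population (divide-by-n)
variance m2, so Σ_i I_i = n·I for row-standardised weights (asserted at
1e-10). LISA inference is conditional permutation (hold z_i, permute the
rest onto the neighbours; one shared permutation table across tracts, the
standard shortcut). The pseudo p-value is two-sided — the smaller tail is
doubled — so the significant fraction under a null surface is calibrated
at α rather than at 2α as with the one-tailed min-tail convention; the
null calibration test verifies this. No multiple-testing adjustment is
applied by default (matching common presentation of LISA maps);
Benjamini–Hochberg is available behind a flag. Significant tracts are
classed high-high/low-low (I_i > 0) or high-low/low-high (I_i < 0) by the
quadrant of (z_i, lagged z). Isolated tracts have undefined local
statistics and stay not-significant.

## Synthetic generator

No admission registry of this kind is publicly distributable, so the
package ships a generator that mirrors the model being fitted — which
makes parameter recovery well-posed and is the standard self-consistency
design for validating disease-mapping code.

- **Geography**: rook/queen lattices with deterministic ids; GAL and
  GeoJSON export; queen/rook contiguity can also be derived from arbitrary
  GeoJSON polygons.
- **Population**: tract totals negative-binomial around the mean
  (dispersion 4, coefficient of variation ≈ 0.5, emulating the strong
  size heterogeneity of real census tracts), split into 2 sexes × 5 age
  groups by a multinomial draw from a profile typical of an aged
  north-Spanish urban population.
- **Risk surface**: u from the ICAR distribution (sampled on the non-null
  eigenspace of Q, hence exactly sum-to-zero per component) plus iid v.
- **Counts**: Poisson with stratum rates × tract relative risk.

The `asturias-like` preset fixes the scale of the motivating study area:
558 tracts (an 18×31 queen lattice standing in for the real contiguity),
mean tract population 1265 (≈ 706,000 inhabitants), an expected 3,218
admissions over a 3-year window split 64.42/35.58 male/female, and a raw
event register in which ≈ 1.01% of records lack a resolvable tract
(geocoding failure emulation). Per-age-group admission rates are not
published for the study area, so the preset uses a steeply age-increasing
shape (relative weights 0.001 / 0.05 / 1 / 4 / 7 for the five age groups
— ischemic-heart-disease admissions concentrate in 65+) scaled per sex to
hit the expected totals; the intercept of each risk surface is chosen so
the expected event total matches the calibration despite exp() of a
mean-zero field having mean > 1. The two sexes share 70% of their spatial
risk variance by default (risk factors cluster in the same neighbourhoods
for both sexes); spatial and unstructured precisions default to τ_u = 3,
τ_v = 50, giving tract relative risks mostly between ~60 and ~170, the
range typical of published SRR maps.

What the generator does **not** emulate: real tract polygons and their
very irregular contiguity (degree distribution differs from a lattice),
address-level geocoding, within-period population change,
disease-specific (infarction vs angina) structure, and any covariate
confounding. Passing tests therefore demonstrate the correctness and
calibration of the machinery under the model's own assumptions, not the
epidemiology of any real study area.

## Degenerate inputs and tie-breaks

Constant value vectors are rejected by the Moran statistics (zero
variance). Strata with events but zero population are an error;
zero-population strata without events get rate 0. Threshold summaries use
strict inequality (a tract exactly at SAR = 100 is not "above"). The GAL
reader symmetrises asymmetric neighbour lists. Percentages in reports are
rounded half-up to 2 decimals; JSON keeps full precision.

## Known limitations

- MCMC precision hyperparameters (τ_u, τ_v) mix slowly in the BYM model —
  a well-known near-nonidentifiability of the unscaled parameterisation;
  risk summaries (SRR, PP) mix well, but hyperparameter posteriors need
  long runs and their R-hat can trip the 1.1 warning on short ones.
- The Leroux λ update evaluates the prior determinant from a dense
  eigendecomposition of Q, fine up to a few thousand tracts but not
  beyond.
- The pipeline's per-stage seeds are global seed + fixed offsets; two
  configs whose seeds differ by less than the largest offset share some
  stage streams.
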