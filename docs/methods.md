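# Methods

## The model

`suppdrive` models a CRISPR homing suppression drive inserted in a
haplosufficient, recessive female-sterile fertility gene of *Drosophila
melanogaster*, with a single effective cut site and three allele classes:
wild-type (W), drive (D), and nonfunctional resistance (R). Collapsing a
multiplexed-gRNA construct to one effective site is justified by the same
argument used for the experimental design it emulates: with several closely
spaced gRNAs, a functional repair product at every site simultaneously is
vanishingly unlikely, so end-joining outcomes can be treated as uniformly
nonfunctional, and the germline cut rate defaults to 1 (few or no wild-type
alleles escape cleavage; the rate is exposed for sensitivity runs).

**Germline conversion.** In the germline of an individual carrying both a
drive allele (the gRNA source) and Cas9, each wild-type allele is cut with
probability *g* and, if cut, converted to D by homology-directed repair with
probability *c* (sex-specific: *c_f*, *c_m*) or left as R. A D/W germline
transmits D with probability 1/2 + *gc*/2 — the drive inheritance rate
measured in single-vial crosses, which is how conversion rates are
calibrated (*c* = 2·inheritance − 1 at *g* = 1).

**Embryo resistance.** A mother carrying Cas9 and a drive allele deposits
Cas9/gRNA into the egg; each zygotic wild-type allele is independently
converted to R with probability *e*. Mosaicism is collapsed to
all-or-nothing per allele; consequently the model cannot represent
partially mosaic males that remain capable of drive conversion, which can
make a sterility-calibrated *e* conservative for male-line dynamics. Under
the model, the sterile fraction of drive daughters from a D/W × W/W cross
equals *e* exactly, which is what makes the sterility-based estimator of
embryo resistance coherent.

**Fertility.** Females with no W allele (D/D, D/R, R/R) are sterile; W/W
and W/R females have fecundity 1; D/W females have relative fecundity
*f_het*, the main inferred quantity. An optional distinct value applies to
D/W females whose mother lacked Cas9, for contrasting split- versus
complete-drive maternal-deposition effects. Males are unaffected. Whether
the cost acts on fecundity or on offspring viability is not identifiable
from carrier frequencies; it is modelled as fecundity.

Cas9 is tracked as a flag, not a segregating locus: the cage populations
this package emulates are fixed for Cas9 by design, and the cross schemes
that vary Cas9 parentage set the flag explicitly.

An important subtlety: the drive allele is *never* neutral in this model,
even with *c* = *e* = *g* = 0 and *f_het* = 1, because D/D females are
sterile. A D/W release is therefore weakly selected against, at rate of
order the squared drive allele frequency per generation. The correct null
for drift calibration is an inert marker at a non-essential site, available
as `DriveParams(fertility_target=False)` and the `neutral` preset.

## Cage dynamics

Generations are discrete and non-overlapping, mirroring a 13-day
bottle-replacement cycle. One generation consists of:

1. **Random mating with fecundity weighting** (monandry): mothers are drawn
   from the female genotype distribution weighted by fecundity; each pairs
   with one male drawn from the male distribution. Offspring genotype
   frequencies are the fecundity-weighted expectation over parent pairs;
   sexes are identical at birth (1:1 ratio).
2. **Drift**: one multinomial draw of size *Ne* over the six genotypes
   (sexes pooled), the simplest defensible drift operator.
3. **Density-dependent census**: expected adults
   N' = min(K, β · N/2 · w̄), where β is the low-density number of adult
   offspring per fully fertile female (default 6), K the adult capacity,
   and w̄ the mean female fecundity weight (1 − w̄ is the genetic load).
   The realised census is Poisson around N', capped at K. An optional Allee
   term multiplies output by N/(N + a): per-female output halves at census
   a, representing the observed failure of sparse cages (few egg-laying
   females, microbial overgrowth killing larvae).
4. The realised adult genotype counts are a multinomial of the census from
   the drifted frequencies; all adults are phenotyped, so the observed
   carrier count is exact for the realised adults. Census 0 or loss of all
   potentially fertile female genotypes sets the absorbing `eliminated`
   flag.

The experiments report no demographic rates, so β = 6, K, and the Allee
scale are declared plumbing: they support qualitative contrasts
(elimination versus persistence), not quantitative census prediction. The
`stl` cage presets use a few hundred adults, capacity 600 and Allee scale
100, reflecting the reported cage sizes and the role the Allee effect
played in the final elimination; the drift size Ne = 200 is a typical
bottle-population effective size well below census.

## Fitness and effective-size inference

Given a carrier-count trajectory (kₜ of nₜ phenotyped, all adults), the
conversion and embryo-resistance rates are fixed at their cross-measured
values and (*f_het*, *Ne*) are fitted by maximum likelihood.

The likelihood is one-step-ahead conditional with observation assimilation.
The model maintains within-carrier and within-non-carrier genotype
compositions (initialised from the release: carriers D/W, background W/W).
At each observed generation the mixture is rescaled so its carrier
frequency matches kₜ/nₜ, one deterministic generation is applied, and the
next count is scored as beta-binomial with mean p̂ₜ₊₁, size nₜ₊₁, and
overdispersion ρ = 1/(Ne + 1) (equivalently shape parameters p̂Ne and
(1 − p̂)Ne), which adds one generation of drift variance on top of binomial
sampling noise and reduces to the binomial as Ne → ∞. Unobserved
intermediate generations are propagated without assimilation. This
assimilated conditional likelihood was chosen over full latent-state
marginalisation for tractability and determinism; it is a reconstruction,
not a port, of the likelihood used by the original analyses, so published
fitness values are expected to reproduce only within a tolerance (±0.05)
rather than exactly. When modelling a cage whose Cas9 promoter has very low
maternal deposition, *e* is set to 0.

Optimisation: a coarse grid (f ∈ [0, 1.2], Ne log-spaced from 10 to 10× the
largest count) followed by Nelder-Mead refinement on (f, log Ne). The 95%
CI for *f_het* is the profile-likelihood interval (drop of 1.92 log-units,
χ²₁), with Ne profiled out numerically at each f and linear interpolation at
the crossings — chosen over bootstrap because the published intervals are
asymmetric and can exceed 1. Degenerate predictions (p̂ exactly 0 or 1)
score 0 or −∞ according to whether the observation agrees; a flat
likelihood or boundary estimate is flagged in the result diagnostics
rather than raised.

Simulation checks: over 50 synthetic cages (6 generations, ~500
phenotyped/generation, p0 = 0.2, c_f = 0.85, c_m = 0.8, e = 0.5, true
f = 0.25, Ne = 200) the median f̂ falls within ±0.05 of truth, profile-CI
coverage is ≥85% at nominal 95%, and median N̂e is within a factor of two
of truth; the drift/sampling split is only approximately identified at
these sizes, so Ne recovery is the weaker of the two.

## Cross-experiment estimators

- **Pooled rate**: p̂ = Σk/Σn with binomial SE and Wald CI (Clopper-Pearson
  behind a flag for small n). Correct only if vials are exchangeable
  Bernoulli pools.
- **Batch-aware rate**: binomial GLMM logit(p_vial) = μ + b_vial,
  b ~ N(0, σ²), fitted by maximum marginal likelihood with mode-and-
  curvature-adapted Gauss–Hermite quadrature (default 25 nodes; 1 node is
  the Laplace approximation). The quadrature agrees with direct numerical
  integration to ~1e-10, and the fit agrees with an independent
  implementation of the same model (lme4, nAGQ = 25) to ~1e-5 on the same
  data. The reported rate is expit(μ̂) with a delta-method SE from the
  observed information of (μ, log σ).
- **z-tests**: z = (p̂_a − p̂_b)/√(SE²_a + SE²_b), two-sided normal p; also
  one-sample against a null constant. With tens of vials per group the
  GLMM-based Wald z-test is mildly liberal (type-I error ~0.06–0.07 at
  nominal 0.05 with 20 vials × 50 offspring and σ = 0.5 — a well-known
  small-cluster property of Wald tests), while the pooled test is
  drastically anti-conservative (~0.25) on the same data; this contrast is
  the reason the batch-aware estimator exists.
- **Fecundity**: Welch two-sample t-test on per-female mean daily egg
  counts (unequal variances assumed, the safer default).
- **Viability**: standard pooled two-proportion z-test on egg-to-adult
  survival.
- No multiple-testing correction is applied by default (matching the
  reporting convention of the experiments emulated); Bonferroni/BH can be
  layered on the returned p-values.

## Synthetic data

The generators produce every input the estimators consume, with the
dependence structure the estimators assume: vial tables with logit-normal
batch effects (σ default 0.5) over binomial counts and Poisson offspring
numbers; fertility tables with negative-binomial daily egg counts
(dispersion k = 10, reflecting between-batch overdispersion) and binomial
egg-to-adult survival; cage tables from the stochastic simulator itself,
with ground truth returned alongside. They emulate the *statistical* shape
of the experiments, not their biology: there are no real batch covariates,
no mosaicism, no functional resistance, no age structure, and demography is
the declared plumbing above — so passing recovery tests demonstrates
internal consistency of estimator and generator, not field accuracy.

All randomness flows through a single `numpy` Generator or integer seed;
identical seeds give identical outputs.

## Numerical choices and degenerate inputs

- Distributions are validated to sum to 1 within 1e-9 (1e-12 for
  construction); the deterministic step renormalises after the tensor
  contraction to absorb float error.
- The offspring tensor (6×6×6) depends only on conversion/embryo rates, so
  it is cached per fit; likelihood evaluations cost microseconds.
- GLMM per-vial modes are found by vectorised Newton iteration on a
  concave objective; the marginal likelihood optimiser restarts from three
  σ starting values to avoid the σ → 0 ridge.
- Zero-denominator vials, carrier counts exceeding totals, non-integral
  counts, and empty tables are rejected with line-numbered errors; counts
  are stored as integers end to end.
- Ties in the profile CI are resolved toward wider intervals; the CI always
  contains the point estimate by construction.

## Known limitations

- Single effective cut site: no partial-resistance genotypes, no
  multi-gRNA allele space, no functional (r1) resistance.
- Fitness costs enter only through D/W female fecundity; somatic-cleavage
  costs, male costs, and viability costs are not separately identifiable
  and are absorbed into *f_het*.
- The inference model assimilates observed frequencies rather than
  marginalising latent states; with very small populations (near
  elimination) the beta-binomial drift approximation is crude.
- X-linked targets and overlapping generations are out of scope.
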