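# Methods

`caprigen` analyses parity-wise binary abortion records from pedigreed
dairy-goat herds. This note documents the models, the algorithms behind
them, the synthetic-herd generator, and the numerical and design choices a
user should know before trusting (or extending) the results.

## The liability threshold animal model

Abortion in parity *t* (coded 1 = abortion) is modelled through a latent
Gaussian liability

    l = X b + Z a + e ,      y = 1{ l > 0 },

with fixed effects `b` (year of kidding, season, age class), additive
genetic effects `a` with prior `a ~ N(0, A ⊗ G0)` where `A` is the
numerator relationship matrix of the full pedigree, and residuals `e` with
per-doe trait vectors `e_d ~ N(0, R0)`. Identifiability on the liability
scale is fixed by the standard constraints: threshold at 0 and unit
residual variance for every threshold trait (R0 has unit diagonal).
Heritability on the liability scale is `h²_t = G0_tt / (G0_tt + 1)`;
genetic and phenotypic correlations follow from `G0` and `G0 + R0`. The
same machinery fits the binary codes as a Gaussian trait ("linear" scale),
which is one of the four model variants compared by cross-validation
(linear/threshold × univariate/multivariate).

### Pedigree algebra

Inbreeding coefficients use the Meuwissen–Luo indirect method (ancestor
worklist over the Cholesky factorisation `A = L D L'`), `A` itself is built
by the tabular method (guarded by a dense-size cap, default 5,000), and
`A⁻¹` is assembled sparsely from Henderson's rules with inbreeding-adjusted
Mendelian-sampling variances `d_i = 0.5 − 0.25(F_s + F_d)` (0.75 − 0.25 F
with one known parent, 1 with none). Two invariants tie the three
algorithms together and are tested on random pedigrees: `diag(A) − 1`
equals the inbreeding coefficients exactly, and `A⁻¹ A = I` to 1e-8.
Unknown parents are treated as unrelated, non-inbred founders; there are no
unknown-parent groups.

### Gibbs sampler

One iteration sweeps, in a fixed order: liability / augmented-residual
draws (truncated or untruncated normals from the R0-conditional), scalar
fixed-effect draws, scalar breeding-value draws in pedigree order using the
sparse `A⁻¹`, an inverse-Wishart draw of `G0` given `a' A⁻¹ a`, group
(scale) moves described below, and an inverse-Wishart draw of `R0` from the
augmented residual cross-products, normalised so threshold traits keep unit
residual variance (a correlation-preserving rescale of R0 only; the
liabilities keep their scale). Does missing a parity keep that parity's
residual as an augmented latent variable, so residual covariances between
parities remain estimable and no doe is dropped. The inner loops are
numba-compiled; truncated normals use rejection sampling with an
exponential proposal in the tail, so draws are exact. The chain is fully
deterministic given the seed.

**Scale (group) moves.** Single-site sweeps mix the joint scale of
`(a_t, G0)` only through O(1/q) nudges per iteration, so the variance chain
behaves as an almost driftless multiplicative random walk. After each `G0`
draw the sampler therefore makes one generalized-Gibbs move per trait along
the scale orbit — `a_t → s a_t`, `G0[t,·] → s G0[t,·]`, and for threshold
traits also the liability block (`l_t`, `b_t`) — drawing `s` from its exact
one-dimensional conditional (a `s^k exp(−A₂s²/2 − B₁s − …)` density,
sampled by an independence Metropolis–Hastings step from its Laplace
approximation). These moves were validated against analytic toy posteriors
to three decimals and make the variance chains mix orders of magnitude
faster.

### Priors, propriety, and the quasi-separation regime

Fixed effects carry a weak proper prior `N(0, 100)` on the liability scale.
For threshold models `G0` carries a proper, mildly informative
inverse-Wishart prior equivalent to about **two pseudo-records centred on
a genetic variance of 0.25** (prior mean h² = 0.2), and multivariate
threshold models give `R0` an IW(T+2, I) prior; all-linear models keep
flat-equivalent priors (their posterior is proper without help).

These choices are not cosmetic. With flat priors the threshold-model
posterior is improper: as the liability scale grows the orthant likelihood
tends to a positive constant (every animal has its own genetic effect, so
the latent liabilities can reproduce the observed outcome signs almost
freely), and flat fixed effects make the marginal likelihood grow
polynomially in the scale. Even with proper vague priors the posterior
retains a quasi-separation regime near h² = 1 that dominates when records
are dense relative to the pedigree. Well-mixing chains (the scale moves
above) expose this regime; the conventional single-site samplers used for
such models in practice never reach it and report the data-interpretable
interior mode. `caprigen` documents rather than hides this: with
study-like data (a few pedigree animals per record) and the reduced chain
protocols used here, the chains explore the interior mode; long chains on
densely phenotyped data will migrate to the high-h² regime, and that is a
property of the model class, not of the implementation. Reported estimates
should be read as mode-local finite-chain inference in the tradition of the
field's standard tooling.

### Chain protocol

The default protocol is the long single chain used for final estimates:
200,000 iterations, 20,000 burn-in, thinning 100, retaining exactly 1,800
draws. Cross-validation and the package's own end-to-end tests use a
reduced protocol (20,000 iterations, 2,000 burn-in, thinning 20; CV folds
use 4,000–6,000-iteration chains), chosen as desk-scale protocols that
keep full pipelines runnable in minutes. Burn-in matters here: chains
started at a neutral heritability need several thousand iterations before
the variance components decorrelate from the start, and halving the
protocol visibly biases threshold heritabilities upward. Convergence tooling is the field's: trace-plot export,
posterior standard deviations, and effective sample size via Geyer's
initial-positive-sequence truncation. Summaries use the empirical
shortest-interval HPD (Chen–Shao); a parameter is flagged significant when
its 95% HPD excludes zero. Heritabilities and correlations are derived
draw-by-draw and then summarized — never as ratios of posterior means.

## Synthetic herd generator

No herd data are distributed, so the generator is a first-class module. It
emulates an intensive dairy-goat herd: unrelated founder bucks and does,
discrete generations, a 15:1 doe-to-buck mating ratio (half/full-sib and
deeper relationships, hence inbreeding, arise naturally), breeding values
gene-dropped with inbreeding-adjusted Mendelian-sampling variances,
per-doe residual vectors drawn from `R0`, and parity-wise binary records
from calibrated thresholds. Defaults are the study conditions the models
assume:

| quantity | default | note |
|---|---|---|
| liability h² by parity | 0.25 / 0.11 / 0.19 | `G0` built from these with unit residuals |
| genetic correlations | 0.23 / 0.29 / 0.48 | pairs (1,2), (1,3), (2,3) |
| residual correlations | 0.064 / −0.171 / 0.083 | chosen so phenotypic correlations ≈ 0.09 / −0.07 / 0.14 |
| incidence by parity | 0.15 / 0.18 / 0.15 | thresholds calibrated by bisection to 1e-6 |
| record retention | 1.0 / 0.817 / 0.596 | reproduces the declining parity counts |
| fixed effects | year (7), season (2), age (4) | liability-scale effects; cold season protective (−0.25) |
| herd size | 200 bucks + 3,000 does founding, 3 generations | ~21,000 pedigree animals, ~3,000 phenotyped does |

Only the terminal generation's does are phenotyped by default
(`phenotype="terminal"`), giving a records-to-pedigree ratio (~0.35) like
real herd books, where most pedigree animals are unphenotyped ancestors.
Year and season are assigned uniformly per record; age class advances with
parity (parity p draws age class p or p+1), mirroring how reference levels
shift across parities in herd data. What the generator does **not**
emulate: infectious-abortion outbreaks (spatially/temporally clustered
cases), selection across generations, litter size, culling tied to the
outcome, and year-to-year incidence waves. Passing recovery tests
therefore show the estimators work when the model's assumptions hold — not
that real abortion data satisfy those assumptions.

## Cross-validated model comparison

Five-fold cross-validation stratified by doe (all of a doe's parities share
a fold, so a test doe's breeding value is informed only through relatives).
All four variants reuse byte-identical folds. Training fits use posterior
means of fixed effects and breeding values; linear variants predict
`x'b̂ + â`, threshold variants the abortion probability `Φ(x'b̂ + â)`.
Predictive ability is Pearson's r(y, ŷ) per fold, averaged; its p-value
comes from a one-sample t-test of Fisher-z fold correlations. With
doe-stratified folds the margin between variants is small by construction —
a doe's own other parities are never available, and Pearson correlation
with a binary outcome is nearly invariant to the monotone probit transform
— so rankings at small n are noisy; the package reports per-fold detail so
users can judge the noise themselves.

## Logistic risk-factor analysis

One-trait-at-a-time logistic regressions (logit link; the odds-ratio
interpretation requires it) of abortion status on year, season and age
class simultaneously, fitted by maximum likelihood via statsmodels.
Reports odds ratios `exp(β)` with Wald confidence intervals against
configurable reference levels, and per-factor joint Wald chi-square tests
(likelihood-ratio variant available, and used automatically if the Wald
sub-covariance is singular). The event modelled is an abortion; source
datasets sometimes code the outcome the other way around, so the reader of
any imported data must check the coding before comparing odds ratios.

## Numerical choices and degenerate inputs

- Threshold calibration solves `E[Φ((μ_fixed − t)/σ)] = target` by
  bisection to 1e-6.
- A threshold trait whose records are all 0 or all 1 raises a separation
  error before any sampling; a doe with records but no pedigree entry
  raises a linkage error naming the doe.
- Factor levels never observed for a trait are dropped; a factor left with
  one level is dropped entirely with a warning. The first fixed factor is
  coded with all levels (absorbing the intercept), later factors are
  reference-coded.
- Zero-variance draws are excluded from correlation derivation with a
  logged count; constant chains report ESS = n with a degeneracy warning.
- Draw counts follow `(n_iter − burn_in)/thin` exactly; configurations
  retaining fewer than 2 draws are rejected.

## Known limitations

- Genetic correlations from binary records are weakly identified at desk
  scale: the phenotypic covariance splits into genetic and residual parts
  only through cross-relative information, so `r_g` posteriors are wide and
  their means unstable below a few hundred sire families. Heritability
  recovery is much better behaved.
- The quasi-separation regime (above) bounds how long threshold chains can
  be run on densely phenotyped data before drifting toward h² ≈ 1 under
  weak priors.
- Single chains only (matching the analysis protocol this package
  mirrors); no Gelman–Rubin diagnostics.
- No maternal, permanent-environment or dominance effects; no genomic
  relationships; no unknown-parent groups.
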