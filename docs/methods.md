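# Methods

## Model

### Allometric mean structure

Both scaling directions parameterize one curve family with a pair of
dimensionless power coefficients (a, b) and an establishment-year height
offset H₀ (metres):

* height from diameter: H = H₀ + exp(a + 1/(b + D))
* diameter from height: D = 1/(ln(H − H₀) − a) − b

The two forms are exact algebraic inverses of each other, but they are
**not** fitted as one model: each direction conditions on the *observed*
values of its predictor trait, so the two directions carry different
residual structures and different fitted coefficients. That asymmetry is
the point — it separates loci acting on height gain per unit diameter
from loci acting on girth gain per unit height.

Two analytic facts about this family shape everything downstream:

1. **Branch structure.** The curve is singular at b + D = 0 (equivalently
   ln(H − H₀) = a) and has two smooth branches on either side. No sign
   constraint is imposed on a or b; the optimizer may settle on either
   branch.
2. **Monotonicity.** On each branch, dH/dD = −exp(a + 1/(b+D))/(b+D)² is
   strictly negative: the raw equation is a *decreasing* function of its
   predictor. Consequently, mean response curves generated from this
   family decline mildly along a rising predictor series, and sampled
   series need not be monotone in age. The container type treats
   non-monotone series as a warning, never an error, because the
   likelihood itself is indifferent to monotonicity; the warning exists
   because stem-analysis data are monotone by construction and a
   violation in *real* data suggests an input problem.

H₀ is an observable (the planting-year stem height), taken from the
phenotype file when supplied and fixed at 0 otherwise — it is never a
free parameter. Estimating it per progeny would add n parameters for a
quantity the field measures directly; when it is absent, its effect is
absorbed by the fitted (a, b).

### Likelihood

At one SNP, progeny fall into J genotype classes (J = 2 for a 1:1
testcross marker, 3 for a 1:2:1 intercross marker; classes below the
minimum size, default 5, are dropped and a SNP with fewer than two
surviving classes is reported untestable). The length-T response vector
of progeny i in class j is multivariate normal with mean given by the
allometric curve of class j evaluated at progeny i's own predictor
series, and an AR(1) covariance Σ(s,t) = σ²ρ^|s−t| **shared across
classes** — the covariance carries no genotype index, which both matches
the model's formulation and stabilizes small-class fits. Stationarity
(one σ², one ρ for all ages) is an explicit assumption; the residual
spread of these data is close to constant along the predictor, which is
what justifies the cheap AR(1) form over antedependence or ARMA
structures (not implemented).

The AR(1) algebra is closed-form and O(T):
log|Σ| = T·ln σ² + (T−1)·ln(1−ρ²), and the quadratic form uses the
tridiagonal inverse. A test asserts agreement with a dense generic MVN
evaluation to 1e-8 over randomized instances.

### Testing

Null: (a_j, b_j) ≡ (a, b) for all j (4 free parameters: a, b, σ², ρ).
Alternative: one pair per class (2J + 2). Both hypotheses re-estimate
their own covariance. LR = 2(ℓ₁ − ℓ₀) is referred to χ² with
df = 2(J − 1) — the count of parameters freed by untying, with the
covariance common to both models. Genome-wide correction is Bonferroni
with denominator equal to the number of SNPs *actually tested*
(untestable SNPs do not consume test budget); both α (default 0.01) and
the denominator can be overridden, because the operational threshold of
any given study may use an effective number of tests. An LR below
−1e-6 is reported as a non-convergence (p = NA) rather than clipped
silently.

For intercross SNPs the fitted class curves μ₀, μ₁, μ₂ (by copies of the
reference allele) decompose at each predictor value x into
additive = [μ₂(x) − μ₀(x)]/2 and dominance = μ₁(x) − [μ₂(x) + μ₀(x)]/2 —
the standard codominant contrast, exactly invertible, and the only
decomposition consistent with three genotype curves indexed by allele
count. Trajectories are reported against the predictor trait (diameter
for piQTLs, height for miQTLs), not calendar age, because that is the
axis on which the allometry is defined. Testcross SNPs yield the
additive contrast only.

## Fitting

Maximization is derivative-free Nelder–Mead simplex search, with:

* **σ² profiled analytically.** For fixed (a_j, b_j, ρ) the conditional
  MLE is σ̂² = Q(ρ)/(nT) with Q the pooled unit-variance quadratic form.
  Profiling removes one search dimension and makes the noiseless limit
  well behaved (as residuals → 0, σ̂² → a floored value and the search
  still localizes (a_j, b_j) sharply). The reported parameter count
  still includes σ².
* **ρ through a tanh transform**, bounded to |ρ| < 0.999.
* **Initialization** by log-linearized least squares: the height
  direction satisfies ln(H − H₀) = a + 1/(b + z), so a coarse geometric
  grid over b (both branches of the data envelope) with the closed-form
  conditional a picks the best start; the diameter direction swaps the
  roles of a and b. ρ starts at the lag-one autocorrelation of the
  initializer's residuals.
* **Multi-start**: default 5 Nelder–Mead starts — the first from the
  initializer (null fit) or from the null solution (alternative fit),
  the rest jittered. Jitter is seeded from the run seed; identical seeds
  give byte-identical scan output. Warm-starting the alternative at the
  null solution makes the nesting inequality ℓ₁ ≥ ℓ₀ a structural
  guarantee (simplex never returns a point worse than its start), not a
  numerical hope.
* **Domain handling**: parameter proposals that push any progeny's mean
  across a singularity or overflow (exponent > 700) score −∞ and the
  search moves on; exceptions are reserved for direct user calls with
  invalid arguments.
* Complete-case analysis: all progeny share one age grid; progeny
  missing either trait at any age are rejected at read time. Partial
  series would break the closed-form AR(1) inverse and are out of scope.

During a genome scan the null fit depends only on *which* progeny have
observed genotypes, not on the grouping, so it is cached per progeny
subset and reused across SNPs — with complete genotyping the entire scan
shares a single null fit.

## The generator

The synthetic-data module emulates the structure of a destructive
stem-analysis study of a single interspecific full-sib family:
defaults of 64 progeny, T = 24 annual measurements, and a marker panel
with the testcross fraction of the motivating panel (94 591/156 362 ≈
0.605). Genotypes are Mendelian draws (1:1 or 1:2:1), independent across
SNPs. Phenotypes follow the model's own generative assumptions: the
conditioning trait grows along a logistic curve (diameter: asymptote
28 cm, rate 0.30 yr⁻¹, inflection at year 9; height: 26 m, 0.25 yr⁻¹,
year 10) with progeny-level lognormal jitter on the asymptote (CV 0.12)
and Gaussian jitter on the inflection age (sd 1 yr); the response trait
sits on the allometric curve of the progeny's QTL genotype — baseline
(a, b) = (3.0, 1.0) for height-from-diameter, (−1.0, −6.0) for
diameter-from-height, placing trees at plausible sizes for a
fast-growing 24-season trial — plus stationary AR(1) residuals
(height σ² = 1 m², diameter σ² = 0.09 cm², ρ = 0.7; growth increments
of one tree are strongly autocorrelated). Establishment heights are
uniform on 0.2–0.6 m. QTL effects enter only through (a, b); multiple
planted QTLs combine additively on the coefficient scale.

What the generator does **not** emulate — and what passing tests on it
therefore cannot show: linkage disequilibrium between markers (the scan
tests SNPs marginally, so power against linked-null structure is
untested), genotyping error, partially missing phenotype series,
non-stationary residual variance, and any monotone-increasing
height-versus-diameter relationship (see the monotonicity note above:
the curve family itself is decreasing in its predictor, so simulated
mean heights decline mildly over the diameter range while spanning a
realistic 20–30 m). Residual draws that would push a height below H₀
are redrawn (logged; essentially never triggered at the default noise).

## Validation studies and problem sizes

The test suite validates the pipeline at these scales, chosen to make
the statistical properties measurable on a single CPU:

* analytic identities (curve inversion to 1e-9 over 1 000 grid points;
  AR(1) density vs dense MVN to 1e-8 over 100 randomized instances);
* noiseless self-consistency at the full design (64 × 24): every
  genotype's (a, b) recovered to 1e-4 relative error;
* noisy recovery at n = 200 progeny, T = 24, default noise,
  50 replicates: median relative error of each (a_j, b_j, σ², ρ)
  under 5%;
* null calibration of the df = 4 intercross test at n = 200, T = 8,
  500 replicates: empirical rejection at nominal 0.05 within the exact
  binomial 95% interval [0.032, 0.071] (T does not enter the asymptotic
  argument, n does; n = 64 designs are below the comfortable asymptotic
  regime for a df = 4 LRT, which is a known caveat of the method at
  realistic family sizes);
* detection: one strong intercross QTL (Δa = ±0.15 between homozygotes,
  roughly a 15% height displacement) planted among 100 null SNPs at the
  study's own n = 64, T = 8: the planted SNP attains the minimum p-value
  in ≥ 95% of 100 replicate scans;
* structural guarantees on every scan: ℓ₁ ≥ ℓ₀ − 1e-6 per SNP, and
  byte-identical output under identical seeds.

The replicate studies use 1–2 optimizer starts (the warm-started
alternative converges from the null solution); the single-fit checks
use the default 5.

## Known limitations

* Markers are tested one at a time; no multi-QTL or variable-selection
  model, no positional inference between markers.
* The χ² reference for the LRT is asymptotic; at n = 64 with df = 4 it
  is mildly approximate (see above).
* The AR(1) structure is stationary by assumption; data with strongly
  age-dependent residual variance would need a different covariance
  family.
* Complete-case only: a progeny missing any measurement is dropped from
  the affected fits.
* The curve family cannot represent an increasing height-diameter
  relationship (its derivative is negative on each branch); fitted
  coefficients describe the data through the branch geometry, and the
  package treats the equations as given rather than selecting among
  alternative allometric families.
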