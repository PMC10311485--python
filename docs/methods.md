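# Methods

## The structural model

A twin–spouse quartet (twin1, spouse1, twin2, spouse2) is modelled as
jointly Gaussian. Each phenotype is `P = a·A + s·S + e·E` with unit-variance
latent components: additive genetic (A), social background (S), and unique
environment (E). The social-background factor deliberately absorbs the
classical twin shared environment: fitting a separate C factor next to S is
not identified (see *Identifiability* below), so S carries both. Total
variance is `V = a² + s² + e²` on the years² scale; variance proportions
`h² = a²/V`, `s² = s²/V`, `e² = e²/V` are reported post hoc — V is not
constrained during fitting.

Twins reared together share S exactly (correlation 1 in both zygosity
groups). The twin–twin genetic correlation is 1 for MZ pairs and
`α = ½(1 + Δp)` for DZ pairs: under equilibrium phenotypic assortment the
parents' genotypes correlate, raising the DZ genetic correlation above the
random-mating value ½. Opposite-sex DZ pairs share the same-sex DZ
covariance structure; sex affects the means only (`μ` for men, `μ + β` for
women).

Two copaths generate spousal resemblance:

* `Δp` (phenotypic assortment) — a direct copath between the phenotypes of
  each twin and their own spouse;
* `Δy` (social homogamy) — the strata of the two in-marrying spouses
  correlate `Δy` with the twin family's stratum *and with each other*
  (exchangeable strata: both spouses are drawn from the same social pool as
  the twin family, so their mutual stratum correlation equals their
  correlation with the family stratum rather than its square).

The exchangeable-stratum convention is a deliberate design choice. It is
what makes the model's qualitative predictions exact: under pure social
homogamy (`Δp = 0`) all three spousal correlations equal `s²·Δy` for *any*
`Δy`, and it is what makes a separate C factor *exactly* redundant — C and
S then enter every implied moment only through `c² + s²` and `s²·Δy`
products. With a squared spouse–spouse term (`s²·Δy²`), both properties
would hold only at `Δy = 1`.

Closed-form standardized entries (`r_tt = α·h² + s²`):

```
r1 = Δp + s²·Δy                          twin – own spouse
r2 = Δp·r_tt + s²·Δy                     cotwin – spouse
r3 = Δp²·r_tt + 2·Δp·s²·Δy + s²·Δy       spouse – spouse
```

Correctness is defined by an independent latent construction
(`implied_latent_covariance`): an explicit 12×12 covariance over the A/S/E
components of all four individuals, built by component-level path tracing
through the copaths (each copath at most once per chain) with the
equicorrelated stratum block. Propagating it through the loadings
reproduces the closed forms to machine precision; the test suite checks the
equality to 1e-10 over random admissible draws.

**Admissibility.** The latent construction requires a PSD 12×12 matrix, so
in particular `|Δy| ≤ 1`. The cohort estimates put `Δy` slightly above 1
(1.03 and 1.18) — interpretable because a copath is not a correlation.
Fitting therefore enforces only *observed-level* admissibility (PSD 4×4
implied covariance); non-PSD parameter regions receive a large finite
likelihood penalty rather than an exception so that optimization and
profiling remain robust. The within-person A–S covariance is fixed at 0 (no
cultural transmission is modelled).

## Estimation and inference

Each family contributes the multivariate-normal log-density of whichever
roles it observed (FIML; families enter exactly once). Families are grouped
by (zygosity, missingness pattern); within a group the likelihood depends
on the data only through cross-product sufficient statistics, so one
likelihood evaluation costs O(#groups), independent of the number of
families.

Maximization uses L-BFGS-B with numeric gradients from a moment-based start
plus seeded jittered restarts (5 by default), followed by a Nelder–Mead
polish from the best point — the quasi-Newton runs occasionally stall on
the Δp/Δy likelihood ridge, and the derivative-free polish recovers those
cases cheaply. Convergence tolerance on the log-likelihood is ~1e-5; paths
are bounded at 0 from below.

* **Likelihood-ratio tests**: −2·Δlog-likelihood against χ² with df equal to
  the free-parameter difference; α = 0.05. Copaths can be negative, so the
  plain χ² reference is used (no boundary mixture correction).
* **Confidence intervals**: profile likelihood (endpoints where the profile
  drops by χ²₁(0.95)/2 = 1.9207, re-optimizing the remaining parameters;
  bounds respected, with one-sided intervals flagged when the profile never
  crosses the threshold). Wald SEs from a central-difference numeric
  Hessian are attached to every fit as diagnostics, and a delta-method
  helper gives SEs for derived quantities such as h².
* **Identifiability**: numeric Jacobian of the stacked unique implied
  moments (means for both sexes plus the five distinct covariance entries
  per zygosity) with rank from the singular spectrum (relative tolerance
  1e-6). The A+S+E model with both copaths is full rank at generic points;
  adding a separate C factor yields an exact null direction trading c²
  against s²/Δy, and fixing s = 0 leaves Δy as a structural zero column.
* **Monte-Carlo power**: replicate simulate–fit–test cycles; rejection when
  p ≤ α; binomial MC standard errors reported.

## Synthetic data

No cohort micro-data are distributable (access is by application), so the
package generates its own. The primary generator samples observed-role
vectors directly from the implied multivariate-normal moments per
(zygosity × configuration) cell — sampling at the observed level is what
keeps the latent-inadmissible but observed-admissible estimate `Δy = 1.03`
simulable. Default designs mirror the two cohorts' family-configuration
tables (per zygosity: single twins with/without a spouse; twin pairs with
zero, one or two participating spouses), rescalable to any total.
Configurations are assigned independently of the phenotypes, i.e. MCAR, so
FIML on masked and full data estimate the same parameters — this is tested.
Sexes: MZ/SSDZ pairs get one sex per pair at 50/50, OSDZ twins are
opposite-sex by construction, every spouse is opposite-sex to their twin.

Country presets carry the published variance proportions, copaths and sex
effects. The raw scale (grand mean and total variance) is not printed in
the source material; presets use means near 13 years and SDs near 2.1–2.4
years to match the cohort descriptive tables. All graded quantities
(proportions, copaths, the sex effect in years) are invariant to this
choice.

What the generator does *not* emulate: integer-valued years (phenotypes are
continuous Gaussian), nonresponse correlated with education (MNAR),
age/cohort moderation, and any OSDZ-specific covariance effects. Passing
tests therefore demonstrate correctness of the machinery under the model's
own assumptions, not robustness to real-data violations of them.

A second, mechanistic generator (`mate_choice_oracle`) builds populations
of agents with explicit A/S/E values and matches spouses by rank on a noisy
weighted score of phenotype and stratum. It validates the model's
qualitative predictions from an independent route: phenotype-only matching
produces the strict descent r1 > r2 > r3; tight stratum-only matching
equalizes the three correlations (loose stratum matching necessarily gives
r3 = r1·δ < r1, δ being the achieved stratum alignment — "pure social
homogamy" means drawing spouses from the family's stratum, not vaguely near
it); iterated phenotype matching raises the full-sib genetic correlation
above 0.5 and drives the genetic variance to an equilibrium plateau
(segregation variance is held at half the base-population additive
variance; the stratum pool is renormalized each generation). The plateau
criterion is a relative variance change below 1% across the final two
generations, reached within ~30 generations at a spousal correlation of
0.5.

## Descriptives and harmonization

Pairwise-complete Pearson correlations per zygosity group and pooled.
Symmetric relations (twin–twin, cotwin–spouse, spouse–spouse) use double
entry — each pair contributes in both orders — which removes the arbitrary
twin-1/twin-2 labelling; twin–own-spouse is role-asymmetric and single
entry. Fisher-z confidence intervals use the number of *distinct* pairs as
effective n; cells with fewer than three pairs are reported missing. The
rank-order label uses an equality tolerance of 0.02 (configurable; the
equal-correlation prediction is exact in the model, the tolerance absorbs
sampling noise). Group means come with Welch t tests (Satterthwaite df)
contrasting men and women within twins and within spouses.

Education levels map to years through a shipped, editable YAML table
(five categories per country; 9/10/12/15/16 years for Finland,
6/10/13/15/16 for the Netherlands). The Dutch seven-category coding is
first merged to the common five ({2,3}→2, {4,5}→3, 1→1, 6→4, 7→5); a
not-completed highest level steps down one seven-level category *before*
the merge, and the still-enrolled rule (years − 1) applies *after* the
merge to both countries. Both order-of-operations choices are conventions
recorded in the harmonization metadata; the source rules state the
enrolled adjustment only for the Finnish survey and leave the step-down/
merge order open.

## Numerical choices and limitations

* Likelihood penalty for non-PSD regions: −1e12·(1 + |min eigenvalue|),
  finite so optimizers and profilers can retreat.
* Numeric derivatives are central differences (relative steps 1e-6 for
  Jacobians/gradients, 1e-4 for Hessians); no external differentiation
  dependency.
* Replicate studies in the test suite run at the cohorts' family counts
  (≈2,400 families per replicate, 500 replicates for null calibration);
  parameter-recovery checks use 5,000 complete quartets per zygosity.
  These sizes are the package's reference conditions for stochastic
  assertions.
* Ordinal-threshold likelihoods for the raw education categories, Bayesian
  estimation, dominance, cultural transmission and multi-trait assortment
  are out of scope. Raw-scale confidence intervals for the variance
  proportions cannot be compared against the source tables because the raw
  path estimates were published only in supplementary material.
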