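# Methods

## Linear reaction norms and derived parameters

Mean development times *D* (days) at constant rearing temperatures *T* (°C)
are inverted to rates *R* = 1/*D* and fitted by ordinary least squares,
*R* = *a* + *b·T*.  Derived quantities: lower temperature threshold
LTT = −*a*/*b*, degree-day sum SDD = 1/*b*, and elevation = arithmetic mean
of the observed rates over the retained regimens (observed, not fitted,
values; for perfectly linear data the two coincide at the mean temperature).
Fits with *b* ≤ 0 keep their coefficients but are flagged unusable: LTT and
SDD are undefined, and such records are excluded from correlation and
intersection analyses.

Male and female series sharing a temperature grid are pooled per regimen by
the sample-size-weighted mean when both *n* are reported, otherwise the
simple mean.  Temperature grids are matched with a tolerance of 1e−6 °C.

**Truncation to the linear range.**  Complete reaction norms are sigmoid;
only end temperatures may be discarded.  All contiguous windows with at
least `min_points` (default 3) temperatures are enumerated; among windows
whose OLS r² reaches `r2_target` (default 0.980) the longest is retained,
ties broken by higher r²; if no window qualifies the full series is kept and
falls into the "bad" class.  This is a package design choice: it removes
sigmoid tails without ever discarding interior regimens, and it deliberately
does not rescue series with interior irregularities.

**Quality split.**  r² ≥ 0.980 → "good", otherwise "bad"; the two classes
are analysed separately and deduplicated independently (one record per
species × stage per class, highest r² first, then more temperatures, then
input order), so their species lists may overlap.

## Intersection abscissas

Two lines cross at T\* = (a_j − a_i)/(b_i − b_j).  Pairs with
|b_i − b_j| < 1e−9 (1/(day·°C)) are treated as parallel and counted as
excluded rather than producing distant pseudo-intersections from float
noise.  Raw abscissas per line are summarised by their median (their
distribution is heavy-tailed by construction: nearly parallel pairs produce
extreme abscissas); the per-line medians are summarised by an arithmetic
mean, with a one-sample Kolmogorov–Smirnov test against a normal with the
sample mean and SD attached (a Lilliefors-corrected variant is available).
A probability ≤ 0.1 flags that the mean may be a poor summary.  The
proportion of raw abscissas outside the conventional 15–30 °C rearing window
is reported alongside.

## Phylogenetic model

A rooted tree with branch lengths induces the Brownian covariance
C[i,j] = shared root-to-MRCA path length.  Pagel's λ multiplies the
off-diagonal entries.  For *p* traits (*p* = 1 for signal estimation, 2 for
correlation), the trait matrix is modelled as matrix normal with mean
(α₁·1, α₂·1) and covariance Σ ⊗ C_λ, where Σ has rates σ²_k and, for
*p* = 2, the evolutionary correlation ρ.  The 2n-dimensional density is
evaluated from a single n×n Cholesky factorization:

log L = −½ [ np·log 2π + p·log|C_λ| + n·log|Σ| + tr(Σ⁻¹ X'C_λ⁻¹X) ].

**Arbitrary branch lengths.**  Composite trees have no meaningful branch
lengths, so four assignments are used per topology: *unit* (every branch 1),
*grafen* (node height ∝ descendant tips − 1, root scaled to 1), *nee*
(node height ∝ log descendant tips, root scaled to 1), and *pagel* (all
branches 1, terminal branches extended until ultrametric).  These follow the
PDAP/PDTREE documentation lineage; the original programs print no closed
formulae, so the definitions here should be read as this package's own.
Zero-length internal edges (a common encoding of polytomies in bifurcating
exports) are collapsed into true polytomies before any transform, making the
result independent of the encoding.

Each covariance is normalized to unit mean root-to-tip distance before
sampling.  λ and ρ are invariant to this overall factor, but the four
transforms otherwise differ in depth by the number of tree levels, and a
single σ² cannot serve a collection whose members disagree about scale by
nearly an order of magnitude.

**Tree uncertainty.**  The collection (by default the four transforms of one
topology) enters as a uniform prior over branch-length assignments that is
marginalized analytically: the sampler's acceptance ratio uses the
arithmetic-mixture likelihood over the collection, and each retained draw
records a tree index sampled from its conditional posterior given the
parameters.  The mean posterior tree weights are reported as a diagnostic.
This Rao-Blackwellized treatment samples the tree-averaged posterior
exactly; carrying the tree index in the chain state is equivalent in
distribution but mixes very poorly when the collection members disagree.

**Priors and proposals.**  Traits are z-standardized (λ, ρ are invariant;
the priors and steps then live on one scale).  Priors: ρ ~ U(−1,1),
λ ~ U(0,1), α_k ~ U(mean ± 10 SD), ln σ_k ~ U(ln SD − 8, ln SD + 4).
Proposals: Gaussian random walk on one uniformly chosen free parameter per
iteration, reflected at the prior bounds (reflection is symmetric, so the
Metropolis ratio is unchanged; it keeps λ mobile when its posterior piles up
near 1).  Step sizes adapt toward 20–40 % acceptance during burn-in in
windows of 200 iterations, bounded to [1e−4, 0.25] of each prior range, and
are frozen afterwards.

**Likelihood cache.**  For each tree, log|C_λ| and the cross-products of
[X, 1] whitened by C_λ are precomputed on a 201-point λ grid (step 0.005,
well below the two decimals at which posteriors are reported); each MCMC
iteration then costs O(1) in the number of species, which is what makes
million-iteration schedules affordable.  The cached route is verified
against the direct Cholesky evaluation in the tests.  Near-singular
covariances (exact ties at λ = 1) receive a diagonal jitter of 1e−8 × tree
depth.

**Schedules.**  The long-run default is 1,010,000 iterations, 10,000
burn-in, every 1000th draw retained (1000 samples); a fast profile
(110,000 / 10,000 / 100) gives the same number of retained draws at desk
scale, and the test suite and acceptance script use 20,000 / 4,000 / 16 —
still 1000 retained draws.  Repeat runs at a 200,000-iteration schedule
agree on posterior medians to < 0.01 on 40-tip data; shorter schedules trade
some Monte-Carlo error for speed without changing posterior width.  Each
analysis can be repeated (3 repeats mirror common
practice); reports quote the first run and carry all repeat medians.

**Model comparison.**  Marginal likelihoods are estimated by the harmonic
mean of the sampled mixture log-likelihoods, computed with a log-sum-exp
shift; log BF = 2 × (HM_main − HM_simpler) with categories 0–2 / 2–6 /
6–10 / >10.  The harmonic-mean estimator is known to be unstable — it is
dominated by the deepest likelihood excursion a chain happens to visit — and
log Bayes factors of a few units should be read qualitatively.  With the
exact marginalized sampler the logL tails are Gaussian-like and contrasts of
the same data are reproducible to a few units across seeds at n ≈ 35; no
stepping-stone or thermodynamic-integration alternative is provided by
design, matching the two-run workflow this package mirrors.

**GLS cross-check.**  At fixed λ the maximum-likelihood ρ has a closed form:
whiten [X, 1] by the Cholesky factor of C_λ, take GLS ancestral means, and
correlate the residuals.  The MCMC posterior median agrees with this
estimate to well under ±0.15 on 40-tip data, and the likelihood itself is
verified against an explicitly built Kronecker-product normal density to
1e−8 on 6-tip fixtures.

## Synthetic data

The generator emulates the statistical structure of a compiled comparative
dataset; its defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| n_species | 60 | a realistic per-stage species count for a well-studied family |
| temperatures | 15, 20, 25, 30 °C | the conventional rearing grid |
| extreme temperatures | 10, 33 °C | appended only with sigmoid curvature |
| noise_cv | 0.02 | calibrated so the median 5-point fit clears r² = 0.98 |
| true_lambda / true_rho | 0.7 / 0.5 | moderate-to-strong signal and correlation |
| slope_range | 0.004–0.012 1/(day·°C) | SDD ≈ 85–250 degree-days |
| ltt_range | 6–14 °C | thresholds spanning ~8 °C around 10 °C |

Trees are unit-depth Yule trees (optional polytomy collapse; 1.0 gives a
star).  Traits are exact draws from the Σ ⊗ C_λ normal.  Bivariate traits
map to line parameters through their normal CDF (rank-preserving) stretched
into the slope and LTT ranges; scenarios override one degree of freedom:
*parallel_shift* pins every slope at mid-range (no intersections),
*common_intersection* rotates all lines around a pivot (default 12 °C,
0.002 1/day).  Development times are 1/(a + bT) with multiplicative
lognormal rate noise of the given CV.  Sigmoid curvature distorts the
extreme regimens the way real norms bend: the hot end saturates at 0.8 × the
line, and the cold end flattens upward toward the linear prediction 5 °C
warmer (weight 0.3 on the line) — a multiplicative depression of the
near-zero cold rate would barely perturb linearity and could never be
removed by the truncation rule.

What the generator does *not* emulate: mortality and regimen failure near
the thermal limits, interactive effects (diet, humidity, photoperiod),
heteroscedastic sample sizes, and non-Brownian trait evolution.  Passing
tests therefore demonstrate correctness of the machinery under the stated
model, not robustness of the biology to model violations.

## Numerical choices and degenerate inputs

- Temperature-grid matching tolerance 1e−6 °C; parallel-slope tolerance
  1e−9 1/(day·°C).
- OLS is the closed-form normal-equation solution; r² is clipped at 1 to
  absorb float round-off on exact data.
- Identical per-line medians (a perfect common pivot) short-circuit the KS
  test to p = 1 rather than dividing by a zero SD.
- MCMC initialization starts at the data moments; if the likelihood is not
  finite there, up to 20 jittered restarts are attempted before failing.
- Retained-draw count is exactly (n_iter − burn_in) // thin; constrained
  parameters appear as constant columns so every result has one schema.

## Known limitations

- The harmonic-mean marginal likelihood converges slowly and its contrasts
  should not be over-read near category boundaries.
- The truncation rule can retain a short late window for series with
  interior irregularities; such series are better left to the "bad" class,
  which the default r2_target achieves for interior deviations (no
  contiguous window avoids them).
- Posterior interquartile ranges are 50 % credible intervals; under correct
  calibration they cover the generating value in about half of replicates,
  which parameter-recovery checks must take into account.
- Composite-tree polytomies are treated as hard polytomies; no attempt is
  made to resolve them or to model within-species variation.
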