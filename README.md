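# thermnorm

Comparative analysis of **linear thermal reaction norms** for ectotherm
development, with Bayesian **phylogenetically informed** correlation and
signal estimation.

## The problem

Development time *D* of insects reared at a constant temperature *T* shortens
with warmth; over the permissive mid-range the developmental **rate**
*R* = 1/*D* is very nearly linear in temperature,

```
R = a + b·T
```

Two derived parameters carry the biology: the slope *b* (thermal
sensitivity), and the **lower temperature threshold** LTT = −*a*/*b*, the
extrapolated temperature at which the rate reaches zero.  The reciprocal
slope SDD = 1/*b* is the sum of degree-days (physiological time), and the
**elevation** — the mean rate across the temperature regimens — locates the
line vertically.

Comparative questions about these parameters are entangled with two
confounders this package is built to handle:

1. **Shared ancestry.** Related species have similar thermal phenotypes, so
   ordinary correlations across species are not based on independent data
   points.  Correlations are therefore re-estimated under a Brownian-motion
   model on a phylogeny, with Pagel's λ scaling the off-diagonal covariance
   (λ = 0: star phylogeny; λ = 1: full Brownian expectation), by MCMC over a
   collection of trees carrying different arbitrary branch-length
   assignments (unit, Grafen, Pagel, Nee).  Model contrasts (correlation
   free vs. fixed 0; λ free vs. fixed 0) are judged by a log Bayes factor,
   2 × the difference of harmonic-mean log marginal likelihoods
   (0–2 barely noteworthy, 2–6 positive, 6–10 strong, >10 very strong).
2. **Measurement noise.** Random scatter around a single true line produces
   a spurious positive correlation between the fitted slope and threshold
   (the noise artifact of slope–threshold correlation).  Series are
   therefore split at r² ≥ 0.980 into "good" and "bad" quality classes and
   analysed separately.

The package also computes the **intersection-abscissa statistic**: the
temperature at which two fitted lines cross, T\* = (a₂−a₁)/(b₁−b₂),
summarised per line by the median over all pairings and per stage by the
arithmetic mean of those medians — the quantity that tests whether reaction
norms rotate around one common point.

Because no public archive carries a suitable compiled dataset, a first-class
synthetic-data module generates trees (Yule, with optional polytomies),
λ/ρ-structured traits, and development-time tables with controllable noise
and sigmoid tails, so every claim is testable end to end.

## Worked example

```python
import thermnorm as tn

# synthetic study: 40 species, lambda = 0.7, evolutionary correlation 0.5
cfg = tn.SimConfig(n_species=40, true_lambda=0.7, true_rho=0.5, seed=11)
manifest = tn.generate_dataset(cfg, "scratch/demo")

series = tn.read_development_csv("scratch/demo/development.csv")
records = tn.fit_all_series(series)
norms = [nm for _, nm in records if nm.quality == "good" and nm.usable]
tree = tn.read_newick("scratch/demo/tree.nwk")

traits = tn.norms_to_frame(norms).set_index("species_id")
covs = [tn.phylo_covariance(tn.transform_branch_lengths(tree, m))
        for m in ("unit", "grafen", "pagel", "nee")]
model = tn.BrownianModel(traits[["slope_b", "ltt"]], covs)
result = model.fit(n_iter=110_000, burn_in=10_000, thin=100, seed=1)
print(result.summary())
```

prints (abridged):

```
Brownian trait model (random-walk Metropolis over tree collection)
  species: 40   traits: slope_b, ltt
  iterations: 110,000  burn-in: 10,000  thin: 100  retained: 1000
  seed: 1  acceptance rate: 0.358
  posterior tree weights: [0.0931, 0.3434, 0.0859, 0.4775]
  harmonic-mean log marginal likelihood: -110.417

  parameter   median     q25      q75
  rho           0.340    0.232    0.432
  lambda        0.695    0.596    0.784
  ...
```

The posterior median of the evolutionary correlation ρ (here 0.34 with
quartiles 0.23–0.43) and of Pagel's λ (0.70, quartiles 0.60–0.78) recover
the generating values within posterior uncertainty; the tree weights show
how much each branch-length assignment contributes to the average.  Fitting
the same data with `rho=0.0` and calling
`tn.log_bayes_factor(result, null_result)` yields the log Bayes factor and
its evidence category for the correlation.

A command-line interface wraps the same steps:

```bash
thermnorm simulate --out-dir demo --seed 11 --n-species 40
thermnorm fit --dev-csv demo/development.csv --out norms.csv
thermnorm correlate --dev-csv demo/development.csv
thermnorm report --dev-csv demo/development.csv --tree demo/tree.nwk \
    --out-dir demo_report --fast --seed 1
```

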