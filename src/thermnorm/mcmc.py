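"""Bayesian MCMC for phylogenetically informed trait correlation and signal.

The central object is :class:`BrownianModel`, built from a table of one or
two species traits and a collection of candidate trees (typically the four
arbitrary branch-length transforms of one composite topology).  ``fit()``
runs a random-walk Metropolis sampler over the free parameters -- ancestral
means, log rates, the evolutionary correlation rho, and Pagel's lambda --
with the tree index marginalized analytically over the collection (uniform
tree prior), so the posterior averages over branch-length uncertainty; each
retained draw also records a tree sampled from p(tree | parameters).  The returned
:class:`BrownianResults` carries the thinned samples, the harmonic-mean
estimate of the log marginal likelihood, and median/quartile summaries.

Model comparison follows the two-run scheme: fit the main model and a
constrained one (rho = 0, or lambda = 0) on the same data and trees, then
``log_bayes_factor(main, simpler)`` = twice the difference of harmonic-mean
log marginal likelihoods.  Values in (0, 2) are barely noteworthy, [2, 6)
positive, [6, 10) strong and >= 10 very strong evidence for the main model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .brownian import BMParams, bm_loglik, _LOG_2PI
from .trees import PhyloCovariance, lambda_scaled_matrix, phylo_covariance

__all__ = [
    "BrownianModel",
    "BrownianResults",
    "harmonic_mean_logL",
    "log_bayes_factor",
    "bayes_factor_category",
    "summarize_posterior",
]

#: the long-run sampling schedule (iterations, burn-in, thinning)
DEFAULT_SCHEDULE = (1_010_000, 10_000, 1_000)
#: desk-scale schedule for quick runs
FAST_SCHEDULE = (110_000, 10_000, 100)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposal back into [lo, hi] (symmetric, so MH-valid).

    Keeps the sampler from stalling when the posterior piles up against a
    boundary, as Pagel's lambda often does near 1.
    """
    width = hi - lo
    for _ in range(8):  # more than one bounce only for absurd step sizes
        if x < lo:
            x = lo + (lo - x)
        elif x > hi:
            x = hi - (x - hi)
        else:
            return x
        if not np.isfinite(x) or abs(x) > abs(lo) + abs(hi) + 8 * width:
            break
    return x


def harmonic_mean_logL(logL_samples) -> float:
    """Harmonic-mean estimate of the log marginal likelihood.

    Computed as -(log mean of exp(-logL)) with a log-sum-exp shift, so the
    result is exact for constant samples and stable for large magnitudes.
    """
    x = np.asarray(logL_samples, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one log-likelihood sample")
    return float(-(logsumexp(-x) - np.log(x.size)))


def bayes_factor_category(log_bf: float) -> str:
    if log_bf < 0:
        return "favors simpler model"
    if log_bf < 2:
        return "barely noteworthy"
    if log_bf < 6:
        return "positive"
    if log_bf < 10:
        return "strong"
    return "very strong"


def log_bayes_factor(main, simpler) -> tuple[float, str]:
    """log BF = 2 x (harmonic-mean logL of main - that of the simpler model)."""
    hm_main = main.harmonic_mean_logL if hasattr(main, "harmonic_mean_logL") else float(main)
    hm_simp = simpler.harmonic_mean_logL if hasattr(simpler, "harmonic_mean_logL") else float(simpler)
    value = 2.0 * (hm_main - hm_simp)
    return value, bayes_factor_category(value)


def summarize_posterior(samples: pd.DataFrame) -> pd.DataFrame:
    """Median with lower/upper quartiles per sampled parameter."""
    if len(samples) < 4:
        raise ValueError("need at least 4 retained samples to summarise")
    q = samples.quantile([0.25, 0.5, 0.75])
    out = pd.DataFrame(
        {"median": q.loc[0.5], "q25": q.loc[0.25], "q75": q.loc[0.75]}
    )
    return out


class BrownianModel:
    """Brownian trait model over a collection of candidate trees.

    Parameters
    ----------
    traits
        DataFrame indexed by species with one column (phylogenetic-signal
        model) or two columns (correlation model).
    trees
        Sequence of dendropy trees or precomputed :class:`PhyloCovariance`
        objects, all covering every species in ``traits``.
    rho
        ``"free"`` to sample the evolutionary correlation, or a fixed number
        (``0`` for the uncorrelated null).  Ignored for one trait.
    lam
        ``"free"`` to sample Pagel's lambda, or a fixed value in [0, 1].
    standardize
        Z-standardise each trait before sampling (default).  rho and lambda
        are invariant to this affine rescaling; it keeps the vague priors
        and proposal steps on a common scale.
    """

    def __init__(self, traits: pd.DataFrame, trees, *, rho="free", lam="free",
                 standardize: bool = True):
        if isinstance(traits, pd.Series):
            traits = traits.to_frame()
        self.species = list(traits.index.astype(str))
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in trait table")
        if len(self.species) < 3:
            raise ValueError("need at least 3 species")
        X = traits.to_numpy(dtype=float)
        if X.ndim != 2 or X.shape[1] not in (1, 2):
            raise ValueError("traits must have one or two columns")
        if not np.all(np.isfinite(X)):
            raise ValueError("traits contain non-finite values")
        self.trait_names = list(traits.columns.astype(str))
        self.n, self.p = X.shape

        self._scale_mean = X.mean(axis=0)
        self._scale_sd = X.std(axis=0, ddof=1)
        if np.any(self._scale_sd == 0):
            raise ValueError("a trait has zero variance")
        self.X = (X - self._scale_mean) / self._scale_sd if standardize else X.copy()
        self.standardize = standardize

        self.covariances: list[np.ndarray] = []
        for t in trees:
            cov = t if isinstance(t, PhyloCovariance) else phylo_covariance(t)
            cov = cov.reorder(self.species)
            # normalize to unit mean root-to-tip distance: the transforms
            # produce trees of very different depths (unit/pagel scale with
            # the number of levels, Grafen/Nee are scaled to height 1), and
            # lambda and rho are invariant to this overall factor.  A common
            # scale lets one sigma^2 fit every tree in the collection.
            m = cov.matrix
            self.covariances.append(m / float(np.mean(np.diag(m))))
        if not self.covariances:
            raise ValueError("need at least one tree")

        if self.p == 1:
            rho = 0.0
        self.rho_spec = rho
        self.lam_spec = lam
        self._build_parameterisation()
        self._build_likelihood_cache()

    # -- parameter bookkeeping ---------------------------------------------
    def _build_parameterisation(self) -> None:
        m = self.X.mean(axis=0)
        s = self.X.std(axis=0, ddof=1)
        names, lo, hi, init, step = [], [], [], [], []
        for k in range(self.p):
            names.append(f"alpha{k + 1}")
            lo.append(m[k] - 10 * s[k])
            hi.append(m[k] + 10 * s[k])
            init.append(m[k])
            step.append(0.3 * s[k])
        for k in range(self.p):
            names.append(f"log_sigma{k + 1}")
            lo.append(np.log(s[k]) - 8.0)
            hi.append(np.log(s[k]) + 4.0)
            init.append(np.log(s[k]))
            step.append(0.3)
        if self.p == 2 and self.rho_spec == "free":
            names.append("rho")
            lo.append(-1.0 + 1e-9)
            hi.append(1.0 - 1e-9)
            init.append(0.0)
            step.append(0.2)
        if self.lam_spec == "free":
            names.append("lambda")
            lo.append(0.0)
            hi.append(1.0)
            init.append(0.5)
            step.append(0.2)
        self.param_names = names
        self._lo = np.array(lo)
        self._hi = np.array(hi)
        self._init = np.array(init)
        self._step0 = np.array(step)

    #: resolution of the lambda grid used to cache Cholesky cross-products
    LAMBDA_GRID_SIZE = 201

    def _build_likelihood_cache(self) -> None:
        """Precompute, per tree and lambda grid point, the sufficient pieces.

        For fixed tree and lambda the log-likelihood depends on the data only
        through log|C_lambda| and the cross-products of [X, 1] whitened by
        C_lambda; caching those makes each MCMC iteration O(1) regardless of
        the number of species, which is what allows million-iteration chains.
        Lambda is evaluated on a grid of 201 points (step 0.005), well below
        the two decimals at which posterior summaries are reported.
        """
        from .brownian import _chol
        from scipy.linalg import solve_triangular

        if self.lam_spec == "free":
            self._lambda_grid = np.linspace(0.0, 1.0, self.LAMBDA_GRID_SIZE)
        else:
            self._lambda_grid = np.array([float(self.lam_spec)])
        A = np.column_stack([self.X, np.ones(self.n)])
        self._cache_logdet = np.empty((len(self.covariances), len(self._lambda_grid)))
        self._cache_G = np.empty(
            (len(self.covariances), len(self._lambda_grid), self.p + 1, self.p + 1)
        )
        for ti, C in enumerate(self.covariances):
            d = np.diag(C).copy()
            for gi, lam in enumerate(self._lambda_grid):
                Cl = C * lam
                np.fill_diagonal(Cl, d)
                L = _chol(Cl)
                self._cache_logdet[ti, gi] = 2.0 * float(np.sum(np.log(np.diag(L))))
                Z = solve_triangular(L, A, lower=True, check_finite=False)
                self._cache_G[ti, gi] = Z.T @ Z

    def _grid_index(self, lam: float) -> int:
        if len(self._lambda_grid) == 1:
            return 0
        return int(round(lam * (self.LAMBDA_GRID_SIZE - 1)))

    def _unpack(self, theta: np.ndarray) -> BMParams:
        i = 0
        alpha = tuple(theta[i : i + self.p]); i += self.p
        rate = tuple(np.exp(2.0 * theta[i : i + self.p])); i += self.p
        if self.p == 2 and self.rho_spec == "free":
            rho = float(theta[i]); i += 1
        else:
            rho = 0.0 if self.rho_spec == "free" else float(self.rho_spec)
        lam = float(theta[i]) if self.lam_spec == "free" else float(self.lam_spec)
        return BMParams(ancestral_mean=alpha, rate=rate, rho=rho, lam=lam)

    def loglike(self, theta: np.ndarray, tree_index: int = 0) -> float:
        """Cached log-likelihood (lambda snapped to the cache grid)."""
        i = 0
        alpha = theta[i : i + self.p]; i += self.p
        log_sig = theta[i : i + self.p]; i += self.p
        if self.p == 2 and self.rho_spec == "free":
            rho = float(theta[i]); i += 1
        else:
            rho = 0.0 if self.rho_spec == "free" else float(self.rho_spec)
        lam = float(theta[i]) if self.lam_spec == "free" else float(self.lam_spec)

        gi = self._grid_index(lam)
        logdet_C = self._cache_logdet[tree_index, gi]
        G = self._cache_G[tree_index, gi]
        n, p = self.n, self.p
        # R' C^-1 R from the cached cross-products, R = X - 1 alpha'
        Gxx = G[:p, :p]
        Gx1 = G[:p, p]
        g11 = G[p, p]
        M = Gxx - np.outer(Gx1, alpha) - np.outer(alpha, Gx1) + g11 * np.outer(alpha, alpha)
        if p == 1:
            s2 = float(np.exp(2.0 * log_sig[0]))
            logdet_S = np.log(s2)
            quad = float(M[0, 0]) / s2
        else:
            s1, s2_ = float(np.exp(log_sig[0])), float(np.exp(log_sig[1]))
            det = (s1 * s2_) ** 2 * (1.0 - rho * rho)
            if det <= 0:
                return -np.inf
            logdet_S = np.log(det)
            # explicit 2x2 inverse of Sigma
            i11 = s2_ * s2_ / det
            i22 = s1 * s1 / det
            i12 = -rho * s1 * s2_ / det
            quad = i11 * M[0, 0] + i22 * M[1, 1] + 2.0 * i12 * M[0, 1]
        return -0.5 * (n * p * _LOG_2PI + p * logdet_C + n * logdet_S + quad)

    def _mixture_loglike(self, theta: np.ndarray, weights: bool = False):
        """Likelihood under the uniform mixture over the tree collection.

        Treating the candidate trees as a uniform prior over branch-length
        assignments and marginalizing the tree index analytically gives the
        arithmetic-mixture likelihood; sampling on it is exact (Rao-
        Blackwellized over trees) and far better behaved than carrying the
        tree in the chain state, because tree switches need no uphill move.
        With ``weights=True`` also returns the conditional posterior
        probability of each tree given ``theta``.
        """
        vals = np.array(
            [self.loglike(theta, t) for t in range(len(self.covariances))]
        )
        total = logsumexp(vals)
        mix = float(total - np.log(len(vals)))
        if not weights:
            return mix
        w = np.exp(vals - total)
        return mix, w / w.sum()

    def loglike_direct(self, theta: np.ndarray, tree_index: int = 0) -> float:
        """Uncached likelihood via the full Cholesky route (cross-check path)."""
        params = self._unpack(theta)
        C = lambda_scaled_matrix(self.covariances[tree_index], params.lam)
        try:
            return bm_loglik(self.X, params, C)
        except np.linalg.LinAlgError:
            return -np.inf

    # -- sampling ----------------------------------------------------------
    def fit(
        self,
        n_iter: int = DEFAULT_SCHEDULE[0],
        burn_in: int = DEFAULT_SCHEDULE[1],
        thin: int = DEFAULT_SCHEDULE[2],
        seed: int | None = None,
        tune: bool = True,
    ) -> "BrownianResults":
        """Run the random-walk Metropolis sampler.

        One randomly chosen free parameter is perturbed per iteration, and a
        tree is drawn uniformly from the collection as part of the same
        proposal.  Step sizes are adapted toward a 20-40% acceptance rate
        during burn-in and frozen afterwards.  Retained draws are every
        ``thin``-th post-burn-in state.
        """
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        rng = np.random.default_rng(seed)
        n_trees = len(self.covariances)
        n_par = len(self.param_names)
        step = self._step0.copy()

        theta = self._init.copy()
        logL, tree_w = self._mixture_loglike(theta, weights=True)
        for _ in range(20):
            if np.isfinite(logL):
                break
            theta = self._init + 0.1 * rng.standard_normal(n_par) * self._step0
            theta = np.clip(theta, self._lo, self._hi)
            logL, tree_w = self._mixture_loglike(theta, weights=True)
        if not np.isfinite(logL):
            raise RuntimeError("could not find a finite-likelihood start point")

        n_keep = (n_iter - burn_in) // thin
        records = np.empty((n_keep, n_par + 3))  # + tree, logL, iteration
        kept = 0
        acc_window = np.zeros(n_par)
        try_window = np.zeros(n_par)
        n_accept = 0
        tree_weight_total = np.zeros(n_trees)

        for i in range(1, n_iter + 1):
            k = int(rng.integers(n_par))
            prop = theta.copy()
            prop[k] += step[k] * rng.standard_normal()
            prop[k] = _reflect(prop[k], self._lo[k], self._hi[k])
            try_window[k] += 1
            if self._lo[k] <= prop[k] <= self._hi[k]:
                logL_new, tree_w_new = self._mixture_loglike(prop, weights=True)
                if np.log(rng.uniform()) < logL_new - logL:
                    theta, logL, tree_w = prop, logL_new, tree_w_new
                    n_accept += 1
                    acc_window[k] += 1
            tree_weight_total += tree_w

            if tune and i <= burn_in and i % 200 == 0:
                with np.errstate(invalid="ignore"):
                    rate = np.where(try_window > 0, acc_window / np.maximum(try_window, 1), 0.3)
                step = np.where(rate > 0.4, step * 1.4, step)
                step = np.where(rate < 0.2, step * 0.7, step)
                # keep proposals local: a step beyond a fraction of the prior
                # range degenerates into an independence sampler
                step = np.clip(step, 1e-4 * (self._hi - self._lo),
                               0.25 * (self._hi - self._lo))
                acc_window[:] = 0
                try_window[:] = 0

            if i > burn_in and (i - burn_in) % thin == 0 and kept < n_keep:
                records[kept, :n_par] = theta
                # tree index drawn from its conditional posterior p(T | theta)
                records[kept, n_par] = rng.choice(n_trees, p=tree_w)
                records[kept, n_par + 1] = logL
                records[kept, n_par + 2] = i
                kept += 1

        cols = self.param_names + ["tree_index", "logL", "iteration"]
        raw = pd.DataFrame(records[:kept], columns=cols)
        samples = self._natural_scale(raw)
        return BrownianResults(
            model=self,
            samples=samples,
            n_iterations=n_iter,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            acceptance_rate=n_accept / n_iter,
            tree_weights=(tree_weight_total / n_iter).round(4).tolist(),
            step_sizes=step.tolist(),
        )

    def _natural_scale(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Convert sampled (alpha, log sigma) into reporting columns.

        Constrained parameters are included as constant columns so that
        every result exposes the same schema.
        """
        out = pd.DataFrame(index=raw.index)
        for k in range(self.p):
            out[f"alpha{k + 1}"] = raw[f"alpha{k + 1}"]
            out[f"sigma2_{k + 1}"] = np.exp(2.0 * raw[f"log_sigma{k + 1}"])
        if self.p == 2:
            out["rho"] = raw["rho"] if self.rho_spec == "free" else float(self.rho_spec)
        out["lambda"] = raw["lambda"] if self.lam_spec == "free" else float(self.lam_spec)
        out["tree_index"] = raw["tree_index"].astype(int)
        out["logL"] = raw["logL"]
        out["iteration"] = raw["iteration"].astype(int)
        return out


@dataclass
class BrownianResults:
    """Posterior summary of a fitted :class:`BrownianModel`."""

    model: BrownianModel
    samples: pd.DataFrame
    n_iterations: int
    burn_in: int
    thin: int
    seed: int | None
    acceptance_rate: float
    tree_weights: list[float] = field(default_factory=list)  # mean posterior weight per tree
    step_sizes: list[float] = field(default_factory=list)

    _PARAM_COLS = ("rho", "lambda", "alpha1", "alpha2", "sigma2_1", "sigma2_2")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def harmonic_mean_logL(self) -> float:
        return harmonic_mean_logL(self.samples["logL"].to_numpy())

    def param_samples(self) -> pd.DataFrame:
        cols = [c for c in self._PARAM_COLS if c in self.samples.columns]
        return self.samples[cols]

    def posterior_summary(self) -> pd.DataFrame:
        return summarize_posterior(self.param_samples())

    def median(self, name: str) -> float:
        return float(self.samples[name].median())

    def quartiles(self, name: str) -> tuple[float, float]:
        col = self.samples[name]
        return float(col.quantile(0.25)), float(col.quantile(0.75))

    def compare(self, simpler: "BrownianResults") -> tuple[float, str]:
        """Log Bayes factor of this (main) model over a constrained one."""
        return log_bayes_factor(self, simpler)

    def summary(self) -> str:
        lines = [
            "Brownian trait model (random-walk Metropolis over tree collection)",
            f"  species: {self.model.n}   traits: {', '.join(self.model.trait_names)}",
            f"  iterations: {self.n_iterations:,}  burn-in: {self.burn_in:,}  "
            f"thin: {self.thin}  retained: {self.n_samples}",
            f"  seed: {self.seed}  acceptance rate: {self.acceptance_rate:.3f}",
            f"  posterior tree weights: {self.tree_weights}",
            f"  harmonic-mean log marginal likelihood: {self.harmonic_mean_logL:.3f}",
            "",
            "  parameter   median     q25      q75",
        ]
        summ = self.posterior_summary()
        for name, row in summ.iterrows():
            lines.append(
                f"  {name:<10} {row['median']:8.3f} {row['q25']:8.3f} {row['q75']:8.3f}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Write thinned draws (one row per retained sample)."""
        self.samples.to_csv(path, index=False)
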