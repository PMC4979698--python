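"""End-to-end orchestration: from raw tables to correlation/signal reports.

`run_full_analysis` reproduces the comparative workflow: fit and quality-
classify linear reaction norms per species x stage, deduplicate, compute
ordinary Pearson correlations between line parameters (slope vs lower
threshold for the variation pattern, elevation vs threshold for the
"warmer is better" question), the intersection-abscissa statistics, and the
Bayesian phylogenetically informed analogues -- Pagel's lambda for each
trait, for the correlation residuals and for the median intersection
abscissas, and the evolutionary correlations themselves -- with each model
contrast evaluated by a two-run log Bayes factor.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import reaction_norms as rn
from . import intersections as ix
from .mcmc import (
    BrownianModel,
    DEFAULT_SCHEDULE,
    FAST_SCHEDULE,
    log_bayes_factor,
)
from .trees import (
    BRANCH_LENGTH_METHODS,
    phylo_covariance,
    prune_to_species,
    read_newick,
    tip_labels,
    transform_branch_lengths,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "ordinary_correlation",
    "run_full_analysis",
]

logger = logging.getLogger("thermnorm")

TRAIT_COLUMNS = ("slope_b", "ltt", "elevation")
CORRELATION_PAIRS = (("slope_b", "ltt"), ("elevation", "ltt"))


def ordinary_correlation(x, y) -> tuple[float, float]:
    """Ordinary Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs and knobs of one full comparative analysis."""

    development_csv: str
    tree_newick: str
    stages: tuple[str, ...] = rn.STAGES
    qualities: tuple[str, ...] = ("good", "bad")
    mcmc_schedule: tuple[int, int, int] = DEFAULT_SCHEDULE
    n_repeats: int = 1
    seed: int = 0
    min_points: int = 3
    r2_target: float = rn.R2_GOOD_THRESHOLD
    run_phylo: bool = True

    @classmethod
    def fast(cls, development_csv, tree_newick, **kw):
        kw.setdefault("mcmc_schedule", FAST_SCHEDULE)
        return cls(str(development_csv), str(tree_newick), **kw)


@dataclass
class AnalysisReport:
    """Nested per-stage, per-quality results with full provenance."""

    config: dict
    stages: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"config": self.config, "stages": self.stages},
            indent=2,
            sort_keys=True,
            default=float,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def norms_table(self) -> pd.DataFrame:
        rows = []
        for stage, qualities in self.stages.items():
            for quality, cell in qualities.items():
                rows.append(
                    {
                        "stage": stage,
                        "quality": quality,
                        "n_species": cell["n_species"],
                        "mean_ltt": cell.get("mean_ltt"),
                        "r_slope_ltt": cell["ordinary"]["slope_b~ltt"]["r"],
                        "p_slope_ltt": cell["ordinary"]["slope_b~ltt"]["p"],
                        "r_elevation_ltt": cell["ordinary"]["elevation~ltt"]["r"],
                        "p_elevation_ltt": cell["ordinary"]["elevation~ltt"]["p"],
                    }
                )
        return pd.DataFrame(rows)

    def lambda_table(self) -> pd.DataFrame:
        """Phylogenetic-signal table: lambda per trait / residual / abscissa."""
        rows = []
        for stage, qualities in self.stages.items():
            for quality, cell in qualities.items():
                for key, est in cell.get("phylo", {}).get("lambda", {}).items():
                    rows.append(
                        {"stage": stage, "quality": quality, "target": key, **est}
                    )
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        """Phylogenetically informed correlation table."""
        rows = []
        for stage, qualities in self.stages.items():
            for quality, cell in qualities.items():
                for key, est in cell.get("phylo", {}).get("correlation", {}).items():
                    rows.append(
                        {"stage": stage, "quality": quality, "pair": key, **est}
                    )
        return pd.DataFrame(rows)

    def write_tables(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_json(out / "report.json")
        self.norms_table().to_csv(out / "ordinary_statistics.csv", index=False)
        lt = self.lambda_table()
        if not lt.empty:
            lt.to_csv(out / "phylo_lambda.csv", index=False)
        ct = self.correlation_table()
        if not ct.empty:
            ct.to_csv(out / "phylo_correlation.csv", index=False)


def _posterior_cell(results, param: str) -> dict:
    q25, q75 = results.quartiles(param)
    return {
        "median": results.median(param),
        "q25": q25,
        "q75": q75,
        "n_samples": results.n_samples,
        "seed": results.seed,
        "acceptance_rate": round(results.acceptance_rate, 4),
    }


def _fit_repeats(model: BrownianModel, schedule, seeds) -> list:
    n_iter, burn_in, thin = schedule
    return [
        model.fit(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=int(s))
        for s in seeds
    ]


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the whole comparative analysis described by ``config``."""
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    series = rn.read_development_csv(config.development_csv)
    base_tree = read_newick(config.tree_newick)
    tree_species = set(tip_labels(base_tree))

    report = AnalysisReport(config=asdict(config))
    for stage in config.stages:
        stage_series = [s for s in series if s.stage == stage]
        if not stage_series:
            continue
        records = rn.fit_all_series(
            stage_series, min_points=config.min_points, r2_target=config.r2_target
        )
        stage_out: dict = {}
        for quality in config.qualities:
            norms = [
                nm
                for _, nm in records
                if nm.quality == quality and nm.usable
            ]
            if len(norms) < 3:
                logger.info("stage %s/%s: only %d usable norms; skipped",
                            stage, quality, len(norms))
                continue
            stage_out[quality] = _analyse_cell(
                norms, base_tree, tree_species, config, rng, stage, quality
            )
        if stage_out:
            report.stages[stage] = stage_out
    logger.info("full analysis finished in %.1f s", time.time() - t0)
    return report


def _analyse_cell(norms, base_tree, tree_species, config, rng, stage, quality) -> dict:
    traits = rn.norms_to_frame(norms).set_index("species_id")
    cell: dict = {"n_species": int(len(norms)), "seed": int(config.seed)}
    cell["mean_ltt"] = float(traits["ltt"].mean())

    cell["ordinary"] = {}
    for xcol, ycol in CORRELATION_PAIRS:
        r, p = ordinary_correlation(traits[xcol], traits[ycol])
        cell["ordinary"][f"{xcol}~{ycol}"] = {"r": r, "p": p, "n": int(len(traits))}

    medians, n_excluded = ix.median_abscissas_per_line(norms)
    summary = ix.stage_mean_intersection(medians, n_pairs_excluded=n_excluded)
    abscissas = ix.all_pairwise_abscissas(norms)
    cell["intersections"] = {
        "stage_mean": summary.stage_mean,
        "ks_p": summary.ks_p,
        "normality_ok": summary.normality_ok,
        "n_lines": len(medians),
        "n_pairs_excluded": summary.n_pairs_excluded,
        "fraction_outside_15_30": ix.fraction_outside_range(abscissas)
        if abscissas
        else None,
    }

    if not config.run_phylo:
        return cell

    present = [s for s in traits.index if s in tree_species]
    absent = sorted(set(traits.index) - tree_species)
    if absent:
        warnings.warn(
            f"{stage}/{quality}: species absent from tree, excluded: {absent}"
        )
        cell["species_not_in_tree"] = absent
    if len(present) < 4:
        logger.info("stage %s/%s: too few species on tree for MCMC", stage, quality)
        return cell
    traits = traits.loc[present]
    medians_present = {s: medians[s] for s in present if s in medians}

    pruned = prune_to_species(base_tree, present)
    covs = [
        phylo_covariance(transform_branch_lengths(pruned, m))
        for m in BRANCH_LENGTH_METHODS
    ]
    schedule = config.mcmc_schedule
    seeds = lambda: rng.integers(2**31 - 1, size=config.n_repeats)  # noqa: E731

    phylo: dict = {"lambda": {}, "correlation": {}, "log_bayes_factors": {}}

    # -- Pagel's lambda in each trait (univariate model), free vs fixed 0
    for colname in TRAIT_COLUMNS:
        tr = traits[[colname]]
        free = _fit_repeats(BrownianModel(tr, covs, lam="free"), schedule, seeds())
        null = _fit_repeats(BrownianModel(tr, covs, lam=0.0), schedule, seeds())
        bf, cat = log_bayes_factor(free[0], null[0])
        phylo["lambda"][colname] = {
            **_posterior_cell(free[0], "lambda"),
            "log_bf_vs_lambda0": bf,
            "evidence": cat,
            "repeat_medians": [r.median("lambda") for r in free],
        }

    # -- lambda in the median intersection abscissas (trait, not residual)
    if len(medians_present) >= 4:
        med_tr = pd.DataFrame(
            {"median_abscissa": pd.Series(medians_present)}
        )
        if med_tr["median_abscissa"].std() > 0:
            free = _fit_repeats(
                BrownianModel(med_tr, covs, lam="free"), schedule, seeds()
            )
            null = _fit_repeats(
                BrownianModel(med_tr, covs, lam=0.0), schedule, seeds()
            )
            bf, cat = log_bayes_factor(free[0], null[0])
            phylo["lambda"]["median_abscissa"] = {
                **_posterior_cell(free[0], "lambda"),
                "log_bf_vs_lambda0": bf,
                "evidence": cat,
                "repeat_medians": [r.median("lambda") for r in free],
            }

    # -- evolutionary correlations: rho free vs rho = 0 (both lambda free),
    #    plus residual signal: lambda free vs lambda = 0 (both rho free)
    for xcol, ycol in CORRELATION_PAIRS:
        tr = traits[[xcol, ycol]]
        full = _fit_repeats(
            BrownianModel(tr, covs, rho="free", lam="free"), schedule, seeds()
        )
        rho0 = _fit_repeats(
            BrownianModel(tr, covs, rho=0.0, lam="free"), schedule, seeds()
        )
        lam0 = _fit_repeats(
            BrownianModel(tr, covs, rho="free", lam=0.0), schedule, seeds()
        )
        key = f"{xcol}~{ycol}"
        bf_rho, cat_rho = log_bayes_factor(full[0], rho0[0])
        bf_lam, cat_lam = log_bayes_factor(full[0], lam0[0])
        phylo["correlation"][key] = {
            **_posterior_cell(full[0], "rho"),
            "log_bf_vs_rho0": bf_rho,
            "evidence": cat_rho,
            "repeat_medians": [r.median("rho") for r in full],
        }
        phylo["lambda"][f"residual:{key}"] = {
            **_posterior_cell(full[0], "lambda"),
            "log_bf_vs_lambda0": bf_lam,
            "evidence": cat_lam,
        }
        phylo["log_bayes_factors"][key] = {
            "rho_free_vs_rho0": {"log_bf": bf_rho, "category": cat_rho},
            "lambda_free_vs_lambda0": {"log_bf": bf_lam, "category": cat_lam},
        }

    cell["phylo"] = phylo
    return cell
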