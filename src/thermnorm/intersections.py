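"""Pairwise intersection abscissas of linear thermal reaction norms.

Setting two fitted lines equal, a_i + b_i*T = a_j + b_j*T, gives the
temperature T* = (a_j - a_i)/(b_i - b_j) at which they cross.  Under the
common-intersection hypothesis all lines of a clade rotate around one pivot,
so every pairwise abscissa should coincide; under parallel shift the slopes
are equal and no intersections exist.  Abscissas are summarised per line by
their median (their raw distribution is skewed), and the per-line medians --
which are expected to be approximately normal -- by an arithmetic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reaction_norms import LinearNorm

__all__ = [
    "IntersectionSummary",
    "PARALLEL_SLOPE_TOL",
    "intersection_abscissa",
    "all_pairwise_abscissas",
    "median_abscissas_per_line",
    "stage_mean_intersection",
    "fraction_outside_range",
]

#: slopes closer than this (1/(day*degC)) are treated as parallel
PARALLEL_SLOPE_TOL = 1e-9


@dataclass(frozen=True)
class IntersectionSummary:
    """Average intersection point of a set of regression lines."""

    per_line_median: dict[str, float]  # species -> degC
    stage_mean: float  # degC, mean of the medians
    ks_p: float  # normality probability of the medians
    n_pairs_excluded: int  # parallel or degenerate pairs
    normality_ok: bool  # ks_p > 0.1


def intersection_abscissa(norm_i: LinearNorm, norm_j: LinearNorm) -> float | None:
    """Temperature at which two reaction norms cross, or None if parallel."""
    db = norm_i.slope_b - norm_j.slope_b
    if abs(db) < PARALLEL_SLOPE_TOL:
        return None
    return (norm_j.intercept_a - norm_i.intercept_a) / db


def all_pairwise_abscissas(norms: list[LinearNorm]) -> list[float]:
    """Flat list of the abscissas of every unordered pair that intersects."""
    out = []
    for i in range(len(norms)):
        for j in range(i + 1, len(norms)):
            t = intersection_abscissa(norms[i], norms[j])
            if t is not None:
                out.append(t)
    return out


def median_abscissas_per_line(
    all_norms: list[LinearNorm],
) -> tuple[dict[str, float], int]:
    """Median intersection abscissa of each line with every other line.

    Returns (species -> median degC, number of excluded parallel pairs).
    Lines with no valid intersection at all are dropped with a warning.
    """
    if len(all_norms) < 2:
        raise ValueError("need at least 2 lines to intersect")
    n = len(all_norms)
    per_line: dict[str, list[float]] = {nm.species_id: [] for nm in all_norms}
    n_excluded = 0
    for i in range(n):
        for j in range(i + 1, n):
            t = intersection_abscissa(all_norms[i], all_norms[j])
            if t is None:
                n_excluded += 1
            else:
                per_line[all_norms[i].species_id].append(t)
                per_line[all_norms[j].species_id].append(t)
    medians = {}
    for sp, vals in per_line.items():
        if not vals:
            warnings.warn(f"line {sp} has no valid intersections; excluded")
            continue
        medians[sp] = float(np.median(vals))
    return medians, n_excluded


def stage_mean_intersection(
    medians: dict[str, float],
    n_pairs_excluded: int = 0,
    lilliefors: bool = False,
) -> IntersectionSummary:
    """Arithmetic mean of per-line medians with a normality check.

    The one-sample Kolmogorov-Smirnov test is run against a normal with the
    sample mean and SD; ``lilliefors=True`` applies the Lilliefors correction
    for those estimated parameters instead.  A probability <= 0.1 flags that
    averaging the medians may be inappropriate.
    """
    if len(medians) < 3:
        raise ValueError(f"need >= 3 per-line medians, got {len(medians)}")
    vals = np.array(list(medians.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        ks_p = 1.0  # degenerate: all medians identical (common pivot)
    elif lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, ks_p = _lf(vals, dist="norm")
        ks_p = float(ks_p)
    else:
        ks_p = float(stats.kstest(vals, "norm", args=(mean, sd)).pvalue)
    return IntersectionSummary(
        per_line_median=dict(medians),
        stage_mean=mean,
        ks_p=ks_p,
        n_pairs_excluded=n_pairs_excluded,
        normality_ok=ks_p > 0.1,
    )


def fraction_outside_range(
    abscissas: list[float], low: float = 15.0, high: float = 30.0
) -> float:
    """Proportion of intersection abscissas outside [low, high] degC.

    Defaults to the 15-30 degC window most commonly covered by constant-
    temperature rearing experiments.
    """
    if len(abscissas) == 0:
        raise ValueError("empty abscissa list")
    arr = np.asarray(abscissas)
    return float(np.mean((arr < low) | (arr > high)))
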