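"""Linear thermal reaction norms for ectotherm development.

Mean development times D (days) at constant rearing temperatures T (degrees C)
are converted to developmental rates R = 1/D and regressed on temperature,
R = a + b*T, over the quasi-linear mid-temperature range.  Two parameters
describe the line -- the slope b (thermal sensitivity, 1/(day*degC)) and the
lower temperature threshold LTT = -a/b (extrapolated x-intercept where the
rate reaches zero).  The reciprocal slope SDD = 1/b is the sum of degree-days
(physiological time), and the elevation is the mean rate across the retained
temperature regimens.  Series are split into "good" (r^2 >= 0.980) and "bad"
(r^2 <= 0.979) quality classes that are analysed separately downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegimenObservation",
    "StageSeries",
    "LinearNorm",
    "STAGES",
    "R2_GOOD_THRESHOLD",
    "TEMP_MATCH_TOL",
    "pool_sexes",
    "to_rates",
    "truncate_to_linear",
    "fit_linear",
    "derive_elevation",
    "classify_quality",
    "dedup_species",
    "read_development_csv",
    "norms_to_frame",
    "fit_all_series",
]

STAGES = ("egg", "larva", "pupa", "total")

#: empirical goodness-of-fit split between high- and low-quality regressions
R2_GOOD_THRESHOLD = 0.980

#: tolerance (degrees C) when matching temperature grids between series
TEMP_MATCH_TOL = 1e-6


@dataclass(frozen=True)
class RegimenObservation:
    """Mean development time at one constant temperature regimen."""

    temperature: float  # degrees C
    dev_time: float  # days, mean development time
    n: int | None = None  # individuals behind the mean, if reported
    sex: str | None = None  # {male, female, pooled} or None

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        if not (self.dev_time > 0):
            raise ValueError(f"dev_time must be > 0, got {self.dev_time}")
        if self.n is not None and self.n < 1:
            raise ValueError(f"n must be >= 1 when present, got {self.n}")


@dataclass(frozen=True)
class StageSeries:
    """All temperature regimens for one species x developmental stage."""

    species_id: str
    stage: str
    observations: tuple[RegimenObservation, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        obs = tuple(sorted(self.observations, key=lambda o: o.temperature))
        temps = [o.temperature for o in obs]
        for t0, t1 in zip(temps, temps[1:]):
            if t1 - t0 <= TEMP_MATCH_TOL:
                raise ValueError(
                    f"duplicate temperature {t1} in series {self.species_id}/{self.stage}"
                )
        object.__setattr__(self, "observations", obs)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([o.temperature for o in self.observations])

    @property
    def dev_times(self) -> np.ndarray:
        return np.array([o.dev_time for o in self.observations])

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class LinearNorm:
    """A fitted linear thermal reaction norm and its derived parameters.

    ``ltt`` and ``sdd`` are ``nan`` when the slope is non-positive; such
    records are excluded from correlation and intersection analyses.
    """

    species_id: str
    stage: str
    intercept_a: float  # 1/day
    slope_b: float  # 1/(day*degC)
    ltt: float  # degrees C, -a/b
    sdd: float  # degree-days, 1/b
    elevation: float  # 1/day, mean rate over retained regimens
    r_squared: float
    quality: str  # {good, bad}
    temps_used: tuple[float, ...]
    source_id: str = ""

    @property
    def usable(self) -> bool:
        """True when slope is positive so LTT and SDD are defined."""
        return self.slope_b > 0 and math.isfinite(self.ltt)

    def rate_at(self, temperature: float) -> float:
        return self.intercept_a + self.slope_b * temperature


def pool_sexes(male_series: StageSeries, female_series: StageSeries) -> StageSeries:
    """Pool male and female series into one, per temperature regimen.

    Uses the n-weighted mean of development times when both sample sizes are
    reported, otherwise the simple mean.  Both series must share species,
    stage and temperature grid.
    """
    if male_series.species_id != female_series.species_id:
        raise ValueError("cannot pool series from different species")
    if male_series.stage != female_series.stage:
        raise ValueError("cannot pool series from different stages")
    mt, ft = male_series.temperatures, female_series.temperatures
    if len(mt) != len(ft):
        raise ValueError(
            f"temperature grids differ in length ({len(mt)} vs {len(ft)})"
        )
    mismatch = np.abs(mt - ft) > TEMP_MATCH_TOL
    if mismatch.any():
        raise ValueError(
            f"temperature grids differ: {mt[mismatch][0]} vs "
            f"{ft[mismatch][0]} degC"
        )

    pooled = []
    for om, of in zip(male_series.observations, female_series.observations):
        if om.n is not None and of.n is not None:
            d = (om.dev_time * om.n + of.dev_time * of.n) / (om.n + of.n)
            n: int | None = om.n + of.n
        else:
            d = 0.5 * (om.dev_time + of.dev_time)
            n = None
        pooled.append(RegimenObservation(om.temperature, d, n=n, sex="pooled"))
    return replace(male_series, observations=tuple(pooled))


def to_rates(series: StageSeries) -> list[tuple[float, float]]:
    """Transform development times into rates R = 1/D, order preserved."""
    return [(o.temperature, 1.0 / o.dev_time) for o in series.observations]


def _ols(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Closed-form OLS of rate on temperature: (a, b, r_squared)."""
    t = np.array([p[0] for p in points], dtype=float)
    r = np.array([p[1] for p in points], dtype=float)
    tbar, rbar = t.mean(), r.mean()
    sxx = np.sum((t - tbar) ** 2)
    sxy = np.sum((t - tbar) * (r - rbar))
    syy = np.sum((r - rbar) ** 2)
    b = sxy / sxx
    a = rbar - b * tbar
    r2 = 1.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return a, b, float(min(r2, 1.0))


def fit_linear(
    points: Sequence[tuple[float, float]],
    *,
    species_id: str = "",
    stage: str = "total",
    source_id: str = "",
) -> LinearNorm:
    """Fit R = a + b*T by ordinary least squares and derive LTT and SDD.

    A non-positive slope leaves LTT/SDD undefined (nan); the record is kept
    but flagged unusable for threshold-based analyses.
    """
    temps = sorted({p[0] for p in points})
    if len(points) < 3 or len(temps) < 3:
        raise ValueError("need at least 3 points at 3 distinct temperatures")
    a, b, r2 = _ols(points)
    if b > 0:
        ltt = -a / b
        sdd = 1.0 / b
    else:
        ltt = float("nan")
        sdd = float("nan")
    elevation = float(np.mean([p[1] for p in points]))
    return LinearNorm(
        species_id=species_id,
        stage=stage,
        intercept_a=a,
        slope_b=b,
        ltt=ltt,
        sdd=sdd,
        elevation=elevation,
        r_squared=r2,
        quality=classify_quality(r2),
        temps_used=tuple(temps),
        source_id=source_id,
    )


def derive_elevation(
    norm: LinearNorm, points: Sequence[tuple[float, float]]
) -> float:
    """Elevation: arithmetic mean of the observed rates over retained regimens."""
    if len(points) == 0:
        raise ValueError("cannot derive elevation from zero regimens")
    return float(np.mean([p[1] for p in points]))


def classify_quality(r_squared: float) -> str:
    """Split regressions at the empirical r^2 = 0.980 goodness-of-fit gate."""
    if not (0.0 <= r_squared <= 1.0 + 1e-12):
        raise ValueError(f"r_squared outside [0, 1]: {r_squared}")
    return "good" if r_squared >= R2_GOOD_THRESHOLD else "bad"


def truncate_to_linear(
    series: StageSeries,
    min_points: int = 3,
    r2_target: float = R2_GOOD_THRESHOLD,
) -> StageSeries:
    """Truncate a series to its linear mid-temperature window.

    The full reaction norm is sigmoid: rates flatten near the thermal limits.
    Only extreme (end) temperatures may be dropped.  All contiguous windows of
    at least ``min_points`` temperatures are enumerated; among windows whose
    OLS fit reaches ``r2_target`` the longest is kept (ties broken by higher
    r^2).  If no window reaches the target the full series is returned -- it
    will fall into the "bad" quality class rather than being discarded.
    """
    n = len(series)
    if n < min_points:
        raise ValueError(
            f"series {series.species_id}/{series.stage} has {n} temperatures; "
            f"needs >= {min_points}"
        )
    pts = to_rates(series)
    best: tuple[int, float, int, int] | None = None  # (length, r2, start, stop)
    for start in range(n):
        for stop in range(start + min_points, n + 1):
            window = pts[start:stop]
            _, _, r2 = _ols(window)
            if r2 >= r2_target:
                key = (stop - start, r2, start, stop)
                if best is None or key[:2] > best[:2]:
                    best = key
    if best is None:
        return series
    _, _, start, stop = best
    return replace(series, observations=series.observations[start:stop])


def dedup_species(
    records: Iterable[tuple[StageSeries, LinearNorm]],
) -> list[tuple[StageSeries, LinearNorm]]:
    """Keep one record per species x stage within each quality class.

    Higher r^2 wins; exact ties fall to the record with more temperatures,
    then to first occurrence in input order.  Good and bad classes are
    deduplicated independently (their species lists may overlap).
    """
    best: dict[tuple[str, str, str], tuple[tuple[float, int, int], tuple]] = {}
    for order, (series, norm) in enumerate(records):
        key = (norm.species_id, norm.stage, norm.quality)
        rank = (norm.r_squared, len(norm.temps_used), -order)
        if key not in best or rank > best[key][0]:
            best[key] = (rank, (series, norm))
    return [rec for _, rec in best.values()]


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = ["species_id", "stage", "source_id", "temperature_C", "dev_time_days"]


def read_development_csv(path) -> list[StageSeries]:
    """Read a development-time table into StageSeries records.

    Expected columns: species_id, stage, source_id, temperature_C,
    dev_time_days, and optionally n and sex.  Male/female rows sharing a
    temperature grid are pooled by weighted (or simple) means.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "n" not in df.columns:
        df["n"] = np.nan
    if "sex" not in df.columns:
        df["sex"] = None

    out: list[StageSeries] = []
    for (sp, stage, src), grp in df.groupby(
        ["species_id", "stage", "source_id"], sort=False
    ):
        sexes = {s for s in grp["sex"].dropna().unique()}
        if {"male", "female"} <= sexes:
            by_sex = {}
            for sex in ("male", "female"):
                sub = grp[grp["sex"] == sex]
                by_sex[sex] = StageSeries(
                    species_id=str(sp),
                    stage=str(stage),
                    observations=tuple(_rows_to_obs(sub)),
                    source_id=str(src),
                )
            out.append(pool_sexes(by_sex["male"], by_sex["female"]))
        else:
            out.append(
                StageSeries(
                    species_id=str(sp),
                    stage=str(stage),
                    observations=tuple(_rows_to_obs(grp)),
                    source_id=str(src),
                )
            )
    return out


def _rows_to_obs(df: pd.DataFrame) -> list[RegimenObservation]:
    obs = []
    for row in df.itertuples():
        n = None if pd.isna(row.n) else int(row.n)
        sex = None if pd.isna(row.sex) else str(row.sex)
        obs.append(
            RegimenObservation(
                temperature=float(row.temperature_C),
                dev_time=float(row.dev_time_days),
                n=n,
                sex=sex,
            )
        )
    return obs


def fit_all_series(
    series_list: Iterable[StageSeries],
    min_points: int = 3,
    r2_target: float = R2_GOOD_THRESHOLD,
) -> list[tuple[StageSeries, LinearNorm]]:
    """Truncate, fit and deduplicate every series; returns (series, norm) pairs."""
    fitted = []
    for series in series_list:
        trimmed = truncate_to_linear(series, min_points=min_points, r2_target=r2_target)
        norm = fit_linear(
            to_rates(trimmed),
            species_id=trimmed.species_id,
            stage=trimmed.stage,
            source_id=trimmed.source_id,
        )
        fitted.append((trimmed, norm))
    return dedup_species(fitted)


def norms_to_frame(norms: Iterable[LinearNorm]) -> pd.DataFrame:
    """Flatten LinearNorm records into a DataFrame (one row per record)."""
    rows = []
    for nm in norms:
        rows.append(
            {
                "species_id": nm.species_id,
                "stage": nm.stage,
                "source_id": nm.source_id,
                "intercept_a": nm.intercept_a,
                "slope_b": nm.slope_b,
                "ltt": nm.ltt,
                "sdd": nm.sdd,
                "elevation": nm.elevation,
                "r_squared": nm.r_squared,
                "quality": nm.quality,
                "n_temps": len(nm.temps_used),
            }
        )
    return pd.DataFrame(rows)
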