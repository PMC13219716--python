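"""Cross-species survey statistics for pavement-cell shape.

The survey asks two questions per species: (1) does lobeyness increase with
cell width (min-axis), quantified by a Pearson correlation classified at the
r >= 0.3 threshold; and (2) does the largest-empty-circle (LEC) grow more
slowly than cell size, quantified by the curvature sign of an
origin-constrained quadratic fit of LEC area against cell area.  The
curvature signs are aggregated over species with an exact two-sided binomial
test against the null that negative and positive curvature are equally
likely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError

R_THRESHOLD_DEFAULT = 0.3


def percentile_select(values: pd.Series | np.ndarray, q: float,
                      labels: np.ndarray | None = None):
    """Index (or label) of the nearest-rank q-th percentile member.

    The nearest-rank convention (the ceil(q/100 * n)-th order statistic)
    always selects an actual member, so the chosen cell's contour can be
    displayed; interpolating percentile definitions would return values that
    belong to no cell.  Ties are broken by label.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty group")
    if not 0 <= q <= 100:
        raise ValueError("percentile must be in [0, 100]")
    if labels is None:
        labels = (values.index.to_numpy() if isinstance(values, pd.Series)
                  else np.arange(len(v)))
    labels = np.asarray(labels)
    order = np.lexsort((labels, v))
    rank = max(math.ceil(q / 100.0 * len(v)), 1) - 1
    value = v[order[rank]]
    tied = labels[v == value]
    return tied.min()


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (flagged) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def classify_species(r: float, threshold: float = R_THRESHOLD_DEFAULT) -> str:
    """'moderate-high' for r at or above the threshold, else 'weak'.

    Undefined correlations (NaN) fall in an 'excluded' category.
    """
    if math.isnan(r):
        return "excluded"
    return "moderate-high" if r >= threshold else "weak"


def fit_quadratic_origin(x, y) -> tuple[float, float]:
    """Least squares for y = beta*x + alpha*x^2 constrained through the origin.

    Returns ``(beta, alpha)``; ``alpha < 0`` marks a concave-downward
    relation, i.e. y saturating as x grows.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise FitError("origin-constrained quadratic needs >= 2 distinct x values")
    design = np.column_stack([x, x**2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def binomial_sign_test(n_negative: int, n_total: int) -> float:
    """Exact two-sided binomial p-value at null probability 1/2.

    Two-sidedness doubles the smaller tail (capped at 1); at p = 1/2 this
    coincides with the minimum-likelihood definition by symmetry.
    """
    if not 0 <= n_negative <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_negative <= n_total, n_total >= 1")
    return float(stats.binomtest(n_negative, n_total, p=0.5,
                                 alternative="two-sided").pvalue)


def areal_strain(a1: float, a2: float) -> float:
    """Relative area increase (A2 - A1) / A1 between two time points."""
    if a1 <= 0:
        raise ValueError("initial area must be positive")
    return (a2 - a1) / a1


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species statistics feeding the survey aggregation."""

    species: str
    n_cells: int
    pearson_r: float           # min-axis vs lobeyness; NaN if undefined
    p95_lobeyness: float
    beta: float                # linear coefficient, LEC area vs cell area
    alpha: float               # quadratic coefficient (curvature sign)
    beta_daxis: float          # LEC diameter vs min-axis fit
    alpha_daxis: float
    classification: str


@dataclass(frozen=True)
class SurveyResult:
    n_species: int
    n_r_ge_threshold: int
    n_alpha_negative: int
    pct_r_ge_threshold: float
    pct_alpha_negative: float
    binomial_p: float
    n_excluded_r: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_species(metrics: pd.DataFrame,
                      r_threshold: float = R_THRESHOLD_DEFAULT,
                      percentile: float = 95.0) -> list[SpeciesSummary]:
    """Per-species statistics from a metrics table (one row per cell).

    Cells flagged as failed are excluded.  A species needs at least 3 cells
    for a correlation and 2 distinct sizes for the quadratic fits; species
    missing either are reported with NaN in the affected fields.
    """
    df = metrics
    if "failed" in df.columns:
        df = df[~df["failed"].astype(bool)]
    out: list[SpeciesSummary] = []
    for species, g in df.groupby("species", sort=True):
        n = len(g)
        r = float("nan")
        if n >= 3:
            r = pearson_r(g["min_axis_um"], g["lobeyness"])
        lob = g["lobeyness"].to_numpy()
        p95 = float(lob[percentile_select(lob, percentile)])
        lec_r = g["lec_radius_um"].to_numpy()
        beta = alpha = beta_d = alpha_d = float("nan")
        try:
            beta, alpha = fit_quadratic_origin(
                g["area_um2"], math.pi * lec_r**2)
            beta_d, alpha_d = fit_quadratic_origin(
                g["min_axis_um"], 2.0 * lec_r)
        except FitError:
            pass
        out.append(SpeciesSummary(
            species=str(species), n_cells=n, pearson_r=r, p95_lobeyness=p95,
            beta=beta, alpha=alpha, beta_daxis=beta_d, alpha_daxis=alpha_d,
            classification=classify_species(r, r_threshold)))
    return out


def survey(summaries: list[SpeciesSummary],
           r_threshold: float = R_THRESHOLD_DEFAULT,
           exclude_undefined: bool = False) -> SurveyResult:
    """Aggregate per-species summaries into the survey counts and test.

    ``exclude_undefined`` removes species with undefined correlations from
    the denominator; by default they stay in and count as 'weak'.  The
    binomial test is applied to the sign counts of the area-area curvature
    alpha over species with a defined fit.
    """
    if not summaries:
        raise ValueError("survey needs at least one species summary")
    n_excl = sum(1 for s in summaries if s.classification == "excluded")
    pool = [s for s in summaries if s.classification != "excluded"] \
        if exclude_undefined else summaries
    n_species = len(pool)
    n_r = sum(1 for s in pool if s.classification == "moderate-high")
    with_fit = [s for s in pool if not math.isnan(s.alpha)]
    n_neg = sum(1 for s in with_fit if s.alpha < 0)
    p = binomial_sign_test(n_neg, len(with_fit)) if with_fit else float("nan")
    return SurveyResult(
        n_species=n_species,
        n_r_ge_threshold=n_r,
        n_alpha_negative=n_neg,
        pct_r_ge_threshold=100.0 * n_r / n_species,
        pct_alpha_negative=100.0 * n_neg / max(len(with_fit), 1),
        binomial_p=p,
        n_excluded_r=n_excl,
    )


def survey_from_counts(n_r_ge: int, n_alpha_negative: int,
                       n_species: int) -> SurveyResult:
    """Survey result directly from headline counts (no per-cell data)."""
    return SurveyResult(
        n_species=n_species,
        n_r_ge_threshold=n_r_ge,
        n_alpha_negative=n_alpha_negative,
        pct_r_ge_threshold=100.0 * n_r_ge / n_species,
        pct_alpha_negative=100.0 * n_alpha_negative / n_species,
        binomial_p=binomial_sign_test(n_alpha_negative, n_species),
    )


def summaries_table(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])
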