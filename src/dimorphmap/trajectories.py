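"""Effect-size trajectories of dimorphic voxels, k-means clusters, growth rates.

For every voxel passing the dimorphism test at q < 0.1, the sex effect
size at each timepoint is the pooled-SD Cohen's d of the relative log
determinants,

    d = (mu_M - mu_F) * sqrt((n_M + n_F - 2) / (n_M s_M^2 + n_F s_F^2)),

with maximum-likelihood (divide-by-n) group variances, signed positive
when larger in males.  The voxels x timepoints matrix of d values is
clustered with k-means (k = 4 by default, mirroring the four
developmental trajectories; a within-cluster sum-of-squares curve over
k = 1..8 is emitted for the elbow diagnostic).  Growth rates come from
per-voxel, per-subject spline fits of determinant against age, with the
spline order chosen by AIC and the derivative taken analytically.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.cluster import KMeans

from .volumes import DeterminantField

__all__ = [
    "cohens_d",
    "effect_size_matrix",
    "EffectSizeMatrix",
    "ClusterResult",
    "cluster_trajectories",
    "fit_growth_spline",
    "growth_rate_curves",
    "cluster_summaries",
]


def cohens_d(male_values, female_values) -> float:
    """Pooled-SD standardized mean difference, positive = larger in males.

    Group variances are maximum-likelihood (divide by n), which makes the
    scaling factor sqrt((n1+n0-2)/(n1 s1^2 + n0 s0^2)) the classic pooled
    unbiased-variance Cohen's d.  Zero pooled variance yields signed
    infinity (NaN when the mean difference is also zero).
    """
    m = np.asarray(male_values, dtype=float)
    f = np.asarray(female_values, dtype=float)
    n1, n0 = m.size, f.size
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 values per sex")
    diff = m.mean() - f.mean()
    pooled = n1 * m.var() + n0 * f.var()
    if pooled == 0.0:
        return float(np.sign(diff) * np.inf) if diff != 0 else float("nan")
    return float(diff * np.sqrt((n1 + n0 - 2) / pooled))


@dataclasses.dataclass
class EffectSizeMatrix:
    """(voxels x timepoints) Cohen's d with voxel coordinates retained."""

    values: np.ndarray
    ages: np.ndarray
    voxel_coords: np.ndarray  # (n_voxels, 3)


def effect_size_matrix(fields: list[DeterminantField], dimorphic_mask: np.ndarray
                       ) -> EffectSizeMatrix:
    """Per-voxel, per-timepoint sex effect sizes over a dimorphic mask."""
    mask = np.asarray(dimorphic_mask, dtype=bool)
    coords = np.argwhere(mask)
    ages = np.array(sorted({f.age_days for f in fields}))
    out = np.empty((coords.shape[0], ages.size))
    for k, age in enumerate(ages):
        males = np.stack([f.values[mask] for f in fields
                          if f.age_days == age and f.sex == "M"], axis=0)
        females = np.stack([f.values[mask] for f in fields
                            if f.age_days == age and f.sex == "F"], axis=0)
        if males.shape[0] < 2 or females.shape[0] < 2:
            raise ValueError(f"timepoint {age}: need >= 2 scans per sex")
        n1, n0 = males.shape[0], females.shape[0]
        diff = males.mean(axis=0) - females.mean(axis=0)
        pooled = n1 * males.var(axis=0) + n0 * females.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, k] = diff * np.sqrt((n1 + n0 - 2) / pooled)
    return EffectSizeMatrix(values=out, ages=ages, voxel_coords=coords)


@dataclasses.dataclass
class ClusterResult:
    labels: np.ndarray            # per-voxel cluster label, 1..k
    centroids: np.ndarray         # (k, n_timepoints)
    inertia: float
    wss_curve: dict               # k -> within-cluster sum of squares


def cluster_trajectories(matrix: EffectSizeMatrix, k: int = 4, seed: int = 0,
                         n_init: int = 20, k_diagnostic: range = range(1, 9),
                         standardize: bool = False) -> ClusterResult:
    """k-means on effect-size time-series (Euclidean, best of n_init).

    Rows are not re-standardized by default: effect sizes are already
    dimensionless and share a scale across timepoints.  ``standardize``
    z-scores each row first (shape-only clustering).
    """
    X = np.asarray(matrix.values, dtype=float)
    if standardize:
        sd = X.std(axis=1, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    if X.shape[0] < k:
        raise ValueError(f"only {X.shape[0]} rows for k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    wss = {}
    for kk in k_diagnostic:
        if kk > X.shape[0]:
            break
        wss[kk] = float(KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
                        .fit(X).inertia_)
    # recompute centroids as exact member means (KMeans centers already are,
    # but this pins the contract)
    labels = km.labels_ + 1
    centroids = np.stack([X[labels == c].mean(axis=0) for c in range(1, k + 1)])
    return ClusterResult(labels=labels, centroids=centroids,
                         inertia=float(km.inertia_), wss_curve=wss)


def _spline_basis(df: int, ages: np.ndarray):
    """Knot vector and degree for the candidate spline of a given df.

    df counts coefficients beyond a constant: df=1 is linear, df=2
    quadratic, df=3 a full cubic; df=4,5 are cubic B-splines with one or
    two interior knots at age quantiles.  The basis is unconstrained (no
    boundary-linearity condition), so polynomial growth up to cubic order
    is representable exactly.
    """
    degree = min(df, 3)
    n_interior = df - degree
    lo, hi = float(ages.min()), float(ages.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(ages, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return t, degree


def fit_growth_spline(ages, values, candidate_df=range(1, 6)):
    """AIC-selected spline fit of one subject's series; returns (spline, df).

    AIC uses the Gaussian ML variance; ties break toward smaller df.  The
    returned object is a scipy BSpline whose ``derivative()`` is the exact
    analytic derivative of the fitted curve.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 observed timepoints")
    best = None
    for df in candidate_df:
        n_par = df + 1
        if n_par > ages.size:
            break
        t, degree = _spline_basis(df, ages)
        B = BSpline.design_matrix(ages, t, degree).toarray()
        coef, *_ = np.linalg.lstsq(B, values, rcond=None)
        rss = float(np.sum((values - B @ coef) ** 2))
        n = ages.size
        # floor at numerical precision so exact fits tie (broken toward small df)
        floor = n * (1e-10 * max(np.abs(values).max(), 1e-30)) ** 2
        aic = n * np.log(max(rss, floor) / n) + 2 * (n_par + 1)
        if best is None or aic < best[0] - 1e-9:
            best = (aic, df, BSpline(t, coef, degree))
    _, df_sel, spline = best
    return spline, df_sel


@dataclasses.dataclass
class GrowthRateCurves:
    """Fitted growth-rate (derivative) curves per voxel x subject."""

    age_grid: np.ndarray
    rates: np.ndarray          # (n_voxels, n_subjects, n_grid), NaN if skipped
    rates_at_ages: np.ndarray  # (n_voxels, n_subjects, n_timepoints)
    subjects: list
    sexes: list
    ages: np.ndarray
    selected_df: np.ndarray    # (n_voxels, n_subjects), -1 if skipped
    n_skipped: int = 0


def growth_rate_curves(fields: list[DeterminantField], mask: np.ndarray,
                       n_grid: int = 50, min_timepoints: int = 4) -> GrowthRateCurves:
    """Spline growth rates of the determinant at masked voxels, per subject."""
    mask = np.asarray(mask, dtype=bool)
    ages_all = np.array(sorted({f.age_days for f in fields}))
    subjects = sorted({f.mouse_id for f in fields})
    sex_of = {f.mouse_id: f.sex for f in fields}
    grid = np.linspace(ages_all.min(), ages_all.max(), n_grid)
    V = int(mask.sum())
    rates = np.full((V, len(subjects), n_grid), np.nan)
    rates_at = np.full((V, len(subjects), ages_all.size), np.nan)
    seldf = np.full((V, len(subjects)), -1, dtype=int)
    n_skipped = 0
    for si, subj in enumerate(subjects):
        scans = sorted((f.age_days, f) for f in fields if f.mouse_id == subj)
        ages = np.array([a for a, _ in scans])
        if ages.size < min_timepoints:
            n_skipped += 1
            continue
        series = np.stack([f.values[mask] for _, f in scans], axis=0)  # (T, V)
        for v in range(V):
            spline, df_sel = fit_growth_spline(ages, series[:, v])
            deriv = spline.derivative()
            rates[v, si] = deriv(grid)
            rates_at[v, si] = deriv(ages_all)
            seldf[v, si] = df_sel
    return GrowthRateCurves(age_grid=grid, rates=rates, rates_at_ages=rates_at,
                            subjects=subjects, sexes=[sex_of[s] for s in subjects],
                            ages=ages_all, selected_df=seldf, n_skipped=n_skipped)


@dataclasses.dataclass
class ClusterSummaries:
    volume_effect: pd.DataFrame        # cluster, age, mean Cohen's d (relative volume)
    growth_effect: pd.DataFrame | None  # cluster, age, mean Cohen's d (growth rate)
    per_subject: pd.DataFrame | None    # cluster, subject, sex, age, mean value


def cluster_summaries(result: ClusterResult, matrix: EffectSizeMatrix,
                      growth: GrowthRateCurves | None = None,
                      fields: list[DeterminantField] | None = None) -> ClusterSummaries:
    """Per-cluster mean trajectories (unweighted over member voxels)."""
    k = result.centroids.shape[0]
    rows = []
    for c in range(1, k + 1):
        members = result.labels == c
        if not members.any():
            raise ValueError(f"cluster {c} is empty")
        for j, age in enumerate(matrix.ages):
            rows.append((c, float(age), float(matrix.values[members, j].mean())))
    vol = pd.DataFrame(rows, columns=["cluster", "age_days", "effect_size"])

    growth_df = None
    if growth is not None:
        sexes = np.array(growth.sexes)
        rows = []
        for c in range(1, k + 1):
            members = result.labels == c
            for j, age in enumerate(growth.ages):
                male = growth.rates_at_ages[members][:, sexes == "M", j].mean(axis=0)
                female = growth.rates_at_ages[members][:, sexes == "F", j].mean(axis=0)
                male, female = male[np.isfinite(male)], female[np.isfinite(female)]
                d = cohens_d(male, female) if male.size >= 2 and female.size >= 2 else np.nan
                rows.append((c, float(age), float(d)))
        growth_df = pd.DataFrame(rows, columns=["cluster", "age_days", "effect_size"])

    per_subject = None
    if fields is not None:
        mask = np.zeros(fields[0].values.shape, dtype=bool)
        mask[tuple(matrix.voxel_coords.T)] = True
        rows = []
        for f in fields:
            vals = f.values[mask]
            for c in range(1, k + 1):
                rows.append((c, f.mouse_id, f.sex, f.age_days,
                             float(vals[result.labels == c].mean())))
        per_subject = pd.DataFrame(
            rows, columns=["cluster", "mouse_id", "sex", "age_days", "mean_value"])
    return ClusterSummaries(vol, growth_df, per_subject)
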