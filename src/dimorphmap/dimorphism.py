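"""Sex-dimorphism mapping with linear mixed-effects likelihood-ratio tests.

Structure level: volume (absolute or relative) is modelled with fixed
effects of sex, timepoint factor and their interaction plus a per-mouse
random intercept, and compared by LRT against the model without any sex
terms — with nine timepoints under treatment coding the test has Q = 9
degrees of freedom (sex main effect + eight interactions).

Voxel level: the relative log-determinant at each voxel is modelled with
sex, age (linear by default), their interaction and a random mouse
intercept, against the no-sex model (Q = 2); q-values are
Benjamini-Hochberg over the mask.  Age-centered variants translate the
age axis so the sex main effect reads out the sex difference at a chosen
age, with Satterthwaite p-values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import mixedlm
from .mixedlm import LRTResult, MixedModelFit
from .volumes import DeterminantField, validate_volume_table

__all__ = [
    "VoxelStatMap",
    "StructureTestResult",
    "TimingTable",
    "structure_response",
    "structure_sex_test",
    "structure_sex_lrt_batch",
    "earliest_dimorphic_timepoint",
    "voxelwise_sex_test",
    "age_centered_sex_map",
    "age_centered_maps",
    "variance_equality_ftest",
]


@dataclasses.dataclass
class VoxelStatMap:
    """Per-voxel statistic map with p- and q-values inside a mask."""

    statistic: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    mask: np.ndarray
    df: float
    model: str
    n_failed: int = 0

    def significant(self, q_threshold: float = 0.1) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.qvalues, nan=np.inf) < q_threshold


@dataclasses.dataclass
class StructureTestResult:
    structure: str
    response: str
    lrt: LRTResult
    fit_full: MixedModelFit
    fit_reduced: MixedModelFit
    bands: pd.DataFrame  # per (sex, age): modelled mean and standard error


@dataclasses.dataclass
class TimingTable:
    """Per-age sex-difference contrasts and the earliest significant age."""

    structure: str
    response: str
    table: pd.DataFrame  # age, estimate, se, tvalue, df, pvalue
    earliest_age: float | None


def structure_response(table: pd.DataFrame, structure: str, response: str) -> pd.DataFrame:
    """Rows for one structure with a 'y' column (absolute mm^3 or % brain)."""
    validate_volume_table(table)
    sub = table[table["structure"] == structure].copy()
    if sub.empty:
        raise ValueError(f"structure {structure!r} absent from the table")
    if response == "absolute":
        sub["y"] = sub["volume_mm3"]
    elif response == "relative":
        sub["y"] = 100.0 * sub["volume_mm3"] / sub["brain_volume_mm3"]
    else:
        raise ValueError("response must be 'absolute' or 'relative'")
    return sub


def _factor_design(sexes: np.ndarray, tp_idx: np.ndarray, n_tp: int):
    """Treatment-coded full/reduced designs for the structure-level test.

    Full: intercept, sex, timepoint dummies (earliest age = reference),
    sex x timepoint; reduced drops all sex terms.
    """
    s = (np.asarray(sexes) == "M").astype(float)
    n = s.size
    dummies = np.zeros((n, n_tp - 1))
    for k in range(1, n_tp):
        dummies[:, k - 1] = (tp_idx == k).astype(float)
    X_full = np.column_stack([np.ones(n), s, dummies, s[:, None] * dummies])
    X_reduced = np.column_stack([np.ones(n), dummies])
    return X_full, X_reduced


def structure_sex_test(table: pd.DataFrame, structure: str,
                       response: str = "absolute") -> StructureTestResult:
    """LRT for any effect of sex (main or interaction) on structure volume."""
    sub = structure_response(table, structure, response)
    if sub["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    tps = np.sort(sub["timepoint_index"].unique())
    if tps.size < 2:
        raise ValueError("need at least 2 timepoints")
    tp_map = {t: i for i, t in enumerate(tps)}
    tp_idx = sub["timepoint_index"].map(tp_map).to_numpy()
    X_full, X_red = _factor_design(sub["sex"].to_numpy(), tp_idx, tps.size)
    y = sub["y"].to_numpy()
    groups = sub["mouse_id"].to_numpy()
    fit_full = mixedlm.fit_lme_ml(y, X_full, groups, design_info="sex*timepoint + (1|mouse)")
    fit_red = mixedlm.fit_lme_ml(y, X_red, groups, design_info="timepoint + (1|mouse)")
    res = mixedlm.lrt(fit_full, fit_red)

    ages = sub.groupby("timepoint_index")["age_days"].first()
    rows = []
    for k in range(tps.size):
        for sex, sval in (("F", 0.0), ("M", 1.0)):
            c = np.zeros(X_full.shape[1])
            c[0] = 1.0
            c[1] = sval
            if k > 0:
                c[1 + k] = 1.0
                c[tps.size + k] = sval
            mean = float(c @ fit_full.params)
            se = float(np.sqrt(c @ fit_full.cov_params @ c))
            rows.append((sex, float(ages[tps[k]]), mean, se))
    bands = pd.DataFrame(rows, columns=["sex", "age_days", "mean", "se"])
    return StructureTestResult(structure, response, res, fit_full, fit_red, bands)


def structure_sex_lrt_batch(sexes, tp_idx, mouse_ids, Y: np.ndarray):
    """Vectorised structure-level LRT over many response vectors.

    Intended for calibration studies where thousands of simulated cohorts
    share one scan layout.  Returns (D, pvalues, Q).
    """
    tp_idx = np.asarray(tp_idx)
    n_tp = int(tp_idx.max()) + 1
    X_full, X_red = _factor_design(np.asarray(sexes), tp_idx, n_tp)
    full = mixedlm.fit_lme_ml_batch(Y, X_full, mouse_ids)
    red = mixedlm.fit_lme_ml_batch(Y, X_red, mouse_ids)
    Q = X_full.shape[1] - X_red.shape[1]
    D, p = mixedlm.lrt_batch(full["loglik"], red["loglik"], Q)
    return D, p, Q


def earliest_dimorphic_timepoint(table: pd.DataFrame, structure: str,
                                 response: str = "absolute",
                                 alpha: float = 0.05) -> TimingTable:
    """Per-age sex-difference contrasts with Satterthwaite df.

    The contrast at age k is the sex main effect plus that age's
    sex x timepoint interaction (at the reference age it is the main
    effect alone).  Per-age p-values are reported uncorrected; the
    "earliest significant age" is a descriptive summary of them.
    """
    res = structure_sex_test(table, structure, response)
    fit = res.fit_full
    sub = structure_response(table, structure, response)
    tps = np.sort(sub["timepoint_index"].unique())
    ages = sub.groupby("timepoint_index")["age_days"].first()
    p_dim = fit.params.size
    rows = []
    for k in range(tps.size):
        c = np.zeros(p_dim)
        c[1] = 1.0
        if k > 0:
            c[tps.size + k] = 1.0
        est, se, t, df, p = mixedlm.contrast_test(fit, c)
        rows.append((float(ages[tps[k]]), est, se, t, df, p))
    tab = pd.DataFrame(rows, columns=["age_days", "estimate", "se", "tvalue", "df", "pvalue"])
    sig = tab[tab["pvalue"] < alpha]
    earliest = float(sig["age_days"].iloc[0]) if len(sig) else None
    return TimingTable(structure, response, tab, earliest)


def _stack_fields(fields: list[DeterminantField], mask: np.ndarray):
    shape = fields[0].values.shape
    for f in fields:
        if f.values.shape != shape:
            raise ValueError("all determinant fields must share one grid")
    Y = np.stack([f.values[mask] for f in fields])  # (n_scans, n_voxels)
    sexes = np.array([f.sex for f in fields])
    ages = np.array([f.age_days for f in fields])
    mice = np.array([f.mouse_id for f in fields])
    return Y, sexes, ages, mice


def _time_axis(ages: np.ndarray, time_coding: str) -> np.ndarray:
    if time_coding == "actual":
        return ages.astype(float)
    if time_coding == "rank":
        # equally spaced timepoints: replace each age by its rank
        uniq = np.unique(ages)
        return np.searchsorted(uniq, ages).astype(float)
    raise ValueError("time_coding must be 'actual' or 'rank'")


def voxelwise_sex_test(fields: list[DeterminantField],
                       mask: np.ndarray | None = None,
                       time_coding: str = "actual",
                       growth: str = "linear",
                       random_slope: bool = False) -> VoxelStatMap:
    """Mass-univariate LRT for sex at every voxel of a determinant field set.

    Full model per voxel: sex + age + sex x age + (1 | mouse); the reduced
    model drops the sex terms, so the default linear-growth test has
    Q = 2.  ``growth='quadratic'`` adds age^2 and its sex interaction;
    ``random_slope=True`` adds a per-mouse random age slope (slower:
    per-voxel 2-D variance optimization).  Voxels whose fit fails are
    excluded from the FDR correction and counted in ``n_failed``.
    """
    if mask is None:
        mask = np.any([f.values != 0 for f in fields], axis=0)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    Y, sexes, ages, mice = _stack_fields(fields, mask)
    s = (sexes == "M").astype(float)
    t = _time_axis(ages, time_coding)
    t = t / t.max()  # scale for conditioning; LRT invariant to this
    cols_full = [np.ones_like(t), s, t, s * t]
    cols_red = [np.ones_like(t), t]
    if growth == "quadratic":
        cols_full += [t**2, s * t**2]
        cols_red += [t**2]
    elif growth != "linear":
        raise ValueError("growth must be 'linear' or 'quadratic'")
    X_full = np.column_stack(cols_full)
    X_red = np.column_stack(cols_red)
    Q = X_full.shape[1] - X_red.shape[1]

    if random_slope:
        ll_full = np.array([
            mixedlm.fit_lme_ml2(Y[:, v], X_full, mice, t).loglik for v in range(Y.shape[1])
        ])
        ll_red = np.array([
            mixedlm.fit_lme_ml2(Y[:, v], X_red, mice, t).loglik for v in range(Y.shape[1])
        ])
        D, p = mixedlm.lrt_batch(ll_full, ll_red, Q)
        model = f"sex*age[{growth}] + (age|mouse), {time_coding} time"
    else:
        full = mixedlm.fit_lme_ml_batch(Y, X_full, mice)
        red = mixedlm.fit_lme_ml_batch(Y, X_red, mice)
        D, p = mixedlm.lrt_batch(full["loglik"], red["loglik"], Q)
        model = f"sex*age[{growth}] + (1|mouse), {time_coding} time"

    q = mixedlm.fdr_bh(p)
    n_failed = int(np.sum(~np.isfinite(D)))
    stat_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    q_map = np.full(mask.shape, np.nan)
    stat_map[mask] = D
    p_map[mask] = p
    q_map[mask] = q
    return VoxelStatMap(stat_map, p_map, q_map, mask, float(Q), model, n_failed)


def age_centered_sex_map(fields: list[DeterminantField], mask: np.ndarray,
                         t_prime: float, time_coding: str = "actual") -> VoxelStatMap:
    """Sex-difference t-map at a reference age t'.

    Translating the age axis to t' makes the time-independent sex
    coefficient the sex difference at that age; it is a pure
    reparameterization of the linear-growth model (identical likelihood),
    read out with Satterthwaite p-values per voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    Y, sexes, ages, mice = _stack_fields(fields, mask)
    t = _time_axis(ages, time_coding)
    if not (min(0.0, t.min()) <= t_prime <= t.max()):
        raise ValueError(f"t_prime {t_prime} outside the observed age range")
    s = (sexes == "M").astype(float)
    tc = (t - float(t_prime)) / t.max()
    X = np.column_stack([np.ones_like(tc), s, tc, s * tc])
    res = mixedlm.fit_lme_ml_batch(Y, X, mice)
    c = np.array([0.0, 1.0, 0.0, 0.0])
    est, se, df = mixedlm.contrast_inference_batch(res["_prob"], c)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = est / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    q = mixedlm.fdr_bh(p)
    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    q_map = np.full(mask.shape, np.nan)
    t_map[mask] = tval
    p_map[mask] = p
    q_map[mask] = q
    return VoxelStatMap(t_map, p_map, q_map, mask, float(np.median(df)),
                        f"age-centered at t'={t_prime}")


def age_centered_maps(fields: list[DeterminantField], mask: np.ndarray,
                      ages: list[float] | None = None,
                      fdr_q: float = 0.1) -> dict:
    """Age-centered t-maps for every cohort age, thresholded consistently.

    The q < ``fdr_q`` cut is taken from the model centered at the oldest
    age and the corresponding p-value threshold is applied to all ages,
    so maps across development are comparable.
    """
    if ages is None:
        ages = sorted({f.age_days for f in fields})
    maps = {a: age_centered_sex_map(fields, mask, a) for a in ages}
    oldest = maps[max(ages)]
    sel = np.nan_to_num(oldest.qvalues[mask], nan=np.inf) < fdr_q
    pvals = oldest.pvalues[mask]
    p_thresh = float(np.nanmax(pvals[sel])) if sel.any() else 0.0
    out = {}
    for a, m in maps.items():
        sig = np.zeros(mask.shape, dtype=bool)
        sig[mask] = np.nan_to_num(m.pvalues[mask], nan=np.inf) <= p_thresh
        out[a] = {"map": m, "significant": sig, "p_threshold": p_thresh}
    return out


def variance_equality_ftest(table: pd.DataFrame, structure: str, age_days: float,
                            response: str = "absolute"):
    """Cross-sectional F-test for equality of variances between the sexes.

    F is the larger sample variance over the smaller (so F >= 1); the
    two-sided p doubles the upper tail, capped at 1.
    """
    sub = structure_response(table, structure, response)
    sub = sub[sub["age_days"] == age_days]
    vals = {sex: sub.loc[sub["sex"] == sex, "y"].to_numpy() for sex in ("M", "F")}
    for sex, v in vals.items():
        if v.size < 2:
            raise ValueError(f"need >= 2 observations for sex {sex} at age {age_days}")
    v_m = np.var(vals["M"], ddof=1)
    v_f = np.var(vals["F"], ddof=1)
    if v_m >= v_f:
        F, dfn, dfd = v_m / v_f, vals["M"].size - 1, vals["F"].size - 1
    else:
        F, dfn, dfd = v_f / v_m, vals["F"].size - 1, vals["M"].size - 1
    p = min(1.0, 2.0 * float(stats.f.sf(F, dfn, dfd)))
    return float(F), p
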