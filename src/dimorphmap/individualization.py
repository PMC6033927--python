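"""Leave-one-out prediction of mature structure volumes; individualization timing.

A subject's structure volume at a target age t is predicted from its own
volumes at timepoints up to an accessed bound x < t, using per-structure
linear models trained on all *other* subjects — the training set never
contains the predicted subject's row at t, nor any data later than t.
Prediction error over the J atlas structures is summarized as

    RMSD  = sqrt(1/J sum_j (yhat_j - y_j)^2)          (mm^3)
    RMSPD = sqrt(1/J sum_j ((yhat_j - y_j)/y_j)^2)    (dimensionless)

the latter being invariant to whole-brain scaling.  Specificity asks
whether each subject's prediction matches its own observation more
closely than other subjects' observations (one-sided KS of diagonal vs
off-diagonal RMSD).  Individualization timing fits a mixed model to RMSD
against the accessed timepoint, windows where prediction first improves,
and permutes sex labels to test whether one sex individualizes earlier.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special

from . import mixedlm
from .volumes import validate_volume_table

__all__ = [
    "predict_structure_volumes",
    "predict_all_subjects",
    "rmsd_rmspd",
    "SpecificityMatrix",
    "specificity_analysis",
    "accuracy_curve",
    "TimingResult",
    "individualization_timing",
    "training_audit",
]


@dataclasses.dataclass
class _Pivots:
    """Dense per-structure volume arrays with within-subject interpolation."""

    ages: np.ndarray              # (T,)
    structures: list
    subjects: list
    sexes: np.ndarray             # per subject
    volumes: np.ndarray           # (n_structures, n_subjects, T), interpolated
    observed: np.ndarray          # (n_subjects, T) any-structure observation
    brain: np.ndarray             # (n_subjects, T) brain volume, interpolated


def _volume_pivots(table: pd.DataFrame) -> _Pivots:
    """Missing scans are linearly interpolated within-subject on age;
    ages outside a subject's observed span take the nearest scan's value
    (constant extrapolation)."""
    ages = np.sort(table["age_days"].unique())
    structures = sorted(table["structure"].unique())
    subjects = sorted(table["mouse_id"].unique())
    sexes = table.groupby("mouse_id")["sex"].first().loc[subjects].to_numpy()
    a_idx = {a: i for i, a in enumerate(ages)}
    s_idx = {s: i for i, s in enumerate(structures)}
    m_idx = {m: i for i, m in enumerate(subjects)}
    T, S, M = ages.size, len(structures), len(subjects)
    vol = np.full((S, M, T), np.nan)
    brain = np.full((M, T), np.nan)
    ai = table["age_days"].map(a_idx).to_numpy()
    si = table["structure"].map(s_idx).to_numpy()
    mi = table["mouse_id"].map(m_idx).to_numpy()
    vol[si, mi, ai] = table["volume_mm3"].to_numpy()
    brain[mi, ai] = table["brain_volume_mm3"].to_numpy()
    observed = np.isfinite(vol).any(axis=0)
    for m in range(M):
        obs = observed[m]
        if not obs.any():
            continue
        for s in range(S):
            row = vol[s, m]
            ok = np.isfinite(row)
            if ok.any() and not ok.all():
                vol[s, m] = np.interp(ages, ages[ok], row[ok])
        ok = np.isfinite(brain[m])
        if ok.any() and not ok.all():
            brain[m] = np.interp(ages, ages[ok], brain[m][ok])
    return _Pivots(ages, structures, subjects, sexes, vol, observed, brain)


def _predict_one(piv: _Pivots, t_idx: int, acc_idx: np.ndarray, m: int,
                 weights=None, method: str = "wls",
                 brain_volume_covariate: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(predicted, observed) per structure for one left-out subject index."""
    train = [j for j in range(len(piv.subjects)) if j != m and piv.observed[j, t_idx]]
    if not train:
        raise ValueError("no training subjects with an observed response at t")
    preds = np.empty(len(piv.structures))
    obs = piv.volumes[:, m, t_idx]
    for s in range(len(piv.structures)):
        Xtr = piv.volumes[s][train][:, acc_idx]
        ytr = piv.volumes[s][train, t_idx]
        xte = piv.volumes[s, m, acc_idx]
        if brain_volume_covariate:
            Xtr = np.column_stack([Xtr, piv.brain[train, acc_idx[-1]]])
            xte = np.append(xte, piv.brain[m, acc_idx[-1]])
        if method == "random_forest":
            from sklearn.ensemble import RandomForestRegressor

            rf = RandomForestRegressor(n_estimators=100, random_state=0)
            rf.fit(Xtr, ytr)
            preds[s] = float(rf.predict(xte[None, :])[0])
        elif method == "wls":
            A = np.column_stack([np.ones(len(train)), Xtr])
            if weights is not None:
                sw = np.sqrt(np.asarray(weights, float))
                A, ytr = A * sw[:, None], ytr * sw
            coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
            preds[s] = float(np.concatenate([[1.0], xte]) @ coef)
        else:
            raise ValueError("method must be 'wls' or 'random_forest'")
    return preds, obs


def _frame(piv: _Pivots, m: int, target_time, accessed_bound, preds, obs) -> pd.DataFrame:
    return pd.DataFrame({
        "mouse_id": piv.subjects[m], "structure": piv.structures,
        "target_time": target_time, "accessed_bound": accessed_bound,
        "predicted": preds, "observed": obs,
    })


def _check_times(piv: _Pivots, target_time: float, accessed_bound: float):
    if accessed_bound >= target_time:
        raise ValueError("accessed bound must precede the target time")
    t_where = np.where(piv.ages == target_time)[0]
    if t_where.size == 0:
        raise ValueError(f"target time {target_time} is not a cohort age")
    acc_idx = np.where(piv.ages <= accessed_bound)[0]
    if acc_idx.size == 0:
        raise ValueError("no accessed timepoints at or before the bound")
    return int(t_where[0]), acc_idx


def predict_structure_volumes(table: pd.DataFrame, target_time: float,
                              accessed_bound: float, subject: str,
                              weights=None, method: str = "wls",
                              brain_volume_covariate: bool = False,
                              _pivots: _Pivots | None = None) -> pd.DataFrame:
    """Predict one subject's structure volumes at ``target_time``.

    Per structure, the response (volume at t) of every *training* subject
    is regressed on that subject's volumes at the accessed timepoints
    <= x; the fitted model is applied to the left-out subject's accessed
    volumes.  Training excludes the predicted subject entirely and uses
    no data later than t for anyone.  ``method='random_forest'`` and a
    whole-brain-volume covariate are available as robustness hooks.
    """
    piv = _pivots if _pivots is not None else _volume_pivots(validate_volume_table(table))
    t_idx, acc_idx = _check_times(piv, target_time, accessed_bound)
    if subject not in piv.subjects:
        raise ValueError(f"unknown subject {subject!r}")
    m = piv.subjects.index(subject)
    if not piv.observed[m, t_idx]:
        raise ValueError(f"subject {subject} has no observed scan at t={target_time}")
    preds, obs = _predict_one(piv, t_idx, acc_idx, m, weights, method,
                              brain_volume_covariate)
    return _frame(piv, m, target_time, accessed_bound, preds, obs)


def predict_all_subjects(table: pd.DataFrame, target_time: float,
                         accessed_bound: float, _pivots: _Pivots | None = None,
                         **kw) -> pd.DataFrame:
    """Leave-one-out predictions for every subject observed at the target."""
    piv = _pivots if _pivots is not None else _volume_pivots(validate_volume_table(table))
    t_idx, acc_idx = _check_times(piv, target_time, accessed_bound)
    frames = [
        _frame(piv, m, target_time, accessed_bound,
               *_predict_one(piv, t_idx, acc_idx, m, **kw))
        for m in range(len(piv.subjects))
        if piv.observed[m, t_idx]
    ]
    return pd.concat(frames, ignore_index=True)


def training_audit(table: pd.DataFrame, target_time: float, subject: str) -> pd.DataFrame:
    """Rows a leave-one-out training set may legitimately contain.

    Excludes the predicted subject's rows at the target time and every
    row (any subject) later than the target — an automated hygiene check
    used by the test-suite.
    """
    keep = ~(
        ((table["mouse_id"] == subject) & (table["age_days"] == target_time))
        | (table["age_days"] > target_time)
    )
    return table[keep]


def rmsd_rmspd(predictions: pd.DataFrame) -> tuple[float, float]:
    """RMSD (mm^3) and RMSPD (dimensionless) over the structure set."""
    if len(predictions) < 1:
        raise ValueError("need at least one structure")
    err = predictions["predicted"].to_numpy() - predictions["observed"].to_numpy()
    obs = predictions["observed"].to_numpy()
    if (obs == 0).any():
        raise ValueError("observed volume of zero: RMSPD undefined")
    rmsd = float(np.sqrt(np.mean(err**2)))
    rmspd = float(np.sqrt(np.mean((err / obs) ** 2)))
    return rmsd, rmspd


@dataclasses.dataclass
class SpecificityMatrix:
    """Observed-vs-predicted RMSD matrix and its diagonal-bias KS test."""

    subjects: list
    rmsd: np.ndarray              # rows = observed subject, cols = predicted subject
    centered: np.ndarray          # columns shifted so the diagonal is 0
    d_plus: float
    pvalue: float
    specificity_probability: float


def specificity_analysis(predictions: pd.DataFrame) -> SpecificityMatrix:
    """Does each subject's prediction match itself better than others?

    Entry (i, j) is the RMSD between subject i's observed volumes and
    subject j's predicted volumes.  Diagonal entries are tested one-sided
    (stochastically smaller) against the empirical CDF of off-diagonal
    entries: D+ = sup(F_diag - F_offdiag), with an exact Smirnov p for
    n < 50.
    """
    subjects = sorted(predictions["mouse_id"].unique())
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    structures = sorted(predictions["structure"].unique())
    pred = predictions.pivot(index="mouse_id", columns="structure", values="predicted")
    obs = predictions.pivot(index="mouse_id", columns="structure", values="observed")
    P = pred.loc[subjects, structures].to_numpy(dtype=float)
    O = obs.loc[subjects, structures].to_numpy(dtype=float)
    diff = O[:, None, :] - P[None, :, :]
    M = np.sqrt(np.mean(diff**2, axis=2))          # (observed i, predicted j)
    centered = M - np.diag(M)[None, :]

    diag = np.diag(M)
    off = M[~np.eye(n, dtype=bool)]
    bg = np.sort(off)
    x = np.sort(diag)
    Fn = np.arange(1, n + 1) / n
    F0 = np.searchsorted(bg, x, side="right") / bg.size
    d_plus = float(np.max(Fn - F0))
    d_plus = max(d_plus, 0.0)
    p = float(special.smirnov(n, d_plus)) if n < 50 else float(np.exp(-2 * n * d_plus**2))

    col_off_median = np.array([
        np.median(np.delete(M[:, j], j)) for j in range(n)
    ])
    spec_prob = float(np.mean(diag < col_off_median))
    return SpecificityMatrix(subjects, M, centered, d_plus, min(p, 1.0), spec_prob)


def accuracy_curve(table: pd.DataFrame, target_time: float,
                   accessed_ages: tuple = (3, 5, 7, 10, 17, 23, 29),
                   **kw) -> pd.DataFrame:
    """Per-subject RMSD/RMSPD as a function of the accessed timepoint."""
    piv = _volume_pivots(validate_volume_table(table))
    rows = []
    for x in accessed_ages:
        if x >= target_time:
            raise ValueError(f"accessed age {x} must precede target {target_time}")
        t_idx, acc_idx = _check_times(piv, target_time, x)
        for m in range(len(piv.subjects)):
            if not piv.observed[m, t_idx]:
                continue
            preds, obs = _predict_one(piv, t_idx, acc_idx, m, **kw)
            err = preds - obs
            rows.append((piv.subjects[m], piv.sexes[m], float(x),
                         float(np.sqrt(np.mean(err**2))),
                         float(np.sqrt(np.mean((err / obs) ** 2)))))
    return pd.DataFrame(rows, columns=["mouse_id", "sex", "accessed", "rmsd", "rmspd"])


@dataclasses.dataclass
class TimingResult:
    improvement: pd.DataFrame       # sex, accessed, estimate, tvalue, df, pvalue
    window: tuple | None            # (lower age, upper age)
    observed_diff: float | None     # mean Z-RMSD (female) - (male) inside window
    perm_pvalue: float | None
    n_perm: int
    seed: int
    status: str


def individualization_timing(curves: pd.DataFrame, n_perm: int = 10000,
                             seed: int = 0, metric: str = "rmsd",
                             step_mode: str = "consecutive") -> TimingResult:
    """Sex difference in when prediction accuracy starts improving.

    A mixed model of RMSD on accessed-timepoint factor, sex and their
    interaction (random mouse intercept) gives one-sided consecutive-step
    improvement p-values per sex (Satterthwaite df).  The individualization
    window runs from the first step where either sex improves (p < 0.05)
    to the first where both improve strongly (p < 0.01); improvement
    contrasts compare consecutive steps by default (``step_mode=
    'baseline'`` compares each step with the earliest accessed age
    instead).  Each subject's
    RMSD series is Z-scored over accessed timepoints; the statistic is the
    female-minus-male difference in mean Z-RMSD inside the window, with a
    sex-label permutation p-value counting permuted differences >= the
    observed one (the identity permutation is included, so p >= 1/n_perm).
    """
    xs = np.sort(curves["accessed"].unique())
    y = curves[metric].to_numpy(dtype=float)
    sexes = curves["sex"].to_numpy()
    mice = curves["mouse_id"].to_numpy()
    x_idx = np.searchsorted(xs, curves["accessed"].to_numpy())
    n = len(curves)
    s = (sexes == "M").astype(float)
    dummies = np.zeros((n, xs.size - 1))
    for k in range(1, xs.size):
        dummies[:, k - 1] = (x_idx == k).astype(float)
    X = np.column_stack([np.ones(n), s, dummies, s[:, None] * dummies])
    fit = mixedlm.fit_lme_ml(y, X, mice, design_info="accessed*sex + (1|mouse)")

    rows = []
    for sex, sval in (("F", 0.0), ("M", 1.0)):
        for k in range(1, xs.size):
            c = np.zeros(X.shape[1])
            c[1 + k] = 1.0
            c[xs.size + k] = sval
            if step_mode == "consecutive" and k > 1:
                c[k] = -1.0
                c[xs.size + k - 1] = -sval
            elif step_mode not in ("consecutive", "baseline"):
                raise ValueError("step_mode must be 'consecutive' or 'baseline'")
            est, se, t, df, p = mixedlm.contrast_test(fit, c, one_sided="less")
            rows.append((sex, float(xs[k]), est, t, df, p))
    imp = pd.DataFrame(rows, columns=["sex", "accessed", "estimate", "tvalue", "df", "pvalue"])

    by_x = imp.pivot(index="accessed", columns="sex", values="pvalue").sort_index()
    lower = next((a for a, r in by_x.iterrows() if (r < 0.05).any()), None)
    upper = next((a for a, r in by_x.iterrows() if (r < 0.01).all()), None)
    if lower is None:
        return TimingResult(imp, None, None, None, n_perm, seed,
                            status="no significant improvement for either sex")
    if upper is None or upper < lower:
        upper = float(xs[-1]) if upper is None else lower
    window = (float(lower), float(upper))

    wide = curves.pivot(index="mouse_id", columns="accessed", values=metric)
    Z = wide.sub(wide.mean(axis=1), axis=0).div(wide.std(axis=1, ddof=1), axis=0)
    in_window = [c for c in wide.columns if window[0] <= c <= window[1]]
    zmean = Z[in_window].mean(axis=1)
    sex_vec = curves.groupby("mouse_id")["sex"].first().loc[zmean.index].to_numpy()
    is_f = sex_vec == "F"
    observed = float(zmean[is_f].mean() - zmean[~is_f].mean())

    rng = np.random.default_rng(seed)
    z = zmean.to_numpy()
    n_f = int(is_f.sum())
    count = 0
    for i in range(n_perm):
        lab = is_f if i == 0 else np.isin(np.arange(z.size),
                                          rng.choice(z.size, n_f, replace=False))
        diff = z[lab].mean() - z[~lab].mean()
        if diff >= observed:
            count += 1
    p_perm = count / n_perm
    return TimingResult(imp, window, observed, p_perm, n_perm, seed, status="ok")
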