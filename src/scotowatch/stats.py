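"""Statistics applied to event tables and group summaries.

Conventions pinned here (and used everywhere):

* Pearson chi-square without continuity correction, for 2x2 and
  goodness-of-fit tables alike.
* Mann-Whitney U counts 0.5 per tie and reports min(U1, U2).
* Two-sample t supports both the classical pooled-variance form
  (df = n1 + n2 - 2) and Welch's form with Satterthwaite df.
* Reaction times are log-transformed with the natural log.
* Median confidence intervals are percentile-bootstrap, B = 2000, seeded.
* No multiple-testing correction is applied.

scipy.stats and statsmodels provide the numerics behind this surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "chi2_2x2",
    "chi2_gof",
    "mann_whitney_u",
    "two_sample_t",
    "pearson_r",
    "ols_logrt",
    "untimely_summary",
    "median_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group and columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class GroupSummary:
    group: tuple
    n: int
    median: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def chi2_2x2(t) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table; returns (statistic, p).

    ``t`` may be a :class:`ContingencyTable2x2` or any 2x2 array-like.
    """
    arr = t.as_array() if isinstance(t, ContingencyTable2x2) else np.asarray(t, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def chi2_gof(observed, expected_weights) -> tuple[float, float]:
    """Goodness-of-fit chi-square with expectation proportional to weights."""
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(expected_weights, dtype=float)
    if obs.shape != w.shape:
        raise ValueError("observed and weights must have the same length")
    if obs.sum() <= 0:
        raise ValueError("observed counts sum to zero")
    if np.any(w <= 0):
        raise ValueError("expected weights must be positive")
    expected = w / w.sum() * obs.sum()
    stat, p = sps.chisquare(obs, f_exp=expected)
    return float(stat), float(p)


def mann_whitney_u(x, y) -> float:
    """Mann-Whitney U with 0.5 per tie, reported as min(U1, U2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u1 = float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    u2 = x.size * y.size - u1
    return min(u1, u2)


def two_sample_t(x, y, variant: str = "pooled") -> tuple[float, float]:
    """Two-sample t statistic and degrees of freedom.

    ``variant='pooled'`` is the classical equal-variance test
    (df = n1 + n2 - 2); ``'welch'`` uses the Satterthwaite approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    if variant == "pooled":
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    elif variant == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    return float(res.statistic), float(df)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input has no defined correlation")
    return float(sps.pearsonr(x, y).statistic)


def ols_logrt(log_rt, occlusion_time, subject, extra: pd.DataFrame | None = None):
    """Least-squares regression of log reaction time on occlusion time.

    Subjects enter as indicator contrasts against the alphabetically first
    participant; ``extra`` may carry additional covariate columns (e.g. an
    eccentricity-class indicator).  Returns a dict with the occlusion slope
    and its 95% CI, subject effects, overall F, df, and adjusted R^2.
    """
    import statsmodels.api as sm

    y = np.asarray(log_rt, dtype=float)
    occ = np.asarray(occlusion_time, dtype=float)
    subj = pd.Categorical([str(s) for s in subject], ordered=False)
    df = pd.DataFrame({"occlusion_time": occ})
    levels = sorted(subj.categories)
    for lev in levels[1:]:
        df[f"subject[{lev}]"] = (np.asarray(subj) == lev).astype(float)
    if extra is not None:
        for col in extra.columns:
            df[col] = np.asarray(extra[col], dtype=float)
    X = sm.add_constant(df, has_constant="add")
    if y.size <= X.shape[1]:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased column: first column whose removal restores full rank
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear design: column '{col}' is aliased")
        raise ValueError("collinear design")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["occlusion_time"]
    return {
        "occ_slope": float(fit.params["occlusion_time"]),
        "occ_slope_ci": (float(ci[0]), float(ci[1])),
        "occ_slope_se": float(fit.bse["occlusion_time"]),
        "subject_effects": {
            lev: float(fit.params.get(f"subject[{lev}]", 0.0)) for lev in levels
        },
        "intercept": float(fit.params["const"]),
        "params": {k: float(v) for k, v in fit.params.items()},
        "f_statistic": float(fit.fvalue),
        "df_model": float(fit.df_model),
        "df_resid": float(fit.df_resid),
        "adj_r2": float(fit.rsquared_adj),
        "r2": float(fit.rsquared),
        "resid_sd": float(np.sqrt(fit.scale)),
    }


def untimely_summary(table: pd.DataFrame) -> dict:
    """Untimely-reaction proportions by stratum and the occlusion-by-timeliness 2x2.

    Proportions are over detected events; the contingency table (rows
    untimely/timely, columns occluded/not) uses gaze-usable detected events,
    with "occluded" meaning any scotoma occlusion before the press.  Empty
    strata are reported as None, and the chi-square is skipped when a margin
    is empty.
    """
    det = table.loc[table["detected"].astype(bool)].copy()
    det["untimely"] = ~det["timely"].astype(bool)

    def _prop(sub: pd.DataFrame):
        return None if len(sub) == 0 else float(sub["untimely"].mean())

    out = {
        "overall": _prop(det),
        "by_group": {},
        "by_ecc_class": {k: _prop(g) for k, g in det.groupby("ecc_class")},
        "by_drive_type": {k: _prop(g) for k, g in det.groupby("drive_type")},
    }
    if "group" in det.columns:
        out["by_group"] = {k: _prop(g) for k, g in det.groupby("group")}
    usable = det.loc[det["gaze_usable"].astype(bool)]
    occluded = usable["occlusion_time"].to_numpy() > 0
    untimely = usable["untimely"].to_numpy(dtype=bool)
    tab = ContingencyTable2x2(
        a=int((untimely & occluded).sum()),
        b=int((untimely & ~occluded).sum()),
        c=int((~untimely & occluded).sum()),
        d=int((~untimely & ~occluded).sum()),
    )
    out["occlusion_by_timeliness"] = tab
    arr = tab.as_array()
    if np.all(arr.sum(axis=0) > 0) and np.all(arr.sum(axis=1) > 0):
        stat, p = chi2_2x2(tab)
        out["chi2"] = stat
        out["chi2_p"] = p
    else:
        out["chi2"] = None
        out["chi2_p"] = None
    return out


def median_summary(
    table: pd.DataFrame,
    by=("participant_id",),
    value: str = "reaction_time",
    n_boot: int = 2000,
    seed: int = 0,
) -> list[GroupSummary]:
    """Per-stratum median with a seeded percentile-bootstrap 95% CI (B = 2000)."""
    rng = np.random.default_rng(seed)
    det = table.loc[table["detected"].astype(bool)]
    out = []
    for key, g in det.groupby(list(by)):
        vals = g[value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        if vals.size == 1:
            med = float(vals[0])
            out.append(GroupSummary(tuple(np.atleast_1d(key)), 1, med, med, 0.0, med, med))
            continue
        boots = np.median(
            rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out.append(
            GroupSummary(
                group=tuple(np.atleast_1d(key)),
                n=int(vals.size),
                median=float(np.median(vals)),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)),
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    return out
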