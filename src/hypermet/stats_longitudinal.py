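"""Longitudinal statistics for the tumor-progression study design.

Covers the full statistical layer used around the imaging and ex vivo
assays: one-way ANOVA with Fisher's LSD follow-ups, the
Benjamini–Krieger–Yekutieli two-stage adaptive FDR, Kaplan–Meier /
Mantel–Cox logrank survival comparison with an O/E hazard ratio, slope
estimation and comparison for trajectory trends, complete-case
repeated-measures ANOVA with the Geisser–Greenhouse correction,
percent-of-baseline normalization, biomarker cutoff classification, and
log-linear exponential growth fits.

Fisher's LSD is deliberately unadjusted (that is its definition); the FDR
procedure is applied only where many parallel contrasts arise (the
metabolite panel).  The BKY adjusted q-values are *level-dependent*: the
stage-2 threshold depends on the stage-1 rejection count, which depends on
the chosen Q — the rejection set is the contract, the q-values bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSeries", "SurvivalData",
    "AnovaLsdResult", "BkyResult", "KmResult", "SlopeFit", "SlopeComparison",
    "RmAnovaResult", "CutoffResult", "ExpGrowthFit",
    "anova_lsd", "bky_fdr", "km_logrank_hr", "slope_fit", "compare_slopes",
    "rm_anova_gg", "percent_change", "cutoff_performance", "exp_growth_fit",
]


# ---------------------------------------------------------------- containers

@dataclass
class GroupSeries:
    """Tidy observations (group, day, value[, subject]) with an optional
    log transform applied lazily through :meth:`frame`."""

    data: pd.DataFrame
    transform: str = "none"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        required = {"group", "day", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"GroupSeries needs columns {sorted(required)}")
        if not np.isfinite(df["value"]).all():
            raise ValueError("values must be finite")
        if self.transform not in ("none", "log"):
            raise ValueError("transform must be 'none' or 'log'")
        if self.transform == "log" and (df["value"] <= 0).any():
            raise ValueError("log transform requires positive values")
        self.data = df

    def frame(self) -> pd.DataFrame:
        df = self.data.copy()
        if self.transform == "log":
            df["value"] = np.log(df["value"])
        return df


@dataclass
class SurvivalData:
    """Per-subject survival time (days), event flag (1 = death, 0 =
    censored) and arm label."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        required = {"time", "event", "arm"}
        if not required.issubset(df.columns):
            raise ValueError(f"SurvivalData needs columns {sorted(required)}")
        if (df["time"] <= 0).any():
            raise ValueError("times must be > 0")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event must be 0 or 1")
        self.data = df


# ------------------------------------------------------- ANOVA + Fisher LSD

@dataclass
class AnovaLsdResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_error: float
    table: pd.DataFrame      # pairwise contrasts: estimate, t, p, significant


def anova_lsd(series: GroupSeries, alpha: float = 0.05) -> AnovaLsdResult:
    """Ordinary one-way ANOVA plus all pairwise Fisher LSD contrasts.

    LSD contrasts are pairwise t tests using the pooled mean-square error
    with N − k degrees of freedom and no multiplicity adjustment.
    """
    df = series.frame()
    groups = {g: sub["value"].to_numpy() for g, sub in df.groupby("group")}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    k = len(groups)
    n_total = all_vals.size
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_e = ss_within / df_w
    if ms_e == 0.0:
        f = 0.0 if ms_b == 0.0 else np.inf
        p = 1.0 if ms_b == 0.0 else 0.0
    else:
        f = ms_b / ms_e
        p = float(sps.f.sf(f, df_b, df_w))

    rows = []
    names = list(groups)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            va, vb = groups[a], groups[b]
            est = va.mean() - vb.mean()
            se = np.sqrt(ms_e * (1.0 / va.size + 1.0 / vb.size))
            if se == 0.0:
                t = 0.0 if est == 0.0 else np.inf * np.sign(est)
                pv = 1.0 if est == 0.0 else 0.0
            else:
                t = est / se
                pv = float(2.0 * sps.t.sf(abs(t), df_w))
            rows.append({"group_a": a, "group_b": b, "estimate": est,
                         "t": t, "p": pv, "significant": pv < alpha})
    table = pd.DataFrame(rows)
    return AnovaLsdResult(float(f), float(p), df_b, df_w, float(ms_e), table)


# ------------------------------------------------- two-stage adaptive FDR

@dataclass
class BkyResult:
    reject: np.ndarray
    qvalues: np.ndarray
    n_stage1_rejections: int
    q: float


def _bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at the given level."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = level * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[order[: k + 1]] = True
    return reject


def bky_fdr(pvalues, q: float = 0.05) -> BkyResult:
    """Benjamini–Krieger–Yekutieli two-stage step-up FDR control.

    Stage 1 runs BH at q' = q/(1+q); with r1 rejections (0 < r1 < m), the
    estimated number of true nulls m − r1 sharpens stage 2, BH at
    q'·m/(m−r1).  Adjusted q-values are defined so that (qvalue ≤ q) ⇔
    rejection under the procedure at this q, monotone in p rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0 or r1 == m:
        reject = stage1
        m0_hat = m
    else:
        reject = _bh_reject(p, q1 * m / (m - r1))
        m0_hat = m - r1
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    raw = p[order] * (1.0 + q) * m0_hat / ranks
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    qvalues = np.empty(m)
    qvalues[order] = np.minimum(adj, 1.0)
    return BkyResult(reject, qvalues, r1, q)


# -------------------------------------------------- Kaplan–Meier / logrank

@dataclass
class KmResult:
    medians: dict
    chi2: float
    p: float
    hazard_ratio: float
    hr_estimable: bool
    observed: dict
    expected: dict


def km_logrank_hr(data: SurvivalData) -> KmResult:
    """Two-arm Kaplan–Meier comparison: medians, Mantel–Cox logrank test
    and the logrank (O/E) hazard ratio.

    Median survival is the smallest time with S(t) ≤ 0.5 (standard KM
    software convention; NaN when the curve never reaches 0.5).  The hazard
    ratio is (O₁/E₁)/(O₂/E₂) in the order the arms first appear; it is
    flagged non-estimable when an arm has zero observed or expected events.
    """
    from lifelines import KaplanMeierFitter

    df = data.data
    arms = list(pd.unique(df["arm"]))
    if len(arms) != 2:
        raise ValueError("km_logrank_hr requires exactly two arms")

    medians = {}
    for arm in arms:
        sub = df[df["arm"] == arm]
        km = KaplanMeierFitter().fit(sub["time"], sub["event"])
        medians[arm] = float(km.median_survival_time_)

    # pooled risk table at each distinct event time
    event_times = np.sort(df.loc[df["event"] == 1, "time"].unique())
    o = {a: 0.0 for a in arms}
    e = {a: 0.0 for a in arms}
    var = 0.0
    for t in event_times:
        at_risk = {a: float(((df["arm"] == a) & (df["time"] >= t)).sum())
                   for a in arms}
        deaths = {a: float(((df["arm"] == a) & (df["time"] == t) &
                            (df["event"] == 1)).sum()) for a in arms}
        n = sum(at_risk.values())
        d = sum(deaths.values())
        if n == 0 or d == 0:
            continue
        for a in arms:
            o[a] += deaths[a]
            e[a] += d * at_risk[a] / n
        if n > 1:
            var += (d * (at_risk[arms[0]] / n) * (1 - at_risk[arms[0]] / n)
                    * (n - d) / (n - 1))

    if var > 0:
        chi2 = (o[arms[0]] - e[arms[0]]) ** 2 / var
        p = float(sps.chi2.sf(chi2, 1))
    else:
        chi2, p = 0.0, 1.0
    estimable = all(o[a] > 0 for a in arms) and all(e[a] > 0 for a in arms)
    hr = ((o[arms[0]] / e[arms[0]]) / (o[arms[1]] / e[arms[1]])
          if estimable else float("nan"))
    return KmResult(medians, float(chi2), p, float(hr), estimable, o, e)


# ------------------------------------------------------------ trend slopes

@dataclass
class SlopeFit:
    slope: float
    intercept: float
    se: float
    p: float
    n: int
    on: str


def _series_xy(series: GroupSeries, day_range, on: str):
    df = series.frame()
    if day_range is not None:
        lo, hi = day_range
        df = df[(df["day"] >= lo) & (df["day"] <= hi)]
    if on == "means":
        agg = df.groupby("day")["value"].mean().reset_index()
        x, y = agg["day"].to_numpy(float), agg["value"].to_numpy(float)
    elif on == "observations":
        x, y = df["day"].to_numpy(float), df["value"].to_numpy(float)
    else:
        raise ValueError("on must be 'means' or 'observations'")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct days for a slope fit")
    return x, y


def slope_fit(series: GroupSeries, day_range: tuple[float, float] | None = None,
              on: str = "means") -> SlopeFit:
    """OLS trend of value vs day; by default on per-day group means.

    For an exact (zero-residual) fit the slope test is degenerate: the
    convention here is p = 1 for a zero slope (no evidence of trend beyond
    a constant) and p = 0 for a nonzero slope fit with zero residual.
    """
    x, y = _series_xy(series, day_range, on)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    dof = n - 2
    rss = float((resid ** 2).sum())
    # an exactly linear input leaves only rounding-level residual
    exact_floor = (1e-10 * max(1.0, float(np.abs(y).max()))) ** 2 * n
    if dof <= 0 or rss <= exact_floor:
        se = 0.0
        p = 1.0 if slope == 0.0 else 0.0
    else:
        se = np.sqrt(rss / dof / sxx)
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return SlopeFit(float(slope), float(intercept), float(se), p, n, on)


@dataclass
class SlopeComparison:
    delta: float
    t: float
    p: float
    df: int


def compare_slopes(series_a: GroupSeries, series_b: GroupSeries,
                   day_range_a=None, day_range_b=None,
                   on: str = "means") -> SlopeComparison:
    """Test of equal slopes via the interaction term of a pooled two-line
    regression with a common residual variance."""
    import statsmodels.api as sm

    xa, ya = _series_xy(series_a, day_range_a, on)
    xb, yb = _series_xy(series_b, day_range_b, on)
    x = np.concatenate([xa, xb])
    g = np.concatenate([np.zeros_like(xa), np.ones_like(xb)])
    y = np.concatenate([ya, yb])
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, design).fit()
    delta = float(fit.params[3])
    t = float(fit.tvalues[3])
    p = float(fit.pvalues[3])
    if not np.isfinite(t):  # degenerate zero-residual pooled fit
        t = 0.0 if delta == 0.0 else np.inf
        p = 1.0 if delta == 0.0 else 0.0
    return SlopeComparison(delta, t, p, int(fit.df_resid))


# -------------------------------------- repeated measures with GG correction

@dataclass
class RmAnovaResult:
    f: float
    p: float
    epsilon: float
    df1: float
    df2: float
    df1_adj: float
    df2_adj: float
    n_subjects: int


def rm_anova_gg(matrix) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with the Geisser–Greenhouse
    (Greenhouse–Geisser) sphericity correction, complete cases only.

    ``matrix`` is subjects × conditions; rows containing NaN are dropped.
    Epsilon is computed from the double-centered sample covariance of the
    conditions and multiplies both degrees of freedom; k = 2 conditions
    give epsilon = 1 identically.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be subjects x conditions")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 complete subjects and >= 2 conditions")

    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2

    s = np.cov(m, rowvar=False, ddof=1)
    centered = (s - s.mean(axis=0, keepdims=True)
                - s.mean(axis=1, keepdims=True) + s.mean())
    tr = np.trace(centered)
    denom = (k - 1) * (centered ** 2).sum()
    eps = float(tr ** 2 / denom) if denom > 0 else 1.0
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)

    if ms_err == 0.0:
        f = 0.0 if ms_cond == 0.0 else np.inf
        p = 1.0 if ms_cond == 0.0 else 0.0
    else:
        f = ms_cond / ms_err
        p = float(sps.f.sf(f, df1 * eps, df2 * eps))
    return RmAnovaResult(float(f), p, eps, df1, df2, df1 * eps, df2 * eps, n)


# --------------------------------------------------- percent change, cutoff

def percent_change(df: pd.DataFrame, baseline_day: float,
                   value_col: str = "value") -> pd.DataFrame:
    """Normalize each subject's trajectory to its baseline-day value × 100.

    Subjects without a baseline measurement are dropped with a warning.
    Requires columns ``subject``, ``day`` and ``value_col``.
    """
    out = []
    for subject, sub in df.groupby("subject"):
        base = sub.loc[sub["day"] == baseline_day, value_col]
        if base.empty or base.iloc[0] == 0:
            warnings.warn(f"subject {subject!r} has no usable baseline at "
                          f"day {baseline_day}; dropped")
            continue
        norm = sub.copy()
        norm["percent_of_baseline"] = 100.0 * sub[value_col] / base.iloc[0]
        out.append(norm)
    if not out:
        return df.iloc[0:0].assign(percent_of_baseline=[])
    return pd.concat(out, ignore_index=True)


@dataclass
class CutoffResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float     # percent; NaN if no positives
    specificity: float     # percent; NaN if no negatives


def cutoff_performance(baseline_values, outcomes, cutoff: float = 0.4
                       ) -> CutoffResult:
    """Classify subjects by (baseline value > cutoff) against a binary
    outcome (1 = death before the study endpoint).

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), both in percent;
    a metric with an empty denominator is reported as NaN.
    """
    v = np.asarray(baseline_values, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and outcomes must align")
    pred = v > cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return CutoffResult(tp, fp, tn, fn, sens, spec)


# ------------------------------------------------------- exponential growth

@dataclass
class ExpGrowthFit:
    rate: float        # 1/day
    v0: float
    r2: float          # on the log (fitting) scale
    n: int


def exp_growth_fit(days, volumes) -> ExpGrowthFit:
    """Log-linear least squares V(t) = V0 · exp(rate · t).

    R² is reported on the fitting (log) scale.  Non-positive volumes are an
    error under the log model.
    """
    t = np.asarray(days, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volumes must be positive for a log-linear fit")
    y = np.log(v)
    res = sps.linregress(t, y)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    if np.allclose(y, y[0]):
        # constant data: rate 0, perfect fit of a flat exponential
        return ExpGrowthFit(0.0, float(np.exp(y[0])), 1.0, t.size)
    return ExpGrowthFit(float(res.slope), float(np.exp(res.intercept)),
                        r2, t.size)
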