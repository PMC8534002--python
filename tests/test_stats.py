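"""Statistical layer: closed-form oracles, independent brute-force
implementations, and cross-checks against lifelines / pingouin /
statsmodels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hypermet.stats_longitudinal import (GroupSeries, SurvivalData, anova_lsd,
                                         bky_fdr, compare_slopes,
                                         cutoff_performance, exp_growth_fit,
                                         km_logrank_hr, percent_change,
                                         rm_anova_gg, slope_fit)


def gs(groups: dict, transform="none") -> GroupSeries:
    rows = []
    for g, pairs in groups.items():
        for i, (day, value) in enumerate(pairs):
            rows.append({"group": g, "day": day, "value": value,
                         "subject": f"{g}{i}"})
    return GroupSeries(pd.DataFrame(rows), transform)


# ------------------------------------------------------------- ANOVA + LSD

def test_anova_identical_means_f_zero():
    series = gs({"a": [(1, 5.0), (2, 7.0)], "b": [(1, 5.0), (2, 7.0)],
                 "c": [(1, 5.0), (2, 7.0)]})
    res = anova_lsd(series)
    assert res.f == 0.0
    assert res.p == pytest.approx(1.0)


def test_anova_matches_hand_computed_sums_of_squares():
    """3-group toy data against an explicitly hand-computed decomposition."""
    groups = {"a": [3.0, 5.0, 4.0], "b": [7.0, 9.0, 8.0], "c": [4.0, 6.0, 5.0]}
    series = gs({g: [(i, v) for i, v in enumerate(vals)]
                 for g, vals in groups.items()})
    res = anova_lsd(series)
    grand = np.mean([v for vals in groups.values() for v in vals])
    ss_b = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
    ss_w = sum(sum((x - np.mean(v)) ** 2 for x in v)
               for v in groups.values())
    f = (ss_b / 2) / (ss_w / 6)
    assert res.f == pytest.approx(f, abs=1e-10)
    assert res.p == pytest.approx(sps.f.sf(f, 2, 6), abs=1e-12)
    # and against scipy's independent implementation
    f2, p2 = sps.f_oneway(*groups.values())
    assert res.f == pytest.approx(f2, rel=1e-12)
    assert res.p == pytest.approx(p2, rel=1e-9)


def test_two_group_lsd_equals_pooled_t():
    a = [3.1, 4.5, 2.8, 3.9]
    b = [5.0, 6.2, 5.8]
    series = gs({"a": [(i, v) for i, v in enumerate(a)],
                 "b": [(i, v) for i, v in enumerate(b)]})
    res = anova_lsd(series)
    t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
    row = res.table.iloc[0]
    assert abs(row["t"]) == pytest.approx(abs(t_ref), rel=1e-12)
    assert row["p"] == pytest.approx(p_ref, rel=1e-9)


def test_anova_undersized_group_rejected():
    with pytest.raises(ValueError):
        anova_lsd(gs({"a": [(0, 1.0)], "b": [(0, 2.0), (1, 3.0)]}))


def test_log_transform_validates_positivity():
    with pytest.raises(ValueError):
        gs({"a": [(0, -1.0), (1, 2.0)], "b": [(0, 1.0), (1, 2.0)]},
           transform="log")


# ------------------------------------------------------------------ BKY FDR

def brute_force_bky(p: np.ndarray, q: float) -> np.ndarray:
    """Literal two-stage definition, written independently of the
    implementation: BH at q/(1+q); if 0 < r1 < m, BH again at
    (q/(1+q)) * m/(m - r1)."""
    m = p.size

    def bh(level):
        order = np.argsort(p)
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * level / m:
                k_max = k
        rej = np.zeros(m, dtype=bool)
        rej[order[:k_max]] = True
        return rej

    q1 = q / (1.0 + q)
    stage1 = bh(q1)
    r1 = int(stage1.sum())
    if r1 == 0 or r1 == m:
        return stage1
    return bh(q1 * m / (m - r1))


def test_bky_trivial_cases():
    assert not bky_fdr(np.ones(20), 0.05).reject.any()
    assert bky_fdr(np.full(26, 1e-10), 0.05).reject.all()


def test_bky_matches_brute_force_on_random_vectors():
    """200 random p-vectors: rejection sets identical to the independent
    brute-force two-stage implementation, and q-value thresholding at Q
    reproduces the rejection set."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        m = int(rng.integers(1, 40))
        p = np.where(rng.random(m) < 0.4, rng.random(m) * 0.05,
                     rng.random(m))
        res = bky_fdr(p, 0.05)
        assert np.array_equal(res.reject, brute_force_bky(p, 0.05))
        assert np.array_equal(res.qvalues <= 0.05, res.reject)


def test_bky_matches_statsmodels_two_stage():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(7)
    for _ in range(50):
        m = int(rng.integers(2, 30))
        p = np.where(rng.random(m) < 0.5, rng.random(m) * 0.08,
                     rng.random(m))
        res = bky_fdr(p, 0.05)
        sm_reject = multipletests(p, 0.05, method="fdr_tsbky")[0]
        assert np.array_equal(res.reject, sm_reject)


def test_bky_rejects_superset_of_bh():
    """Adaptivity: whenever stage 2 runs, the rejection set contains the
    plain BH rejections at the same q."""
    rng = np.random.default_rng(3)
    seen_stage2 = False
    for _ in range(100):
        m = int(rng.integers(5, 40))
        p = np.where(rng.random(m) < 0.5, rng.random(m) * 0.05,
                     rng.random(m))
        res = bky_fdr(p, 0.05)
        bh = sps.false_discovery_control(p, method="bh") <= 0.05
        if 0 < res.n_stage1_rejections < m:
            seen_stage2 = True
            assert (res.reject | ~bh).all()  # reject ⊇ BH
    assert seen_stage2


def test_bky_validates_inputs():
    with pytest.raises(ValueError):
        bky_fdr([0.1, 0.2], q=1.5)
    with pytest.raises(ValueError):
        bky_fdr([1.2], q=0.05)


# ---------------------------------------------------------- KM / logrank

TOY_SURVIVAL = pd.DataFrame({
    "time": [5, 8, 12, 20, 25, 30, 10, 15, 22, 30, 35, 40],
    "event": [1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1],
    "arm": ["a"] * 6 + ["b"] * 6,
})


def naive_logrank(df: pd.DataFrame, arm0: str):
    """Independent risk-table walk (naive loops, no shared code)."""
    o = e = v = 0.0
    for t in sorted(df.loc[df.event == 1, "time"].unique()):
        n0 = ((df.arm == arm0) & (df.time >= t)).sum()
        n1 = ((df.arm != arm0) & (df.time >= t)).sum()
        d0 = ((df.arm == arm0) & (df.time == t) & (df.event == 1)).sum()
        d1 = ((df.arm != arm0) & (df.time == t) & (df.event == 1)).sum()
        n, d = n0 + n1, d0 + d1
        o += d0
        e += d * n0 / n
        if n > 1:
            v += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o, e, v


def test_logrank_matches_hand_risk_table():
    res = km_logrank_hr(SurvivalData(TOY_SURVIVAL))
    o, e, v = naive_logrank(TOY_SURVIVAL, "a")
    assert res.observed["a"] == pytest.approx(o)
    assert res.expected["a"] == pytest.approx(e)
    assert res.chi2 == pytest.approx((o - e) ** 2 / v, rel=1e-12)
    o_b = res.observed["b"]
    e_b = res.expected["b"]
    assert res.hazard_ratio == pytest.approx((o / e) / (o_b / e_b), rel=1e-12)


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test
    df = TOY_SURVIVAL
    res = km_logrank_hr(SurvivalData(df))
    ref = logrank_test(df[df.arm == "a"].time, df[df.arm == "b"].time,
                       df[df.arm == "a"].event, df[df.arm == "b"].event)
    assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert res.p == pytest.approx(ref.p_value, rel=1e-9)


def test_identical_arms_null():
    df = pd.DataFrame({"time": [3, 5, 7] * 2, "event": [1, 1, 0] * 2,
                       "arm": ["x"] * 3 + ["y"] * 3})
    res = km_logrank_hr(SurvivalData(df))
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.hazard_ratio == pytest.approx(1.0, rel=1e-12)


def test_time_translation_invariance():
    res1 = km_logrank_hr(SurvivalData(TOY_SURVIVAL))
    shifted = TOY_SURVIVAL.assign(time=TOY_SURVIVAL.time + 17)
    res2 = km_logrank_hr(SurvivalData(shifted))
    assert res2.chi2 == pytest.approx(res1.chi2, rel=1e-12)
    assert res2.hazard_ratio == pytest.approx(res1.hazard_ratio, rel=1e-12)
    assert res2.medians["a"] == res1.medians["a"] + 17


def test_median_convention_smallest_time_below_half():
    df = pd.DataFrame({"time": [2, 4, 6, 8], "event": [1, 1, 1, 1],
                       "arm": ["a"] * 4})
    df = pd.concat([df, pd.DataFrame({"time": [9, 9], "event": [1, 1],
                                      "arm": ["b", "b"]})])
    res = km_logrank_hr(SurvivalData(df))
    assert res.medians["a"] == 4.0  # S(4) = 0.5 exactly


def test_zero_event_arm_flagged():
    df = pd.DataFrame({"time": [5, 6, 7, 8], "event": [1, 1, 0, 0],
                       "arm": ["a", "a", "b", "b"]})
    res = km_logrank_hr(SurvivalData(df))
    assert not res.hr_estimable
    assert np.isnan(res.hazard_ratio)


# ------------------------------------------------------------------ slopes

def test_slope_exact_line_and_flat_convention():
    flat = gs({"c": [(d, 0.26) for d in (0, 7, 14, 21)]})
    res = slope_fit(flat)
    assert res.slope == 0.0
    assert res.p == 1.0
    line = gs({"u": [(d, 0.2154 + 0.0069 * d) for d in (7, 14, 21, 28, 34)]})
    res = slope_fit(line)
    assert res.slope == pytest.approx(0.0069, abs=1e-12)
    assert res.p == 0.0  # exact nonzero trend


def test_slope_matches_scipy_on_noisy_data():
    rng = np.random.default_rng(5)
    days = np.repeat([0, 7, 14, 21, 28], 4)
    vals = 0.2 + 0.005 * days + 0.03 * rng.standard_normal(days.size)
    series = GroupSeries(pd.DataFrame({"group": "g", "day": days,
                                       "value": vals}))
    res = slope_fit(series, on="observations")
    ref = sps.linregress(days, vals)
    assert res.slope == pytest.approx(ref.slope, rel=1e-12)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_slope_requires_three_days():
    with pytest.raises(ValueError):
        slope_fit(gs({"g": [(0, 1.0), (7, 2.0)]}))


def test_slope_ci_coverage_monte_carlo():
    """95% CI coverage of the slope over 400 noisy replicates ∈ [0.93, 0.97]."""
    rng = np.random.default_rng(11)
    days = np.array([0.0, 7, 14, 21, 28, 35])
    true_slope = 0.007
    cover = 0
    n_rep = 400
    for _ in range(n_rep):
        vals = 0.25 + true_slope * days + 0.02 * rng.standard_normal(6)
        series = GroupSeries(pd.DataFrame(
            {"group": "g", "day": days, "value": vals}))
        res = slope_fit(series)
        tcrit = sps.t.ppf(0.975, 4)
        if abs(res.slope - true_slope) <= tcrit * res.se:
            cover += 1
    assert 0.93 <= cover / n_rep <= 0.97


def test_compare_slopes_identical_series():
    series = gs({"g": [(d, 0.2 + 0.01 * d + 0.05 * np.sin(d))
                       for d in range(8)]})
    res = compare_slopes(series, series)
    assert res.delta == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_compare_slopes_type_i_calibration():
    """Equal-slope null: rejection rate at α = 0.05 lands in 0.05 ± 0.02
    over 600 simulated pairs."""
    rng = np.random.default_rng(23)
    days = np.arange(0.0, 36.0, 5.0)
    rejections = 0
    n_rep = 600
    for _ in range(n_rep):
        a = 0.2 + 0.006 * days + 0.02 * rng.standard_normal(days.size)
        b = 0.3 + 0.006 * days + 0.02 * rng.standard_normal(days.size)
        sa = GroupSeries(pd.DataFrame({"group": "a", "day": days, "value": a}))
        sb = GroupSeries(pd.DataFrame({"group": "b", "day": days, "value": b}))
        if compare_slopes(sa, sb).p < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_rep <= 0.07


def test_compare_slopes_power_exceeds_alpha():
    rng = np.random.default_rng(31)
    days = np.arange(0.0, 36.0, 5.0)
    rejections = 0
    for _ in range(100):
        a = 0.2 + 0.0069 * days + 0.01 * rng.standard_normal(days.size)
        b = 0.2 + 0.0035 * days + 0.01 * rng.standard_normal(days.size)
        sa = GroupSeries(pd.DataFrame({"group": "a", "day": days, "value": a}))
        sb = GroupSeries(pd.DataFrame({"group": "b", "day": days, "value": b}))
        if compare_slopes(sa, sb).p < 0.05:
            rejections += 1
    assert rejections / 100 > 0.3


# ------------------------------------------------------ repeated measures

def test_gg_epsilon_identity_for_two_conditions():
    rng = np.random.default_rng(2)
    res = rm_anova_gg(rng.normal(size=(6, 2)))
    assert res.epsilon == pytest.approx(1.0, abs=1e-12)


def test_rm_anova_matches_pingouin():
    import pingouin as pg
    rng = np.random.default_rng(1)
    m = rng.normal(size=(8, 4)) + np.array([0.0, 0.3, 0.5, 0.2])
    res = rm_anova_gg(m)
    long = pd.DataFrame({"y": m.ravel(),
                         "subj": np.repeat(np.arange(8), 4),
                         "cond": np.tile(np.arange(4), 8)})
    ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                      correction=True).iloc[0]
    assert res.f == pytest.approx(ref["F"], rel=1e-9)
    assert res.epsilon == pytest.approx(ref["eps"], rel=1e-9)
    assert res.p == pytest.approx(ref["p_GG_corr"], rel=1e-6)


def test_rm_anova_toy_matrix_hand_values():
    """4 subjects × 3 conditions, against the textbook decomposition."""
    m = np.array([[7.0, 9.0, 8.0],
                  [5.0, 6.0, 7.0],
                  [8.0, 10.0, 9.0],
                  [6.0, 5.0, 7.0]])
    res = rm_anova_gg(m)
    grand = m.mean()
    ss_cond = 4 * ((m.mean(0) - grand) ** 2).sum()
    ss_subj = 3 * ((m.mean(1) - grand) ** 2).sum()
    ss_err = ((m - grand) ** 2).sum() - ss_cond - ss_subj
    f = (ss_cond / 2) / (ss_err / 6)
    assert res.f == pytest.approx(f, rel=1e-12)
    assert 1.0 / 2.0 <= res.epsilon <= 1.0


def test_rm_anova_drops_incomplete_and_validates():
    m = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 4.0], [3.0, 1.0]])
    res = rm_anova_gg(m)
    assert res.n_subjects == 3
    with pytest.raises(ValueError):
        rm_anova_gg(np.array([[1.0, 2.0], [np.nan, 3.0]]))


def test_gg_epsilon_near_one_under_compound_symmetry():
    """Compound-symmetric covariance satisfies sphericity: average epsilon
    over simulated datasets stays high."""
    rng = np.random.default_rng(17)
    eps = []
    for _ in range(200):
        subject = rng.standard_normal((40, 1))
        m = subject + rng.standard_normal((40, 4))
        eps.append(rm_anova_gg(m).epsilon)
    assert np.mean(eps) >= 0.9


# --------------------------------------------- percent change and cutoff

def test_percent_change_baseline_and_halving():
    df = pd.DataFrame({
        "subject": ["m1"] * 3 + ["m2"] * 3,
        "day": [28, 48, 68] * 2,
        "value": [0.44, 0.22, 0.44, 0.40, 0.30, 0.20],
    })
    out = percent_change(df, 28.0)
    m1 = out[out.subject == "m1"].set_index("day")["percent_of_baseline"]
    assert m1[28] == 100.0
    assert m1[48] == 50.0
    m2 = out[out.subject == "m2"].set_index("day")["percent_of_baseline"]
    assert m2[68] == pytest.approx(50.0)


def test_percent_change_missing_baseline_dropped_with_warning():
    df = pd.DataFrame({"subject": ["a", "b", "b"], "day": [48, 28, 48],
                       "value": [0.5, 0.4, 0.2]})
    with pytest.warns(UserWarning, match="baseline"):
        out = percent_change(df, 28.0)
    assert set(out.subject) == {"b"}


def test_cutoff_worked_outcome_counts():
    """0/3 deaths below the 0.4 cutoff and 5/7 above: sensitivity 100%,
    specificity 60%."""
    below = [0.31, 0.35, 0.38]
    above = [0.41, 0.43, 0.45, 0.46, 0.47, 0.48, 0.49]
    values = np.array(below + above)
    outcomes = np.array([0, 0, 0] + [1, 1, 1, 1, 1, 0, 0])
    res = cutoff_performance(values, outcomes, cutoff=0.4)
    assert res.sensitivity == 100.0
    assert res.specificity == 60.0
    assert (res.tp, res.fp, res.tn, res.fn) == (5, 2, 3, 0)


def test_cutoff_edge_conventions():
    perfect = cutoff_performance([0.2, 0.3, 0.6, 0.7], [0, 0, 1, 1], 0.4)
    assert perfect.sensitivity == 100.0 and perfect.specificity == 100.0
    low = cutoff_performance([0.5, 0.6, 0.7], [1, 1, 0], 0.1)
    assert low.sensitivity == 100.0 and low.specificity == 0.0
    no_pos = cutoff_performance([0.5, 0.6], [0, 0], 0.4)
    assert np.isnan(no_pos.sensitivity)


# --------------------------------------------------------------- growth fit

def test_exp_growth_exact_and_constant():
    days = np.array([5.0, 10, 20, 34])
    vols = 1.4 * np.exp(0.1431 * (days - 5.0))
    res = exp_growth_fit(days, vols)
    assert res.rate == pytest.approx(0.1431, abs=1e-12)
    assert res.r2 == pytest.approx(1.0)
    const = exp_growth_fit(days, np.full(4, 7.0))
    assert const.rate == 0.0
    assert const.r2 == 1.0


def test_exp_growth_rejects_nonpositive():
    with pytest.raises(ValueError):
        exp_growth_fit([1, 2, 3], [1.0, -0.5, 2.0])


def test_exp_growth_recovery_monte_carlo():
    rng = np.random.default_rng(9)
    days = np.arange(5.0, 35.0, 3.0)
    rates = []
    for _ in range(200):
        vols = 1.4 * np.exp(0.14 * (days - 5.0) +
                            0.2 * rng.standard_normal(days.size))
        rates.append(exp_growth_fit(days, vols).rate)
    se = np.std(rates) / np.sqrt(len(rates))
    assert abs(np.mean(rates) - 0.14) <= 2.5 * se + 1e-3
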