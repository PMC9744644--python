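"""Physiological indices and repeated-measures statistics.

The rmcorr implementation is cross-checked against an explicit
normal-equations ANCOVA (independent oracle) and against pingouin's
rm_corr; RM-ANOVA against statsmodels' AnovaRM.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from foct.physio import (cao2, day_deltas, linregress, mean_arterial_pressure,
                         rm_anova_bonferroni, rmcorr, stimulus_index)
from foct.synthetic import CohortParams, generate_cohort


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def test_cao2_worked_examples():
    # Hb 150 g/L fully saturated at PaO2 100 mmHg carries 20.7 mL/dL
    assert cao2(150.0, 100.0, 100.0) == pytest.approx(20.7)
    assert cao2(0.0, 50.0, 0.0) == 0.0
    # formula applied to day-0 group means; the printed group mean (20.1) is
    # a mean of per-subject values, so only the formula value is asserted
    assert cao2(150.7, 96.3, 84.8) == pytest.approx(19.99, abs=0.005)
    with pytest.raises(ValueError):
        cao2(150.0, 101.0, 90.0)


def test_stimulus_index_table_values():
    assert round(stimulus_index(37.9, 84.8), 2) == 0.45   # day 0
    assert round(stimulus_index(30.4, 54.5), 2) == 0.56   # day 9
    assert stimulus_index(40.0, 40.0) == 1.0
    with pytest.raises(ZeroDivisionError):
        stimulus_index(40.0, 0.0)


def test_mean_arterial_pressure():
    assert mean_arterial_pressure(120, 80) == pytest.approx(93.333, abs=1e-3)
    assert mean_arterial_pressure(90, 90) == 90.0
    assert mean_arterial_pressure(150, 60) == pytest.approx(90.0)
    with pytest.raises(ValueError):
        mean_arterial_pressure(80, 90)


# ---------------------------------------------------------------------------
# day deltas
# ---------------------------------------------------------------------------

def _long(rows):
    return pd.DataFrame(rows, columns=["subject", "day", "variable", "value"])


def test_day_deltas_hand_example():
    table = _long([("A", 0, "PaO2", 85.0), ("A", 2, "PaO2", 77.0),
                   ("B", 0, "PaO2", 90.0), ("B", 2, "PaO2", 80.0),
                   ("C", 2, "PaO2", 70.0)])  # C misses day 0 -> dropped
    deltas, summary = day_deltas(table, ref_day=0)
    assert set(deltas["subject"]) == {"A", "B"}
    row = summary.iloc[0]
    assert row["mean"] == pytest.approx(-9.0)
    assert row["sd"] == pytest.approx(np.sqrt(2.0))
    assert row["n"] == 2


def test_day_deltas_identical_days_zero():
    table = _long([(s, d, "X", 5.0) for s in "AB" for d in (0, 2)])
    deltas, _ = day_deltas(table, ref_day=0)
    assert np.allclose(deltas["delta"], 0.0)


# ---------------------------------------------------------------------------
# rmcorr
# ---------------------------------------------------------------------------

def _rmcorr_oracle(df, subject, x, y):
    """ANCOVA by explicit normal equations: y ~ subject dummies + x."""
    subjects = sorted(df[subject].unique())
    X = np.column_stack([ (df[subject] == s).to_numpy(float) for s in subjects]
                        + [df[x].to_numpy(float)])
    yv = df[y].to_numpy(float)
    beta = np.linalg.solve(X.T @ X, X.T @ yv)
    resid = yv - X @ beta
    ss_err = resid @ resid
    # error SS of the subject-only model
    X0 = X[:, :-1]
    beta0 = np.linalg.solve(X0.T @ X0, X0.T @ yv)
    ss_err0 = (yv - X0 @ beta0) @ (yv - X0 @ beta0)
    ss_x = ss_err0 - ss_err
    dof = len(yv) - len(subjects) - 1
    f = ss_x / (ss_err / dof)
    p = sps.f.sf(f, 1, dof)
    r = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + ss_err))
    return r, p, beta[-1]


def test_rmcorr_perfect_lines():
    rows = []
    for i, intercept in enumerate([0.0, 5.0, -3.0]):
        for xv in (0.0, 1.0, 2.0):
            rows.append((f"S{i}", xv, intercept + 2.0 * xv))
    df = pd.DataFrame(rows, columns=["subject", "x", "y"])
    res = rmcorr(df)
    assert res.r_rm == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)
    df["y"] = -df["y"]
    assert rmcorr(df).r_rm == pytest.approx(-1.0)


def test_rmcorr_matches_normal_equations_oracle():
    cohort = generate_cohort(CohortParams(n_subjects=14, seed=5))
    wide = cohort.pivot_table(index=["subject", "day"], columns="variable",
                              values="value").reset_index()
    df = wide.rename(columns={"PaO2": "x", "vessel_fraction": "y"})
    res = rmcorr(df)
    r_o, p_o, slope_o = _rmcorr_oracle(df, "subject", "x", "y")
    assert res.r_rm == pytest.approx(r_o, abs=1e-8)
    assert res.p == pytest.approx(p_o, abs=1e-8)
    assert res.slope == pytest.approx(slope_o, abs=1e-8)
    assert res.df == len(df) - 14 - 1


def test_rmcorr_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    cohort = generate_cohort(CohortParams(n_subjects=10, seed=9))
    wide = cohort.pivot_table(index=["subject", "day"], columns="variable",
                              values="value").reset_index()
    res = rmcorr(wide.rename(columns={"PaO2": "x", "SaO2": "y"}))
    pg = pingouin.rm_corr(data=wide, x="PaO2", y="SaO2", subject="subject")
    assert res.r_rm == pytest.approx(float(pg["r"].iloc[0]), abs=1e-6)
    assert res.p == pytest.approx(float(pg["pval"].iloc[0]), abs=1e-6)
    assert res.df == int(pg["dof"].iloc[0])


def test_rmcorr_constant_x_is_error():
    df = pd.DataFrame({"subject": ["A", "A", "B", "B"],
                       "x": [1.0, 1.0, 2.0, 2.0],
                       "y": [0.0, 1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        rmcorr(df)


# ---------------------------------------------------------------------------
# regression and RM-ANOVA
# ---------------------------------------------------------------------------

def test_linregress_exact_and_null():
    x = np.arange(5.0)
    slope, intercept, r2, p = linregress(x, 2.0 * x)
    assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)
    # hand-computed 5-point set via normal equations
    y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    sl_hand = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
    slope, intercept, r2, _ = linregress(x, y)
    assert slope == pytest.approx(sl_hand)
    assert intercept == pytest.approx(y.mean() - sl_hand * x.mean())
    rng = np.random.default_rng(2)
    xn = rng.normal(size=10_000)
    yn = rng.normal(size=10_000)       # independent: planted slope 0
    *_, r2n, _ = linregress(xn, yn)
    assert r2n < 0.01
    with pytest.raises(ValueError):
        linregress(np.ones(5), np.arange(5.0))


def test_rm_anova_identical_days_is_null():
    table = _long([(s, d, "v", 3.0) for s in "ABC" for d in (0, 2, 9)])
    out = rm_anova_bonferroni(table)
    assert out["F"] == 0.0
    assert all(p == 1.0 for p in out["pairwise_p"].values())


def test_rm_anova_detects_planted_day_effect():
    means = {"PaO2": {0: 84.8, 2: 52.5, 9: 54.5}}
    sds = {"PaO2": {0: 2.0, 2: 2.0, 9: 2.0}}   # shift >> SD
    cohort = generate_cohort(CohortParams(n_subjects=18, means=means, sds=sds,
                                          seed=9))
    table = cohort[cohort.variable == "PaO2"]
    out = rm_anova_bonferroni(table)
    assert out["p"] < 1e-3
    assert out["pairwise_p"][(0, 2)] < 1e-3


def test_rm_anova_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM

    cohort = generate_cohort(CohortParams(n_subjects=9, seed=4))
    table = cohort[cohort.variable == "HR"]
    ours = rm_anova_bonferroni(table)
    sm = AnovaRM(table, depvar="value", subject="subject",
                 within=["day"]).fit().anova_table
    assert ours["F"] == pytest.approx(float(sm["F Value"].iloc[0]), rel=1e-10)
    assert ours["p"] == pytest.approx(float(sm["Pr > F"].iloc[0]), abs=1e-12)


def test_bonferroni_is_raw_times_m_capped():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(6, 3))
    rows = [(f"S{i}", d, "v", vals[i, j])
            for i in range(6) for j, d in enumerate((0, 2, 9))]
    out = rm_anova_bonferroni(_long(rows))
    for (a, b), adj in out["pairwise_p"].items():
        da = vals[:, [0, 2, 9].index(a) if a in (0, 2, 9) else 0]
    # recompute one pair by hand
    raw = sps.ttest_rel(vals[:, 0], vals[:, 1]).pvalue
    assert out["pairwise_p"][(0, 2)] == pytest.approx(min(1.0, raw * 3))
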