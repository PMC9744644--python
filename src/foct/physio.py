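"""Hypoxia physiology indices and repeated-measures statistics.

Implements the indices used to characterise a high-altitude sojourn —
arterial oxygen content (CaO2), the stimulus index (PaCO2/PaO2, the balance
of hypoxemic vasodilation against hypocapnic vasoconstriction) and mean
arterial pressure — together with the repeated-measures machinery used to
relate them to retinal outcomes: per-subject day deltas, repeated-measures
correlation (common within-subject slope with subject intercepts), ordinary
linear regression, and one-way repeated-measures ANOVA with Bonferroni
pairwise comparisons. Tests are two-tailed at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PhysioRecord",
    "RmCorrResult",
    "cao2",
    "stimulus_index",
    "mean_arterial_pressure",
    "day_deltas",
    "rmcorr",
    "linregress",
    "rm_anova_bonferroni",
]


@dataclass
class PhysioRecord:
    """One subject-day of arterial blood and cardiorespiratory values.

    Units: PaO2/PaCO2/SBP/DBP mmHg, SaO2 %, Hb g/L, Hct %, HCO3 mmol/L,
    HR beats/min, VE L/min. Missing values are allowed and propagate.
    """

    subject: str
    day: int
    pao2: float | None = None
    paco2: float | None = None
    sao2: float | None = None
    hb: float | None = None
    hct: float | None = None
    hco3: float | None = None
    ph: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    hr: float | None = None
    ve: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if self.sao2 is not None and not (0.0 <= self.sao2 <= 100.0):
            raise ValueError("SaO2 must lie in [0, 100] %")
        for name in ("pao2", "paco2", "sbp", "dbp"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


@dataclass(frozen=True)
class RmCorrResult:
    """Repeated-measures correlation: common within-subject association."""

    r_rm: float
    df: int
    p: float
    slope: float

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.r_rm <= 1.0 + 1e-12):
            raise ValueError("r_rm must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# physiological indices
# ---------------------------------------------------------------------------

def cao2(hb_g_per_l, sao2_pct, pao2_mmhg):
    """Arterial oxygen content, mL O2 / dL blood.

    CaO2 = 1.36 * Hb[g/dL] * SaO2/100 + 0.003 * PaO2, where 1.36 mL/g is the
    O2-binding capacity of haemoglobin and 0.003 mL/dL/mmHg the dissolved
    fraction at 37 C. Hb is passed in g/L and converted internally.
    """
    hb = np.asarray(hb_g_per_l, dtype=float)
    sao2 = np.asarray(sao2_pct, dtype=float)
    pao2 = np.asarray(pao2_mmhg, dtype=float)
    if np.any(sao2 > 100.0) or np.any(sao2 < 0.0):
        raise ValueError("SaO2 must lie in [0, 100] %")
    if np.any(hb < 0) or np.any(pao2 < 0):
        raise ValueError("inputs must be non-negative")
    out = 1.36 * (hb / 10.0) * (sao2 / 100.0) + 0.003 * pao2
    return float(out) if out.ndim == 0 else out


def stimulus_index(paco2_mmhg, pao2_mmhg):
    """Stimulus index PaCO2/PaO2 (dimensionless; reported to two decimals)."""
    paco2 = np.asarray(paco2_mmhg, dtype=float)
    pao2 = np.asarray(pao2_mmhg, dtype=float)
    if np.any(pao2 <= 0):
        raise ZeroDivisionError("PaO2 must be positive")
    out = paco2 / pao2
    return float(out) if out.ndim == 0 else out


def mean_arterial_pressure(sbp_mmhg, dbp_mmhg):
    """MAP = SBP/3 + 2*DBP/3, mmHg."""
    sbp = np.asarray(sbp_mmhg, dtype=float)
    dbp = np.asarray(dbp_mmhg, dtype=float)
    if np.any(dbp <= 0) or np.any(sbp < dbp):
        raise ValueError("require SBP >= DBP > 0")
    out = sbp / 3.0 + 2.0 * dbp / 3.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# repeated-measures statistics
# ---------------------------------------------------------------------------

def day_deltas(table: pd.DataFrame, ref_day) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject changes from a reference day, complete-case.

    ``table`` is long format (subject, day, variable, value). Returns
    ``(deltas, summary)``: deltas holds value(day) - value(ref_day) for each
    subject/variable/day with both days present; summary holds mean, SD and
    n per variable/day, with the number of dropped (incomplete) subjects
    logged.
    """
    days = sorted(set(table["day"]) - {ref_day})
    if ref_day not in set(table["day"]):
        raise ValueError(f"reference day {ref_day!r} not present")
    wide = table.pivot_table(index=["subject", "variable"], columns="day",
                             values="value", aggfunc="first")
    rows = []
    n_dropped = 0
    for day in days:
        if day not in wide.columns:
            continue
        pair = wide[[ref_day, day]].dropna()
        n_dropped += wide[[ref_day, day]].isna().any(axis=1).sum()
        delta = pair[day] - pair[ref_day]
        for (subject, variable), value in delta.items():
            rows.append((subject, day, variable, value))
    if n_dropped:
        logger.info("day_deltas: dropped %d incomplete subject-variable pairs",
                    int(n_dropped))
    deltas = pd.DataFrame(rows, columns=["subject", "day", "variable", "delta"])
    summary = (deltas.groupby(["variable", "day"])["delta"]
               .agg(mean="mean", sd="std", n="count").reset_index())
    return deltas, summary


def rmcorr(table: pd.DataFrame, subject="subject", x="x", y="y") -> RmCorrResult:
    """Repeated-measures correlation.

    Fits y on x with subject-specific intercepts and one common slope
    (equivalently, least squares on within-subject centred x and y);
    r_rm = sign(slope) * sqrt(SS_x / (SS_x + SS_err)) where SS_x is the sum
    of squares removed by x after subject; df = total pairs - N - 1; p from
    F(1, df), two-tailed.
    """
    df_in = table[[subject, x, y]].dropna()
    counts = df_in.groupby(subject).size()
    df_in = df_in[df_in[subject].isin(counts[counts >= 2].index)]
    n_subj = df_in[subject].nunique()
    n_obs = len(df_in)
    if n_subj < 2:
        raise ValueError("rmcorr needs >=2 subjects with >=2 paired observations")
    xs = df_in[x].to_numpy(float)
    ys = df_in[y].to_numpy(float)
    codes = pd.factorize(df_in[subject])[0]
    return _rmcorr_core(codes, xs, ys, n_subj, n_obs)


def _rmcorr_core(codes, xs, ys, n_subj, n_obs) -> RmCorrResult:
    """Array fast path shared with simulation loops."""
    xc = xs - np.bincount(codes, xs)[codes] / np.bincount(codes)[codes]
    yc = ys - np.bincount(codes, ys)[codes] / np.bincount(codes)[codes]
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("x is constant within every subject; rmcorr undefined")
    slope = float(xc @ yc) / sxx
    ss_x = slope**2 * sxx                      # SS removed by x after subject
    ss_err = float(yc @ yc) - ss_x
    dof = n_obs - n_subj - 1
    if dof <= 0:
        raise ValueError("not enough observations for rmcorr")
    denom = ss_x + ss_err
    r = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(ss_x / denom)
    if ss_err <= 0:
        p = 0.0
    else:
        f = ss_x / (ss_err / dof)
        p = float(stats.f.sf(f, 1, dof))
    return RmCorrResult(float(np.clip(r, -1, 1)), dof, p, slope)


def linregress(x, y):
    """OLS slope/intercept with R^2 and the two-sided slope p (t-test).

    Returns ``(slope, intercept, r_squared, p)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue


def rm_anova_bonferroni(table: pd.DataFrame, subject="subject", day="day",
                        value="value") -> dict:
    """One-way repeated-measures ANOVA across days with Bonferroni pairwise
    paired t-tests. Incomplete subjects are dropped (complete-case) and the
    drop count logged; mixed-model handling of missingness is delegated to
    standard packages downstream.
    """
    wide = table.pivot_table(index=subject, columns=day, values=value,
                             aggfunc="first")
    n_before = len(wide)
    wide = wide.dropna()
    n_dropped = n_before - len(wide)
    if n_dropped:
        logger.info("rm_anova: dropped %d incomplete subjects", n_dropped)
    n, k = wide.shape
    if k < 2 or n < 2:
        raise ValueError("need >=2 days and >=2 complete subjects")
    vals = wide.to_numpy(float)
    grand = vals.mean()
    ss_subject = k * ((vals.mean(axis=1) - grand) ** 2).sum()
    ss_day = n * ((vals.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((vals - grand) ** 2).sum()
    ss_err = ss_total - ss_subject - ss_day
    df_day = k - 1
    df_err = (k - 1) * (n - 1)
    ms_day = ss_day / df_day
    ms_err = ss_err / df_err
    if ms_err == 0:
        f_stat, p = 0.0 if ss_day == 0 else np.inf, 1.0 if ss_day == 0 else 0.0
    else:
        f_stat = ms_day / ms_err
        p = float(stats.f.sf(f_stat, df_day, df_err))
    m = k * (k - 1) // 2
    pairwise = {}
    for a, b in combinations(wide.columns, 2):
        da, db = wide[a].to_numpy(), wide[b].to_numpy()
        if np.allclose(da, db):
            raw = 1.0
        else:
            raw = float(stats.ttest_rel(da, db).pvalue)
        pairwise[(a, b)] = min(1.0, raw * m)
    return {
        "F": float(f_stat), "p": p, "df": (df_day, df_err),
        "n_subjects": n, "n_dropped": n_dropped,
        "ss": {"day": float(ss_day), "subject": float(ss_subject),
               "error": float(ss_err)},
        "pairwise_p": pairwise,
    }
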