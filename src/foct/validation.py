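"""Validation experiments: worked examples, oracle equivalence, parameter
recovery, statistical calibration, and the end-to-end study analogue.

Each function runs one self-contained experiment on synthetic data with
known ground truth and returns a flat dict of scalar outcomes. They back
both the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import enface as ef
from . import physio, thickness as th, vessels as vs
from .io import EnFaceImage
from .pipeline import RunConfig, calibrate_pipeline, run_study, segment_enface
from .synthetic import (CohortParams, SceneParams, generate_cohort,
                        generate_volume)

__all__ = [
    "worked_examples",
    "oracle_equivalence",
    "parameter_recovery",
    "thickness_recovery",
    "statistical_calibration",
    "registration_recovery",
    "study_analogue",
    "planted_rmcorr_r2",
]


# ---------------------------------------------------------------------------
# worked examples from the study's group summary
# ---------------------------------------------------------------------------

def worked_examples(seed: int = 0) -> dict:
    """Physiological indices computed from the configured day-wise group
    means, plus the simulated SaO2 day-2 delta at large n."""
    from .synthetic import TABLE1_MEANS

    si0 = physio.stimulus_index(TABLE1_MEANS["PaCO2"][0], TABLE1_MEANS["PaO2"][0])
    si9 = physio.stimulus_index(TABLE1_MEANS["PaCO2"][9], TABLE1_MEANS["PaO2"][9])
    cao2_day0 = physio.cao2(TABLE1_MEANS["Hb"][0], TABLE1_MEANS["SaO2"][0],
                            TABLE1_MEANS["PaO2"][0])
    map_day0 = physio.mean_arterial_pressure(TABLE1_MEANS["SBP"][0],
                                             TABLE1_MEANS["DBP"][0])
    # Monte-Carlo group delta from the cohort generator
    cohort = generate_cohort(CohortParams(n_subjects=10_000,
                                          seed=int(seed % 2**31)))
    _, summary = physio.day_deltas(cohort, ref_day=0)
    sel = summary[(summary.variable == "SaO2") & (summary.day == 2)]
    sao2_delta = float(sel["mean"].iloc[0])
    return {
        "stimulus_index_day0": round(float(si0), 2),
        "stimulus_index_day9": round(float(si9), 2),
        "cao2_day0_ml_per_dl": float(cao2_day0),
        "map_day0_mmhg": float(map_day0),
        "sao2_delta_day2_pct": sao2_delta,
    }


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def _gaussian_kernel(sigma_px):
    radius = int(4.0 * sigma_px + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2.0 * sigma_px**2))
    return k / k.sum()


def _dense_smooth(image, sigma_px_x, sigma_px_y):
    """Separable Gaussian smoothing by direct dense summation (edge
    replication), independent of scipy's filtering path."""
    kx, ky = _gaussian_kernel(sigma_px_x), _gaussian_kernel(sigma_px_y)
    rx, ry = len(kx) // 2, len(ky) // 2
    padded = np.pad(image, ((rx, rx), (ry, ry)), mode="edge")
    nx, ny = image.shape
    tmp = np.zeros((nx, ny + 2 * ry))
    for i in range(nx):
        for j in range(ny + 2 * ry):
            tmp[i, j] = (padded[i: i + 2 * rx + 1, j] * kx).sum()
    out = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            out[i, j] = (tmp[i, j: j + 2 * ry + 1] * ky).sum()
    return out


def frangi_brute_force(data, spacing_um, params) -> np.ndarray:
    """Brute-force vesselness: per-pixel finite-difference Hessian and
    formula evaluation in explicit loops."""
    sx, sy = spacing_um
    nx, ny = data.shape
    best = np.zeros((nx, ny))
    for sigma in params.scales_um:
        sm = _dense_smooth(np.asarray(data, float), sigma / sx, sigma / sy)
        pad = np.pad(sm, 2, mode="edge")
        l1 = np.zeros((nx, ny))
        l2 = np.zeros((nx, ny))
        s2max = 0.0
        for i in range(nx):
            for j in range(ny):
                pi, pj = i + 2, j + 2
                hxx = (pad[pi + 2, pj] - 2 * pad[pi, pj] + pad[pi - 2, pj]) / (4 * sx * sx)
                hyy = (pad[pi, pj + 2] - 2 * pad[pi, pj] + pad[pi, pj - 2]) / (4 * sy * sy)
                hxy = (pad[pi + 2, pj + 2] - pad[pi + 2, pj - 2]
                       - pad[pi - 2, pj + 2] + pad[pi - 2, pj - 2]) / (16 * sx * sy)
                a, b, c = sigma**2 * hxx, sigma**2 * hxy, sigma**2 * hyy
                tr, det = a + c, np.sqrt(((a - c) / 2) ** 2 + b**2)
                e1, e2 = tr / 2 + det, tr / 2 - det
                if abs(e1) > abs(e2):
                    e1, e2 = e2, e1
                l1[i, j], l2[i, j] = e1, e2
                s2max = max(s2max, e1 * e1 + e2 * e2)
        if s2max == 0:
            continue
        cprime = params.c * np.sqrt(s2max)
        vmap = np.zeros((nx, ny))
        for i in range(nx):
            for j in range(ny):
                e1, e2 = l1[i, j], l2[i, j]
                wrong = e2 >= 0 if params.polarity == "bright" else e2 <= 0
                if wrong or e2 == 0:
                    continue
                rb2 = (e1 / e2) ** 2
                s2 = e1 * e1 + e2 * e2
                vmap[i, j] = np.exp(-rb2 / (2 * params.beta**2)) * (
                    1.0 - np.exp(-s2 / (2 * cprime**2)))
        best = np.maximum(best, vmap)
    peak = best.max()
    return best / peak if peak > 0 else best


def oracle_equivalence(seed: int = 0) -> dict:
    """Frangi vs brute force; RPCA planted decomposition; rmcorr vs explicit
    normal-equations ANCOVA."""
    rng = np.random.default_rng(seed + 5)
    data = rng.random((64, 64))
    data[28:34, :] += 1.0
    params = vs.FrangiParams(scales_um=(30.0, 60.0))
    ours = vs.frangi_vesselness(EnFaceImage(data, (20.0, 20.0)), params).data
    oracle = frangi_brute_force(data, (20.0, 20.0), params)
    frangi_err = float(np.abs(ours - oracle).max())

    rng = np.random.default_rng(seed + 11)
    u, v = rng.normal(size=(80, 1)), rng.normal(size=(1, 60))
    L0 = u @ v
    S0 = np.zeros((80, 60))
    idx = rng.random(S0.shape) < 0.01
    S0[idx] = rng.normal(scale=5.0, size=int(idx.sum()))
    res = vs.rpca_decompose(L0 + S0, vs.RpcaParams(tol=1e-8, max_iter=1000))
    rpca_err = float(np.linalg.norm(res.low_rank - L0) / np.linalg.norm(L0))

    import pandas as pd

    cohort = generate_cohort(CohortParams(n_subjects=14, seed=seed + 5))
    wide = cohort.pivot_table(index=["subject", "day"], columns="variable",
                              values="value").reset_index()
    df = wide.rename(columns={"PaO2": "x", "vessel_fraction": "y"})
    ours_rm = physio.rmcorr(df)
    # explicit normal-equations ANCOVA
    subjects = sorted(df["subject"].unique())
    X = np.column_stack([(df["subject"] == s).to_numpy(float) for s in subjects]
                        + [df["x"].to_numpy(float)])
    yv = df["y"].to_numpy(float)
    beta = np.linalg.solve(X.T @ X, X.T @ yv)
    ss_err = float((yv - X @ beta) @ (yv - X @ beta))
    X0 = X[:, :-1]
    beta0 = np.linalg.solve(X0.T @ X0, X0.T @ yv)
    ss_err0 = float((yv - X0 @ beta0) @ (yv - X0 @ beta0))
    ss_x = ss_err0 - ss_err
    dof = len(yv) - len(subjects) - 1
    r_oracle = float(np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + ss_err)))
    p_oracle = float(sps.f.sf(ss_x / (ss_err / dof), 1, dof))
    rmcorr_err = max(abs(ours_rm.r_rm - r_oracle), abs(ours_rm.p - p_oracle))
    return {
        "frangi_oracle_max_abs_diff": frangi_err,
        "rpca_recovery_rel_frobenius": rpca_err,
        "rmcorr_oracle_max_abs_diff": float(rmcorr_err),
    }


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def parameter_recovery(seed: int = 0, grid=(256, 128, 512),
                       eval_fractions=(0.03, 0.045, 0.06, 0.075),
                       n_repeat: int = 2) -> dict:
    """Calibrate the pipeline on phantoms, then recover planted vessel
    fractions on held-out scenes (top-k repeat-scan aggregates)."""
    config = RunConfig(seed=int(seed), grid_shape=tuple(grid))
    threshold, contrast = calibrate_pipeline(config)
    errors = {}
    for i, frac in enumerate(eval_fractions):
        scene_seed = int((seed * 31337 + i) % 2**31)
        estimates, truth_frac = [], None
        for k in range(n_repeat):
            volume, truth = generate_volume(SceneParams(
                grid_shape=tuple(grid), target_vessel_fraction=float(frac),
                seed=scene_seed, noise_seed=int((scene_seed + 1000 * (k + 1)) % 2**31)))
            surfaces = th.extract_surfaces(volume, config.smoothness)
            image = ef.project_enface(volume, surfaces, config.band_um,
                                      config.reducer)
            _, mask = segment_enface(image, config, threshold=threshold,
                                     contrast_scale=contrast)
            estimates.append(float(mask.data.mean()))
            truth_frac = truth.true_vessel_fraction
        est = float(np.mean(estimates))
        errors[frac] = (est - truth_frac) / truth_frac
    rel = np.array(list(errors.values()))
    return {
        "rvpd_recovery_max_rel_err_pct": float(100.0 * np.abs(rel).max()),
        "rvpd_recovery_mean_rel_err_pct": float(100.0 * np.abs(rel).mean()),
        "calibrated_threshold": float(threshold),
    }


def thickness_recovery(seed: int = 0, grid=(128, 64, 256),
                       n_seeds: int = 10) -> dict:
    """Recover the planted 300 um mean RT and a planted -3 um thinning."""
    diffs, rts = [], []
    for k in range(n_seeds):
        scene_seed = int((seed * 7919 + k) % 2**31)
        pair = []
        for thick in (300.0, 297.0):
            volume, _ = generate_volume(SceneParams(
                grid_shape=tuple(grid), mean_thickness_um=thick,
                seed=scene_seed))
            surf = th.extract_surfaces(volume)
            pair.append(th.thickness_from_surfaces(surf, volume.spacing_um)
                        .mean_rt_um)
        rts.append(pair[0])
        diffs.append(pair[1] - pair[0])
    return {
        "mean_rt_recovered_um": float(np.mean(rts)),
        "rt_shift_recovered_um": float(np.mean(diffs)),
        "rt_shift_bias_um": float(abs(np.mean(diffs) - (-3.0))),
    }


# ---------------------------------------------------------------------------
# statistical calibration
# ---------------------------------------------------------------------------

def planted_rmcorr_r2(params: CohortParams, days=(0, 2)) -> float:
    """Analytic within-subject R^2 planted between vessel fraction and PaO2
    for two measurement days under the cohort model."""
    d0, d1 = days
    m0, m1 = params.means["PaO2"][d0], params.means["PaO2"][d1]
    s0, s1 = params.sds["PaO2"][d0], params.sds["PaO2"][d1]
    w = params.within_subject_sd
    ex2 = (m0 - m1) ** 2 + (1 - w**2) * (s0 - s1) ** 2 + w**2 * (s0**2 + s1**2)
    num = params.rvpd_pao2_slope**2 * ex2 / 2.0
    return num / (num + params.rvpd_resid_sd**2)


def _simulate_pairs(rng, params: CohortParams, n_subjects, null=False):
    """Fast two-day (x, y) draw following the cohort model."""
    w = params.within_subject_sd
    between = np.sqrt(1 - w**2)
    b = rng.standard_normal(n_subjects)
    xs, ys = [], []
    base = params.rvpd_base_mean + params.rvpd_base_sd * rng.standard_normal(n_subjects)
    ref = params.means["PaO2"][0]
    for d in (0, 2):
        mu, sd = params.means["PaO2"][d], params.sds["PaO2"][d]
        x = mu + sd * (between * b + w * rng.standard_normal(n_subjects))
        slope = 0.0 if null else params.rvpd_pao2_slope
        y = base + slope * (x - ref) + params.rvpd_resid_sd * rng.standard_normal(n_subjects)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    codes = np.tile(np.arange(n_subjects), 2)
    return codes, x, y


def statistical_calibration(seed: int = 0, n_null: int = 2000,
                            n_power: int = 500, n_subjects: int = 14) -> dict:
    """Type-I error of rmcorr on null draws and recovery of the planted
    within-subject R^2 (~0.45, the study's rVPD-PaO2 effect size)."""
    params = CohortParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))
    rejections = 0
    for _ in range(n_null):
        codes, x, y = _simulate_pairs(rng, params, n_subjects, null=True)
        res = physio._rmcorr_core(codes, x, y, n_subjects, 2 * n_subjects)
        rejections += res.p < 0.05
    r2s = []
    for _ in range(n_power):
        codes, x, y = _simulate_pairs(rng, params, n_subjects, null=False)
        res = physio._rmcorr_core(codes, x, y, n_subjects, 2 * n_subjects)
        r2s.append(res.r_rm**2)
    return {
        "rmcorr_type1_error_pct": float(100.0 * rejections / n_null),
        "rmcorr_r2_recovered": float(np.mean(r2s)),
        "rmcorr_r2_planted": float(planted_rmcorr_r2(params)),
    }


# ---------------------------------------------------------------------------
# registration recovery
# ---------------------------------------------------------------------------

def registration_recovery(seed: int = 0) -> dict:
    """Planted shifts (<=10 px) and rotations (<=10 deg) recovered from a
    textured synthetic en-face image."""
    volume, truth = generate_volume(SceneParams(
        grid_shape=(96, 96, 96), extent_mm=(3.0, 3.0, 1.0),
        seed=int((seed + 9) % 2**31)))
    image = ef.project_enface(volume, truth, band=(0.0, 60.0), reducer="mean")
    shift_errs, rot_errs = [], []
    for t in (ef.RigidTransform(0.0, 10.0, -7.0),
              ef.RigidTransform(4.0, 3.0, 2.0),
              ef.RigidTransform(-10.0, -6.0, 9.0),
              ef.RigidTransform(8.0, 0.0, 0.0)):
        moved = ef.apply_transform(image, t)
        rec = ef.register_rigid(image, moved)
        inv = t.inverse()
        rot_errs.append(abs(rec.rotation_deg - inv.rotation_deg))
        shift_errs.append(max(abs(rec.shift_x_px - inv.shift_x_px),
                              abs(rec.shift_y_px - inv.shift_y_px)))
    return {
        "registration_max_shift_err_px": float(max(shift_errs)),
        "registration_max_rot_err_deg": float(max(rot_errs)),
    }


# ---------------------------------------------------------------------------
# end-to-end study analogue
# ---------------------------------------------------------------------------

def study_analogue(seed: int = 0, n_subjects: int = 18,
                   grid=(128, 64, 256)) -> dict:
    """Full simulated expedition: day-0 vs day-2 rVPD with the planted
    +0.6 pp day-2 vessel-fraction increase on a 4.4% base."""
    config = RunConfig(seed=int(seed), n_subjects=n_subjects, days=(0, 2),
                       images_per_subject_day=2, grid_shape=tuple(grid),
                       n_calibration=4)
    result = run_study(config)
    wide = result.per_subject_day.pivot_table(index="subject", columns="day",
                                              values="rvpd_pct")
    delta = wide[2] - wide[0]
    p_paired = float(sps.ttest_rel(wide[2], wide[0]).pvalue)
    out = {
        "study_day0_rvpd_pct": float(wide[0].mean()),
        "study_day2_rvpd_pct": float(wide[2].mean()),
        "study_day2_rvpd_increase_pp": float(delta.mean()),
        "study_day2_paired_p": p_paired,
    }
    rm = result.stats.get("rvpd_pao2_rmcorr")
    if rm is not None:
        out["study_rmcorr_r_rm"] = float(rm["r_rm"])
    return out
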