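"""End-to-end study orchestration.

Runs the full analysis analogue: simulate (or ingest) repeated macular scans
per subject and day, score and reject low-quality scans, extract surfaces,
project the superficial slab, rigidly coregister repeats, remove artifacts,
segment vessels with one shared global threshold, compute rVPD and mean RT
per subject-day, join with the physiology table, and run the
repeated-measures statistics. Every run is reproducible from (config, seed)
and writes its resolved configuration beside the results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enface as ef
from . import physio, thickness as th, vessels as vs
from .io import EnFaceImage, OctVolume, _NumpyEncoder
from .synthetic import CohortParams, SceneParams, generate_cohort, generate_volume

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyResult", "run_study", "segment_enface",
           "calibrate_threshold", "calibrate_pipeline", "process_volume"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one study run."""

    mode: str = "simulate"                # simulate | directory
    input_dir: str | None = None
    n_subjects: int = 18
    days: tuple = (0, 2)
    images_per_subject_day: int = 2
    grid_shape: tuple = (128, 64, 256)    # study-analogue scale
    qc_threshold: int = 8
    top_k: int = 3
    band_um: tuple = (0.0, 120.0)
    reducer: str = "mean"
    motion_px: float = 3.0                # planted inter-scan motion amplitude
    motion_deg: float = 1.5
    denoise_sigma_um: float = 15.0
    clahe_clip: float = 0.01
    use_rpca: bool = True
    min_elongation: float = 2.5
    min_area_px: int = 30
    support_threshold: float = 0.01      # component support for artifact filtering
    gate_softness: float = 0.05          # vesselness gate half-response point
    contrast_quantile: float = 0.95      # in-vessel quantile for contrast scale
    measure_upsample: int = 2            # subpixel area measurement factor
    smoothness: int = 2
    n_calibration: int = 6               # phantom count for threshold calibration
    frangi: vs.FrangiParams = field(default_factory=vs.FrangiParams)
    rpca: vs.RpcaParams = field(default_factory=vs.RpcaParams)
    cohort_overrides: dict = field(default_factory=dict)
    scene_overrides: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class StudyResult:
    """Per-subject-day retinal outcomes plus cohort-level statistics."""

    per_subject_day: pd.DataFrame
    day_summary: pd.DataFrame
    stats: dict
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "per_subject_day": self.per_subject_day.to_dict(orient="records"),
            "day_summary": self.day_summary.to_dict(orient="records"),
            "stats": self.stats,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder)


def _probability_parts(image: EnFaceImage, config: RunConfig):
    """Shared vessel-probability computation for one en-face image.

    Stages: Gaussian denoise; robust-PCA destriping (the separable part of
    the low-rank component is the vertical/horizontal band artifact and is
    subtracted); CLAHE feeding multiscale Frangi vesselness; disc/speck
    suppression. The final probability is a soft vesselness gate (locating
    tubes) times the destriped intensity above background (carrying vessel
    calibre), normalised by a contrast scale shared across the whole study
    so that one global threshold means the same physical cut everywhere.

    Returns ``(gate, intensity, background_median, image_contrast)``.
    """
    dn = vs.denoise(image, config.denoise_sigma_um)
    prov = dict(dn.provenance)
    if config.use_rpca:
        rp = vs.rpca_decompose(dn.data, config.rpca)
        rclean = dn.data - vs.separable_field(rp.low_rank)
        prov.update({"rpca_converged": rp.converged, "rpca_iters": rp.n_iter})
    else:
        rclean = dn.data
    enh = vs.enhance_contrast(EnFaceImage(rclean, image.spacing_um, prov),
                              config.clahe_clip)
    vmap = vs.frangi_vesselness(enh, config.frangi)
    vmap = vs.suppress_circular_artifacts(vmap, config.min_elongation,
                                          support_threshold=config.support_threshold,
                                          min_area_px=config.min_area_px)
    gate = vmap.data / (vmap.data + config.gate_softness)
    support = vmap.data > 0.05
    bg = rclean[~support]
    med = float(np.median(bg if bg.size else rclean))
    inside = rclean[support]
    contrast = float(np.quantile(inside, config.contrast_quantile) - med) \
        if inside.size else float(rclean.max() - med + 1e-9)
    return gate, rclean, med, contrast


def segment_enface(image: EnFaceImage, config: RunConfig = RunConfig(),
                   threshold: float | None = None,
                   contrast_scale: float | None = None):
    """Compute the vessel probability map of one en-face image; threshold it
    if a threshold is given.

    ``contrast_scale`` is the study-level intensity contrast (from
    :func:`calibrate_pipeline`); standalone calls fall back to the image's
    own contrast estimate. Returns ``(prob_map, mask_or_None)``.
    """
    from scipy import ndimage

    gate, rclean, med, c_img = _probability_parts(image, config)
    scale = contrast_scale if contrast_scale is not None else c_img
    prob = np.clip(gate * np.clip((rclean - med) / max(scale, 1e-9), 0.0, 1.0),
                   0.0, 1.0)
    up = max(1, int(config.measure_upsample))
    if up > 1:  # subpixel area measurement: threshold crossings land between
        prob = np.clip(ndimage.zoom(prob, (up, up), order=1), 0.0, 1.0)
    spacing = tuple(s / up for s in image.spacing_um)
    pmap = vs.VesselProbabilityMap(prob, config.frangi, spacing,
                                   provenance={**image.provenance,
                                               "contrast_scale": scale,
                                               "background_median": med,
                                               "measure_upsample": up})
    if threshold is None:
        return pmap, None
    return pmap, vs.global_threshold(pmap, method="fixed", t=threshold)


def calibrate_threshold(prob_maps, true_fractions=None) -> float:
    """One global threshold shared by every image of every subject.

    With known planted fractions (synthetic phantom calibration) the
    threshold minimises the summed squared relative area error over the
    calibration set; without ground truth it falls back to Otsu on the
    pooled probability values.
    """
    from skimage.filters import threshold_otsu

    arrays = [np.asarray(getattr(p, "data", p)) for p in prob_maps]
    if true_fractions is None:
        pooled = np.concatenate([a.ravel() for a in arrays])
        return float(threshold_otsu(pooled))
    grid = np.linspace(0.05, 0.95, 181)
    best_t, best_loss = grid[0], np.inf
    for t in grid:
        loss = sum(((a > t).mean() - f) ** 2 / f**2
                   for a, f in zip(arrays, true_fractions))
        if loss < best_loss:
            best_t, best_loss = float(t), loss
    return best_t


def calibrate_pipeline(config: RunConfig, grid_shape=None):
    """Fix the study-level segmentation constants on synthetic phantoms.

    Generates ``config.n_calibration`` phantom volumes with planted vessel
    fractions spanning the operating range (3-8%), runs the probability
    chain, and returns ``(threshold, contrast_scale)``: the global contrast
    scale is the median per-phantom contrast, the global threshold minimises
    the relative area error against the planted fractions. Both constants
    are then applied unchanged to every study image.
    """
    from .thickness import extract_surfaces

    grid = grid_shape or config.grid_shape
    n = max(2, config.n_calibration)
    fractions = np.linspace(0.03, 0.08, n)
    images, contrasts, truths = [], [], []
    for i, frac in enumerate(fractions):
        params = SceneParams(grid_shape=tuple(grid),
                             target_vessel_fraction=float(frac),
                             seed=int((config.seed * 99991 + 7 * i + 5) % 2**31),
                             **config.scene_overrides)
        volume, truth = generate_volume(params)
        surfaces = extract_surfaces(volume, config.smoothness)
        image = ef.project_enface(volume, surfaces, config.band_um, config.reducer)
        contrasts.append(_probability_parts(image, config)[3])
        images.append(image)
        truths.append(truth.true_vessel_fraction)
    contrast = float(np.median(contrasts))
    probs = [segment_enface(img, config, contrast_scale=contrast)[0]
             for img in images]
    threshold = calibrate_threshold(probs, truths)
    return threshold, contrast


def process_volume(volume: OctVolume, config: RunConfig):
    """QC, surfaces, thickness and projection for one scan.

    Returns ``(quality, surfaces, thickness_map, enface_image)`` or ``None``
    if the scan fails QC.
    """
    q = ef.quality_score(volume)
    if q.score < config.qc_threshold:
        return None
    surfaces = th.extract_surfaces(volume, config.smoothness)
    tmap = th.thickness_from_surfaces(surfaces, volume.spacing_um)
    image = ef.project_enface(volume, surfaces, config.band_um, config.reducer)
    return q, surfaces, tmap, image


def _simulate_images(config: RunConfig, fractions: dict):
    """Yield (subject, day, image_idx, volume, truth) for the simulated cohort.

    Repeated scans of one subject-day share anatomy (same scene seed) but
    carry independent speckle/artifact noise, plus a small rigid scene
    motion relative to the subject's first scan (inter-scan eye motion,
    planted in continuous coordinates so no image is ever resampled).
    """
    mrng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                        spawn_key=(42,)))
    counter = 0
    first_of_subject = set()
    for (subject, day), frac in sorted(fractions.items()):
        scene_seed = int((config.seed * 100003 + counter) % 2**31)
        counter += 1
        for i in range(config.images_per_subject_day):
            noise_seed = int((scene_seed + 7919 * (i + 1)) % 2**31)
            motion = None
            if subject in first_of_subject or i > 0:
                if config.motion_px > 0 or config.motion_deg > 0:
                    px_mm = 6.0 / config.grid_shape[0]
                    motion = (float(mrng.uniform(-config.motion_deg,
                                                 config.motion_deg)),
                              float(mrng.uniform(-config.motion_px,
                                                 config.motion_px) * px_mm),
                              float(mrng.uniform(-config.motion_px,
                                                 config.motion_px) * px_mm))
            params = SceneParams(
                grid_shape=config.grid_shape,
                target_vessel_fraction=float(frac),
                seed=scene_seed,
                noise_seed=noise_seed,
                motion=motion,
                **config.scene_overrides,
            )
            volume, truth = generate_volume(params)
            volume.meta.update({"subject": subject, "day": day, "image": i})
            yield subject, day, i, volume, truth
        first_of_subject.add(subject)


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full study analogue and return a :class:`StudyResult`.

    A stage failure aborts that subject-day with a logged reason; the run
    continues. If every image fails QC the result is empty and flagged.
    """
    t0 = time.time()
    cohort = generate_cohort(CohortParams(
        n_subjects=config.n_subjects, days=tuple(config.days),
        seed=config.seed, **config.cohort_overrides))
    frac_table = cohort[cohort["variable"] == "vessel_fraction"]
    fractions = {(r.subject, r.day): r.value for r in frac_table.itertuples()}

    # ---- stage 1: per-image QC, surfaces, projection -----------------------
    images = {}     # (subject, day) -> list of dicts
    references = {}  # subject -> reference EnFaceImage
    n_rejected = 0
    for subject, day, i, volume, truth in _simulate_images(config, fractions):
        t_img = time.time()
        try:
            processed = process_volume(volume, config)
        except ValueError as exc:
            logger.warning("subject %s day %s image %d failed: %s",
                           subject, day, i, exc)
            continue
        if processed is None:
            n_rejected += 1
            logger.info("subject %s day %s image %d rejected by QC", subject, day, i)
            continue
        q, surfaces, tmap, image = processed
        # registration recovers the transform aligning this scan to the
        # subject's reference (inter-scan motion is planted in the scene).
        # The transform is recorded but the image is NOT resampled for
        # measurement: rVPD and RT are area statistics, invariant to rigid
        # motion, and resampling would blur vessels.
        transform = ef.RigidTransform()
        if subject not in references:
            references[subject] = image
        else:
            transform = ef.register_rigid(references[subject], image)
        images.setdefault((subject, day), []).append(
            {"image": i, "quality": q, "enface": image, "rt": tmap,
             "transform": (transform.rotation_deg, transform.shift_x_px,
                           transform.shift_y_px),
             "true_fraction": truth.true_vessel_fraction})
        logger.info("stage=image subject=%s day=%s image=%d qc=%d dt=%.2fs",
                    subject, day, i, q.score, time.time() - t_img)

    if not images:
        logger.warning("all images rejected by QC; empty result")
        return StudyResult(pd.DataFrame(), pd.DataFrame(),
                           {"empty": True, "n_rejected": n_rejected},
                           {"config": config.to_dict(), "seed": config.seed})

    # ---- stage 2: calibrated constants, then probability maps --------------
    threshold, contrast = calibrate_pipeline(config)
    for imgs in images.values():
        for rec in imgs:
            rec["prob"], _ = segment_enface(rec["enface"], config,
                                            contrast_scale=contrast)

    # ---- stage 3: masks, rVPD and RT per subject-day -----------------------
    rows = []
    for (subject, day), imgs in sorted(images.items()):
        results, qualities, rts = [], [], []
        for rec in imgs:
            mask = vs.global_threshold(rec["prob"], method="fixed", t=threshold)
            results.append(vs.compute_rvpd(mask, image_id=rec["image"]))
            qualities.append(rec["quality"].score)
            rts.append(rec["rt"])
        agg = vs.aggregate_subject(results, qualities, config.top_k)
        rt_um = th.aggregate_rt(rts, qualities, config.top_k)
        rows.append({"subject": subject, "day": day,
                     "rvpd_pct": agg.rvpd_pct, "mean_rt_um": rt_um,
                     "true_fraction_pct": 100.0 * float(np.mean(
                         [rec["true_fraction"] for rec in imgs])),
                     "n_images": len(imgs),
                     "qc_scores": [q for q in qualities]})
    per_sd = pd.DataFrame(rows).sort_values(["subject", "day"]).reset_index(drop=True)

    # ---- stage 4: join physiology and run statistics -----------------------
    phys_wide = (cohort[cohort["variable"] != "vessel_fraction"]
                 .pivot_table(index=["subject", "day"], columns="variable",
                              values="value", aggfunc="first").reset_index())
    merged = per_sd.merge(phys_wide, on=["subject", "day"], how="left")

    day_summary = (per_sd.groupby("day")[["rvpd_pct", "mean_rt_um"]]
                   .agg(["mean", "std"]).reset_index())
    day_summary.columns = ["day"] + [f"{a}_{b}" for a, b in day_summary.columns[1:]]

    stats_out = {"threshold": threshold, "contrast_scale": contrast,
                 "n_rejected": n_rejected}
    try:
        long_rvpd = per_sd.rename(columns={"rvpd_pct": "value"})[
            ["subject", "day", "value"]]
        anova = physio.rm_anova_bonferroni(long_rvpd)
        stats_out["rvpd_anova"] = {
            "F": anova["F"], "p": anova["p"],
            "pairwise_p": {f"{a}-{b}": p for (a, b), p in anova["pairwise_p"].items()},
        }
    except ValueError as exc:
        logger.warning("rVPD ANOVA skipped: %s", exc)
    try:
        rm = physio.rmcorr(merged.rename(columns={"PaO2": "x", "rvpd_pct": "y"}),
                           subject="subject", x="x", y="y")
        stats_out["rvpd_pao2_rmcorr"] = {"r_rm": rm.r_rm, "p": rm.p,
                                         "df": rm.df, "slope": rm.slope}
    except ValueError as exc:
        logger.warning("rmcorr skipped: %s", exc)
    try:
        days = sorted(per_sd["day"].unique())
        if len(days) >= 2:
            wide = merged.pivot_table(index="subject", columns="day",
                                      values=["rvpd_pct", "PaO2"]).dropna()
            d0, d1 = days[0], days[1]
            dx = (wide[("PaO2", d1)] - wide[("PaO2", d0)]).to_numpy()
            dy = (wide[("rvpd_pct", d1)] - wide[("rvpd_pct", d0)]).to_numpy()
            slope, intercept, r2, p = physio.linregress(dx, dy)
            stats_out["delta_regression"] = {"slope": slope, "intercept": intercept,
                                             "r_squared": r2, "p": p,
                                             "x": "delta_PaO2", "y": "delta_rvpd_pct"}
    except ValueError as exc:
        logger.warning("delta regression skipped: %s", exc)

    provenance = {"config": config.to_dict(), "seed": config.seed,
                  "runtime_s": round(time.time() - t0, 2),
                  "n_images": int(sum(len(v) for v in images.values()))}
    result = StudyResult(merged, day_summary, stats_out, provenance)

    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: StudyResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "study_result.json").write_text(result.to_json() + "\n")
    result.per_subject_day.to_csv(out / "per_subject_day.csv", index=False)
    result.day_summary.to_csv(out / "day_summary.csv", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
    try:
        _write_figures(result, out)
    except Exception as exc:  # plotting must never kill a run
        logger.warning("figure generation failed: %s", exc)


def _write_figures(result: StudyResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.per_subject_day
    for col, fname, ylabel in (("rvpd_pct", "rvpd_by_day.png", "rVPD (%)"),
                               ("mean_rt_um", "rt_by_day.png", "RT (um)")):
        fig, ax = plt.subplots(figsize=(4, 3))
        for subject, grp in df.groupby("subject"):
            ax.plot(grp["day"], grp[col], "o-", color="0.7", lw=0.8, ms=3)
        means = df.groupby("day")[col].mean()
        ax.plot(means.index, means.values, "ks-", ms=6, label="group mean")
        ax.set_xlabel("day")
        ax.set_ylabel(ylabel)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=120)
        plt.close(fig)
    reg = result.stats.get("delta_regression")
    if reg is not None and "PaO2" in df.columns:
        days = sorted(df["day"].unique())[:2]
        wide = df.pivot_table(index="subject", columns="day",
                              values=["rvpd_pct", "PaO2"]).dropna()
        dx = wide[("PaO2", days[1])] - wide[("PaO2", days[0])]
        dy = wide[("rvpd_pct", days[1])] - wide[("rvpd_pct", days[0])]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(dx, dy, "ko", ms=4)
        xs = np.linspace(dx.min(), dx.max(), 10)
        ax.plot(xs, reg["intercept"] + reg["slope"] * xs, "r-",
                label=f"$R^2$={reg['r_squared']:.2f}")
        ax.set_xlabel(r"$\Delta$ PaO2 (mmHg)")
        ax.set_ylabel(r"$\Delta$ rVPD (%)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / "delta_scatter.png", dpi=120)
        plt.close(fig)
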