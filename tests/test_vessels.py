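"""Vessel pipeline stages: denoising, CLAHE, RPCA, Frangi, thresholding, rVPD.

The Frangi implementation is checked against a brute-force oracle that
builds the sampled Gaussian kernels explicitly, convolves by direct dense
summation, and evaluates the vesselness formula per pixel.
"""

import numpy as np
import pytest

import foct
from foct.io import EnFaceImage
from foct.vessels import (FrangiParams, PerfusionResult, RpcaParams,
                          VesselProbabilityMap, aggregate_subject,
                          compute_rvpd, denoise, enhance_contrast,
                          frangi_vesselness, global_threshold, rpca_decompose,
                          suppress_circular_artifacts)


# ---------------------------------------------------------------------------
# denoise / enhance
# ---------------------------------------------------------------------------

def test_denoise_identity_constant_and_variance():
    rng = np.random.default_rng(0)
    img = EnFaceImage(rng.random((64, 64)), (20.0, 20.0))
    assert denoise(img, 0.0) is img
    const = EnFaceImage(np.full((32, 32), 0.4), (20.0, 20.0))
    np.testing.assert_allclose(denoise(const, 30.0).data, 0.4, atol=1e-9)
    assert denoise(img, 20.0).data.var() < img.data.var()


def test_clahe_contract(tube_image):
    const = EnFaceImage(np.full((64, 64), 0.3), (20.0, 20.0))
    out = enhance_contrast(const)
    assert np.ptp(out.data) == 0.0            # no spurious structure
    rng = np.random.default_rng(1)
    img = EnFaceImage(rng.random((64, 64)), (20.0, 20.0))
    out = enhance_contrast(img)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
    # separation between tube and background grows on a low-contrast tube
    weak = EnFaceImage(0.01 * tube_image.data, tube_image.spacing_um)
    enh = enhance_contrast(weak)
    tube = weak.data > np.quantile(weak.data, 0.9)
    sep_before = np.median(weak.data[tube]) - np.median(weak.data[~tube])
    sep_after = np.median(enh.data[tube]) - np.median(enh.data[~tube])
    assert sep_after > sep_before


# ---------------------------------------------------------------------------
# robust PCA
# ---------------------------------------------------------------------------

def test_rpca_zero_matrix():
    res = rpca_decompose(np.zeros((20, 10)))
    assert res.converged
    assert np.all(res.low_rank == 0) and np.all(res.sparse == 0)


def test_rpca_recovers_planted_rank1_plus_sparse():
    rng = np.random.default_rng(11)
    u = rng.normal(size=(80, 1))
    v = rng.normal(size=(1, 60))
    L0 = u @ v
    S0 = np.zeros((80, 60))
    idx = rng.random(S0.shape) < 0.01           # 1% support spikes
    S0[idx] = rng.normal(scale=5.0, size=idx.sum())
    res = rpca_decompose(L0 + S0, RpcaParams(tol=1e-8, max_iter=1000))
    assert res.converged
    assert np.linalg.norm(res.low_rank - L0) / np.linalg.norm(L0) <= 1e-3
    assert np.linalg.norm(res.sparse - S0) / np.linalg.norm(S0) <= 1e-3


def test_rpca_reconstruction_within_tol():
    rng = np.random.default_rng(3)
    M = rng.normal(size=(40, 30))
    res = rpca_decompose(M, RpcaParams(tol=1e-6))
    rel = np.linalg.norm(M - res.low_rank - res.sparse) / np.linalg.norm(M)
    assert rel <= 1e-6


def test_rpca_flags_non_convergence():
    rng = np.random.default_rng(4)
    M = rng.normal(size=(40, 30))
    with pytest.warns(UserWarning, match="converge"):
        res = rpca_decompose(M, RpcaParams(tol=1e-14, max_iter=3))
    assert not res.converged


# ---------------------------------------------------------------------------
# Frangi vesselness + oracle
# ---------------------------------------------------------------------------

def _gaussian_kernel(sigma_px):
    radius = int(4.0 * sigma_px + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2.0 * sigma_px**2))
    return k / k.sum()


def _dense_smooth(image, sigma_px_x, sigma_px_y):
    """Separable Gaussian smoothing by direct dense summation with edge
    replication (mirrors scipy's 'nearest' mode)."""
    kx = _gaussian_kernel(sigma_px_x)
    ky = _gaussian_kernel(sigma_px_y)
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


def frangi_oracle(image, spacing_um, params):
    """Brute-force vesselness: dense convolution smoothing, per-pixel finite
    differences and formula evaluation in plain loops."""
    sx, sy = spacing_um
    data = np.asarray(image, float)
    nx, ny = data.shape
    best = np.zeros((nx, ny))
    for sigma in params.scales_um:
        sm = _dense_smooth(data, sigma / sx, sigma / sy)
        pad = np.pad(sm, 2, mode="edge")
        vmap = np.zeros((nx, ny))
        hxx = np.zeros((nx, ny))
        hxy = np.zeros((nx, ny))
        hyy = np.zeros((nx, ny))
        for i in range(nx):
            for j in range(ny):
                pi, pj = i + 2, j + 2
                hxx[i, j] = (pad[pi + 2, pj] - 2 * pad[pi, pj] + pad[pi - 2, pj]) / (4 * sx * sx)
                hyy[i, j] = (pad[pi, pj + 2] - 2 * pad[pi, pj] + pad[pi, pj - 2]) / (4 * sy * sy)
                hxy[i, j] = (pad[pi + 2, pj + 2] - pad[pi + 2, pj - 2]
                             - pad[pi - 2, pj + 2] + pad[pi - 2, pj - 2]) / (16 * sx * sy)
        s2max = 0.0
        l1 = np.zeros((nx, ny))
        l2 = np.zeros((nx, ny))
        for i in range(nx):
            for j in range(ny):
                a, b, c = sigma**2 * hxx[i, j], sigma**2 * hxy[i, j], sigma**2 * hyy[i, j]
                tr, det = a + c, np.sqrt(((a - c) / 2) ** 2 + b**2)
                e1, e2 = tr / 2 + det, tr / 2 - det
                if abs(e1) > abs(e2):
                    e1, e2 = e2, e1
                l1[i, j], l2[i, j] = e1, e2
                s2max = max(s2max, e1 * e1 + e2 * e2)
        if s2max == 0:
            continue
        cprime = params.c * np.sqrt(s2max)
        for i in range(nx):
            for j in range(ny):
                e1, e2 = l1[i, j], l2[i, j]
                if e2 >= 0 if params.polarity == "bright" else e2 <= 0:
                    continue
                if e2 == 0:
                    continue
                rb2 = (e1 / e2) ** 2
                s2 = e1 * e1 + e2 * e2
                v = np.exp(-rb2 / (2 * params.beta**2)) * (
                    1.0 - np.exp(-s2 / (2 * cprime**2)))
                vmap[i, j] = v
        best = np.maximum(best, vmap)
    peak = best.max()
    return best / peak if peak > 0 else best


def test_frangi_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    data = rng.random((64, 64))
    data[28:34, :] += 1.0                      # a horizontal ridge
    img = EnFaceImage(data, (20.0, 20.0))
    params = FrangiParams(scales_um=(30.0, 60.0))
    ours = frangi_vesselness(img, params).data
    oracle = frangi_oracle(data, (20.0, 20.0), params)
    assert np.abs(ours - oracle).max() <= 1e-6


def test_frangi_constant_image_is_zero():
    img = EnFaceImage(np.full((32, 32), 0.7), (20.0, 20.0))
    out = frangi_vesselness(img).data
    assert np.all(out == 0.0)


def test_frangi_tube_beats_blob_and_centerline_peaks(tube_image):
    nx, ny = tube_image.data.shape
    spacing = tube_image.spacing_um
    bx, by = 3 * nx // 4, ny // 4              # blob centre off the tube
    dx = (np.arange(nx) - bx)[:, None] * spacing[0]
    dy = (np.arange(ny) - by)[None, :] * spacing[1]
    blob = 0.5 * np.exp(-(dx**2 + dy**2) / (2 * 30.0**2))
    data = tube_image.data + blob
    out = frangi_vesselness(EnFaceImage(data, spacing),
                            FrangiParams(scales_um=(20.0, 30.0, 45.0))).data
    centerline = out[nx // 2, ny // 2]
    blob_center = out[bx, by]
    assert centerline > blob_center
    # argmax of the tube's cross profile sits on the centerline
    assert abs(int(np.argmax(out[nx // 2])) - ny // 2) <= 1


def test_frangi_bounds_and_errors(tube_image):
    out = frangi_vesselness(tube_image).data
    assert out.min() >= 0.0 and out.max() <= 1.0
    with pytest.raises(ValueError):
        FrangiParams(scales_um=())
    with pytest.raises(ValueError):
        FrangiParams(scales_um=(30.0, 20.0))


# ---------------------------------------------------------------------------
# circular artifact suppression
# ---------------------------------------------------------------------------

def _map_with(tube=True, disc=True):
    data = np.zeros((80, 80))
    if tube:
        data[10:70, 38:42] = 0.8
    if disc:
        yy, xx = np.mgrid[:80, :80]
        data[(xx - 20) ** 2 + (yy - 20) ** 2 < 49] = 0.8
    return VesselProbabilityMap(data, spacing_um=(20.0, 20.0))


def test_disc_removed_tube_kept():
    out = suppress_circular_artifacts(_map_with(), min_elongation=2.5,
                                      min_area_px=10)
    assert out.data[40, 40] > 0           # tube survives
    assert out.data[20, 20] == 0          # disc removed


def test_suppression_identity_cases():
    zero = VesselProbabilityMap(np.zeros((16, 16)))
    assert np.all(suppress_circular_artifacts(zero).data == 0)
    m = _map_with()
    out = suppress_circular_artifacts(m, min_elongation=1.0, min_area_px=0)
    np.testing.assert_array_equal(out.data, m.data)


# ---------------------------------------------------------------------------
# thresholding, rVPD, aggregation
# ---------------------------------------------------------------------------

def test_global_threshold_extremes(tube_image):
    prob = VesselProbabilityMap(tube_image.data / tube_image.data.max())
    all_on = global_threshold(prob, method="fixed", t=0.0)
    assert all_on.data.sum() == (prob.data > 0).sum()
    none_on = global_threshold(prob, method="fixed", t=1.0)
    assert none_on.data.sum() == 0
    with pytest.raises(ValueError):
        global_threshold(prob, method="fixed", t=1.5)


def test_rvpd_exact_arithmetic():
    mask = np.zeros((10, 10), bool)
    mask.ravel()[:5] = True
    res = compute_rvpd(foct.BinaryVesselMask(mask))
    assert res.rvpd_pct == 5.0
    empty = compute_rvpd(foct.BinaryVesselMask(np.zeros((10, 10), bool)))
    assert empty.rvpd_pct == 0.0


def test_rvpd_matches_generator_truth(small_default_volume):
    _, truth = small_default_volume
    res = compute_rvpd(foct.BinaryVesselMask(truth.vessel_mask))
    assert res.n_vessel_px == truth.vessel_mask.sum()
    assert res.rvpd_pct == pytest.approx(truth.true_vessel_fraction * 100.0,
                                         rel=1e-12)


def _result(pct, n_total=1000):
    n_vessel = int(round(pct * n_total / 100.0))
    return PerfusionResult(100.0 * n_vessel / n_total, n_vessel, n_total)


def test_aggregate_top_k_by_quality():
    results = [_result(4.0), _result(5.0), _result(6.0), _result(9.9)]
    qualities = [9, 9, 9, 5]           # the 9.9 image ranks last
    agg = aggregate_subject(results, qualities, k=3)
    assert agg.rvpd_pct == pytest.approx(5.0)
    single = aggregate_subject([_result(7.2)], [8], k=3)
    assert single.rvpd_pct == pytest.approx(7.2)
    same = aggregate_subject([_result(4.0)] * 4, [8] * 4, k=2)
    assert same.rvpd_pct == pytest.approx(4.0)
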