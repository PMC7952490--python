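"""Synthetic phantom generator: cohort statistics, rasterization, decay."""

import numpy as np
import pytest
from scipy import stats

from ludose import phantom as P
from ludose.constants import voxel_volume_ml
from ludose.materials import hu_to_density


def test_empty_cohort_has_body_and_kidneys_only():
    spec = P.cohort_sampler(0, seed=1)
    assert spec.lesions == []
    truth = P.build_phantom(spec)
    labels = set(np.unique(truth.voi_map).tolist())
    assert labels == {P.LABEL_BACKGROUND, P.LABEL_BODY, P.LABEL_KIDNEY, P.LABEL_BONE}


def test_cohort_sampler_deterministic():
    a = P.cohort_sampler(4, seed=11)
    b = P.cohort_sampler(4, seed=11)
    assert a == b


def test_sampled_density_distribution_matches_cohort():
    """Mean lesion density within 3 SE of 1.25 g/cm^3, range respected."""
    rng = np.random.default_rng(5)
    d = P._truncated_normal(
        rng, P.LESION_DENSITY_MEAN, P.LESION_DENSITY_SD, *P.LESION_DENSITY_RANGE, size=1000
    )
    assert d.min() >= 0.80 and d.max() <= 1.66
    se = d.std(ddof=1) / np.sqrt(d.size)
    assert abs(d.mean() - 1.25) < 3 * se


def test_sampled_volumes_match_cohort():
    rng = np.random.default_rng(6)
    v = P._sample_volumes(rng, 4000)
    assert v.min() >= 1.1 and v.max() <= 453.2
    # log-normal mean calibrated to the cohort mean of 19.1 ml
    se = v.std(ddof=1) / np.sqrt(v.size)
    assert abs(v.mean() - 19.1) < 3 * se


def test_sphere_rasterization_matches_analytic_volume():
    """Voxelized 14.14 ml sphere within one surface layer of the analytic value."""
    les = P.LesionSpec(center_mm=(115.0, 115.0, 115.0), volume_ml=14.14, mean_density=1.25)
    spec = P.PhantomSpec(lesions=[les], seed=0)
    truth = P.build_phantom(spec)
    n_vox = int((truth.voi_map >= P.LESION_LABEL_START).sum())
    vol = n_vox * voxel_volume_ml(spec.voxel_size_mm)
    r_mm = les.radius_mm
    h = spec.voxel_size_mm
    shell = 4 * np.pi * r_mm**2 * h / 1000.0  # one voxel layer, ml
    assert abs(vol - 14.14) < shell


def test_zero_heterogeneity_gives_constant_density():
    les = P.LesionSpec(
        center_mm=(115.0, 115.0, 115.0), volume_ml=20.0, mean_density=1.3, density_std=0.0
    )
    truth = P.build_phantom(P.PhantomSpec(lesions=[les], seed=0))
    inside = truth.voi_map >= P.LESION_LABEL_START
    assert np.allclose(truth.density[inside], 1.3, atol=1e-9)


def test_unit_density_lesion_has_zero_hu():
    les = P.LesionSpec(
        center_mm=(115.0, 115.0, 115.0), volume_ml=20.0, mean_density=1.0, density_std=0.0
    )
    truth = P.build_phantom(P.PhantomSpec(lesions=[les], seed=0))
    inside = truth.voi_map >= P.LESION_LABEL_START
    assert np.allclose(truth.hu[inside], 0.0, atol=1e-6)


def test_density_image_consistent_with_ct(small_phantom):
    assert np.allclose(small_phantom.density, hu_to_density(small_phantom.hu), atol=1e-12)


def test_overlapping_lesions_rejected():
    lesions = [
        P.LesionSpec(center_mm=(115.0, 115.0, 115.0), volume_ml=30.0, mean_density=1.2),
        P.LesionSpec(center_mm=(120.0, 115.0, 115.0), volume_ml=30.0, mean_density=1.2),
    ]
    with pytest.raises(ValueError, match="overlaps"):
        P.build_phantom(P.PhantomSpec(lesions=lesions, seed=0))


def test_truth_tia_matches_closed_form(small_phantom):
    truth = small_phantom
    for label, lam in truth.lambda_per_voi.items():
        sel = truth.voi_map == label
        a0 = truth.uptake_t0[sel]
        assert np.allclose(truth.tia[sel], a0 / lam, rtol=1e-12)


def test_noiseless_decay_is_exact(small_phantom):
    imgs = P.simulate_timepoints(small_phantom, times_h=(24.0, 48.0), noise_counts_per_bq=0.0)
    for label, lam in small_phantom.lambda_per_voi.items():
        sel = small_phantom.voi_map == label
        ratio = np.exp(-lam * 24 * 3600.0)
        assert np.allclose(imgs[1][sel], imgs[0][sel] * ratio, rtol=1e-12)


def test_time_zero_equals_uptake(small_phantom):
    with pytest.raises(ValueError):
        P.simulate_timepoints(small_phantom, times_h=(-1.0, 24.0))
    img0 = P.simulate_timepoints(small_phantom, times_h=(0.0, 24.0), noise_counts_per_bq=0.0)[0]
    assert np.allclose(img0, small_phantom.uptake_t0, rtol=1e-12)


def test_poisson_noise_variance_matches_counts_scale():
    """Variance/mean ratio of a uniform region compatible with Poisson."""
    spec = P.PhantomSpec(seed=0)
    truth = P.build_phantom(spec)
    scale = 1e-3
    img = P.simulate_timepoints(truth, times_h=(24.0,), noise_counts_per_bq=scale, seed=3)[0]
    sel = truth.voi_map == P.LABEL_BODY
    counts = img[sel] * scale
    mu = truth.uptake_t0[sel][0] * np.exp(-truth.lambda_per_voi[P.LABEL_BODY] * 24 * 3600) * scale
    n = counts.size
    # chi-square test of the dispersion against Poisson(mu)
    disp = counts.var(ddof=1) / mu
    z = (disp - 1.0) * np.sqrt(n / 2.0)
    assert abs(z) < 4.0
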