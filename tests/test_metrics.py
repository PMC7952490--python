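"""Comparison metrics: PD, DVH percentiles, Bland-Altman."""

import numpy as np
import pytest

from ludose import metrics as M


def test_voi_average_dose():
    dose = np.array([[[5.0, 5.0], [2.0, 4.0]]])
    mask = np.array([[[True, True], [False, False]]])
    assert M.voi_average_dose(dose, mask) == 5.0
    mask2 = np.array([[[False, False], [True, True]]])
    assert M.voi_average_dose(dose, mask2) == 3.0
    with pytest.raises(ValueError):
        M.voi_average_dose(dose, np.zeros_like(mask))


def test_percentage_difference_arithmetic():
    assert M.percentage_difference(1.14, 1.0) == pytest.approx(14.0)
    assert M.percentage_difference(1.0, 1.0) == 0.0
    assert M.percentage_difference(0.8, 1.0) == pytest.approx(-20.0)
    with pytest.raises(ValueError):
        M.percentage_difference(1.0, 0.0)


def test_pd_vox_proportional_maps():
    rng = np.random.default_rng(0)
    mc = rng.random((4, 4, 4)) + 0.5
    mask = np.ones((4, 4, 4), bool)
    assert M.pd_vox_lesion(1.1 * mc, mc, mask) == pytest.approx(10.0, rel=1e-12)
    assert M.pd_vox_lesion(mc, mc, mask) == 0.0


def test_pd_vox_matches_brute_force():
    rng = np.random.default_rng(1)
    mc = rng.random((4, 4, 4)) + 0.1
    method = rng.random((4, 4, 4)) + 0.1
    mask = rng.random((4, 4, 4)) > 0.4
    expected = np.mean((method[mask] - mc[mask]) / mc[mask] * 100.0)
    assert M.pd_vox_lesion(method, mc, mask) == pytest.approx(expected, rel=1e-12)


def test_pd_vox_uncertainty_exclusion():
    mc = np.ones((2, 2, 2))
    method = np.full((2, 2, 2), 1.5)
    unc = np.zeros((2, 2, 2))
    unc[0] = 0.5  # half the voxels too noisy
    mask = np.ones((2, 2, 2), bool)
    assert M.pd_vox_lesion(method, mc, mask, mc_rel_uncertainty=unc) == pytest.approx(50.0)
    with pytest.raises(ValueError, match="excluded"):
        M.pd_vox_lesion(method, mc, mask, mc_rel_uncertainty=np.full((2, 2, 2), 0.9))


def test_dvh_percentiles_ceiling_rule():
    """Hottest-fraction minimum with the ceil(f*n) voxel, no interpolation."""
    dose = np.arange(1.0, 11.0).reshape(1, 2, 5)
    mask = np.ones_like(dose, bool)
    assert M.dvh_percentile(dose, mask, 0.5) == 6.0
    assert M.dvh_percentile(dose, mask, 0.25) == 8.0
    assert M.dvh_percentile(dose, mask, 0.75) == 3.0
    uniform = np.full((2, 2, 2), 4.2)
    for f in (0.25, 0.5, 0.75, 1.0):
        assert M.dvh_percentile(uniform, np.ones((2, 2, 2), bool), f) == 4.2


def test_dvh_percentiles_monotone_in_fraction():
    rng = np.random.default_rng(2)
    dose = rng.random((5, 5, 5))
    mask = rng.random((5, 5, 5)) > 0.3
    d25 = M.dvh_percentile(dose, mask, 0.25)
    d50 = M.dvh_percentile(dose, mask, 0.50)
    d75 = M.dvh_percentile(dose, mask, 0.75)
    assert d25 >= d50 >= d75


def test_bland_altman_closed_form_example():
    """Pairs (1.1, 1.0), (0.9, 1.0): mean -0.00501, limits (-0.2829, +0.2729)."""
    summary, points = M.bland_altman([1.1, 0.9], [1.0, 1.0])
    rel = np.array([0.1 / 1.05, -0.1 / 0.95])  # independent closed form
    assert summary.mean_relative_difference == pytest.approx(rel.mean(), rel=1e-12)
    assert summary.mean_relative_difference == pytest.approx(-0.00501, abs=5e-6)
    assert summary.lower_limit == pytest.approx(-0.2829, abs=5e-5)
    assert summary.upper_limit == pytest.approx(0.2729, abs=5e-5)
    assert np.allclose(points[:, 0], [1.05, 0.95])


def test_bland_altman_identity_and_scale_invariance():
    summary, _ = M.bland_altman([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
    assert summary.mean_relative_difference == 0.0
    assert summary.sd_relative_difference == 0.0
    assert summary.lower_limit == summary.upper_limit == 0.0
    a = np.array([1.1, 0.9, 1.3])
    b = np.array([1.0, 1.0, 1.0])
    s1, _ = M.bland_altman(a, b)
    s2, _ = M.bland_altman(7.0 * a, 7.0 * b)
    assert s1.mean_relative_difference == pytest.approx(s2.mean_relative_difference, rel=1e-12)
    assert s1.upper_limit == pytest.approx(s2.upper_limit, rel=1e-12)
    assert s1.lower_limit == pytest.approx(s2.lower_limit, rel=1e-12)


def test_bland_altman_excludes_zero_mean_pairs():
    summary, _ = M.bland_altman([1.0, -1.0, 2.0], [1.0, 1.0, 2.0])
    assert summary.n == 2 and summary.n_excluded == 1
    with pytest.raises(ValueError):
        M.bland_altman([1.0], [1.0])
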