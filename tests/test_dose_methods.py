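"""Sphere-model TSV, density weighting and VSV convolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ludose import dose_methods as D
from ludose.mc import VSVKernel


def test_tsv_formula_printed_values():
    assert D.tsv_dose(1.0, 1.0) == pytest.approx(2.19e-5, rel=1e-12)
    assert D.tsv_dose(0.0, 5.0) == 0.0
    assert D.tsv_dose(1.0, 10.0) == pytest.approx(2.19e-5 * 10 ** -0.99, rel=1e-12)
    assert D.tsv_dose(1.0, 10.0) == pytest.approx(2.241e-6, rel=1e-3)
    with pytest.raises(ValueError):
        D.tsv_dose(1.0, 0.0)


def test_tsv_weighting_arithmetic_exact():
    assert D.tsv_weighted(10.0, 1.25) == pytest.approx(8.0, rel=1e-15)
    assert D.tsv_weighted(10.0, 1.0) == 10.0
    assert D.tsv_weighted(10.0, 0.8) == pytest.approx(12.5, rel=1e-15)
    with pytest.raises(ValueError):
        D.tsv_weighted(10.0, 0.0)


def test_power_law_fit_exact_on_exact_power_law():
    m = np.array([1.0, 5.0, 20.0, 100.0, 1000.0])
    c, b = D.fit_tsv_power_law(m, 2.0 * m**-1.0)
    assert c == pytest.approx(2.0, rel=1e-12)
    assert b == pytest.approx(-1.0, rel=1e-12)


def test_power_law_fit_input_validation():
    with pytest.raises(ValueError):
        D.fit_tsv_power_law([1.0, 2.0], [1.0, 0.5])
    with pytest.raises(ValueError):
        D.fit_tsv_power_law([1.0, 2.0, 4.0], [1.0, 0.5, 0.25])  # < 2 decades
    with pytest.raises(ValueError):
        D.fit_tsv_power_law([1.0, 10.0, 1000.0], [1.0, -0.5, 0.2])


def test_mean_lesion_density():
    dens = np.array([[[1.0, 1.5], [1.25, 9.0]]])
    mask = np.array([[[True, True], [False, False]]])
    assert D.mean_lesion_density(dens, mask) == pytest.approx(1.25)
    with pytest.raises(ValueError):
        D.mean_lesion_density(dens, np.zeros_like(mask))


def _toy_kernel(n=7, seed=0, h=4.7952):
    rng = np.random.default_rng(seed)
    vals = rng.random((n, n, n)) * 1e-12
    vals[n // 2, n // 2, n // 2] = 1e-10
    return VSVKernel(vals, np.zeros_like(vals), "soft_tissue_icrp", 1.0, h, 1, 0)


def test_convolution_delta_input_reproduces_kernel():
    k = _toy_kernel()
    tia = np.zeros((15, 15, 15))
    tia[7, 7, 7] = 2.0e6
    dose = D.vsv_convolve(tia, k, k.voxel_size_mm)
    assert np.allclose(dose[4:11, 4:11, 4:11], 2.0e6 * k.values, rtol=1e-12)


def test_convolution_matches_brute_force_superposition():
    """FFT convolution equals the direct triple-loop sum to 1e-10 relative."""
    k = _toy_kernel(n=5, seed=1)
    rng = np.random.default_rng(2)
    tia = rng.random((8, 8, 8)) * 1e5
    dose = D.vsv_convolve(tia, k, k.voxel_size_mm)
    brute = np.zeros_like(tia)
    n = 5
    for i in range(8):
        for j in range(8):
            for l in range(8):
                if tia[i, j, l] == 0:
                    continue
                for a in range(n):
                    for b in range(n):
                        for c in range(n):
                            x, y, z = i + a - n // 2, j + b - n // 2, l + c - n // 2
                            if 0 <= x < 8 and 0 <= y < 8 and 0 <= z < 8:
                                brute[x, y, z] += tia[i, j, l] * k.values[a, b, c]
    assert np.allclose(dose, brute, rtol=1e-10, atol=brute.max() * 1e-10)


def test_convolution_zero_input_and_voxel_mismatch():
    k = _toy_kernel()
    assert not D.vsv_convolve(np.zeros((8, 8, 8)), k, k.voxel_size_mm).any()
    with pytest.raises(ValueError, match="voxel size"):
        D.vsv_convolve(np.zeros((8, 8, 8)), k, 2.0)


def test_density_weight_map_arithmetic():
    dose = np.full((2, 2, 2), 2.0)
    dens = np.full((2, 2, 2), 1.6)
    out = D.density_weight_map(dose, dens, 1.0)
    assert np.allclose(out, 1.25, rtol=1e-15)
    same = D.density_weight_map(dose, np.full((2, 2, 2), 1.0), 1.0)
    assert np.array_equal(same, dose)
    dens[0, 0, 0] = 0.0
    with pytest.raises(ValueError, match="non-positive density"):
        D.density_weight_map(dose, dens, 1.0)


def test_composite_soft_bone_selection():
    soft = np.full((3, 3, 3), 1.0)
    bone = np.full((3, 3, 3), 2.0)
    empty = np.zeros((3, 3, 3), bool)
    assert np.array_equal(D.composite_soft_bone(soft, bone, empty), soft)
    assert np.array_equal(D.composite_soft_bone(soft, bone, ~empty), bone)
    half = np.zeros((3, 3, 3), bool)
    half[:, :, :1] = True
    out = D.composite_soft_bone(soft, bone, half)
    manual = soft.copy()
    manual[half] = bone[half]
    assert np.array_equal(out, manual)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=50.0))
def test_methods_linear_in_tia(scale):
    """Doubling the TIA doubles every dose output."""
    assert D.tsv_dose(scale, 19.1) == pytest.approx(scale * D.tsv_dose(1.0, 19.1), rel=1e-12)
    k = _toy_kernel(n=3, seed=3)
    tia = np.arange(27.0).reshape(3, 3, 3)
    a = D.vsv_convolve(tia, k, k.voxel_size_mm)
    b = D.vsv_convolve(scale * tia, k, k.voxel_size_mm)
    assert np.allclose(b, scale * a, rtol=1e-9)
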