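"""Monte Carlo engine: energy ledger, self-dose, symmetry, uncertainty."""

import numpy as np
import pytest

from ludose.constants import voxel_mass_kg
from ludose.mc import SimulationConfig, generate_vsv, run_mc, uncertainty_scaling_check


def _delta_source(shape, center):
    src = np.zeros(shape)
    src[center] = 1.0
    return src


def test_electron_only_energy_stays_in_source_voxel(lu177):
    """Electron range (<2 mm) is far below the 4.8 mm voxel size."""
    shape = (9, 9, 9)
    cfg = SimulationConfig(n_primaries=20_000, seed=1)
    res = run_mc(np.ones(shape), _delta_source(shape, (4, 4, 4)),
                 lu177.without_photons(), cfg, materials=("soft_tissue_icrp",))
    assert res.ledger_closure < 1e-12
    assert res.escaped_j == 0.0
    share = res.dose_per_decay[4, 4, 4] / res.dose_per_decay.sum()
    assert share >= 0.90
    # source-voxel dose = its energy share x mean electron energy / voxel mass
    mass = voxel_mass_kg(1.0, cfg.voxel_size_mm)
    expected = share * (res.emitted_j / res.n_primaries) / mass
    assert res.dose_per_decay[4, 4, 4] == pytest.approx(expected, rel=1e-9)


def test_full_spectrum_ledger_closes(lu177):
    shape = (9, 9, 9)
    cfg = SimulationConfig(n_primaries=20_000, seed=2)
    res = run_mc(np.ones(shape), _delta_source(shape, (4, 4, 4)), lu177, cfg,
                 materials=("soft_tissue_icrp",))
    assert res.ledger_closure < 1e-3
    assert res.escaped_j > 0.0  # photons leave a 4 cm cube


def test_identical_seed_is_bitwise_deterministic(lu177):
    shape = (7, 7, 7)
    cfg = SimulationConfig(n_primaries=10_000, seed=5)
    a = run_mc(np.ones(shape), _delta_source(shape, (3, 3, 3)), lu177, cfg,
               materials=("soft_tissue_icrp",))
    b = run_mc(np.ones(shape), _delta_source(shape, (3, 3, 3)), lu177, cfg,
               materials=("soft_tissue_icrp",))
    assert np.array_equal(a.dose_per_decay, b.dose_per_decay)
    assert a.emitted_j == b.emitted_j


def test_translation_invariance_of_electron_dose(lu177):
    """Shifting a single-voxel source shifts the dose map identically."""
    shape = (11, 11, 11)
    cfg = SimulationConfig(n_primaries=10_000, seed=6)
    sp = lu177.without_photons()
    a = run_mc(np.ones(shape), _delta_source(shape, (5, 5, 5)), sp, cfg,
               materials=("soft_tissue_icrp",))
    b = run_mc(np.ones(shape), _delta_source(shape, (4, 5, 5)), sp, cfg,
               materials=("soft_tissue_icrp",))
    # identical up to floating-point summation order
    assert np.allclose(np.roll(b.dose_per_decay, 1, axis=0), a.dose_per_decay,
                       rtol=1e-9, atol=a.dose_per_decay.max() * 1e-12)


def test_equilibrium_limit_uniform_source(lu177):
    """Charged-particle equilibrium: interior dose = E_e / phantom mass."""
    shape = (13, 13, 13)
    cfg = SimulationConfig(n_primaries=200_000, seed=7)
    res = run_mc(np.ones(shape), np.ones(shape), lu177.without_photons(), cfg,
                 materials=("soft_tissue_icrp",))
    total_mass = voxel_mass_kg(1.0, cfg.voxel_size_mm) * np.prod(shape)
    expected = (res.emitted_j / res.n_primaries) / total_mass
    c = shape[0] // 2
    dose = res.dose_per_decay[c, c, c]
    sigma = res.rel_uncertainty[c, c, c] * dose
    assert abs(dose - expected) < 3 * sigma


def test_kernel_energy_conservation_and_center_dominance(lu177, soft_kernel_small):
    k = soft_kernel_small
    c = k.center
    assert k.values.max() == k.values[c]
    neighbors = [k.values[c[0] + 1, c[1], c[2]], k.values[c[0], c[1] + 1, c[2]]]
    assert all(k.values[c] > 10 * nb for nb in neighbors)
    # deposited + escaped = emitted, via an identical run with the ledger
    cfg = SimulationConfig(n_primaries=k.n_primaries, seed=k.seed)
    shape = k.values.shape
    res = run_mc(np.full(shape, k.medium_density), _delta_source(shape, c), lu177, cfg,
                 materials=(k.medium,))
    assert res.ledger_closure < 1e-3
    dep_from_kernel = (k.values * voxel_mass_kg(k.medium_density, k.voxel_size_mm)).sum()
    assert dep_from_kernel * k.n_primaries == pytest.approx(res.deposited_j, rel=1e-9)
    assert res.deposited_j + res.escaped_j == pytest.approx(res.emitted_j, rel=1e-6)


def test_kernel_octant_symmetry(soft_kernel_small):
    """Mirror voxels agree within 3 combined sigma for >= 99% of sampled voxels."""
    k = soft_kernel_small
    v, u = k.values, k.rel_uncertainty
    well = np.isfinite(u) & (u < 0.5) & (v > 0)
    agree, total = 0, 0
    for axis in range(3):
        vm = np.flip(v, axis=axis)
        um = np.flip(u, axis=axis)
        wm = np.flip(well, axis=axis)
        sel = well & wm
        sigma = np.sqrt((v * u) ** 2 + (vm * um) ** 2)
        agree += int(np.sum(np.abs(v - vm)[sel] <= 3 * sigma[sel]))
        total += int(sel.sum())
    assert total > 1000
    assert agree / total >= 0.99


def test_bone_kernel_center_scales_with_density(lu177, soft_kernel_small):
    """Self-dose-dominated center scales as 1/rho between media."""
    cfg = SimulationConfig(n_primaries=300_000, seed=42)
    kb = generate_vsv("cortical_bone_icrp", lu177, cfg, grid_n=31)
    ks = soft_kernel_small
    ratio = kb.values[kb.center] / ks.values[ks.center]
    assert ratio == pytest.approx(1.0 / 1.85, rel=0.05)


def test_uncertainty_scaling_follows_sqrt_n(lu177):
    cfg = SimulationConfig(n_primaries=50_000, seed=9, voxel_size_mm=4.7952)
    assert uncertainty_scaling_check(cfg, 1, lu177, grid_n=15) == pytest.approx(1.0)
    ratio = uncertainty_scaling_check(cfg, 4, lu177, grid_n=15)
    assert ratio == pytest.approx(2.0, rel=0.10)


def test_even_kernel_grid_rejected(lu177):
    with pytest.raises(ValueError, match="odd"):
        generate_vsv("soft_tissue_icrp", lu177, SimulationConfig(n_primaries=100, seed=0),
                     grid_n=10)


def test_input_validation(lu177):
    cfg = SimulationConfig(n_primaries=100, seed=0)
    with pytest.raises(ValueError, match="geometry"):
        run_mc(np.ones((4, 4, 4)), np.ones((5, 5, 5)), lu177, cfg)
    with pytest.raises(ValueError, match="zero"):
        run_mc(np.ones((4, 4, 4)), np.zeros((4, 4, 4)), lu177, cfg)
    dens = np.ones((4, 4, 4))
    dens[0, 0, 0] = 0.0
    src = np.zeros((4, 4, 4))
    src[0, 0, 0] = 1.0
    with pytest.raises(ValueError, match="density"):
        run_mc(dens, src, lu177, cfg)
    with pytest.raises(ValueError):
        SimulationConfig(n_primaries=5, n_batches=10)


def test_uncertainty_bounded_and_defined(lu177, soft_kernel_small):
    u = soft_kernel_small.rel_uncertainty
    finite = np.isfinite(u)
    assert np.all(u[finite] >= 0) and np.all(u[finite] <= 1.0 + 1e-12)
    # center voxel is extremely well sampled
    assert u[soft_kernel_small.center] < 0.01
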