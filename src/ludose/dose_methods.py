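"""The six non-Monte-Carlo dosimetry methods.

VOI-level: the unit-density sphere-model tumor S value (TSV), with and
without lesion-average density weighting (mass scaling).  Voxel-level:
convolution of the time-integrated-activity image with voxel-S-value
kernels for soft tissue or a soft/cortical-bone composite, with and
without voxel-wise density weighting.

Unit conventions: TIA in MBq*s for the TSV formula (mass in grams), Bq*s
for the voxel convolutions; doses in Gy; densities in g/cm^3.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .constants import voxel_volume_ml
from .grids import check_same_geometry
from .mc import SimulationConfig, VSVKernel, run_mc
from .nuclide import EmissionSpectrum

__all__ = [
    "TSV_COEFF_GY_PER_MBQ_S",
    "TSV_EXPONENT",
    "tsv_dose",
    "tsv_weighted",
    "fit_tsv_power_law",
    "sphere_s_value",
    "mean_lesion_density",
    "vsv_convolve",
    "density_weight_map",
    "composite_soft_bone",
    "composite_reference_density",
]

#: sphere-model tumor S value fit S(m) = c * m^b, m in g, S in Gy/(MBq*s)
TSV_COEFF_GY_PER_MBQ_S = 2.19e-5
TSV_EXPONENT = -0.99


def tsv_dose(
    tia_mbq_s: float,
    volume_ml: float,
    coeff: float = TSV_COEFF_GY_PER_MBQ_S,
    exponent: float = TSV_EXPONENT,
) -> float:
    """Average lesion dose (Gy) from the unit-density sphere model.

    The lesion mass in grams is taken equal to its volume in ml (unit
    density assumption of the sphere model).
    """
    if volume_ml <= 0:
        raise ValueError("lesion volume must be > 0")
    if tia_mbq_s < 0:
        raise ValueError("TIA must be >= 0")
    mass_g = volume_ml
    return coeff * mass_g**exponent * tia_mbq_s


def tsv_weighted(dose_gy: float, mean_density: float) -> float:
    """Mass scaling of the sphere-model dose by 1 g/cm^3 over the lesion density."""
    if mean_density <= 0:
        raise ValueError("lesion density must be > 0")
    return dose_gy * 1.0 / mean_density


def fit_tsv_power_law(masses_g, s_values) -> tuple[float, float]:
    """Log-log least-squares fit S = c * m^b; returns (c, b)."""
    m = np.asarray(masses_g, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if m.size < 3:
        raise ValueError("need at least 3 sphere masses")
    if np.any(s <= 0) or np.any(m <= 0):
        raise ValueError("masses and S values must be positive")
    if np.log10(m.max() / m.min()) < 2:
        raise ValueError("sphere masses should span at least two decades")
    b, logc = np.polyfit(np.log(m), np.log(s), 1)
    return float(np.exp(logc)), float(b)


def sphere_s_value(
    mass_g: float,
    spectrum: EmissionSpectrum,
    n_primaries: int = 200_000,
    seed: int = 0,
    voxels_per_radius: int = 6,
    margin_voxels: int = 2,
) -> float:
    """Self-dose S value of a unit-density sphere, Gy/(MBq*s).

    Simulates uniform activity in a voxelized unit-density soft-tissue
    sphere and scores the mean absorbed dose inside it per decay.  The
    voxel size scales with the sphere radius so small spheres stay well
    resolved.
    """
    radius_mm = (3.0 * mass_g * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    h = radius_mm / voxels_per_radius
    n = 2 * (voxels_per_radius + margin_voxels) + 1
    axis = (np.arange(n) - n // 2) * h
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    sphere = xx**2 + yy**2 + zz**2 <= radius_mm**2
    density = np.ones((n, n, n))
    source = sphere.astype(float)
    cfg = SimulationConfig(n_primaries=n_primaries, seed=seed, voxel_size_mm=h)
    res = run_mc(density, source, spectrum, cfg, materials=("soft_tissue_icrp",))
    mass_vox_g = voxel_volume_ml(h)  # unit density
    sphere_mass_g = sphere.sum() * mass_vox_g
    dep_j_per_decay = (res.dose_per_decay[sphere] * mass_vox_g * 1e-3).sum()
    return dep_j_per_decay / (sphere_mass_g * 1e-3) * 1e6  # Gy/decay -> Gy/(MBq*s)


def mean_lesion_density(density_image: np.ndarray, lesion_mask: np.ndarray) -> float:
    """Arithmetic mean density over the lesion voxels, g/cm^3."""
    check_same_geometry(density_image, lesion_mask)
    if not np.any(lesion_mask):
        raise ValueError("empty lesion mask")
    return float(density_image[lesion_mask.astype(bool)].mean())


def vsv_convolve(tia_bq_s: np.ndarray, kernel: VSVKernel, voxel_size_mm: float) -> np.ndarray:
    """Convolve a TIA image (Bq*s) with a VSV kernel; returns dose in Gy.

    Spectral zero-padded linear convolution (no wrap-around), cropped to
    the input geometry.
    """
    if not np.isclose(voxel_size_mm, kernel.voxel_size_mm, rtol=1e-6):
        raise ValueError(
            f"voxel size mismatch: image {voxel_size_mm} mm vs kernel {kernel.voxel_size_mm} mm"
        )
    return fftconvolve(tia_bq_s, kernel.values, mode="same")


def density_weight_map(
    dose: np.ndarray,
    density: np.ndarray,
    rho_reference,
    body_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel-wise density weighting D * rho_reference / rho_voxel.

    ``rho_reference`` is the nominal density of the kernel medium (scalar)
    or a per-voxel reference-density map (composite methods).  Weighting
    is applied inside ``body_mask`` (everywhere by default); zero or
    negative density inside the weighted region is an error.
    """
    check_same_geometry(dose, density)
    mask = np.ones(dose.shape, bool) if body_mask is None else body_mask.astype(bool)
    bad = mask & (density <= 0)
    if np.any(bad):
        idx = np.argwhere(bad)[:5]
        raise ValueError(f"non-positive density inside weighted region at voxels {idx.tolist()}")
    out = dose.copy()
    ref = np.broadcast_to(np.asarray(rho_reference, dtype=float), dose.shape)
    out[mask] = dose[mask] * ref[mask] / density[mask]
    return out


def composite_soft_bone(
    dose_soft: np.ndarray, dose_bone: np.ndarray, bone_mask: np.ndarray
) -> np.ndarray:
    """Region-wise composite: bone-kernel dose on the bone map, soft elsewhere."""
    check_same_geometry(dose_soft, dose_bone, bone_mask)
    return np.where(bone_mask.astype(bool), dose_bone, dose_soft)


def composite_reference_density(
    bone_mask: np.ndarray, rho_soft: float, rho_bone: float
) -> np.ndarray:
    """Per-voxel kernel-medium density map for weighting the composite."""
    return np.where(bone_mask.astype(bool), rho_bone, rho_soft)
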