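"""Unit conversions and physical constants used across the package."""

KEV_TO_J = 1.602176634e-16
ELECTRON_REST_KEV = 510.99895
FINE_STRUCTURE = 7.2973525693e-3

#: physical half-life of Lu-177 in hours
LU177_HALF_LIFE_H = 6.647 * 24.0
#: physical decay constant of Lu-177 in 1/s
LU177_LAMBDA_S = 0.6931471805599453 / (LU177_HALF_LIFE_H * 3600.0)

#: default isotropic voxel edge, mm (SPECT reconstruction grid)
DEFAULT_VOXEL_MM = 4.7952


def voxel_volume_ml(voxel_mm: float) -> float:
    """Volume of one cubic voxel in millilitres (= cm^3)."""
    return (voxel_mm / 10.0) ** 3


def voxel_mass_kg(density_g_cm3, voxel_mm: float):
    """Voxel mass in kg for a density grid in g/cm^3 (array-safe)."""
    return density_g_cm3 * voxel_volume_ml(voxel_mm) * 1e-3
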