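"""Synthetic SPECT/CT-like phantoms of a skeletal-metastasis cohort.

Generates co-registered CT (HU), truth density, VOI labels, truth
time-integrated activity and noisy multi-timepoint activity images on one
isotropic grid.  Lesion statistics emulate the studied cohort: volumes
log-normal around a 19.1 ml mean within [1.1, 453.2] ml, per-lesion mean
densities normal (1.25, 0.11) g/cm^3 truncated to [0.80, 1.66], with
Gaussian intra-lesion density heterogeneity.  Lesions are placed inside
an ellipsoidal skeleton shell so the HU >= 200 bone map contains them.

VOI label conventions: 0 background (air), 1 body soft tissue,
2 kidneys, 3 skeleton shell, lesions 10, 11, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .constants import DEFAULT_VOXEL_MM, voxel_volume_ml
from .materials import density_to_hu, hu_to_density

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "cohort_sampler",
    "build_phantom",
    "simulate_timepoints",
    "LABEL_BACKGROUND",
    "LABEL_BODY",
    "LABEL_KIDNEY",
    "LABEL_BONE",
    "LESION_LABEL_START",
]

LABEL_BACKGROUND = 0
LABEL_BODY = 1
LABEL_KIDNEY = 2
LABEL_BONE = 3
LESION_LABEL_START = 10

# cohort statistics the sampler emulates
LESION_VOLUME_MEAN_ML = 19.1
LESION_VOLUME_RANGE_ML = (1.1, 453.2)
LESION_DENSITY_MEAN = 1.25
LESION_DENSITY_SD = 0.11
LESION_DENSITY_RANGE = (0.80, 1.66)
#: log-normal shape parameter of the volume distribution (see methods note)
LESION_VOLUME_SIGMA_LOG = 1.1

# default effective half-lives, hours (clinically plausible, configurable)
T_EFF_LESION_H = 40.0
T_EFF_KIDNEY_H = 30.0
T_EFF_REMAINDER_H = 50.0


@dataclass
class LesionSpec:
    center_mm: tuple[float, float, float]
    volume_ml: float
    mean_density: float
    density_std: float = 0.08
    activity_conc_bq_ml: float = 1.0e6   # at the 24 h reference time
    t_eff_h: float = T_EFF_LESION_H

    @property
    def radius_mm(self) -> float:
        return (3.0 * self.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    body_semiaxes_frac: tuple[float, float, float] = (0.42, 0.42, 0.46)
    shell_frac: tuple[float, float] = (0.55, 0.80)
    shell_hu_range: tuple[float, float] = (250.0, 800.0)
    kidney_semiaxes_mm: tuple[float, float, float] = (18.0, 14.0, 28.0)
    kidney_offset_frac: float = 0.30
    kidney_conc_bq_ml: float = 3.0e5
    kidney_t_eff_h: float = T_EFF_KIDNEY_H
    background_conc_bq_ml: float = 2.0e4
    background_t_eff_h: float = T_EFF_REMAINDER_H
    lesions: list[LesionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be > 0")
        for les in self.lesions:
            if les.volume_ml <= 0 or les.mean_density <= 0:
                raise ValueError("lesion volumes and densities must be > 0")


@dataclass
class PhantomTruth:
    spec: PhantomSpec
    hu: np.ndarray
    density: np.ndarray
    voi_map: np.ndarray
    uptake_t0: np.ndarray               # Bq per voxel at t = 0
    lambda_per_voi: dict[int, float]    # 1/s
    tia: np.ndarray                     # Bq*s per voxel

    @property
    def voxel_size_mm(self) -> float:
        return self.spec.voxel_size_mm

    def lesion_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.voi_map) if v >= LESION_LABEL_START)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - n)
        out[n : n + take] = keep[:take]
        n += take
    return out


def _sample_volumes(rng, n):
    lo, hi = LESION_VOLUME_RANGE_ML
    sigma = LESION_VOLUME_SIGMA_LOG
    # mu set so the range-truncated distribution keeps the cohort mean
    mu = np.log(LESION_VOLUME_MEAN_ML) - sigma**2 / 2 - 0.012
    out = np.empty(n)
    k = 0
    while k < n:
        v = rng.lognormal(mu, sigma, size=max(n, 8))
        keep = v[(v >= lo) & (v <= hi)]
        take = min(keep.size, n - k)
        out[k : k + take] = keep[:take]
        k += take
    return out


def cohort_sampler(
    n_lesions: int,
    seed: int = 0,
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_mm: float = DEFAULT_VOXEL_MM,
    max_placement_tries: int = 500,
    **spec_kwargs,
) -> PhantomSpec:
    """Draw a phantom spec whose lesions follow the cohort statistics.

    Lesion centers are placed in the skeleton shell with non-overlap
    rejection; a lesion whose volume cannot be placed after
    ``max_placement_tries`` positions is re-drawn.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(shape=shape, voxel_size_mm=voxel_size_mm, seed=seed, **spec_kwargs)
    extent = np.array(shape) * voxel_size_mm
    center = extent / 2
    body_semi = np.array(spec.body_semiaxes_frac) * extent
    densities = _truncated_normal(
        rng, LESION_DENSITY_MEAN, LESION_DENSITY_SD, *LESION_DENSITY_RANGE, size=max(n_lesions, 1)
    )[:n_lesions]
    placed: list[LesionSpec] = []
    for i in range(n_lesions):
        volume = float(_sample_volumes(rng, 1)[0])
        success = False
        for attempt in range(max_placement_tries):
            if attempt and attempt % 100 == 0:
                volume = float(_sample_volumes(rng, 1)[0])  # re-draw an unplaceable volume
            radius = (3.0 * volume * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            # direction on the unit sphere, radius within the shell band
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            f = rng.uniform(*spec.shell_frac)
            pos = center + u * f * body_semi
            # whole sphere inside the body
            if np.any(np.abs(pos - center) + radius > body_semi * 0.98):
                continue
            ok = all(
                np.linalg.norm(pos - np.array(other.center_mm))
                >= radius + other.radius_mm + voxel_size_mm
                for other in placed
            )
            if ok:
                placed.append(
                    LesionSpec(
                        center_mm=tuple(float(p) for p in pos),
                        volume_ml=volume,
                        mean_density=float(densities[i]),
                    )
                )
                success = True
                break
        if not success:
            raise RuntimeError("could not place lesion; grid too crowded")
    spec.lesions = placed
    return spec


def _ellipsoid_mask(coords, center, semiaxes):
    return (
        ((coords[0] - center[0]) / semiaxes[0]) ** 2
        + ((coords[1] - center[1]) / semiaxes[1]) ** 2
        + ((coords[2] - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def build_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize a spec onto its grid and derive all truth volumes."""
    rng = np.random.default_rng(spec.seed + 104729)
    h = spec.voxel_size_mm
    shape = tuple(spec.shape)
    axes = [(np.arange(n) + 0.5) * h for n in shape]
    coords = np.meshgrid(*axes, indexing="ij")
    extent = np.array(shape) * h
    center = extent / 2
    body_semi = np.array(spec.body_semiaxes_frac) * extent

    density = np.full(shape, hu_to_density(-1000.0))
    voi = np.zeros(shape, dtype=np.int32)

    body = _ellipsoid_mask(coords, center, body_semi)
    density[body] = 1.0
    voi[body] = LABEL_BODY

    # skeleton shell between the two fractional ellipsoids
    outer = _ellipsoid_mask(coords, center, body_semi * spec.shell_frac[1])
    inner = _ellipsoid_mask(coords, center, body_semi * spec.shell_frac[0])
    shell = outer & ~inner
    shell_hu = rng.uniform(*spec.shell_hu_range, size=int(shell.sum()))
    density[shell] = hu_to_density(shell_hu)
    voi[shell] = LABEL_BONE

    # two kidneys inside the inner soft-tissue region
    koff = spec.kidney_offset_frac * body_semi[0]
    for sign in (-1.0, 1.0):
        kc = center + np.array([sign * koff, 0.0, -0.1 * body_semi[2]])
        kid = _ellipsoid_mask(coords, kc, np.array(spec.kidney_semiaxes_mm))
        kid &= inner
        density[kid] = 1.0
        voi[kid] = LABEL_KIDNEY

    # lesions: spherical, voxel-wise Gaussian density heterogeneity
    claimed = np.zeros(shape, dtype=np.int32)
    for li, les in enumerate(spec.lesions):
        label = LESION_LABEL_START + li
        mask = (
            (coords[0] - les.center_mm[0]) ** 2
            + (coords[1] - les.center_mm[1]) ** 2
            + (coords[2] - les.center_mm[2]) ** 2
        ) <= les.radius_mm**2
        overlap = mask & (claimed > 0)
        if np.any(overlap):
            other = sorted(set(claimed[overlap].tolist()))
            raise ValueError(f"lesion {label} overlaps lesion(s) {other}")
        claimed[mask] = label
        vox_density = les.mean_density + rng.normal(0.0, les.density_std, size=int(mask.sum()))
        density[mask] = np.clip(vox_density, 0.05, None)
        voi[mask] = label

    hu = density_to_hu(density)
    density = hu_to_density(hu)  # exact voxel-wise consistency with the CT

    # activity: concentrations at the 24 h reference, extrapolated to t = 0
    lam: dict[int, float] = {}
    uptake24 = np.zeros(shape)
    uptake24[voi == LABEL_BODY] = spec.background_conc_bq_ml
    uptake24[voi == LABEL_BONE] = spec.background_conc_bq_ml
    uptake24[voi == LABEL_KIDNEY] = spec.kidney_conc_bq_ml
    t_eff = {
        LABEL_BODY: spec.background_t_eff_h,
        LABEL_BONE: spec.background_t_eff_h,
        LABEL_KIDNEY: spec.kidney_t_eff_h,
    }
    for li, les in enumerate(spec.lesions):
        label = LESION_LABEL_START + li
        uptake24[voi == label] = les.activity_conc_bq_ml
        t_eff[label] = les.t_eff_h
    uptake24 *= voxel_volume_ml(h)  # Bq per voxel

    uptake_t0 = np.zeros(shape)
    tia = np.zeros(shape)
    for label, t_half in t_eff.items():
        lam_s = np.log(2.0) / (t_half * 3600.0)
        lam[label] = lam_s
        sel = voi == label
        a0 = uptake24[sel] * 2.0 ** (24.0 / t_half)
        uptake_t0[sel] = a0
        tia[sel] = a0 / lam_s
    return PhantomTruth(
        spec=spec, hu=hu, density=density, voi_map=voi,
        uptake_t0=uptake_t0, lambda_per_voi=lam, tia=tia,
    )


def simulate_timepoints(
    truth: PhantomTruth,
    times_h=(24.0, 48.0, 72.0),
    noise_counts_per_bq: float = 0.0,
    psf_fwhm_mm: float | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Noisy activity images (Bq per voxel) at the acquisition times.

    Voxel activity decays mono-exponentially with its VOI's effective
    half-life; an optional isotropic Gaussian PSF emulates system blur and
    Poisson noise is applied on a counts scale (``noise_counts_per_bq``
    counts per Bq; 0 disables noise).
    """
    times = np.asarray(times_h, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    decay = np.zeros(truth.voi_map.shape)
    images = []
    for t in times:
        for label, lam_s in truth.lambda_per_voi.items():
            decay[truth.voi_map == label] = np.exp(-lam_s * t * 3600.0)
        img = truth.uptake_t0 * decay
        if psf_fwhm_mm:
            sigma_vox = psf_fwhm_mm / 2.3548200450309493 / truth.voxel_size_mm
            img = ndimage.gaussian_filter(img, sigma_vox)
        if noise_counts_per_bq > 0:
            img = rng.poisson(img * noise_counts_per_bq) / noise_counts_per_bq
        images.append(img)
    return images


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-ready provenance dictionary of a phantom spec."""
    return asdict(spec)
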