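"""End-to-end synthetic-cohort experiment.

Chains phantom generation, segmentation, TIA estimation, the Monte Carlo
reference, the six simplified dosimetry methods and the comparison
metrics, and collects one row per lesion per method.  Used by the command
line ``run`` subcommand and by the acceptance analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_VOXEL_MM, voxel_volume_ml
from .dose_methods import (
    composite_reference_density,
    composite_soft_bone,
    density_weight_map,
    mean_lesion_density,
    tsv_dose,
    tsv_weighted,
    vsv_convolve,
)
from .grids import save_volume
from .mc import CORTICAL_BONE, SOFT_TISSUE, SimulationConfig, generate_vsv, run_mc
from .metrics import bland_altman, dvh_percentile, pd_vox_lesion, percentage_difference, voi_average_dose
from .nuclide import load_lu177
from .phantom import (
    LABEL_BODY,
    LABEL_BONE,
    build_phantom,
    cohort_sampler,
    simulate_timepoints,
    spec_to_dict,
)
from .segmentation import bone_map, kmeans_lesion_segmentation
from .tia import fit_all_vois, hybrid_tia_image

__all__ = ["PipelineConfig", "CohortResult", "run_cohort", "run_pipeline"]

VOXEL_METHODS = ("vsv_soft", "vsv_soft_w", "vsv_sb", "vsv_sb_w")
ALL_METHODS = ("tsv", "tsv_w") + VOXEL_METHODS


@dataclass
class PipelineConfig:
    """Desk-scale defaults for the cohort comparison experiment."""

    n_lesions: int = 30
    lesions_per_phantom: int = 5
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    times_h: tuple[float, ...] = (24.0, 48.0, 72.0)
    noise_counts_per_bq: float = 0.01
    mc_primaries: int = 2_000_000
    kernel_primaries: int = 2_000_000
    kernel_grid: int = 51
    n_batches: int = 20
    seed: int = 0
    methods: tuple[str, ...] = ALL_METHODS
    voi_source: str = "truth"          # "truth" or "segmented" lesion VOIs
    max_rel_uncertainty: float = 0.20  # voxel exclusion floor for PD^vox
    kernel_cache_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.voi_source not in ("truth", "segmented"):
            raise ValueError("voi_source must be 'truth' or 'segmented'")


@dataclass
class CohortResult:
    lesion_table: pd.DataFrame
    summary: dict
    config: PipelineConfig
    segmentation_tables: list[pd.DataFrame] = field(default_factory=list)


def _get_kernels(config: PipelineConfig, spectrum):
    from .mc import load_kernel, save_kernel

    kernels = {}
    for i, medium in enumerate((SOFT_TISSUE, CORTICAL_BONE)):
        cache = None
        if config.kernel_cache_dir:
            tag = f"{medium}_{config.kernel_grid}_{config.kernel_primaries}_{config.voxel_size_mm}_{config.seed + i}"
            cache = Path(config.kernel_cache_dir) / f"vsv_{tag}.npz"
        if cache is not None and cache.exists():
            kernels[medium] = load_kernel(cache)
            continue
        cfg = SimulationConfig(
            n_primaries=config.kernel_primaries,
            n_batches=config.n_batches,
            seed=config.seed + i,
            voxel_size_mm=config.voxel_size_mm,
        )
        kernels[medium] = generate_vsv(medium, spectrum, cfg, grid_n=config.kernel_grid)
        if cache is not None:
            cache.parent.mkdir(parents=True, exist_ok=True)
            save_kernel(kernels[medium], cache)
    return kernels


def _phantom_dose_maps(truth, tia_img, spectrum, kernels, config: PipelineConfig, seed: int):
    """All requested voxel dose maps (Gy) plus the MC reference and its noise map."""
    h = config.voxel_size_mm
    body = truth.voi_map > 0
    bone = bone_map(truth.hu)
    total_decays = float(tia_img.sum())
    mc_cfg = SimulationConfig(
        n_primaries=config.mc_primaries, n_batches=config.n_batches, seed=seed, voxel_size_mm=h
    )
    material = bone.astype(np.uint8)
    mc_res = run_mc(truth.density, tia_img, spectrum, mc_cfg, material_index=material)
    maps = {"mc": mc_res.dose_per_decay * total_decays}
    need_soft = set(config.methods) & set(VOXEL_METHODS)
    if need_soft:
        k_soft = kernels[SOFT_TISSUE]
        d_soft = vsv_convolve(tia_img, k_soft, h)
        if "vsv_soft" in config.methods:
            maps["vsv_soft"] = d_soft
        if "vsv_soft_w" in config.methods:
            maps["vsv_soft_w"] = density_weight_map(
                d_soft, truth.density, k_soft.medium_density, body_mask=body
            )
        if {"vsv_sb", "vsv_sb_w"} & set(config.methods):
            k_bone = kernels[CORTICAL_BONE]
            d_bone = vsv_convolve(tia_img, k_bone, h)
            d_comp = composite_soft_bone(d_soft, d_bone, bone)
            if "vsv_sb" in config.methods:
                maps["vsv_sb"] = d_comp
            if "vsv_sb_w" in config.methods:
                ref = composite_reference_density(
                    bone, k_soft.medium_density, k_bone.medium_density
                )
                maps["vsv_sb_w"] = density_weight_map(
                    d_comp, truth.density, ref, body_mask=body
                )
    return maps, mc_res


def run_cohort(config: PipelineConfig) -> CohortResult:
    """Run the full synthetic-cohort comparison; one row per lesion."""
    spectrum = load_lu177()
    kernels = _get_kernels(config, spectrum) if set(config.methods) & set(VOXEL_METHODS) else {}
    rows = []
    seg_tables = []
    n_left = config.n_lesions
    phantom_idx = 0
    while n_left > 0:
        n_here = min(config.lesions_per_phantom, n_left)
        pseed = config.seed * 1009 + phantom_idx
        spec = cohort_sampler(
            n_here, seed=pseed, shape=config.shape, voxel_size_mm=config.voxel_size_mm
        )
        truth = build_phantom(spec)
        images = simulate_timepoints(
            truth,
            times_h=config.times_h,
            noise_counts_per_bq=config.noise_counts_per_bq,
            seed=pseed + 1,
        )
        # segmentation runs on every phantom and is reported; the dosimetry
        # VOIs come from the configured source
        seg = kmeans_lesion_segmentation(
            images[0], bone_map(truth.hu), config.voxel_size_mm, seed=pseed
        )
        seg_tables.append(seg.table.assign(phantom=phantom_idx))
        if config.voi_source == "truth":
            voi = truth.voi_map
        else:
            voi = np.where(seg.labels > 0, seg.labels, np.minimum(truth.voi_map, LABEL_BONE))
        groups = {LABEL_BONE: LABEL_BODY}  # skeleton shell fits with the remainder
        fits = fit_all_vois(images, config.times_h, voi, groups=groups)
        tia_img = hybrid_tia_image(images[0], voi, fits, config.times_h[0], groups=groups)
        maps, mc_res = _phantom_dose_maps(truth, tia_img, spectrum, kernels, config, seed=pseed + 2)

        vox_ml = voxel_volume_ml(config.voxel_size_mm)
        for label in sorted(int(v) for v in np.unique(voi) if v >= 10):
            mask = voi == label
            volume_ml = float(mask.sum()) * vox_ml
            rho = mean_lesion_density(truth.density, mask)
            tia_mbq_s = float(tia_img[mask].sum()) * 1e-6
            d_mc_av = voi_average_dose(maps["mc"], mask)
            row = {
                "phantom": phantom_idx,
                "lesion": label,
                "volume_ml": volume_ml,
                "mass_g": volume_ml * rho,
                "mean_density_g_cm3": rho,
                "tia_mbq_s": tia_mbq_s,
                "d_av_mc": d_mc_av,
            }
            if "tsv" in config.methods:
                d = tsv_dose(tia_mbq_s, volume_ml)
                row["d_av_tsv"] = d
                row["pd_av_tsv"] = percentage_difference(d, d_mc_av)
            if "tsv_w" in config.methods and "d_av_tsv" in row:
                dw = tsv_weighted(row["d_av_tsv"], rho)
                row["d_av_tsv_w"] = dw
                row["pd_av_tsv_w"] = percentage_difference(dw, d_mc_av)
            for method in VOXEL_METHODS:
                if method not in config.methods:
                    continue
                dm = maps[method]
                row[f"d_av_{method}"] = voi_average_dose(dm, mask)
                row[f"pd_vox_{method}"] = pd_vox_lesion(
                    dm, maps["mc"], mask,
                    mc_rel_uncertainty=mc_res.rel_uncertainty,
                    max_rel_uncertainty=config.max_rel_uncertainty,
                )
                for f, tag in ((0.25, "d25"), (0.50, "d50"), (0.75, "d75")):
                    row[f"{tag}_{method}"] = dvh_percentile(dm, mask, f)
                    row[f"pd_{tag}_{method}"] = percentage_difference(
                        row[f"{tag}_{method}"], dvh_percentile(maps["mc"], mask, f)
                    )
            for f, tag in ((0.25, "d25"), (0.50, "d50"), (0.75, "d75")):
                row[f"{tag}_mc"] = dvh_percentile(maps["mc"], mask, f)
            rows.append(row)
        n_left -= n_here
        phantom_idx += 1

    table = pd.DataFrame(rows)
    summary = _summarize(table, config)
    return CohortResult(lesion_table=table, summary=summary, config=config,
                        segmentation_tables=seg_tables)


def _summarize(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Cohort summary: per-lesion statistics averaged across lesions."""
    out: dict = {"n_lesions": int(len(table))}
    for col in table.columns:
        if col.startswith(("pd_av_", "pd_vox_", "pd_d")):
            vals = table[col].to_numpy()
            out[col] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
            }
    # Bland-Altman of per-lesion D50 of each voxel method against MC
    for method in VOXEL_METHODS:
        col = f"d50_{method}"
        if col in table.columns and len(table) >= 2:
            summary, _ = bland_altman(table[col].to_numpy(), table["d50_mc"].to_numpy())
            out[f"bland_altman_d50_{method}"] = {
                "mean_relative_difference": summary.mean_relative_difference,
                "sd": summary.sd_relative_difference,
                "lower_limit": summary.lower_limit,
                "upper_limit": summary.upper_limit,
            }
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> CohortResult:
    """Run the cohort experiment and write tables, volumes and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_cohort(config)
    result.lesion_table.to_csv(out / "lesion_table.csv", index=False)
    if result.segmentation_tables:
        pd.concat(result.segmentation_tables).to_csv(out / "segmentation.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))
    cfg_dict = asdict(config)
    manifest = {
        "ludose_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return result


def write_example_phantom(out_dir, n_lesions: int = 3, seed: int = 0) -> None:
    """Write one phantom's volumes as NIfTI with a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort_sampler(n_lesions, seed=seed)
    truth = build_phantom(spec)
    images = simulate_timepoints(truth, seed=seed + 1)
    h = truth.voxel_size_mm
    save_volume(truth.hu, h, out / "ct_hu.nii.gz")
    save_volume(truth.density, h, out / "density.nii.gz")
    save_volume(truth.voi_map.astype(np.int16), h, out / "voi.nii.gz")
    save_volume(truth.tia, h, out / "tia_truth.nii.gz")
    for t, img in zip((24, 48, 72), images):
        save_volume(img, h, out / f"activity_{t:03d}h.nii.gz")
    (out / "phantom_spec.json").write_text(json.dumps(spec_to_dict(spec), indent=1, default=str))
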