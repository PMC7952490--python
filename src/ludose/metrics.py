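"""Comparison statistics of the dosimetry methods against the MC reference.

Per lesion: percentage difference of the VOI-average dose, mean voxel-wise
percentage difference, cumulative-DVH percentiles D25/D50/D75; cohort
summaries are formed per lesion first and then averaged across lesions.
Bland-Altman agreement uses the pair mean as the denominator of the
relative difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import check_same_geometry

__all__ = [
    "voi_average_dose",
    "percentage_difference",
    "pd_vox_lesion",
    "dvh_percentile",
    "bland_altman",
    "BlandAltmanSummary",
]


def voi_average_dose(dose: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean dose over the mask, Gy."""
    check_same_geometry(dose, mask)
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty VOI mask")
    return float(dose[mask].mean())


def percentage_difference(d_method: float, d_reference: float) -> float:
    """(method - reference) / reference * 100."""
    if d_reference <= 0:
        raise ValueError("reference dose must be > 0")
    return (d_method - d_reference) / d_reference * 100.0


def pd_vox_lesion(
    dose_method: np.ndarray,
    dose_mc: np.ndarray,
    lesion_mask: np.ndarray,
    mc_rel_uncertainty: np.ndarray | None = None,
    max_rel_uncertainty: float = 0.20,
) -> float:
    """Mean voxel-wise percentage difference over one lesion.

    Voxels whose MC dose is zero, or whose MC statistical uncertainty
    exceeds ``max_rel_uncertainty`` (the division by a noisy reference
    would dominate otherwise), are excluded.
    """
    check_same_geometry(dose_method, dose_mc, lesion_mask)
    sel = lesion_mask.astype(bool) & (dose_mc > 0)
    if mc_rel_uncertainty is not None:
        sel &= np.nan_to_num(mc_rel_uncertainty, nan=np.inf) <= max_rel_uncertainty
    if not sel.any():
        raise ValueError("all lesion voxels excluded from the voxel-wise comparison")
    pd_vox = (dose_method[sel] - dose_mc[sel]) / dose_mc[sel] * 100.0
    return float(pd_vox.mean())


def dvh_percentile(dose: np.ndarray, mask: np.ndarray, volume_fraction: float) -> float:
    """Minimum dose within the hottest ``volume_fraction`` of the VOI (Gy).

    D25/D50/D75 use fractions 0.25/0.5/0.75: the doses are sorted
    descending and the ceil(f*n)-th voxel is returned (no interpolation).
    """
    if not (0.0 < volume_fraction <= 1.0):
        raise ValueError("volume fraction must be in (0, 1]")
    check_same_geometry(dose, mask)
    vals = np.sort(dose[mask.astype(bool)])[::-1]
    if vals.size == 0:
        raise ValueError("empty VOI mask")
    idx = int(np.ceil(volume_fraction * vals.size)) - 1
    return float(vals[idx])


@dataclass(frozen=True)
class BlandAltmanSummary:
    mean_relative_difference: float
    sd_relative_difference: float
    lower_limit: float
    upper_limit: float
    n: int
    n_excluded: int


def bland_altman(values_a, values_b) -> tuple[BlandAltmanSummary, np.ndarray]:
    """Bland-Altman agreement of two paired dose vectors.

    Relative difference (a - b) / pair mean, plotted against the pair
    mean; limits of agreement are mean +/- 1.96 * sample SD.  Pairs with
    zero mean are excluded.  Returns the summary and the (pair mean,
    relative difference) points.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    means = (a + b) / 2.0
    ok = means != 0
    n_excluded = int((~ok).sum())
    a, b, means = a[ok], b[ok], means[ok]
    if a.size < 2:
        raise ValueError("need at least 2 valid pairs")
    rel = (a - b) / means
    mean = float(rel.mean())
    sd = float(rel.std(ddof=1))
    return (
        BlandAltmanSummary(
            mean_relative_difference=mean,
            sd_relative_difference=sd,
            lower_limit=mean - 1.96 * sd,
            upper_limit=mean + 1.96 * sd,
            n=int(a.size),
            n_excluded=n_excluded,
        ),
        np.column_stack([means, rel]),
    )
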