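"""VOI-wise mono-exponential fitting and the hybrid TIA image.

Each VOI's summed time-activity curve is fitted with a single exponential
(unweighted least squares on log activity).  The time-integrated-activity
image keeps the voxel-wise structure of the 24 h activity image and takes
only its washout rate from the VOI fit: per voxel

    A_t0 = A_t * exp(lambda_VOI * t)        (back-extrapolation)
    TIA  = A_t0 / lambda_VOI                (integral of the exponential)

with lambda in 1/s, so the TIA image is in Bq*s.  A fitted decay rate
<= 0 (a non-decaying VOI, possible with noise) falls back to the physical
Lu-177 decay constant and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import LU177_LAMBDA_S
from .grids import check_same_geometry

__all__ = ["MonoExpFit", "fit_monoexp", "voi_activity_curves", "fit_all_vois", "hybrid_tia_image"]


@dataclass(frozen=True)
class MonoExpFit:
    voi_label: int
    lambda_s: float              # decay constant, 1/s
    amplitude_bq: float          # activity at t = 0
    residual_norm: float         # RMS residual of log activity
    fallback: bool = False       # physical half-life substituted

    @property
    def half_life_h(self) -> float:
        return np.log(2.0) / (self.lambda_s * 3600.0)


def fit_monoexp(times_h, activities_bq, voi_label: int = 0) -> MonoExpFit:
    """Unweighted log-linear mono-exponential fit of one VOI curve.

    Non-positive activity samples are excluded; at least two valid
    samples are required.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(activities_bq, dtype=float)
    ok = a > 0
    t, a = t[ok], a[ok]
    if t.size < 2:
        raise ValueError(f"VOI {voi_label}: need >= 2 positive-activity timepoints")
    if np.unique(t).size < 2:
        raise ValueError(f"VOI {voi_label}: timepoints must be distinct")
    slope, intercept = np.polyfit(t, np.log(a), 1)
    lam_h = -slope
    fallback = lam_h <= 0
    if fallback:
        lam_h = LU177_LAMBDA_S * 3600.0
        intercept = float(np.mean(np.log(a) + lam_h * t))
    resid = np.sqrt(np.mean((np.log(a) - (intercept - lam_h * t)) ** 2))
    return MonoExpFit(
        voi_label=int(voi_label),
        lambda_s=lam_h / 3600.0,
        amplitude_bq=float(np.exp(intercept)),
        residual_norm=float(resid),
        fallback=bool(fallback),
    )


def voi_activity_curves(images, times_h, voi_map, groups: dict[int, int] | None = None):
    """VOI-summed activity per timepoint.

    ``groups`` optionally maps raw labels to a fitting group (e.g. the
    skeleton shell into the remainder-of-body VOI).  Returns a DataFrame
    with columns (voi, time_h, activity_bq).
    """
    voi = np.asarray(voi_map)
    rows = []
    labels = [int(v) for v in np.unique(voi) if v != 0]
    for img, t in zip(images, times_h):
        check_same_geometry(img, voi)
        sums: dict[int, float] = {}
        for label in labels:
            group = groups.get(label, label) if groups else label
            sums[group] = sums.get(group, 0.0) + float(img[voi == label].sum())
        for group, s in sums.items():
            rows.append({"voi": group, "time_h": t, "activity_bq": s})
    return pd.DataFrame(rows)


def fit_all_vois(images, times_h, voi_map, groups=None) -> dict[int, MonoExpFit]:
    """Fit every VOI group curve; returns {group label: fit}."""
    curves = voi_activity_curves(images, times_h, voi_map, groups=groups)
    fits = {}
    for voi_label, sub in curves.groupby("voi"):
        fits[int(voi_label)] = fit_monoexp(sub["time_h"], sub["activity_bq"], voi_label=voi_label)
    return fits


def hybrid_tia_image(
    activity_t: np.ndarray,
    voi_map: np.ndarray,
    fits: dict[int, MonoExpFit],
    acquisition_time_h: float,
    groups: dict[int, int] | None = None,
) -> np.ndarray:
    """Hybrid VOI/voxel TIA image in Bq*s.

    Every voxel keeps its own activity from the reference image; only the
    washout rate comes from its VOI's fit.  Background voxels (label 0,
    outside the body) carry zero TIA; any other label without a fit is an
    error.
    """
    check_same_geometry(activity_t, voi_map)
    if acquisition_time_h < 0:
        raise ValueError("acquisition time must be >= 0")
    tia = np.zeros(activity_t.shape)
    for label in (int(v) for v in np.unique(voi_map) if v != 0):
        group = groups.get(label, label) if groups else label
        if group not in fits:
            raise ValueError(f"no mono-exponential fit for VOI label {label} (group {group})")
        lam = fits[group].lambda_s
        sel = voi_map == label
        a0 = activity_t[sel] * np.exp(lam * acquisition_time_h * 3600.0)
        tia[sel] = a0 / lam
    return tia
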