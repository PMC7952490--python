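"""CT- and activity-based VOI derivation.

Bone map and whole-body mask by HU thresholding, bone-lesion foreground by
k-means intensity clustering on the 24 h activity image restricted to the
bone map, individual lesions by 26-connected components with a minimum
volume filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .constants import voxel_volume_ml
from .grids import check_same_geometry
from .phantom import LESION_LABEL_START

__all__ = ["bone_map", "body_mask", "kmeans_lesion_segmentation", "LesionSegmentation"]

BONE_HU_THRESHOLD = 200.0
BODY_HU_THRESHOLD = -150.0
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


def bone_map(hu: np.ndarray, threshold: float = BONE_HU_THRESHOLD) -> np.ndarray:
    """Binary skeleton map: HU >= threshold (inclusive)."""
    return np.asarray(hu) >= threshold


def body_mask(hu: np.ndarray, threshold: float = BODY_HU_THRESHOLD) -> np.ndarray:
    """Whole-body mask: threshold, largest 26-connected component, hole fill."""
    raw = np.asarray(hu) >= threshold
    if not raw.any():
        raise ValueError("body mask is empty at this threshold")
    labels, n = ndimage.label(raw, structure=CONNECTIVITY_26)
    largest = np.argmax(ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))) + 1
    return ndimage.binary_fill_holes(labels == largest)


@dataclass
class LesionSegmentation:
    labels: np.ndarray           # 0 outside lesions, lesion ids >= 10
    table: pd.DataFrame          # lesion id, voxels, volume_ml
    cluster_means: np.ndarray    # sorted ascending


def kmeans_lesion_segmentation(
    activity_24h: np.ndarray,
    bone: np.ndarray,
    voxel_size_mm: float,
    k: int = 4,
    min_lesion_volume_ml: float = 1.0,
    top_clusters: int = 1,
    seed: int = 0,
) -> LesionSegmentation:
    """Segment bone lesions on the 24 h activity image within the bone map.

    Voxel intensities inside the bone map are clustered with k-means
    (k-means++ initialisation seeded by ``seed``); the ``top_clusters``
    highest-mean clusters form the lesion foreground, which is split into
    26-connected components; components below the minimum volume are
    discarded.  Lesion labels start at 10 and are assigned in scan order,
    so the result is deterministic for a fixed seed.
    """
    check_same_geometry(activity_24h, bone)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    bone = bone.astype(bool)
    vals = np.asarray(activity_24h, dtype=float)[bone]
    empty = LesionSegmentation(
        labels=np.zeros(activity_24h.shape, dtype=np.int32),
        table=pd.DataFrame(columns=["lesion", "voxels", "volume_ml"]),
        cluster_means=np.array([]),
    )
    if vals.size < k:
        return empty
    km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(vals.reshape(-1, 1))
    means = km.cluster_centers_.ravel()
    order = np.argsort(means)
    fg_clusters = set(order[-top_clusters:].tolist())
    fg = np.zeros(activity_24h.shape, dtype=bool)
    fg[bone] = np.isin(km.labels_, list(fg_clusters))
    comps, n = ndimage.label(fg, structure=CONNECTIVITY_26)
    min_vox = int(np.ceil(min_lesion_volume_ml / voxel_volume_ml(voxel_size_mm)))
    labels = np.zeros(activity_24h.shape, dtype=np.int32)
    rows = []
    next_label = LESION_LABEL_START
    for comp in range(1, n + 1):
        mask = comps == comp
        nv = int(mask.sum())
        if nv < min_vox:
            continue
        labels[mask] = next_label
        rows.append(
            {"lesion": next_label, "voxels": nv, "volume_ml": nv * voxel_volume_ml(voxel_size_mm)}
        )
        next_label += 1
    return LesionSegmentation(
        labels=labels,
        table=pd.DataFrame(rows, columns=["lesion", "voxels", "volume_ml"]),
        cluster_means=np.sort(means),
    )
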