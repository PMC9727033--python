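"""DBSCAN grouping of localizations and subcellular region assignment.

Clustering uses the standard DBSCAN semantics with a minPts-inclusive
convention (the point itself counts toward ``n_min``), delegating the
neighbourhood expansion to scikit-learn, whose ``min_samples`` follows the
same convention and whose border-point assignment is deterministic in input
order. Cluster ids are relabelled by order of first member appearance so
output depends on input order only up to that stable relabelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import DBSCAN

logger = logging.getLogger(__name__)

REGION_NAMES = {0: "outside", 1: "plasma_membrane", 2: "cytoplasm", 3: "nucleus"}

NOISE = -1


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringParams:
    """DBSCAN parameters (2D Euclidean metric, coordinates in nm)."""

    length_scale: float = 120.0  # nm, DBSCAN eps
    n_min: int = 4  # minPts, including the point itself
    # optional automated curation filters, both off by default
    min_detections: Optional[int] = None
    max_r_gyration: Optional[float] = None  # nm

    def __post_init__(self) -> None:
        if self.length_scale <= 0:
            raise ClusteringError("length_scale must be > 0")
        if self.n_min < 1:
            raise ClusteringError("n_min must be >= 1")


@dataclass
class SpatialCluster:
    cluster_id: int
    member_ids: np.ndarray  # row indices into the localization table
    centroid: tuple  # (x_nm, y_nm)
    n_detections: int
    radius_of_gyration: float  # nm
    region: str = "outside"
    cell_id: int = 0


@dataclass
class RegionMask:
    """Label image: 0 outside, 1 plasma-membrane band, 2 cytoplasm, 3 nucleus."""

    labels: np.ndarray
    pixel_size: float  # nm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(np.unique(self.labels), [0, 1, 2, 3]).all():
            raise ClusteringError("region mask labels must be in {0,1,2,3}")
        if self.pixel_size <= 0:
            raise ClusteringError("pixel_size must be > 0")

    def region_at(self, x_nm: float, y_nm: float) -> str:
        i = int(np.floor(y_nm / self.pixel_size))
        j = int(np.floor(x_nm / self.pixel_size))
        if i < 0 or j < 0 or i >= self.labels.shape[0] or j >= self.labels.shape[1]:
            return "outside"
        return REGION_NAMES[int(self.labels[i, j])]


def _positions(localizations) -> np.ndarray:
    if isinstance(localizations, pd.DataFrame):
        return localizations[["x_nm", "y_nm"]].to_numpy(dtype=float)
    pos = np.asarray(localizations, dtype=float)
    if pos.size == 0:
        return pos.reshape(0, 2)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ClusteringError("positions must be an (n, 2) array or a localization table")
    return pos


def dbscan_cluster(localizations, params: ClusteringParams):
    """Cluster localization positions with DBSCAN.

    Returns
    -------
    clusters : list[SpatialCluster]
        Cluster ids are 0..k-1 in order of first member appearance.
    labels : ndarray of int
        Per-localization cluster id, ``-1`` for noise. Every point is in
        exactly one cluster or noise.
    """
    pos = _positions(localizations)
    if len(pos) == 0:
        return [], np.empty(0, dtype=np.int64)
    if not np.isfinite(pos).all():
        raise ClusteringError("positions must be finite")

    raw = DBSCAN(eps=params.length_scale, min_samples=params.n_min).fit_predict(pos)

    # stable relabelling by first appearance
    labels = np.full(len(pos), NOISE, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab == NOISE:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]

    clusters = []
    dropped = 0
    for cid in range(len(mapping)):
        members = np.nonzero(labels == cid)[0]
        p = pos[members]
        centroid = p.mean(axis=0)
        rg = float(np.sqrt(((p - centroid) ** 2).sum(axis=1).mean()))
        if params.min_detections is not None and len(members) < params.min_detections:
            labels[members] = NOISE
            dropped += 1
            continue
        if params.max_r_gyration is not None and rg > params.max_r_gyration:
            labels[members] = NOISE
            dropped += 1
            continue
        clusters.append(
            SpatialCluster(
                cluster_id=len(clusters),
                member_ids=members,
                centroid=(float(centroid[0]), float(centroid[1])),
                n_detections=int(len(members)),
                radius_of_gyration=rg,
            )
        )
    if dropped:
        # keep ids dense after curation filters
        labels = _relabel_dense(labels)
        logger.info("curation filters dropped %d clusters", dropped)
    return clusters, labels


def _relabel_dense(labels: np.ndarray) -> np.ndarray:
    out = np.full_like(labels, NOISE)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def build_region_mask(
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    pm_band_px: int,
    pixel_size: float = 1.0,
) -> RegionMask:
    """Compose a region label image from nucleus and cell masks.

    The plasma-membrane band is the ``pm_band_px``-wide inner boundary of
    the cell (4-connected erosion); the nucleus overrides everything it
    covers; the remainder of the cell is cytoplasm.
    """
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if nucleus.shape != cell.shape:
        raise ClusteringError("nucleus and cell masks must share a shape")
    if (nucleus & ~cell).any():
        raise ClusteringError("nucleus mask must be contained in the cell mask")
    if pm_band_px < 0:
        raise ClusteringError("pm_band_px must be >= 0")

    labels = np.zeros(cell.shape, dtype=np.uint8)
    labels[cell] = 2
    if pm_band_px > 0:
        interior = ndimage.binary_erosion(
            cell,
            structure=ndimage.generate_binary_structure(2, 1),
            iterations=pm_band_px,
            border_value=0,
        )
        labels[cell & ~interior] = 1
    labels[nucleus] = 3
    return RegionMask(labels=labels, pixel_size=pixel_size)


def assign_regions(
    clusters: Sequence[SpatialCluster], mask: RegionMask
) -> list:
    """Label each cluster with the region at its centroid pixel.

    Clusters whose centroid falls outside the frame (or on a
    label-0 pixel) are labelled ``outside``; downstream statistics exclude
    them, which is logged here.
    """
    n_outside = 0
    for c in clusters:
        c.region = mask.region_at(*c.centroid)
        if c.region == "outside":
            n_outside += 1
    if n_outside:
        logger.info("%d clusters labelled outside and excluded downstream", n_outside)
    return list(clusters)


def clusters_to_frame(clusters: Sequence[SpatialCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "centroid_x_nm": [c.centroid[0] for c in clusters],
            "centroid_y_nm": [c.centroid[1] for c in clusters],
            "n_detections": [c.n_detections for c in clusters],
            "r_gyration_nm": [c.radius_of_gyration for c in clusters],
            "region": [c.region for c in clusters],
            "cell_id": [c.cell_id for c in clusters],
        }
    )
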