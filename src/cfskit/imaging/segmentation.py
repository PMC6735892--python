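"""Nucleus and micronucleus segmentation from DAPI images.

Segmentation is a global Otsu threshold followed by hole filling,
connected-component labelling and a size filter.  Objects below the
nucleus size floor are not discarded: they are kept as micronucleus
candidates, which :func:`detect_micronuclei` assigns to their nearest
nucleus within a search radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)


@dataclass
class NucleusMask:
    """Labelled nuclei plus sub-size candidate objects.

    ``labels`` holds nuclei labelled contiguously from 1; ``small_labels``
    holds connected objects below ``min_area`` (micronucleus candidates),
    labelled independently.
    """

    labels: np.ndarray
    areas: dict[int, int] = field(default_factory=dict)
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    small_labels: np.ndarray | None = None

    @property
    def n_nuclei(self) -> int:
        return len(self.areas)

    def cell_ids(self) -> list[int]:
        return sorted(self.areas)


def _max_project(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    return image.max(axis=0) if image.ndim == 3 else image


def segment_nuclei(
    dapi: np.ndarray, min_area: int = 100, max_area: int = 100000
) -> NucleusMask:
    """Segment nuclei from a DAPI channel (stacks are max-projected)."""
    img = _max_project(dapi)
    if np.ptp(img) == 0:
        logger.warning("blank DAPI image: returning empty mask")
        empty = np.zeros(img.shape, dtype=int)
        return NucleusMask(labels=empty, small_labels=empty.copy())

    binary = img > threshold_otsu(img)
    binary = ndimage.binary_fill_holes(binary)
    raw = cc_label(binary)

    labels = np.zeros(img.shape, dtype=int)
    small = np.zeros(img.shape, dtype=int)
    areas: dict[int, int] = {}
    centroids: dict[int, tuple[float, float]] = {}
    next_id, next_small = 1, 1
    for region in regionprops(raw):
        if region.area < min_area:
            small[raw == region.label] = next_small
            next_small += 1
        elif region.area <= max_area:
            labels[raw == region.label] = next_id
            areas[next_id] = int(region.area)
            centroids[next_id] = tuple(region.centroid)
            next_id += 1
        # above max_area: clump or artifact, dropped
    return NucleusMask(labels=labels, areas=areas, centroids=centroids, small_labels=small)


def detect_micronuclei(
    dapi: np.ndarray,
    mask: NucleusMask,
    max_mn_area: int = 80,
    search_radius: float = 20.0,
) -> dict[int, int]:
    """Count micronuclei per nucleus.

    A micronucleus is a sub-nucleus-size DAPI object with area at most
    ``max_mn_area`` whose centroid lies within ``search_radius`` pixels
    of a nucleus boundary; the nearest nucleus wins.  Returns a count
    for every segmented nucleus (zero included).
    """
    counts = {cid: 0 for cid in mask.cell_ids()}
    if mask.small_labels is None or mask.small_labels.max() == 0 or not counts:
        return counts
    # distance from every pixel to the nearest nucleus pixel, plus which one
    dist, (ir, ic) = ndimage.distance_transform_edt(
        mask.labels == 0, return_indices=True
    )
    for region in regionprops(mask.small_labels):
        if region.area > max_mn_area:
            continue
        r, c = (int(round(x)) for x in region.centroid)
        r = min(max(r, 0), mask.labels.shape[0] - 1)
        c = min(max(c, 0), mask.labels.shape[1] - 1)
        if dist[r, c] <= search_radius:
            owner = int(mask.labels[ir[r, c], ic[r, c]])
            if owner in counts:
                counts[owner] += 1
    return counts
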