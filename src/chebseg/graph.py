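"""SLIC superpixel partitioning and weighted region-adjacency graphs.

A normalized slice is oversegmented into C superpixels; each region becomes
a graph node carrying its mean intensity f_i in [0, 1].  Nodes of regions
that share a 4-connected pixel border are linked, and edges are weighted by
the Gaussian affinity

    w_ij = exp(-beta * (f_i - f_j)^2)

so that similar neighboring regions couple strongly.  Pixel-level masks map
to node labels by area-majority vote and back by painting each region with
its node label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic

from .preprocess import NORMALIZED, BinaryMask, CTSlice

__all__ = [
    "SuperpixelPartition",
    "RegionGraph",
    "slic_partition",
    "region_features",
    "region_adjacency",
    "edge_weights",
    "region_labels",
    "labels_to_mask",
    "build_region_graph",
    "regions_by_area_rule",
]

DEFAULT_REGIONS = 600
DEFAULT_BETA = 10.0
DEFAULT_COMPACTNESS = 0.1


@dataclass(frozen=True)
class SuperpixelPartition:
    """Covering partition of the pixel grid into C contiguous-labelled regions."""

    label_map: np.ndarray
    region_count: int

    def __post_init__(self) -> None:
        labels = np.unique(self.label_map)
        if labels.min() != 0 or labels.max() != self.region_count - 1 \
                or len(labels) != self.region_count:
            raise ValueError("labels must be contiguous 0..C-1 and all nonempty")

    @property
    def areas(self) -> np.ndarray:
        """Pixel count per region."""
        return np.bincount(self.label_map.ravel(), minlength=self.region_count)


@dataclass(frozen=True)
class RegionGraph:
    """Node features X (C x 1), binary adjacency A and Gaussian weights W."""

    features: np.ndarray
    adjacency: np.ndarray
    weights: np.ndarray
    beta: float


def regions_by_area_rule(height: int, width: int) -> int:
    """Alternative region-count rule N = P*Q/1000 tied to image area."""
    return max(2, int(round(height * width / 1000)))


def slic_partition(ct_slice: CTSlice, n_regions: int = DEFAULT_REGIONS,
                   compactness: float = DEFAULT_COMPACTNESS) -> SuperpixelPartition:
    """SLIC oversegmentation of a normalized slice.

    The returned region count may fall below ``n_regions`` (SLIC merges
    small clusters); labels are relabelled to be contiguous from 0.
    """
    if ct_slice.intensity_domain != NORMALIZED:
        raise ValueError("slic_partition expects a normalized slice")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if n_regions > ct_slice.pixels.size:
        raise ValueError("n_regions exceeds the pixel count")
    labels = slic(ct_slice.pixels, n_segments=n_regions,
                  compactness=compactness, channel_axis=None, start_label=0)
    _, contiguous = np.unique(labels, return_inverse=True)
    contiguous = contiguous.reshape(labels.shape)
    return SuperpixelPartition(label_map=contiguous,
                               region_count=int(contiguous.max()) + 1)


def region_features(partition: SuperpixelPartition, ct_slice: CTSlice) -> np.ndarray:
    """C x 1 matrix of per-region mean intensities."""
    if partition.label_map.shape != ct_slice.pixels.shape:
        raise ValueError("partition and slice shapes differ")
    sums = np.bincount(partition.label_map.ravel(),
                       weights=ct_slice.pixels.ravel(),
                       minlength=partition.region_count)
    return (sums / partition.areas)[:, None]


def region_adjacency(partition: SuperpixelPartition) -> np.ndarray:
    """Binary C x C adjacency: 1 iff two regions share a 4-connected border."""
    lab = partition.label_map
    c = partition.region_count
    adj = np.zeros((c, c), dtype=np.int8)
    for a, b in ((lab[:-1, :], lab[1:, :]), (lab[:, :-1], lab[:, 1:])):
        diff = a != b
        adj[a[diff], b[diff]] = 1
    adj |= adj.T
    np.fill_diagonal(adj, 0)
    return adj


def edge_weights(features: np.ndarray, adjacency: np.ndarray,
                 beta: float = DEFAULT_BETA) -> np.ndarray:
    """Gaussian edge weights exp(-beta * squared feature distance) on edges."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    f = np.atleast_2d(features)
    if f.shape[0] == 1 and f.size == adjacency.shape[0]:
        f = f.T
    d2 = ((f[:, None, :] - f[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-beta * d2) * (adjacency != 0)
    return w


def region_labels(partition: SuperpixelPartition, mask: BinaryMask,
                  threshold: float = 0.5) -> np.ndarray:
    """Node labels by area-majority: 1 iff the in-region mask fraction >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if partition.label_map.shape != mask.pixels.shape:
        raise ValueError("partition and mask shapes differ")
    pos = np.bincount(partition.label_map.ravel(),
                      weights=mask.pixels.ravel().astype(float),
                      minlength=partition.region_count)
    frac = pos / partition.areas
    return (frac >= threshold).astype(np.int64)


def labels_to_mask(partition: SuperpixelPartition,
                   node_labels: np.ndarray) -> BinaryMask:
    """Paint each region with its node label, producing a pixel mask."""
    node_labels = np.asarray(node_labels)
    if node_labels.shape[0] != partition.region_count:
        raise ValueError("node_labels length must equal the region count")
    return BinaryMask(pixels=(node_labels != 0)[partition.label_map])


def build_region_graph(partition: SuperpixelPartition, ct_slice: CTSlice,
                       beta: float = DEFAULT_BETA) -> RegionGraph:
    """Assemble features, adjacency and Gaussian weights for one slice."""
    x = region_features(partition, ct_slice)
    a = region_adjacency(partition)
    w = edge_weights(x, a, beta)
    return RegionGraph(features=x, adjacency=a, weights=w, beta=beta)
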