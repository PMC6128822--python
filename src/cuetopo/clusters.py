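"""Suprathreshold cluster labeling and Monte-Carlo cluster-extent correction.

The multiple-comparisons strategy: threshold the t-map at a one-sided voxel
p (positive activations only), group suprathreshold voxels into connected
components, and keep only components at least as large as the minimum extent
for which smooth Gaussian null fields produce a suprathreshold component that
big with probability <= cluster_alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volume import MaskVolume, StatMap, VolumeGrid, voxel_to_mm

__all__ = [
    "ClusterRecord",
    "ExtentThreshold",
    "label_clusters",
    "monte_carlo_extent_threshold",
    "apply_extent_threshold",
    "dilate_mask",
    "connectivity_structure",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D structuring element for 6/18/26 neighbor connectivity."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


@dataclass
class ClusterRecord:
    """A connected suprathreshold component of a thresholded t-map."""

    label_id: int
    size_voxels: int
    peak_t: float
    peak_voxel_index: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    member_voxel_indices: np.ndarray  # (size, 3) int array
    voxel_p: float
    connectivity: int
    cluster_p: float | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        self.member_voxel_indices = np.asarray(self.member_voxel_indices, dtype=int)
        if self.size_voxels != len(self.member_voxel_indices) or self.size_voxels < 1:
            raise ValueError("size_voxels must equal the number of member voxels (>= 1)")


@dataclass
class ExtentThreshold:
    """Monte-Carlo-derived minimum cluster size for (voxel p, alpha, smoothness)."""

    voxel_p: float
    cluster_alpha: float
    min_cluster_size_voxels: int
    smoothness_fwhm_mm: float
    n_iterations: int
    connectivity: int
    seed: int
    null_max_sizes: np.ndarray = field(repr=False)

    def null_exceedance(self, size: int) -> float:
        """Empirical P(max null cluster size >= size)."""
        return float(np.mean(self.null_max_sizes >= size))


def label_clusters(map: StatMap, voxel_p: float, mask: MaskVolume,
                   connectivity: int = 6) -> list[ClusterRecord]:
    """Partition one-sided suprathreshold voxels into connected components.

    Voxels with positive-tail p < ``voxel_p`` inside the mask are grouped under
    the chosen connectivity; records are sorted by size descending with peak t
    descending as tie-break.
    """
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must be in (0, 1)")
    map.grid.require_same_grid(mask.grid, "mask")
    t_thr = stats.t.isf(voxel_p, map.df)
    supra = (map.grid.data > t_thr) & mask.bool_array
    labels, n_labels = ndimage.label(supra, structure=connectivity_structure(connectivity))
    records: list[ClusterRecord] = []
    tvals = map.grid.data
    for lab in range(1, n_labels + 1):
        members = np.argwhere(labels == lab)
        member_t = tvals[tuple(members.T)]
        order = np.lexsort((members[:, 2], members[:, 1], members[:, 0], -member_t))
        peak_idx = tuple(int(v) for v in members[order[0]])
        records.append(ClusterRecord(
            label_id=lab,
            size_voxels=len(members),
            peak_t=float(member_t.max()),
            peak_voxel_index=peak_idx,
            peak_mm=tuple(float(v) for v in voxel_to_mm(map.grid, peak_idx)),
            member_voxel_indices=members,
            voxel_p=voxel_p,
            connectivity=connectivity,
        ))
    records.sort(key=lambda r: (-r.size_voxels, -r.peak_t, r.peak_voxel_index))
    return records


def _smooth_standardized_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    field = rng.standard_normal(shape)
    if np.any(np.asarray(sigma_vox) > 0):
        field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        field = (field - field.mean()) / field.std()
    return field


def monte_carlo_extent_threshold(
    mask: MaskVolume,
    smoothness_fwhm_mm: float,
    voxel_p: float = 0.005,
    cluster_alpha: float = 0.05,
    n_iterations: int = 1000,
    connectivity: int = 6,
    seed: int = 0,
) -> ExtentThreshold:
    """Derive the minimum cluster extent by simulating smooth Gaussian nulls.

    Each iteration draws white Gaussian noise on the mask's bounding grid,
    smooths it to ``smoothness_fwhm_mm`` (Gaussian autocorrelation),
    re-standardizes, thresholds at the one-sided ``voxel_p``, and records the
    largest in-mask component. The returned extent is the smallest k with
    empirical ``P(max size >= k) <= cluster_alpha``.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    if not (0 < voxel_p < 1 and 0 < cluster_alpha <= 1):
        raise ValueError("voxel_p and cluster_alpha must be probabilities")
    voxel_sizes = mask.grid.voxel_sizes
    extent_mm = np.asarray(mask.grid.shape) * voxel_sizes
    if smoothness_fwhm_mm > extent_mm.min():
        raise ValueError("smoothing kernel larger than mask extent")
    sigma_vox = (smoothness_fwhm_mm / np.sqrt(8 * np.log(2))) / voxel_sizes

    rng = np.random.default_rng(seed)
    z_thr = stats.norm.isf(voxel_p)
    structure = connectivity_structure(connectivity)
    m = mask.bool_array
    max_sizes = np.zeros(n_iterations, dtype=int)
    for i in range(n_iterations):
        field = _smooth_standardized_field(rng, mask.grid.shape, sigma_vox)
        supra = (field > z_thr) & m
        labels, n_labels = ndimage.label(supra, structure=structure)
        if n_labels:
            max_sizes[i] = int(np.bincount(labels.ravel())[1:].max())

    if cluster_alpha >= 1:
        min_size = 1
    else:
        sorted_sizes = np.sort(max_sizes)
        min_size = 1
        # smallest k with empirical P(max >= k) <= alpha
        for k in range(1, int(max_sizes.max()) + 2):
            frac = np.mean(max_sizes >= k)
            if frac <= cluster_alpha:
                min_size = k
                break
    return ExtentThreshold(
        voxel_p=voxel_p, cluster_alpha=cluster_alpha,
        min_cluster_size_voxels=int(min_size),
        smoothness_fwhm_mm=smoothness_fwhm_mm,
        n_iterations=n_iterations, connectivity=connectivity, seed=seed,
        null_max_sizes=max_sizes,
    )


def apply_extent_threshold(clusters: list[ClusterRecord],
                           thr: ExtentThreshold) -> list[ClusterRecord]:
    """Keep clusters meeting the extent threshold; annotate cluster-level p.

    The cluster-level p is the empirical fraction of null max sizes at least
    as large as the observed size.
    """
    for c in clusters:
        if not np.isclose(c.voxel_p, thr.voxel_p) or c.connectivity != thr.connectivity:
            raise ValueError("cluster voxel_p/connectivity do not match the threshold")
    kept = [c for c in clusters if c.size_voxels >= thr.min_cluster_size_voxels]
    for c in kept:
        c.cluster_p = thr.null_exceedance(c.size_voxels)
    return kept


def dilate_mask(mask: MaskVolume, iterations: int, connectivity: int = 6) -> MaskVolume:
    """Iterative 3D binary dilation; ``iterations=0`` is the identity."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return MaskVolume(VolumeGrid(mask.grid.data.copy(), mask.grid.affine))
    out = ndimage.binary_dilation(mask.bool_array,
                                  structure=connectivity_structure(connectivity),
                                  iterations=iterations)
    return MaskVolume(VolumeGrid(out.astype(float), mask.grid.affine))
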