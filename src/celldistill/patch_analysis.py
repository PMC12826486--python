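"""Patch-token interpretability: PCA->RGB maps, token matching, heterogeneity.

Patch-level features are projected onto the top three principal components
fit on pooled foreground tokens across an image collection and rendered as
RGB; individual tokens can be matched across images by cosine similarity;
and single-cell embedding collections are summarised by ordered similarity
matrices whose block structure quantifies phenotypic heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import ConfigurationError
from .profiling import cluster_order, cosine_similarity_matrix


@dataclass
class PCAMap:
    rgb: np.ndarray            # (rows, cols, 3) in [0, 1]; background = 0
    foreground: np.ndarray     # (rows, cols) bool


def patch_background_mask(mask_raster: np.ndarray, patch_size: int,
                          min_foreground: float = 0.10) -> np.ndarray:
    """Patch grid foreground mask: a patch counts as foreground when at
    least ``min_foreground`` of its pixels belong to a (ground-truth or
    thresholded) foreground region."""
    h, w = mask_raster.shape
    gh, gw = h // patch_size, w // patch_size
    blocks = (mask_raster[:gh * patch_size, :gw * patch_size] > 0).reshape(
        gh, patch_size, gw, patch_size)
    frac = blocks.mean(axis=(1, 3))
    return frac >= min_foreground


def otsu_foreground(image_data: np.ndarray) -> np.ndarray:
    """Otsu threshold on the mean-over-channels image (fallback mask source)."""
    from skimage.filters import threshold_otsu

    mean_img = image_data.mean(axis=0)
    return mean_img > threshold_otsu(mean_img)


def patch_pca_rgb(token_maps: list[np.ndarray],
                  foreground_masks: list[np.ndarray]) -> tuple[list[PCAMap], PCA]:
    """Collection-level PCA of foreground patch tokens, rendered to RGB.

    The PCA basis is fit on foreground tokens pooled across all images (so
    colors are comparable between images); each component is min-max scaled
    to [0, 1] over the pooled foreground; background patches render black.
    """
    if len(token_maps) != len(foreground_masks):
        raise ConfigurationError("token maps and masks must align")
    pooled = [tm[fm] for tm, fm in zip(token_maps, foreground_masks)]
    stacked = np.concatenate([p for p in pooled if len(p)]) if pooled else np.empty((0,))
    if stacked.shape[0] < 3:
        raise ConfigurationError("PCA needs at least 3 foreground tokens")
    pca = PCA(n_components=3, svd_solver="full")
    proj = pca.fit_transform(stacked)
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    # components with (numerically) no variance render as a constant channel
    span = np.where(hi - lo > 1e-9, hi - lo, 1.0)

    out = []
    for tm, fm in zip(token_maps, foreground_masks):
        rgb = np.zeros(fm.shape + (3,))
        if fm.any():
            p = (pca.transform(tm[fm]) - lo) / span
            rgb[fm] = np.clip(p, 0.0, 1.0)
        out.append(PCAMap(rgb, fm))
    return out, pca


def token_match(query_token: np.ndarray, reference_map: np.ndarray) -> np.ndarray:
    """Cosine similarity between one query token and every reference token."""
    q = np.asarray(query_token, dtype=np.float64)
    ref = np.asarray(reference_map, dtype=np.float64)
    qn = q / max(np.linalg.norm(q), 1e-12)
    norms = np.maximum(np.linalg.norm(ref, axis=-1), 1e-12)
    return (ref @ qn) / norms


def block_contrast(s: np.ndarray, min_block_fraction: float = 0.2,
                   max_blocks: int = 4) -> float:
    """Mean within-block minus between-block similarity after clustering.

    The similarity matrix is cut by average-linkage clustering into up to
    ``max_blocks`` clusters; only clusters holding at least
    ``min_block_fraction`` of the population count as blocks (smaller ones
    are outliers, not heterogeneity).  With fewer than two blocks the
    statistic is 0: a homogeneous population with a few stragglers does not
    register as heterogeneous.
    """
    n = s.shape[0]
    if n < 4:
        return 0.0
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    d = 1.0 - (s + s.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(np.maximum(d, 0.0), checks=False), method="average")
    labels = fcluster(z, t=max_blocks, criterion="maxclust")
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    blocks = [lab for lab, sz in sizes.items() if sz >= min_block_fraction * n]
    if len(blocks) < 2:
        return 0.0
    member = np.isin(labels, blocks)
    within, between = [], []
    for i in range(n):
        if not member[i]:
            continue
        for j in range(i + 1, n):
            if not member[j]:
                continue
            (within if labels[i] == labels[j] else between).append(s[i, j])
    if not within or not between:
        return 0.0
    return float(np.mean(within) - np.mean(between))


@dataclass
class HeterogeneityResult:
    similarity: np.ndarray     # reordered similarity matrix
    order: np.ndarray
    contrast: float


def heterogeneity_matrix(embeddings: np.ndarray,
                         contrast_threshold: float = 0.1) -> HeterogeneityResult:
    """Ordered single-cell similarity matrix plus the block-contrast statistic.

    ``contrast > contrast_threshold`` indicates a heterogeneous population
    (distinct sub-clusters of cells under one nominal condition).
    """
    x = np.asarray(embeddings, dtype=np.float64)
    if x.ndim != 2:
        raise ConfigurationError("need a (cells, features) matrix")
    s = cosine_similarity_matrix(x)
    order = cluster_order(s)
    return HeterogeneityResult(s[np.ix_(order, order)], order, block_contrast(s))
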