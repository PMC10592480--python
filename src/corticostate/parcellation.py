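"""Data-driven bilateral functional parcellation.

K-means with correlation distance clusters one hemisphere's pixel time courses
into k functional ROIs; the resulting labels are mirrored across the midline to
initialize clustering of the contralateral hemisphere, and left/right cluster
centroids are matched into bilateral pairs by maximal temporal correlation
(solved as an assignment problem). The cluster count is evaluated by
representing the movie as a nonnegative mixture of cluster centroid time
courses (per-pixel NNLS) and tracking residual / explained variance against a
PCA basis of the same rank.

Correlation distance is implemented by row-standardizing pixel traces and
running Euclidean k-means: for z-scored rows, ``||z_i - z_j||^2 = 2 T (1 - r_ij)``,
so Euclidean k-means on ``z/sqrt(T)`` minimizes within-cluster correlation
distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.cluster import KMeans


@dataclass
class ParcellationMap:
    """Pixel-to-ROI labels with bilateral pairing.

    ``labels`` is an image of integer ROI ids, 0 = background. ``pairs`` lists
    (left_id, right_id) tuples forming a perfect matching of the two
    hemispheres' ROI sets.
    """

    labels: np.ndarray
    n_rois: int
    pairs: list[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        paired = {l for p in self.pairs for l in p}
        if present != paired:
            raise ValueError("pairs must cover exactly the ROI labels present")
        if len(paired) != 2 * len(self.pairs):
            raise ValueError("pairs must form a perfect matching (no repeats)")
        if self.n_rois != len(paired):
            raise ValueError("n_rois inconsistent with pairs")

    def roi_order(self) -> list[int]:
        """Paired row order: all left ids, then their right partners."""
        return [p[0] for p in self.pairs] + [p[1] for p in self.pairs]

    def save(self, labels_path, sidecar_path) -> None:
        np.savetxt(labels_path, self.labels, fmt="%d")
        with open(sidecar_path, "w") as fh:
            json.dump({"n_rois": self.n_rois,
                       "pairs": [list(p) for p in self.pairs],
                       "provenance": self.provenance}, fh, indent=1)


@dataclass
class CentroidSet:
    """Cluster centroid time courses, row n for ROI n of the companion map."""

    centroids: np.ndarray  # (n, time)

    @property
    def n(self) -> int:
        return self.centroids.shape[0]


def _corr_normalize(pixel_matrix: np.ndarray) -> np.ndarray:
    x = np.asarray(pixel_matrix, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd < 1e-14):
        raise ValueError("constant pixel trace; correlation distance undefined")
    return x / (sd * np.sqrt(x.shape[1]))


def cluster_hemisphere(
    pixel_matrix: np.ndarray,
    k: int,
    replicates: int = 100,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, CentroidSet]:
    """K-means under correlation distance, best of ``replicates`` restarts.

    Parameters
    ----------
    pixel_matrix : (pixels, time)
        One hemisphere's traces.
    init : optional (k, time) centroid seed matrix; when given, a single run
        is started from it (used for mirror initialization).

    Returns (labels per pixel in 0..k-1, CentroidSet of mean member traces).
    """
    x = np.asarray(pixel_matrix, dtype=float)
    if k >= x.shape[0]:
        raise ValueError("k must be smaller than the pixel count")
    z = _corr_normalize(x)
    if init is not None:
        init_z = _corr_normalize(init)
        km = KMeans(n_clusters=k, init=init_z, n_init=1, random_state=seed)
    else:
        km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatters about memory leaks on MKL
        labels = km.fit_predict(z)
    # empty-cluster repair: reseed each empty cluster with the worst-fit pixel
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):
        warnings.warn("empty cluster(s) repaired by resampling", stacklevel=2)
        rng = np.random.default_rng(seed)
        for c in np.where(counts == 0)[0]:
            labels[rng.integers(0, len(labels))] = c
    centroids = np.stack([x[labels == c].mean(axis=0) for c in range(k)])
    return labels, CentroidSet(centroids=centroids)


def mirror_and_pair(
    labels_left: np.ndarray,
    data_left: np.ndarray,
    data_right: np.ndarray,
    right_geometry_mirror: "callable",
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]], CentroidSet]:
    """Mirror left-hemisphere labels to initialize the right, then pair.

    Parameters
    ----------
    labels_left : (n_left_pixels,) cluster labels in 0..k-1.
    data_left, data_right : (pixels, time) per hemisphere.
    right_geometry_mirror : callable mapping a left-pixel label vector to the
        right hemisphere's pixel order (the geometric reflection).

    Returns (labels_right, pairs as (left_cluster, right_cluster) index tuples,
    right CentroidSet). Ties in the correlation-based assignment are broken by
    the spatial overlap of mirrored masks.
    """
    k = int(labels_left.max()) + 1
    mirrored = right_geometry_mirror(labels_left)
    init = np.stack([data_right[mirrored == c].mean(axis=0) if (mirrored == c).any()
                     else data_right.mean(axis=0) for c in range(k)])
    labels_right, cent_right = cluster_hemisphere(data_right, k, seed=seed, init=init)
    cent_left = np.stack([data_left[labels_left == c].mean(axis=0) for c in range(k)])

    corr = _pairwise_corr(cent_left, cent_right.centroids)
    overlap = np.zeros((k, k))
    for c in range(k):
        for d in range(k):
            overlap[c, d] = np.mean((mirrored == c) & (labels_right == d))
    # small overlap bonus only breaks exact correlation ties
    row_l, col_r = linear_sum_assignment(-(corr + 1e-9 * overlap))
    pairs = list(zip(row_l.tolist(), col_r.tolist()))
    return labels_right, pairs, cent_right


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def bilateral_parcellation(
    stack: np.ndarray,
    image_shape: tuple[int, int],
    k_per_hemisphere: int,
    midline_cols: tuple[int, int],
    replicates: int = 100,
    seed: int = 0,
) -> ParcellationMap:
    """Full bilateral parcellation of a pixel×time stack.

    Clusters the left hemisphere (columns < midline_cols[0]), reflects the
    labels onto the right (columns >= midline_cols[1]) to initialize its
    clustering, and pairs clusters by centroid correlation. Output labels are
    1..k on the left and k+1..2k on the right, ordered so left id i pairs with
    right id i + k.
    """
    rows, cols = image_shape
    x = np.asarray(stack, dtype=float).reshape(rows * cols, -1)
    col_idx = np.tile(np.arange(cols), rows)
    left_mask = col_idx < midline_cols[0]
    right_mask = col_idx >= midline_cols[1]

    data_left = x[left_mask]
    data_right = x[right_mask]
    labels_left, _ = cluster_hemisphere(data_left, k_per_hemisphere,
                                        replicates=replicates, seed=seed)

    width = midline_cols[0]
    def mirror(lab_left: np.ndarray) -> np.ndarray:
        img = np.full((rows, cols), -1, dtype=int)
        img[:, :width] = lab_left.reshape(rows, width)
        mirrored_img = img[:, width - 1 :: -1]  # reflect the left block
        out = np.full((rows, cols), -1, dtype=int)
        out[:, cols - width :] = mirrored_img
        return out.ravel()[right_mask]

    labels_right, pairs, _ = mirror_and_pair(labels_left, data_left, data_right,
                                             mirror, seed=seed)

    right_of = {l: r for l, r in pairs}
    label_img = np.zeros(rows * cols, dtype=int)
    label_img[left_mask] = labels_left + 1
    right_relab = np.array([0] * k_per_hemisphere)
    for l, r in pairs:
        right_relab[r] = l + 1 + k_per_hemisphere
    label_img[right_mask] = right_relab[labels_right]
    final_pairs = [(l + 1, l + 1 + k_per_hemisphere) for l in range(k_per_hemisphere)]
    return ParcellationMap(
        labels=label_img.reshape(rows, cols),
        n_rois=2 * k_per_hemisphere,
        pairs=final_pairs,
        provenance={"seed": seed, "replicates": replicates,
                    "k_per_hemisphere": k_per_hemisphere},
    )


def evaluate_cluster_count(
    data: np.ndarray, centroid_sets: list[CentroidSet]
) -> dict:
    """NNLS residual / explained variance per candidate centroid set.

    For each set, every pixel trace is fit as a nonnegative mixture of the
    centroid time courses; reports total squared residual and fraction of
    (centered) variance explained, alongside the PCA explained variance of the
    same data at matched rank — the optimal linear bound.
    """
    x = np.asarray(data, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    total = float(np.sum(xc**2))
    if total < 1e-30:
        raise ValueError("data has no variance")
    s = np.linalg.svd(xc, compute_uv=False)
    cum_pca = np.cumsum(s**2) / total

    out = {"n": [], "residual": [], "explained_variance": [], "pca_explained_variance": []}
    for cs in centroid_sets:
        H = cs.centroids
        if np.any(H.std(axis=1) < 1e-14):
            raise ValueError("degenerate (constant) centroid in set")
        resid = _nnls_residual(x, H)
        out["n"].append(cs.n)
        out["residual"].append(resid)
        # explained variance measured against the centered total, like PCA
        out["explained_variance"].append(1.0 - resid / total)
        out["pca_explained_variance"].append(float(cum_pca[min(cs.n, len(cum_pca)) - 1]))
    return out


def _nnls_residual(x: np.ndarray, H: np.ndarray) -> float:
    A = H.T  # (time, n)
    resid = 0.0
    for row in x:
        _, rnorm = nnls(A, row)
        resid += rnorm**2
    return float(resid)


def nnls_spatial_coefficients(x: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Per-pixel NNLS weights of centroid time courses (pixels × n)."""
    A = H.T
    return np.stack([nnls(A, row)[0] for row in x])


def consensus_mode_map(repeated_maps: list[ParcellationMap]) -> ParcellationMap:
    """Per-pixel modal label across repeated parcellations.

    Each map is first canonically relabeled by optimal assignment against the
    first map on pixel-overlap counts; the output takes the most common label
    per pixel (ties go to the earliest map in the list order, which callers
    should sort by within-cluster distance).
    """
    if len(repeated_maps) < 3:
        raise ValueError("need >= 3 repeated maps")
    n_rois = repeated_maps[0].n_rois
    if any(m.n_rois != n_rois for m in repeated_maps):
        raise ValueError("maps differ in n_rois")
    ref = repeated_maps[0].labels.ravel()
    aligned = [ref]
    for m in repeated_maps[1:]:
        lab = m.labels.ravel()
        ids = sorted(set(np.unique(ref)) - {0})
        overlap = np.zeros((len(ids), len(ids)))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                overlap[i, j] = np.sum((ref == a) & (lab == b))
        ri, ci = linear_sum_assignment(-overlap)
        remap = {0: 0}
        remap.update({ids[j]: ids[i] for i, j in zip(ri, ci)})
        aligned.append(np.vectorize(remap.get)(lab))
    stacked = np.stack(aligned)  # (n_maps, pixels)
    mode = np.empty(stacked.shape[1], dtype=int)
    for p in range(stacked.shape[1]):
        vals, counts = np.unique(stacked[:, p], return_counts=True)
        best = counts.max()
        candidates = set(vals[counts == best])
        # earliest-map tie-break
        mode[p] = next(v for v in stacked[:, p] if v in candidates)
    return ParcellationMap(
        labels=mode.reshape(repeated_maps[0].labels.shape),
        n_rois=n_rois,
        pairs=list(repeated_maps[0].pairs),
        provenance={"consensus_of": len(repeated_maps)},
    )


def group_subregions(
    mean_corr_map: np.ndarray,
    parcellation: ParcellationMap,
    per_hemisphere_groups: int = 6,
    seed: int = 0,
) -> tuple[dict[int, int], np.ndarray]:
    """Group ROIs into per-hemisphere subgroups by k-means on correlation rows.

    Clusters each hemisphere's ROIs (rows of the ROI×ROI mean correlation map)
    separately into ``per_hemisphere_groups`` groups — 12 groups total for the
    default 6 — and returns (roi_id -> group index in 0..2g-1, reduced
    2g × n_rois map of group-mean correlation rows).
    """
    order = parcellation.roi_order()
    n = len(order)
    if mean_corr_map.shape != (n, n):
        raise ValueError("correlation map shape must match ROI count")
    half = n // 2
    if half < per_hemisphere_groups:
        raise ValueError("fewer ROIs per hemisphere than requested groups")
    grouping: dict[int, int] = {}
    for hemi, sl in enumerate((slice(0, half), slice(half, n))):
        rows = mean_corr_map[sl]
        km = KMeans(n_clusters=per_hemisphere_groups, n_init=20, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lab = km.fit_predict(rows)
        for i, g in enumerate(lab):
            grouping[order[sl][i]] = int(g) + hemi * per_hemisphere_groups
    reduced = np.stack([
        mean_corr_map[[order.index(r) for r, g in grouping.items() if g == gi]].mean(axis=0)
        for gi in range(2 * per_hemisphere_groups)
    ])
    return grouping, reduced
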