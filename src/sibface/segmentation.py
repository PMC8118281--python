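"""Global-to-local facial segmentation and per-segment shape spaces.

Landmarks are grouped by the strength of their covariation, measured with
Escoufier's RV coefficient between the 3-column coordinate blocks of every
landmark pair. Hierarchical spectral clustering recursively bisects the
landmark set; five levels of bisection below the full face yield the
63-segment hierarchy. Each segment gets its own shape space: GPA on the
segment's landmarks, PCA, and parallel analysis to pick the number of
retained components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .preprocess import AlignedCohort, gpa

__all__ = [
    "SegmentNode",
    "SegmentHierarchy",
    "SegmentShapeSpace",
    "rv_coefficient",
    "build_landmark_similarity",
    "hierarchical_spectral_bisect",
    "parallel_analysis",
    "build_segment_space",
    "align_to_segment",
]


@dataclass
class SegmentNode:
    node_id: int  # heap numbering: root 1, children of i are 2i and 2i+1
    landmark_indices: np.ndarray
    parent_id: int | None
    child_ids: tuple[int, int] | None
    truncated: bool = False


@dataclass
class SegmentHierarchy:
    nodes: dict[int, SegmentNode]
    depth: int
    n_landmarks: int

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def segment_ids(self) -> list[int]:
        return sorted(self.nodes)

    def validate(self) -> None:
        root = self.nodes[1]
        assert np.array_equal(np.sort(root.landmark_indices), np.arange(self.n_landmarks))
        for node in self.nodes.values():
            if node.child_ids is None:
                continue
            left, right = (self.nodes[c] for c in node.child_ids)
            merged = np.sort(np.concatenate([left.landmark_indices, right.landmark_indices]))
            assert np.array_equal(merged, np.sort(node.landmark_indices))
            assert len(left.landmark_indices) > 0 and len(right.landmark_indices) > 0


@dataclass
class SegmentShapeSpace:
    """PCA shape space of one facial segment."""

    segment_id: int
    landmark_indices: np.ndarray
    consensus: np.ndarray  # segment GPA consensus, (|segment|, 3)
    mean_shape: np.ndarray  # (3 * |segment|,)
    eigenvectors: np.ndarray  # columns, orthonormal
    eigenvalues: np.ndarray  # non-increasing
    n_retained: int
    with_scaling: bool = True

    @property
    def sigma(self) -> np.ndarray:
        """Per-PC standard deviations of the retained components."""
        return np.sqrt(self.eigenvalues[: self.n_retained])

    @property
    def explained_variance_fraction(self) -> float:
        total = self.eigenvalues.sum()
        return float(self.eigenvalues[: self.n_retained].sum() / total) if total > 0 else 0.0


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Escoufier's RV coefficient between two column-centered blocks.

    RV = tr(S_XY S_YX) / sqrt(tr(S_XX^2) tr(S_YY^2)); reduces to the squared
    Pearson correlation when both blocks have one column.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X, Y = X.T, Y.T
    if X.shape[0] != Y.shape[0] or X.shape[0] < 2:
        raise ValueError("blocks must share n >= 2 rows")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.sum((Xc.T @ Xc) ** 2)
    syy = np.sum((Yc.T @ Yc) ** 2)
    if sxx <= 0 or syy <= 0:
        raise ValueError("zero-variance block: RV undefined")
    sxy = np.sum((Xc.T @ Yc) ** 2)
    return float(sxy / np.sqrt(sxx * syy))


def build_landmark_similarity(configurations: np.ndarray) -> np.ndarray:
    """Landmark-by-landmark RV matrix across individuals.

    ``configurations`` is (n, n_landmarks, 3) in a common frame. Entry (i, j)
    is the RV coefficient between landmark i's and landmark j's coordinate
    blocks.
    """
    A = np.asarray(configurations, dtype=float)
    if A.ndim != 3 or A.shape[0] < 3:
        raise ValueError("need (n >= 3, n_landmarks, 3) configurations")
    A = A - A.mean(axis=0)
    # G[i, a, j, b] = sum_n A[n, i, a] * A[n, j, b]
    G = np.einsum("nia,njb->iajb", A, A, optimize=True)
    num = np.einsum("iajb,iajb->ij", G, G, optimize=True)
    den = np.sqrt(np.diag(num))
    bad = np.flatnonzero(den <= 0)
    if bad.size:
        raise ValueError(f"zero-variance landmark(s): {bad.tolist()}; RV undefined")
    rv = num / np.outer(den, den)
    return 0.5 * (rv + rv.T)


def _spectral_bisect(
    S: np.ndarray, seed: int, min_side: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices 0..m-1 in two by the normalized-Laplacian Fiedler vector.

    2-means on a 1-D Fiedler vector produces contiguous clusters in sorted
    order, so the split is a cut point; ``min_side`` clips that cut so both
    children stay large enough to support the remaining hierarchy depth
    (median-cut fallback when the clustering degenerates).
    """
    m = S.shape[0]
    d = S.sum(axis=1)
    d = np.where(d > 0, d, 1.0)
    dinv = 1.0 / np.sqrt(d)
    L = np.eye(m) - dinv[:, None] * S * dinv[None, :]
    L = 0.5 * (L + L.T)
    vals, vecs = eigh(L, subset_by_index=[0, min(1, m - 1)])
    fiedler = vecs[:, -1]
    order = np.argsort(fiedler, kind="stable")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(fiedler[:, None])
    low_cluster = labels[order[0]]
    cut = int(np.sum(labels == low_cluster))
    if cut == 0 or cut == m:
        cut = m // 2  # degenerate clustering: median cut
    cut = int(np.clip(cut, min_side, m - min_side))
    left, right = np.sort(order[:cut]), np.sort(order[cut:])
    # deterministic orientation: the side containing index 0 is 'left'
    if 0 in right:
        left, right = right, left
    return left, right


def hierarchical_spectral_bisect(
    similarity: np.ndarray, depth: int, seed: int = 0
) -> SegmentHierarchy:
    """Recursively bisect the landmark set into a binary segment hierarchy.

    Depth ``d`` yields ``2**(d+1) - 1`` segments when every node remains
    splittable; a node with fewer than 2 landmarks stops early with a warning
    and is marked truncated.
    """
    S = np.asarray(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(S, S.T, atol=1e-10) or (S < -1e-12).any():
        raise ValueError("similarity must be symmetric and non-negative")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    n = S.shape[0]
    nodes: dict[int, SegmentNode] = {
        1: SegmentNode(1, np.arange(n), None, None)
    }

    def split(node_id: int, level: int) -> None:
        node = nodes[node_id]
        if level >= depth:
            return
        idx = node.landmark_indices
        if idx.size < 2:
            warnings.warn(
                f"segment {node_id} has {idx.size} landmark(s); branch truncated"
            )
            node.truncated = True
            return
        # each child must be able to host its own subtree of the remaining
        # depth (one landmark per leaf); only enforceable when the node is
        # large enough for a full subtree
        remaining = depth - level
        min_side = 2 ** (remaining - 1) if idx.size >= 2**remaining else 1
        left, right = _spectral_bisect(
            S[np.ix_(idx, idx)], seed=seed + node_id, min_side=min_side
        )
        lid, rid = 2 * node_id, 2 * node_id + 1
        nodes[lid] = SegmentNode(lid, idx[left], node_id, None)
        nodes[rid] = SegmentNode(rid, idx[right], node_id, None)
        node.child_ids = (lid, rid)
        split(lid, level + 1)
        split(rid, level + 1)

    split(1, 0)
    hierarchy = SegmentHierarchy(nodes=nodes, depth=depth, n_landmarks=n)
    hierarchy.validate()
    return hierarchy


def parallel_analysis(
    data: np.ndarray,
    n_permutations: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Number of PCs whose eigenvalue beats the permutation null.

    Columns are permuted independently to destroy correlation while keeping
    marginals; a component is retained while its sample eigenvalue exceeds
    the chosen percentile of the permuted eigenvalues of the same rank, and
    the retained set is contiguous from the top.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need n >= 3 rows")
    if n_permutations < 20:
        raise ValueError("need n_permutations >= 20")
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=0)
    n, p = Xc.shape
    k = min(n - 1, p)
    sample = (np.linalg.svd(Xc, compute_uv=False) ** 2)[:k] / (n - 1)
    null = np.empty((n_permutations, k))
    perm = Xc.copy()
    for b in range(n_permutations):
        for j in range(p):
            perm[:, j] = perm[rng.permutation(n), j]
        null[b] = (np.linalg.svd(perm, compute_uv=False) ** 2)[:k] / (n - 1)
    thresh = np.percentile(null, percentile, axis=0)
    n_retained = 0
    for lam, t in zip(sample, thresh):
        if lam > t:
            n_retained += 1
        else:
            break
    return n_retained


def build_segment_space(
    configurations: np.ndarray,
    segment: SegmentNode | np.ndarray,
    n_permutations: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
    with_scaling: bool = True,
    min_retained: int = 1,
) -> SegmentShapeSpace:
    """Shape space of one segment: segment GPA, PCA, parallel analysis.

    ``configurations`` is the full-face cohort, (n, n_landmarks, 3); the
    segment's landmarks are extracted and re-aligned before PCA.
    """
    if isinstance(segment, SegmentNode):
        seg_id, idx = segment.node_id, segment.landmark_indices
    else:
        seg_id, idx = 0, np.asarray(segment, dtype=int)
    if idx.size == 0:
        raise ValueError("empty segment")
    if idx.size < 2:
        raise ValueError("segment of a single landmark has no shape after GPA")
    sub = np.asarray(configurations, dtype=float)[:, idx, :]
    aligned = gpa(sub, with_scaling=with_scaling)
    X = aligned.shapes
    mean = X.mean(axis=0)
    Xc = X - mean
    n = X.shape[0]
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    eigenvectors = vt.T
    n_retained = parallel_analysis(
        X, n_permutations=n_permutations, percentile=percentile, seed=seed
    )
    n_retained = int(np.clip(n_retained, min_retained, min(n - 1, X.shape[1])))
    # drop numerically-zero trailing components so sigma stays positive
    positive = int(np.sum(eigenvalues > 1e-12 * max(eigenvalues[0], 1.0)))
    n_retained = min(n_retained, max(positive, 1))
    return SegmentShapeSpace(
        segment_id=seg_id,
        landmark_indices=idx,
        consensus=aligned.consensus,
        mean_shape=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        n_retained=n_retained,
        with_scaling=with_scaling,
    )


def align_to_segment(space: SegmentShapeSpace, configurations: np.ndarray) -> np.ndarray:
    """Procrustes-fit new full-face configurations onto a segment consensus.

    Each individual's segment landmarks are centered, optionally scaled to
    unit centroid size, and rotated onto the stored segment consensus; the
    flattened aligned shapes can then be projected into the segment space.
    """
    from .preprocess import _optimal_rotation  # local import to avoid cycle

    configs = np.asarray(configurations, dtype=float)
    sub = configs[:, space.landmark_indices, :]
    out = np.empty((sub.shape[0], sub.shape[1] * 3))
    for i, cfg in enumerate(sub):
        centered = cfg - cfg.mean(axis=0)
        if space.with_scaling:
            size = np.sqrt(np.sum(centered**2))
            if size <= 1e-12:
                raise ValueError(f"degenerate configuration at row {i}")
            centered = centered / size
        rot = _optimal_rotation(centered, space.consensus)
        out[i] = (centered @ rot).ravel()
    return out
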