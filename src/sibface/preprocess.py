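"""Shape alignment and confounder adjustment.

Generalized Procrustes analysis (GPA) places all landmark configurations in
a common frame by iteratively removing translation, optionally scale, and
rotation. The symmetric shape component is the per-individual average of a
configuration and its relabeled mirror image after a joint GPA of originals
and reflections. Partial least-squares regression (PLSR) residualizes a
response block (shapes, or genotype dosages) on a covariate design; the same
routine serves both phenotype and genotype adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import svd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "AlignedCohort",
    "ConfounderModel",
    "gpa",
    "symmetrize",
    "plsr_residualize",
    "project_to_reference",
    "centroid_size",
]


@dataclass
class AlignedCohort:
    """Shapes in a common Procrustes frame.

    ``shapes`` is (n, 3 * n_landmarks) row-flattened; ``centroid_size`` holds
    the pre-scaling size of every configuration.
    """

    shapes: np.ndarray
    consensus: np.ndarray  # (n_landmarks, 3)
    centroid_size: np.ndarray
    with_scaling: bool

    @property
    def n_landmarks(self) -> int:
        return self.consensus.shape[0]

    def as_configurations(self) -> np.ndarray:
        return self.shapes.reshape(len(self.shapes), self.n_landmarks, 3)


@dataclass
class ConfounderModel:
    predictor_names: list[str]
    dropped: list[str]
    pls: PLSRegression
    response_mean: np.ndarray
    covariate_mean: np.ndarray


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances to the centroid."""
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (proper orthogonal) minimizing ||source @ R - target||_F."""
    u, _, vt = svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _principal_axes(consensus: np.ndarray) -> np.ndarray:
    """Right-handed principal-axes rotation with deterministic axis signs."""
    cov = consensus.T @ consensus
    vals, vecs = np.linalg.eigh(cov)
    V = vecs[:, ::-1]  # descending variance
    proj = consensus @ V
    for j in range(3):
        m3 = np.sum(proj[:, j] ** 3)
        if abs(m3) > 1e-9 * max(np.abs(proj[:, j]).max(), 1e-30) ** 3:
            s = np.sign(m3)
        else:
            s = np.sign(proj[np.argmax(np.abs(proj[:, j])), j]) or 1.0
        V[:, j] *= s
    if np.linalg.det(V) < 0:
        V[:, 2] *= -1
    return V


def gpa(
    configurations: np.ndarray,
    with_scaling: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    consensus_projector=None,
) -> AlignedCohort:
    """Generalized Procrustes alignment of a cohort.

    Parameters
    ----------
    configurations : (n, n_landmarks, 3) array
    with_scaling : rescale every configuration to unit centroid size.
    tol : convergence threshold on the RMS change of the consensus.
    consensus_projector : optional callable applied to the consensus each
        iteration (used to pin the consensus onto the bilateral-symmetry
        subspace during joint original+reflection alignment).
    """
    configs = np.asarray(configurations, dtype=float)
    if configs.ndim != 3 or configs.shape[0] < 2 or configs.shape[2] != 3:
        raise ValueError("need >= 2 configurations of shape (n_landmarks, 3)")
    if not np.isfinite(configs).all():
        raise ValueError("non-finite coordinates")
    n = configs.shape[0]

    centered = configs - configs.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
    if np.any(sizes <= 1e-12):
        raise ValueError("degenerate configuration: all landmarks coincident")
    aligned = centered / sizes[:, None, None] if with_scaling else centered.copy()

    consensus = aligned[0].copy()
    if consensus_projector is not None:
        consensus = consensus_projector(consensus)
    for _ in range(max_iter):
        # batched orthogonal Procrustes: rotate every configuration onto the
        # current consensus in one vectorized SVD
        M = np.einsum("ilk,lm->ikm", aligned, consensus)
        U, _, Vt = np.linalg.svd(M)
        det = np.linalg.det(np.einsum("ikm,imn->ikn", U, Vt))
        U[det < 0, :, -1] *= -1
        R = np.einsum("ikm,imn->ikn", U, Vt)
        aligned = np.einsum("ilk,ikm->ilm", aligned, R)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        if consensus_projector is not None:
            new_consensus = consensus_projector(new_consensus)
        if with_scaling:
            cs = np.sqrt(np.sum(new_consensus**2))
            if cs > 1e-12:
                new_consensus /= cs
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    if consensus_projector is None:
        # canonical orientation (consensus principal axes, moment-fixed
        # signs) so the result is invariant to a global similarity
        # transform of the inputs; skipped when a projector pins the frame
        R = _principal_axes(consensus)
        aligned = aligned @ R
        consensus = consensus @ R
    return AlignedCohort(
        shapes=aligned.reshape(n, -1),
        consensus=consensus,
        centroid_size=sizes,
        with_scaling=with_scaling,
    )


def _check_involution(pairing: np.ndarray, n_landmarks: int) -> np.ndarray:
    pairing = np.asarray(pairing, dtype=int)
    if pairing.shape != (n_landmarks,) or not np.array_equal(
        pairing[pairing], np.arange(n_landmarks)
    ):
        raise ValueError("pairing map must be an involution over landmark indices")
    return pairing


def reflect(configs: np.ndarray, pairing: np.ndarray) -> np.ndarray:
    """Mirror across x=0 and relabel left/right landmarks."""
    out = configs * np.array([-1.0, 1.0, 1.0])
    return out[..., pairing, :]


def symmetrize(
    configurations: np.ndarray,
    pairing: np.ndarray,
    with_scaling: bool = True,
) -> tuple[AlignedCohort, np.ndarray]:
    """Extract the symmetric shape component of every individual.

    Reflected copies (x negated, landmarks relabeled by ``pairing``) are
    pooled with the originals in a single GPA; the symmetric component is the
    per-individual average of its aligned original and aligned reflection.
    The asymmetric component (their difference) is computed but discarded.

    Returns ``(aligned, symmetric)`` where ``aligned`` is the joint GPA fit
    restricted to the originals and ``symmetric`` is (n, n_landmarks, 3).
    """
    configs = np.asarray(configurations, dtype=float)
    n, n_landmarks, _ = configs.shape
    pairing = _check_involution(pairing, n_landmarks)
    mirrored = reflect(configs, pairing)
    # pinning the consensus onto the symmetric subspace makes the optimal
    # per-shape rotations commute with reflection, so the averaged component
    # is exactly mirror-symmetric
    projector = lambda c: 0.5 * (c + reflect(c, pairing))  # noqa: E731
    joint = gpa(
        np.vstack([configs, mirrored]),
        with_scaling=with_scaling,
        consensus_projector=projector,
    )
    both = joint.as_configurations()
    originals, reflections = both[:n], both[n:]
    symmetric = 0.5 * (originals + reflections)
    aligned = AlignedCohort(
        shapes=originals.reshape(n, -1),
        consensus=joint.consensus,
        centroid_size=joint.centroid_size[:n],
        with_scaling=with_scaling,
    )
    return aligned, symmetric


def build_covariate_design(
    covariates: pd.DataFrame,
    facial_size: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standard confounder design: sex, age, age^2, height, weight, facial
    size, camera, plus any ``ancestry*`` columns present."""
    design = pd.DataFrame(index=covariates.index)
    for col in ("sex", "age", "height", "weight", "camera"):
        if col in covariates:
            design[col] = pd.to_numeric(covariates[col])
        if col == "age" and "age" in covariates:
            design["age2"] = design["age"] ** 2
    if facial_size is not None:
        design["facial_size"] = np.asarray(facial_size, dtype=float)
    for col in covariates.columns:
        if col.startswith("ancestry"):
            design[col] = pd.to_numeric(covariates[col])
    return design


def plsr_residualize(
    responses: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
) -> tuple[np.ndarray, ConfounderModel]:
    """Residualize a response block on covariates with PLS regression.

    Residuals are ``Y - Y_hat + mean(Y)``: the confounder-driven variation is
    removed while the mean is restored, so residualized shapes stay
    interpretable as shapes. With full-rank components this is equivalent to
    multivariate OLS residualization.
    """
    Y = np.asarray(responses, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("covariate and response row counts differ")
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite covariate values")

    keep = X.std(axis=0) > 1e-12
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant covariate column(s): {dropped}")
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    y_mean = Y.mean(axis=0)
    if X.shape[1] == 0:
        pls = PLSRegression(n_components=1, scale=False)
        model = ConfounderModel(names, dropped, pls, y_mean, np.zeros(0))
        return Y.copy(), model

    rank = np.linalg.matrix_rank(X - X.mean(0))
    if n_components is None:
        n_components = X.shape[1]
    if n_components > rank:
        warnings.warn(
            f"reducing PLS components from {n_components} to design rank {rank}"
        )
        n_components = max(rank, 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    residuals = Y - pls.predict(X) + y_mean
    model = ConfounderModel(names, dropped, pls, y_mean, X.mean(axis=0))
    return residuals, model


def apply_confounder_model(
    model: ConfounderModel, responses: np.ndarray, covariates: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Residualize new data with a previously fitted model."""
    Y = np.asarray(responses, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        X = covariates[model.predictor_names].to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
    if len(model.predictor_names) == 0:
        return Y.copy()
    return Y - model.pls.predict(X) + model.response_mean


def project_to_reference(shapes: np.ndarray, space) -> np.ndarray:
    """PC scores of shapes in a reference :class:`SegmentShapeSpace`.

    ``scores = (shape - reference_mean) @ eigenvectors[:, :n_retained]``.
    """
    X = np.atleast_2d(np.asarray(shapes, dtype=float))
    if X.shape[1] != space.mean_shape.shape[0]:
        raise ValueError(
            f"shape dimension {X.shape[1]} does not match reference "
            f"{space.mean_shape.shape[0]}"
        )
    return (X - space.mean_shape) @ space.eigenvectors[:, : space.n_retained]
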