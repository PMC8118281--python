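"""Similarity measures, one-to-many sibling identification, and CMC curves.

Four similarity measures operate on per-segment PC-score vectors: Euclidean
distance (ED), Mahalanobis distance (MD, ED after dividing every score by
its PC standard deviation), Euclidean angle (EA) and Mahalanobis angle (MA,
the angle between sigma-normalized vectors). All are "lower is more
similar"; angles are radians in [0, pi], measured from the shape-space
origin (the cohort mean).

An identification experiment takes one sibling as the query, builds a
gallery of the designated true sibling plus all non-relatives, ranks the
gallery by similarity, and records the 1-based rank of the true sibling.
Ties receive the maximal (most pessimistic) competition rank. Performance is
summarized by cumulative match characteristic curves over rank-k%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "similarity",
    "fuse_segments",
    "build_gallery",
    "identify",
    "IdentificationResult",
    "run_identification",
    "CMCCurve",
    "cmc",
    "random_cmc_envelope",
    "gallery_size_resampling",
]

METRICS = ("ED", "MD", "EA", "MA")


def _angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 0 or nb <= 0:
        raise ValueError("undefined angle for zero-norm feature vector")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(c))


def similarity(
    a: np.ndarray, b: np.ndarray, metric: str, sigma: np.ndarray | None = None
) -> float:
    """Similarity value between two feature vectors (lower = more similar)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("feature vectors must have equal length")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric in ("MD", "MA"):
        if sigma is None:
            raise ValueError(f"{metric} requires per-PC standard deviations")
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        a, b = a / sigma, b / sigma
    if metric in ("ED", "MD"):
        return float(np.linalg.norm(a - b))
    return _angle(a, b)


def fuse_segments(
    features: dict[int, np.ndarray],
    sigmas: dict[int, np.ndarray] | None = None,
    segment_ids: list[int] | None = None,
) -> np.ndarray:
    """Feature-level fusion: concatenate per-segment scores in fixed order.

    For the Mahalanobis family pass ``sigmas`` so each segment's scores are
    normalized before concatenation; distance/angle are then computed on the
    fused vector with the plain Euclidean formulas.
    """
    if segment_ids is None:
        segment_ids = sorted(features)
    parts = []
    for sid in segment_ids:
        if sid not in features:
            raise ValueError(f"missing segment {sid} in feature set")
        v = np.asarray(features[sid], dtype=float)
        if sigmas is not None:
            s = np.asarray(sigmas[sid], dtype=float)
            if np.any(s <= 0):
                raise ValueError(f"non-positive sigma in segment {sid}")
            v = v / s
        parts.append(v)
    return np.concatenate(parts)


def build_gallery(
    query_id: str,
    sibling_id: str,
    individual_ids: list[str],
    family_ids: pd.Series | list[str],
) -> list[str]:
    """Gallery = designated true sibling + all individuals from other families.

    The query itself and any other members of the query's family are
    excluded.
    """
    fam = pd.Series(list(family_ids), index=list(individual_ids))
    if query_id not in fam.index or sibling_id not in fam.index:
        raise ValueError("query or sibling absent from cohort")
    qf = fam[query_id]
    if fam[sibling_id] != qf:
        raise ValueError("designated sibling is not in the query's family")
    gallery = [sibling_id]
    gallery += [i for i in fam.index if fam[i] != qf]
    return gallery


def identify(
    query: np.ndarray,
    gallery: dict[str, np.ndarray],
    sibling_id: str,
    metric: str,
    sigma: np.ndarray | None = None,
) -> tuple[int, float, bool]:
    """Rank the true sibling within a gallery.

    Returns ``(rank, similarity_value, tied)``. Ties on the similarity value
    are resolved pessimistically: the rank is the count of candidates at
    least as similar as the sibling (maximal competition rank).
    """
    if sibling_id not in gallery:
        raise ValueError("gallery must contain the true sibling")
    sims = {}
    for cid, feat in gallery.items():
        s = similarity(query, feat, metric, sigma)
        if not np.isfinite(s):
            raise ValueError(f"non-finite similarity for candidate {cid}")
        sims[cid] = s
    s_sib = sims[sibling_id]
    values = np.array(list(sims.values()))
    rank = int(np.sum(values <= s_sib))
    tied = int(np.sum(values == s_sib)) > 1
    return rank, s_sib, tied


@dataclass
class IdentificationResult:
    """Tidy table of one-to-many experiments plus the similarity pool."""

    experiments: pd.DataFrame  # query_id, sibling_id, gallery_size, rank, similarity, tied
    metric: str
    label: str  # segment id or 'fused'
    all_similarities: np.ndarray  # every query-to-candidate value (percentile pool)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)


def enumerate_pairs(individual_ids: list[str], family_ids) -> list[tuple[str, str]]:
    """All unique sibling pairs (families contribute C(size, 2) pairs)."""
    fam = pd.Series(list(family_ids), index=list(individual_ids))
    pairs = []
    for _, members in fam.groupby(fam):
        ids = list(members.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j]))
    return pairs


def run_identification(
    features: np.ndarray,
    individual_ids: list[str],
    family_ids,
    metric: str = "MA",
    sigma: np.ndarray | None = None,
    label: str = "1",
) -> IdentificationResult:
    """Run every one-to-many experiment for a family-structured cohort.

    Each unique sibling pair yields two experiments (either member as the
    query). ``features`` is (n, d) in the order of ``individual_ids``.
    """
    F = np.asarray(features, dtype=float)
    ids = list(individual_ids)
    index = {i: k for k, i in enumerate(ids)}
    fam = pd.Series(list(family_ids), index=ids)
    if metric in ("MD", "MA"):
        if sigma is None:
            raise ValueError(f"{metric} requires sigma")
        F = F / np.asarray(sigma, dtype=float)
        metric_eff = {"MD": "ED", "MA": "EA"}[metric]
    else:
        metric_eff = metric

    rows = []
    pool: list[np.ndarray] = []
    for a, b in enumerate_pairs(ids, fam):
        for query_id, sibling_id in ((a, b), (b, a)):
            gallery_ids = build_gallery(query_id, sibling_id, ids, fam)
            gidx = np.array([index[g] for g in gallery_ids])
            q = F[index[query_id]]
            G = F[gidx]
            if metric_eff == "ED":
                sims = np.linalg.norm(G - q, axis=1)
            else:
                nq = np.linalg.norm(q)
                ng = np.linalg.norm(G, axis=1)
                if nq <= 0 or np.any(ng <= 0):
                    raise ValueError("undefined angle for zero-norm feature vector")
                sims = np.arccos(np.clip(G @ q / (ng * nq), -1.0, 1.0))
            if not np.isfinite(sims).all():
                bad = gallery_ids[int(np.flatnonzero(~np.isfinite(sims))[0])]
                raise ValueError(f"non-finite similarity for candidate {bad}")
            s_sib = sims[0]  # sibling is first in the gallery
            rank = int(np.sum(sims <= s_sib))
            rows.append(
                {
                    "query_id": query_id,
                    "sibling_id": sibling_id,
                    "gallery_size": len(gallery_ids),
                    "rank": rank,
                    "similarity": s_sib,
                    "tied": bool(np.sum(sims == s_sib) > 1),
                }
            )
            pool.append(sims)
    if not rows:
        raise ValueError("no eligible sibling pairs (all families singletons?)")
    return IdentificationResult(
        experiments=pd.DataFrame(rows),
        metric=metric,
        label=label,
        all_similarities=np.concatenate(pool),
    )


@dataclass
class CMCCurve:
    k_pct: np.ndarray
    rate: np.ndarray

    def rate_at(self, k: float) -> float:
        return float(self.rate[np.searchsorted(self.k_pct, k)])


def cmc(result: IdentificationResult | pd.DataFrame, k_grid: np.ndarray | None = None) -> CMCCurve:
    """Cumulative rank-k% identification-rate curve.

    rate(k) = fraction of experiments with rank / gallery_size <= k / 100.
    """
    df = result.experiments if isinstance(result, IdentificationResult) else result
    if len(df) == 0:
        raise ValueError("no experiments")
    if k_grid is None:
        k_grid = np.arange(0.5, 100.5, 0.5)
    ratio = df["rank"].to_numpy() / df["gallery_size"].to_numpy()
    rate = np.array([(ratio <= k / 100.0).mean() for k in k_grid])
    return CMCCurve(k_pct=np.asarray(k_grid, dtype=float), rate=rate)


def random_cmc_envelope(
    n_experiments: int, k_grid: np.ndarray, confidence: float = 0.99
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise binomial envelope of the random-performance diagonal.

    Under random similarity the rank ratio is uniform, so rate(k) is a
    binomial proportion with success probability k/100.
    """
    from scipy.stats import binom

    alpha = 1 - confidence
    p = np.asarray(k_grid, dtype=float) / 100.0
    lo = binom.ppf(alpha / 2, n_experiments, p) / n_experiments
    hi = binom.ppf(1 - alpha / 2, n_experiments, p) / n_experiments
    return lo, hi


def gallery_size_resampling(
    features: np.ndarray,
    individual_ids: list[str],
    family_ids,
    sizes: list[int],
    n_repeats: int = 100,
    metric: str = "MA",
    sigma: np.ndarray | None = None,
    k_pct: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-k% identification rate as a function of gallery size.

    Non-relatives are subsampled to each target size (the true sibling is
    always kept); mean/min/max rates over repeats are reported. A target
    equal to the full gallery reproduces the unsubsampled experiment set.
    """
    rng = np.random.default_rng(seed)
    F = np.asarray(features, dtype=float)
    ids = list(individual_ids)
    index = {i: k for k, i in enumerate(ids)}
    fam = pd.Series(list(family_ids), index=ids)
    if metric in ("MD", "MA"):
        F = F / np.asarray(sigma, dtype=float)
        metric_eff = {"MD": "ED", "MA": "EA"}[metric]
    else:
        metric_eff = metric

    pairs = enumerate_pairs(ids, fam)
    out = []
    for size in sizes:
        if size < 2:
            raise ValueError("gallery size must be >= 2")
        rates = []
        for _ in range(n_repeats):
            hits = 0
            total = 0
            for a, b in pairs:
                for query_id, sibling_id in ((a, b), (b, a)):
                    full = build_gallery(query_id, sibling_id, ids, fam)
                    others = full[1:]
                    if size - 1 > len(others):
                        raise ValueError("requested size exceeds available gallery")
                    if size - 1 == len(others):
                        chosen = others
                    else:
                        chosen = list(
                            np.array(others)[rng.choice(len(others), size - 1, replace=False)]
                        )
                    gidx = np.array([index[g] for g in [sibling_id] + chosen])
                    q = F[index[query_id]]
                    G = F[gidx]
                    if metric_eff == "ED":
                        sims = np.linalg.norm(G - q, axis=1)
                    else:
                        sims = np.arccos(
                            np.clip(
                                G @ q / (np.linalg.norm(G, axis=1) * np.linalg.norm(q)),
                                -1.0,
                                1.0,
                            )
                        )
                    rank = int(np.sum(sims <= sims[0]))
                    hits += rank / len(gidx) <= k_pct / 100.0
                    total += 1
            rates.append(hits / total)
        rates = np.array(rates)
        out.append(
            {
                "gallery_size": size,
                "k_pct": k_pct,
                "mean_rate": rates.mean(),
                "min_rate": rates.min(),
                "max_rate": rates.max(),
            }
        )
    return pd.DataFrame(out)
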