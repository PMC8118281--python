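"""Sib-shared trait selection, scoring, and multiplicity accounting.

A sibling pair defines a trait in a segment when its matching was
near-perfect and symmetric: in both query directions the true sibling must
fall within the top rank fraction (default 1%) of the gallery AND the pair's
similarity value must sit in the lowest percentile (default 2.5) of all
query-to-candidate similarities in that segment. The trait vector is the
pairwise mean PC-score vector, anchored at the reference cohort mean; any
individual is scored by the cosine of the Mahalanobis angle between their
score vector and the trait vector, a magnitude-free value in [-1, 1]
('face' vs 'anti-face' direction).

Because segments overlap hierarchically and one family can contribute
several pairs, traits are correlated; the effective number of independent
traits Meff is estimated from the eigenvalues of the trait score correlation
matrix (integer-part indicator plus fractional part per eigenvalue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matching import IdentificationResult

__all__ = [
    "SibSharedTrait",
    "select_pairs",
    "derive_trait",
    "score_individuals",
    "score_matrix",
    "effective_trait_count",
    "meff_from_correlation",
    "phenotypic_correlation",
    "selection_bias_checks",
]


@dataclass
class SibSharedTrait:
    trait_id: int
    segment_id: int
    family_id: str
    sib1_id: str
    sib2_id: str
    vector: np.ndarray  # pair-mean PC scores in the segment reference space

    def __post_init__(self) -> None:
        if np.linalg.norm(self.vector) <= 0:
            raise ValueError("degenerate trait: zero vector")


def select_pairs(
    result: IdentificationResult,
    top_rank_fraction: float = 0.01,
    similarity_percentile: float = 2.5,
) -> list[tuple[str, str]]:
    """Pairs whose matching is symmetric, top-ranked, and low-similarity.

    Both directions of a pair must satisfy rank / gallery_size <=
    ``top_rank_fraction`` and have a similarity value within the lowest
    ``similarity_percentile`` of the segment's pooled query-to-candidate
    similarity distribution.
    """
    df = result.experiments
    cut = np.percentile(result.all_similarities, similarity_percentile)
    ok = (df["rank"] / df["gallery_size"] <= top_rank_fraction) & (
        df["similarity"] <= cut
    )
    passing = set(
        zip(df.loc[ok, "query_id"], df.loc[ok, "sibling_id"])
    )
    selected = []
    seen = set()
    for q, s in passing:
        key = tuple(sorted((q, s)))
        if key in seen:
            continue
        seen.add(key)
        if (s, q) in passing:  # symmetric matching in the reverse direction
            selected.append(key)
    return sorted(selected)


def derive_trait(
    trait_id: int,
    segment_id: int,
    family_id: str,
    sib1_id: str,
    sib2_id: str,
    scores1: np.ndarray,
    scores2: np.ndarray,
) -> SibSharedTrait:
    """Trait vector = mean of the two siblings' PC-score vectors."""
    t = 0.5 * (np.asarray(scores1, dtype=float) + np.asarray(scores2, dtype=float))
    return SibSharedTrait(trait_id, segment_id, family_id, sib1_id, sib2_id, t)


def render_trait_shape(trait: SibSharedTrait, space) -> np.ndarray:
    """Landmark-space rendering mean + E t of a trait, for visualization."""
    shape = space.mean_shape + space.eigenvectors[:, : space.n_retained] @ trait.vector
    return shape.reshape(-1, 3)


def score_individuals(
    trait: SibSharedTrait | np.ndarray,
    cohort_scores: np.ndarray,
    sigma: np.ndarray,
) -> np.ndarray:
    """Cosine of the Mahalanobis angle between a trait and each individual.

    ``score_i = <t/sigma, x_i/sigma> / (||t/sigma|| ||x_i/sigma||)``, in
    [-1, 1]; invariant to positive rescaling of either vector. Individuals
    whose normalized score vector has zero norm get NaN and a warning.
    """
    t = trait.vector if isinstance(trait, SibSharedTrait) else np.asarray(trait, float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    tn = t / sigma
    nt = np.linalg.norm(tn)
    if nt <= 0:
        raise ValueError("degenerate trait: zero vector")
    X = np.atleast_2d(np.asarray(cohort_scores, dtype=float)) / sigma
    nx = np.linalg.norm(X, axis=1)
    out = np.full(X.shape[0], np.nan)
    good = nx > 0
    if not good.all():
        warnings.warn(f"{int((~good).sum())} individual(s) with zero-norm scores; NaN")
    out[good] = np.clip(X[good] @ tn / (nx[good] * nt), -1.0, 1.0)
    return out


def score_matrix(
    traits: list[SibSharedTrait],
    segment_scores: dict[int, np.ndarray],
    segment_sigmas: dict[int, np.ndarray],
) -> pd.DataFrame:
    """Individuals x traits matrix of MA-cosine scores."""
    cols = {}
    for trait in traits:
        cols[trait.trait_id] = score_individuals(
            trait, segment_scores[trait.segment_id], segment_sigmas[trait.segment_id]
        )
    return pd.DataFrame(cols)


def meff_from_correlation(corr: np.ndarray) -> tuple[float, np.ndarray]:
    """Meff from a trait correlation matrix.

    Meff = sum_i [I(lambda_i >= 1) + (lambda_i - floor(lambda_i))] over the
    eigenvalues of the Pearson correlation matrix; satisfies 1 <= Meff <= m.
    """
    lam = np.linalg.eigvalsh(np.asarray(corr, dtype=float))
    if (lam < -1e-8).any():
        warnings.warn("correlation matrix not PSD; clipping negative eigenvalues")
    lam = np.clip(lam, 0, None)[::-1]
    # snap eigenvalues to exact integers before floor(): otherwise a value
    # like 2 - 1e-15 contributes a spurious fractional part of ~1
    snapped = np.where(np.abs(lam - np.round(lam)) < 1e-9, np.round(lam), lam)
    meff = float(np.sum((snapped >= 1).astype(float) + (snapped - np.floor(snapped))))
    return meff, lam


def effective_trait_count(scores: pd.DataFrame | np.ndarray) -> tuple[float, np.ndarray]:
    """Effective number of independent traits from a trait score matrix."""
    X = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 individuals and >= 2 traits")
    return meff_from_correlation(np.corrcoef(X, rowvar=False))


def phenotypic_correlation(
    scores: pd.DataFrame,
    traits: list[SibSharedTrait] | None = None,
    mask_same_family: bool = False,
) -> pd.DataFrame:
    """Pearson correlation among trait scores across cohort individuals.

    With ``mask_same_family`` set, entries for trait pairs derived from the
    same family are replaced by NaN (reporting convention).
    """
    X = scores.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 individuals")
    sd = X.std(axis=0)
    if (sd <= 0).any():
        warnings.warn("constant score column(s); correlations undefined there")
    corr = pd.DataFrame(
        np.corrcoef(X, rowvar=False), index=scores.columns, columns=scores.columns
    )
    if mask_same_family and traits is not None:
        fam = {t.trait_id: t.family_id for t in traits}
        for a in corr.index:
            for b in corr.columns:
                if a != b and fam.get(a) == fam.get(b):
                    corr.loc[a, b] = np.nan
    return corr


def selection_bias_checks(
    pair_table: pd.DataFrame,
) -> dict[str, float | None]:
    """Check that trait selection is blind to sex composition and age gap.

    ``pair_table`` needs columns ``selected`` (bool), ``same_sex`` (bool) and
    ``age_gap`` (years). Returns a Fisher exact p-value for the 2x2 table of
    same-/different-sex composition in selected vs non-selected pairs, and a
    two-sample t-test p-value for the age gaps; None when a test is
    degenerate (empty group).
    """
    sel = pair_table[pair_table["selected"]]
    non = pair_table[~pair_table["selected"]]
    out: dict[str, float | None] = {"fisher_p": None, "ttest_p": None}
    if len(sel) and len(non):
        table = [
            [int(sel["same_sex"].sum()), int((~sel["same_sex"]).sum())],
            [int(non["same_sex"].sum()), int((~non["same_sex"]).sum())],
        ]
        out["fisher_p"] = float(stats.fisher_exact(table)[1])
        if sel["age_gap"].std() > 0 or non["age_gap"].std() > 0:
            out["ttest_p"] = float(
                stats.ttest_ind(sel["age_gap"], non["age_gap"], equal_var=False).pvalue
            )
    return out
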