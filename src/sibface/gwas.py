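"""Univariate GWAS of trait scores with IVW meta-analysis and peak grouping.

Genotype dosages are first residualized on the confounder design with the
same PLSR routine used for shapes (X-chromosome male genotypes are recoded
0/2 beforehand so they share the 0..2 scale of female 0/1/2 calls). Each
(SNP, trait) association is a simple additive linear regression of the
trait score on the residualized dosage; cohorts are combined by
fixed-effects inverse-variance weighting of effect estimates. Significant
SNPs are grouped into peaks with a greedy lead-first rule on a 1-Mb window;
lead SNPs' explained variance is reported per SNP (squared correlation) and
jointly (multiple-regression R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import plsr_residualize

__all__ = [
    "recode_x_males",
    "residualize_genotypes",
    "regress",
    "regress_many",
    "ivw_meta",
    "significance_thresholds",
    "group_peaks",
    "variance_explained",
    "Peak",
]

GENOME_WIDE_P = 5e-8


def recode_x_males(
    dosages: np.ndarray, chrom: np.ndarray, is_male: np.ndarray
) -> np.ndarray:
    """Recode male X-chromosome dosages 0/1 -> 0/2 (additive scale match)."""
    out = np.array(dosages, dtype=float, copy=True)
    x_cols = np.flatnonzero(np.asarray(chrom).astype(str) == "X")
    males = np.flatnonzero(np.asarray(is_male, dtype=bool))
    if x_cols.size and males.size:
        out[np.ix_(males, x_cols)] *= 2.0
    return out


def residualize_genotypes(
    dosages: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    chrom: np.ndarray | None = None,
    is_male: np.ndarray | None = None,
    n_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PLSR-residualize dosage columns on the confounder design.

    Returns ``(residualized, tested)`` where ``tested`` flags polymorphic
    SNPs; monomorphic columns are kept in place but flagged out.
    """
    G = np.asarray(dosages, dtype=float)
    if chrom is not None and is_male is not None:
        G = recode_x_males(G, chrom, is_male)
    tested = G.std(axis=0) > 0
    if not tested.all():
        warnings.warn(f"excluding {int((~tested).sum())} monomorphic SNP(s)")
    resid = G.copy()
    if tested.any():
        resid[:, tested], _ = plsr_residualize(G[:, tested], covariates, n_components)
    return resid, tested


def regress(y: np.ndarray, x: np.ndarray) -> dict:
    """Additive simple linear regression of a trait score on one dosage.

    Returns beta, se, t, p (two-sided on n-2 df), n.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = y.size
    if n < 10:
        raise ValueError("need n >= 10 complete observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        raise ValueError("zero-variance predictor")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    resid = y - y.mean() - beta * (x - x.mean())
    se = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    if se == 0:
        se = np.finfo(float).tiny
    t = beta / se
    p = max(2 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny)
    return {"beta": beta, "se": se, "t": t, "p": p, "n": n}


def regress_many(
    scores: np.ndarray | pd.DataFrame,
    dosages: np.ndarray,
    snp_info: pd.DataFrame | None = None,
    cohort: str = "cohort",
    tested: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized per-(SNP, trait) regressions.

    ``scores`` is (n, n_traits), ``dosages`` (n, n_snps); returns a tidy
    frame with one row per tested (snp, trait). Closed-form OLS:
    beta = cov(x, y) / var(x), SE = sqrt(RSS / (n-2) / Sxx).
    """
    Y = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    trait_ids = (
        list(scores.columns) if isinstance(scores, pd.DataFrame) else list(range(Y.shape[1]))
    )
    X = np.asarray(dosages, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need n >= 10")
    if tested is None:
        tested = X.std(axis=0) > 0
    cols = np.flatnonzero(tested)
    Xc = X[:, cols] - X[:, cols].mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.sum(Xc**2, axis=0)  # (m,)
    sxy = Xc.T @ Yc  # (m, t)
    beta = sxy / sxx[:, None]
    syy = np.sum(Yc**2, axis=0)  # (t,)
    rss = syy[None, :] - beta * sxy
    rss = np.clip(rss, 0, None)
    se = np.sqrt(rss / (n - 2) / sxx[:, None])
    se = np.where(se > 0, se, np.finfo(float).tiny)
    tstat = beta / se
    p = np.maximum(2 * stats.t.sf(np.abs(tstat), n - 2), np.finfo(float).tiny)

    m, t = beta.shape
    out = pd.DataFrame(
        {
            "snp_index": np.repeat(cols, t),
            "trait_id": np.tile(trait_ids, m),
            "beta": beta.ravel(),
            "se": se.ravel(),
            "t": tstat.ravel(),
            "p": p.ravel(),
            "n": n,
            "cohort": cohort,
        }
    )
    if snp_info is not None:
        info = snp_info.iloc[out["snp_index"]].reset_index(drop=True)
        for col in ("snp_id", "chrom", "pos"):
            out[col] = info[col].to_numpy()
    return out


def ivw_meta(results: pd.DataFrame, method: str = "ivw") -> pd.DataFrame:
    """Fixed-effects meta-analysis across cohorts per (SNP, trait).

    ``method='ivw'``: weights 1/SE^2, beta_meta = sum(w b)/sum(w), SE_meta =
    1/sqrt(sum w). ``method='stouffer'``: sample-size-weighted z (sensitivity
    option; no combined beta scale).
    """
    if method not in ("ivw", "stouffer"):
        raise ValueError("method must be 'ivw' or 'stouffer'")
    keys = [k for k in ("snp_index", "snp_id", "chrom", "pos") if k in results] + ["trait_id"]
    rows = []
    for key, grp in results.groupby(keys, sort=False):
        if method == "ivw":
            w = 1.0 / grp["se"] ** 2
            beta = float(np.sum(w * grp["beta"]) / np.sum(w))
            se = float(1.0 / np.sqrt(np.sum(w)))
            z = beta / se
        else:
            zi = np.sign(grp["beta"]) * stats.norm.isf(grp["p"] / 2)
            w = np.sqrt(grp["n"])
            z = float(np.sum(w * zi) / np.sqrt(np.sum(w**2)))
            beta, se = np.nan, np.nan
        p = max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            beta_meta=beta,
            se_meta=se,
            z=z,
            p_meta=p,
            n_cohorts=len(grp),
            n_total=int(grp["n"].sum()),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def significance_thresholds(meff: float) -> tuple[float, float]:
    """(genome-wide, study-wide) p-value thresholds.

    The study-wide threshold divides the conventional genome-wide 5e-8 by
    the effective number of independent traits.
    """
    if meff < 1:
        raise ValueError("Meff must be >= 1")
    return GENOME_WIDE_P, GENOME_WIDE_P / meff


@dataclass
class Peak:
    peak_id: int
    chrom: str
    lead_snp: str
    lead_pos: int
    best_p: float
    best_trait: object
    member_snps: list[str] = field(default_factory=list)

    @property
    def window(self) -> tuple[int, int]:
        return self.lead_pos, self.lead_pos


def group_peaks(
    meta: pd.DataFrame,
    threshold: float = GENOME_WIDE_P,
    window: int = 1_000_000,
    merge_gap: int | None = None,
) -> list[Peak]:
    """Greedy lead-first grouping of significant SNPs into genomic peaks.

    Repeatedly take the most significant unassigned SNP (any trait) as a
    lead and absorb all significant SNPs on the same chromosome within
    +/- window/2 of it. ``merge_gap`` optionally merges adjacent peaks whose
    leads are closer than the gap (approximation of manual LD-based merges);
    off by default. The result is independent of input row order.
    """
    p_col = "p_meta" if "p_meta" in meta else "p"
    sig = meta[meta[p_col] < threshold]
    if sig.empty:
        return []
    # best p per SNP across traits
    best = (
        sig.sort_values([p_col, "snp_id", "trait_id"], kind="stable")
        .groupby("snp_id", as_index=False, sort=False)
        .first()
        .sort_values([p_col, "chrom", "pos", "snp_id"], kind="stable")
        .reset_index(drop=True)
    )
    unassigned = best.copy()
    peaks: list[Peak] = []
    while not unassigned.empty:
        lead = unassigned.iloc[0]
        same = unassigned[
            (unassigned["chrom"] == lead["chrom"])
            & (np.abs(unassigned["pos"] - lead["pos"]) <= window // 2)
        ]
        peaks.append(
            Peak(
                peak_id=len(peaks) + 1,
                chrom=str(lead["chrom"]),
                lead_snp=str(lead["snp_id"]),
                lead_pos=int(lead["pos"]),
                best_p=float(lead[p_col]),
                best_trait=lead["trait_id"],
                member_snps=list(same["snp_id"]),
            )
        )
        unassigned = unassigned.drop(same.index)
    if merge_gap:
        peaks = _merge_adjacent(peaks, merge_gap)
    return peaks


def _merge_adjacent(peaks: list[Peak], gap: int) -> list[Peak]:
    by_chrom: dict[str, list[Peak]] = {}
    for pk in sorted(peaks, key=lambda p: (p.chrom, p.lead_pos)):
        by_chrom.setdefault(pk.chrom, []).append(pk)
    merged: list[Peak] = []
    for chrom_peaks in by_chrom.values():
        current = chrom_peaks[0]
        for nxt in chrom_peaks[1:]:
            if nxt.lead_pos - current.lead_pos <= gap:
                keep, other = (
                    (current, nxt) if current.best_p <= nxt.best_p else (nxt, current)
                )
                keep.member_snps = sorted(set(keep.member_snps) | set(other.member_snps))
                current = keep
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda p: p.best_p)
    for i, pk in enumerate(merged, 1):
        pk.peak_id = i
    return merged


def variance_explained(
    score: np.ndarray, lead_dosages: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-SNP r^2 and joint multiple-regression R^2 for a trait score."""
    y = np.asarray(score, dtype=float)
    X = np.atleast_2d(np.asarray(lead_dosages, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    yc = y - y.mean()
    per_snp = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        xc = X[:, j] - X[:, j].mean()
        denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        per_snp[j] = (np.sum(xc * yc) / denom) ** 2 if denom > 0 else 0.0
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        warnings.warn("collinear dosage set; joint R^2 from pseudo-inverse fit")
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    fitted = Xc @ coef
    total = np.sum(yc**2)
    joint = float(np.sum(fitted**2) / total) if total > 0 else 0.0
    return per_snp, joint
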