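"""Synthetic family-structured landmark and genotype cohorts.

Generates everything the downstream pipeline consumes with known ground
truth: a bilaterally symmetric landmark template, pedigrees with Mendelian
genotype transmission, latent additive-genetic facial factors realized as
smooth displacement fields, covariate effects (including a camera batch
effect), and isotropic landmark noise.

The generative model for one face is

    X_i = T + sum_k u_ik * s * B_k + covariate effects + eps_i

where ``T`` is the template, ``B_k`` are unit-norm Gaussian-RBF displacement
fields, ``s`` is the per-factor displacement scale in mm, and the latent
factor values ``u_ik`` split into an additive-genetic part (shared by
siblings with expected correlation 0.5, partly driven by causal SNPs) and a
unique environmental part according to ``genetic_variance_fraction``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_template",
    "simulate_genotypes",
    "simulate_faces",
    "simulate_study",
]

# Family-size composition of a 424-child, 194-family sibling cohort with 273
# unique pairs (sizes 2-5).
DEFAULT_FAMILY_SIZE_WEIGHTS = {2: 163 / 194, 3: 28 / 194, 4: 1 / 194, 5: 2 / 194}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    All stochastic structure is controlled here; nothing is hard-coded in the
    generator functions.
    """

    n_landmarks: int = 100
    n_families: int = 194
    family_size_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZE_WEIGHTS)
    )
    n_unrelated: int = 1000
    n_snps: int = 1000
    n_causal: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_latent_factors: int = 10
    genetic_variance_fraction: float = 0.6
    causal_variance_fraction: float = 0.5
    factor_scale: float = 2.0
    covariate_effect_scale: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmarks < 8 or self.n_landmarks % 2:
            raise ValueError("n_landmarks must be even and >= 8")
        for name in ("n_families", "n_unrelated", "n_snps", "n_latent_factors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("n_causal must lie in [0, n_snps]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.genetic_variance_fraction <= 1:
            raise ValueError("genetic_variance_fraction must lie in [0, 1]")
        if not 0 <= self.causal_variance_fraction <= 1:
            raise ValueError("causal_variance_fraction must lie in [0, 1]")
        if self.covariate_effect_scale < 0 or self.noise_sd < 0:
            raise ValueError("effect scales must be non-negative")
        sizes = sorted(self.family_size_weights)
        if not sizes or sizes[0] < 2 or sizes[-1] > 5:
            raise ValueError("family sizes must lie in 2..5")
        if any(w < 0 for w in self.family_size_weights.values()):
            raise ValueError("family_size_weights must be non-negative")


@dataclass
class SyntheticCohort:
    """One simulated cohort (family-structured or unrelated)."""

    configurations: np.ndarray  # (n, n_landmarks, 3)
    individual_ids: list[str]
    covariates: pd.DataFrame  # sex, age, height, weight, camera
    family_id: pd.Series | None  # None for the unrelated cohort
    genotypes: np.ndarray  # (n, n_snps) dosages in {0,1,2}
    snp_info: pd.DataFrame  # chrom, pos, ref, alt, maf
    truth: dict

    @property
    def n_individuals(self) -> int:
        return self.configurations.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.configurations.shape[1]


def generate_template(n_landmarks: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample a bilaterally symmetric template on an ellipsoid-like surface.

    Returns ``(template, pairing)`` where ``template`` is (n_landmarks, 3)
    mirrored across the x=0 plane and ``pairing`` is an involutive
    permutation mapping each landmark to its mirror partner.
    """
    if n_landmarks < 8 or n_landmarks % 2:
        raise ValueError("n_landmarks must be even and >= 8")
    rng = np.random.default_rng(seed)
    half = n_landmarks // 2
    # Quasi-uniform directions on the half-sphere x > 0, pushed onto a
    # face-like ellipsoid (wider than tall, shallow in depth).
    phi = rng.uniform(0, np.pi, size=half)  # polar
    theta = rng.uniform(-np.pi / 2, np.pi / 2, size=half)  # keep x >= 0
    x = np.cos(theta) * np.sin(phi)
    y = np.sin(theta) * np.sin(phi)
    z = np.cos(phi)
    right = np.column_stack([70.0 * x + 1e-3, 90.0 * y, 55.0 * z])
    left = right * np.array([-1.0, 1.0, 1.0])
    template = np.vstack([right, left])
    pairing = np.concatenate([np.arange(half, n_landmarks), np.arange(0, half)])
    return template, pairing


def _sample_family_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.array(sorted(config.family_size_weights))
    probs = np.array([config.family_size_weights[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(sizes, size=config.n_families, p=probs)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Simulate founder and sibling genotypes.

    Unrelated individuals and (unobserved) parents are binomial draws at the
    per-SNP MAF; siblings receive one allele from each parent by Mendelian
    transmission, giving an expected sibling dosage correlation of 0.5.

    Returns ``(dosages, pedigree, snp_info)``. ``pedigree`` has one row per
    observed individual with columns ``individual_id``, ``family_id`` (empty
    string for unrelated), ``role`` ('sib' or 'unrelated').
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    m = config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    chrom = np.where(np.arange(m) < m // 23 + 1, "X", ((np.arange(m) % 22) + 1).astype(str))
    # deterministic sorted positions per chromosome
    snp_info = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(m)],
            "chrom": chrom,
            "pos": np.zeros(m, dtype=int),
            "ref": "A",
            "alt": "G",
            "maf": maf,
        }
    )
    for c, idx in snp_info.groupby("chrom", sort=False).groups.items():
        k = len(idx)
        pos = np.unique(rng.integers(1, 250_000_000, size=k))
        while pos.size < k:  # rare collision top-up
            pos = np.unique(np.concatenate([pos, rng.integers(1, 250_000_000, size=k - pos.size)]))
        snp_info.loc[idx, "pos"] = np.sort(pos)

    sizes = _sample_family_sizes(config, rng)
    rows: list[dict] = []
    blocks: list[np.ndarray] = []
    for f, size in enumerate(sizes):
        parents = rng.binomial(2, maf, size=(2, m))
        # child allele from parent: Bernoulli(parent_dosage / 2) per SNP
        kids = np.empty((size, m), dtype=np.int8)
        for s in range(size):
            a1 = rng.random(m) < parents[0] / 2.0
            a2 = rng.random(m) < parents[1] / 2.0
            kids[s] = a1.astype(np.int8) + a2.astype(np.int8)
        blocks.append(kids)
        for s in range(size):
            rows.append(
                {"individual_id": f"fam{f}_sib{s}", "family_id": f"fam{f}", "role": "sib"}
            )
    founders = rng.binomial(2, maf, size=(config.n_unrelated, m)).astype(np.int8)
    blocks.append(founders)
    for i in range(config.n_unrelated):
        rows.append({"individual_id": f"unrel{i}", "family_id": "", "role": "unrelated"})
    dosages = np.vstack(blocks)
    pedigree = pd.DataFrame(rows)
    return dosages, pedigree, snp_info


def _rbf_fields(
    template: np.ndarray,
    pairing: np.ndarray,
    n_fields: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-norm, bilaterally symmetric Gaussian-RBF displacement fields."""
    n = template.shape[0]
    diameter = np.linalg.norm(template.max(0) - template.min(0))
    h = 0.3 * diameter
    centers = template[rng.integers(0, n, size=n_fields)]
    fields = np.empty((n_fields, n, 3))
    reflect = np.array([-1.0, 1.0, 1.0])
    for k in range(n_fields):
        w = np.exp(-np.sum((template - centers[k]) ** 2, axis=1) / (2 * h * h))
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        B = w[:, None] * d[None, :]
        # symmetrize so the effect survives extraction of the symmetric
        # shape component downstream
        B = 0.5 * (B + (B * reflect)[pairing])
        norm = np.linalg.norm(B)
        if norm < 1e-12:  # pragma: no cover - pathological center draw
            B = np.zeros_like(B)
            B[0, 1] = 1.0
            norm = 1.0
        fields[k] = B / norm
    return fields


def _latent_factors(
    config: SimulationConfig,
    pedigree: pd.DataFrame,
    dosages: np.ndarray,
    snp_info: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-individual latent factor values u (n, K) and genetic part a.

    a = sqrt(c)*snp_score + sqrt(1-c)*polygenic, both unit-variance with
    sibling correlation 0.5; u = sqrt(g)*a + sqrt(1-g)*e.
    """
    n = len(pedigree)
    K = config.n_latent_factors
    g = config.genetic_variance_fraction
    c = config.causal_variance_fraction if config.n_causal > 0 else 0.0

    # polygenic part: family midpoint + segregation; unrelated are iid N(0,1)
    poly = np.empty((n, K))
    for _, idx in pedigree.groupby("family_id", sort=False).groups.items():
        idx = np.asarray(idx)
        fam = pedigree.loc[idx[0], "family_id"]
        if fam == "":
            poly[idx] = rng.standard_normal((len(idx), K))
        else:
            mid = rng.standard_normal(K) * np.sqrt(0.5)
            poly[idx] = mid + rng.standard_normal((len(idx), K)) * np.sqrt(0.5)

    causal_idx = np.array([], dtype=int)
    betas = np.zeros((0, K))
    snp_score = np.zeros((n, K))
    if config.n_causal > 0:
        # autosomal causal SNPs, split round-robin across factors
        auto = np.flatnonzero(snp_info["chrom"].to_numpy() != "X")
        causal_idx = rng.choice(auto, size=config.n_causal, replace=False)
        maf = snp_info["maf"].to_numpy()[causal_idx]
        z = (dosages[:, causal_idx] - 2 * maf) / np.sqrt(2 * maf * (1 - maf))
        betas = np.zeros((config.n_causal, K))
        for j in range(config.n_causal):
            k = j % K
            betas[j, k] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        raw = z @ betas
        scale = np.sqrt(np.sum(betas**2, axis=0))
        scale[scale == 0] = 1.0
        snp_score = raw / scale

    a = np.sqrt(c) * snp_score + np.sqrt(1 - c) * poly
    e = rng.standard_normal((n, K))
    u = np.sqrt(g) * a + np.sqrt(1 - g) * e
    truth = {
        "causal_snp_indices": causal_idx.tolist(),
        "causal_betas": betas.tolist(),
        "genetic_values": a,
        "latent_values": u,
    }
    return u, a, truth


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),  # 0 female, 1 male
            "age": rng.uniform(5, 15, size=n),
            "height": rng.normal(140, 15, size=n),
            "weight": rng.normal(38, 8, size=n),
            "camera": rng.integers(0, 2, size=n),  # 2-level batch label
        }
    )


def simulate_faces(
    template: np.ndarray,
    pairing: np.ndarray,
    dosages: np.ndarray,
    pedigree: pd.DataFrame,
    snp_info: pd.DataFrame,
    config: SimulationConfig,
) -> SyntheticCohort:
    """Realize landmark configurations from the latent-factor face model."""
    if template.shape[0] != config.n_landmarks:
        raise ValueError("template landmark count does not match config")
    if dosages.shape[0] != len(pedigree):
        raise ValueError("dosage rows do not match pedigree")
    seq = np.random.SeedSequence([config.seed, 23])
    rng_fields, rng_factors, rng_cov, rng_noise = (
        np.random.default_rng(s) for s in seq.spawn(4)
    )
    n = len(pedigree)
    fields = _rbf_fields(template, pairing, config.n_latent_factors, rng_fields)
    u, a, truth = _latent_factors(config, pedigree, dosages, snp_info, rng_factors)

    covariates = _covariates(n, rng_cov)
    cov_fields = _rbf_fields(template, pairing, covariates.shape[1], rng_cov)
    C = covariates.to_numpy(dtype=float)
    C = (C - C.mean(0)) / np.where(C.std(0) > 0, C.std(0), 1.0)

    faces = np.broadcast_to(template, (n, *template.shape)).copy()
    faces += np.einsum("ik,klc->ilc", u * config.factor_scale, fields)
    faces += np.einsum("ik,klc->ilc", C * config.covariate_effect_scale, cov_fields)
    faces += rng_noise.standard_normal(faces.shape) * config.noise_sd

    fam = pedigree["family_id"].reset_index(drop=True)
    family_id = None if (fam == "").all() else fam
    truth = dict(
        truth,
        pairing=pairing.tolist(),
        factor_fields=fields,
        covariate_fields=cov_fields,
        factor_scale=config.factor_scale,
    )
    return SyntheticCohort(
        configurations=faces,
        individual_ids=pedigree["individual_id"].tolist(),
        covariates=covariates,
        family_id=family_id,
        genotypes=dosages,
        snp_info=snp_info,
        truth=truth,
    )


def simulate_study(config: SimulationConfig) -> dict:
    """Simulate the full two-cohort study design.

    Returns a dict with the shared ``template`` and ``pairing``, a
    family-structured ``sib`` cohort (no genotypes used downstream) and an
    unrelated ``reference`` cohort (defines segmentation/shape spaces and is
    the GWAS cohort). Both cohorts share the same displacement fields and
    causal architecture so that genotype-phenotype links are consistent
    between the matching and association stages.
    """
    template, pairing = generate_template(config.n_landmarks, config.seed)
    dosages, pedigree, snp_info = simulate_genotypes(config)
    cohort = simulate_faces(template, pairing, dosages, pedigree, snp_info, config)

    sib_mask = (pedigree["role"] == "sib").to_numpy()
    ref_mask = ~sib_mask

    def _subset(mask: np.ndarray) -> SyntheticCohort:
        fam = pedigree.loc[mask, "family_id"].reset_index(drop=True)
        truth = dict(cohort.truth)
        truth["genetic_values"] = cohort.truth["genetic_values"][mask]
        truth["latent_values"] = cohort.truth["latent_values"][mask]
        return SyntheticCohort(
            configurations=cohort.configurations[mask],
            individual_ids=[i for i, m in zip(cohort.individual_ids, mask) if m],
            covariates=cohort.covariates.loc[mask].reset_index(drop=True),
            family_id=fam if (fam != "").any() else None,
            genotypes=cohort.genotypes[mask],
            snp_info=snp_info,
            truth=truth,
        )

    return {
        "template": template,
        "pairing": pairing,
        "sib": _subset(sib_mask),
        "reference": _subset(ref_mask),
        "config": config,
    }
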