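"""End-to-end driver: simulate -> preprocess -> segment -> match -> traits
-> score -> gwas.

Every stage reads/writes plain files so stages can be re-run or swapped for
real data; a JSON manifest records per-stage outputs, content hashes, and
bookkeeping counts. All randomness flows from the seeds in
:class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sfio
from . import gwas as sfgwas
from .matching import cmc, run_identification
from .preprocess import build_covariate_design, gpa, plsr_residualize, project_to_reference, symmetrize
from .segmentation import (
    align_to_segment,
    build_landmark_similarity,
    build_segment_space,
    hierarchical_spectral_bisect,
)
from .synthetic import SimulationConfig, simulate_study
from .traits import (
    derive_trait,
    effective_trait_count,
    score_matrix,
    select_pairs,
    selection_bias_checks,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters for every pipeline stage."""

    outdir: str = "sibface_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    depth: int = 5
    pa_permutations: int = 100
    pa_percentile: float = 95.0
    metric: str = "MA"
    top_rank_fraction: float = 0.01
    similarity_percentile: float = 2.5
    grouping_window: int = 1_000_000
    genome_wide_p: float = 5e-8
    n_meta_cohorts: int = 2
    plsr_components: int | None = None
    segment_seed: int = 0
    match_segments: str = "all"  # 'all', 'full', or comma-separated ids

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["simulation"]["family_size_weights"] = {
            int(k): float(v) for k, v in payload["simulation"]["family_size_weights"].items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        sim = payload.pop("simulation", {})
        if "family_size_weights" in sim:
            sim["family_size_weights"] = {int(k): float(v) for k, v in sim["family_size_weights"].items()}
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        return cls(simulation=SimulationConfig(**sim), **payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, outputs: list[Path], **counts) -> None:
        self.stages[stage] = {
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
            "counts": counts,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.stages, indent=1))
        return path


def _adjust_cohort(cohort, pairing, plsr_components):
    """Symmetrize and PLSR-adjust one cohort; returns (configs, sizes)."""
    aligned, symmetric = symmetrize(cohort.configurations, pairing)
    design = build_covariate_design(cohort.covariates, facial_size=aligned.centroid_size)
    flat = symmetric.reshape(len(symmetric), -1)
    adjusted, _ = plsr_residualize(flat, design, n_components=plsr_components)
    return adjusted.reshape(symmetric.shape), aligned.centroid_size, design


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ("simulate", "preprocess", "segment", "match", "traits", "gwas")) -> dict:
    """Execute the pipeline; returns a dict with the manifest path and the
    in-memory results of the last stages."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    config.to_yaml(out / "config.yaml")
    results: dict = {"outdir": out}

    study = simulate_study(config.simulation)
    if "simulate" in stages:
        sib, ref = study["sib"], study["reference"]
        files = []
        for name, cohort in (("sib", sib), ("reference", ref)):
            lm = out / f"{name}_landmarks.tsv"
            cov = out / f"{name}_covariates.tsv"
            sfio.write_landmark_table(lm, cohort.configurations, cohort.individual_ids)
            cov_df = cohort.covariates.copy()
            if cohort.family_id is not None:
                cov_df["family_id"] = cohort.family_id.to_numpy()
            sfio.write_covariates(cov, cov_df, cohort.individual_ids)
            files += [lm, cov]
        vcf = out / "reference_genotypes.vcf"
        sfio.write_vcf(vcf, ref.genotypes, ref.snp_info, ref.individual_ids)
        truth = out / "truth.json"
        truth.write_text(
            json.dumps(
                {
                    "causal_snp_indices": study["sib"].truth["causal_snp_indices"],
                    "causal_betas": study["sib"].truth["causal_betas"],
                    "pairing": study["pairing"].tolist(),
                },
                indent=1,
            )
        )
        files += [vcf, truth]
        manifest.record(
            "simulate",
            files,
            n_sib=sib.n_individuals,
            n_reference=ref.n_individuals,
            n_snps=ref.genotypes.shape[1],
        )
    if not {"preprocess", "segment", "match", "traits", "gwas"} & set(stages):
        results["manifest"] = manifest.write()
        return results

    pairing = study["pairing"]
    sib, ref = study["sib"], study["reference"]
    ref_adj, ref_size, ref_design = _adjust_cohort(ref, pairing, config.plsr_components)
    sib_adj, sib_size, _ = _adjust_cohort(sib, pairing, config.plsr_components)
    if "preprocess" in stages:
        files = []
        for name, adj, ids in (("reference", ref_adj, ref.individual_ids), ("sib", sib_adj, sib.individual_ids)):
            p = out / f"{name}_symmetric_adjusted.tsv"
            sfio.write_landmark_table(p, adj, ids)
            files.append(p)
        manifest.record("preprocess", files, n_landmarks=ref_adj.shape[1])

    similarity = build_landmark_similarity(ref_adj)
    hierarchy = hierarchical_spectral_bisect(similarity, config.depth, seed=config.segment_seed)
    # a shape space needs >= 3 landmarks (2-point shapes are all identical
    # after scaling); undersized segments are kept in the hierarchy but
    # excluded from matching
    spaces = {
        sid: build_segment_space(
            ref_adj,
            hierarchy.nodes[sid],
            n_permutations=config.pa_permutations,
            percentile=config.pa_percentile,
            seed=config.segment_seed + sid,
        )
        for sid in hierarchy.segment_ids
        if hierarchy.nodes[sid].landmark_indices.size >= 3
    }
    results["hierarchy"] = hierarchy
    results["spaces"] = spaces
    if "segment" in stages:
        hj = out / "hierarchy.json"
        sfio.hierarchy_to_json(hierarchy, hj)
        sz = out / "segment_spaces.npz"
        sfio.save_segment_spaces(sz, spaces)
        manifest.record("segment", [hj, sz], n_segments=len(hierarchy))
    if not {"match", "traits", "gwas"} & set(stages):
        results["manifest"] = manifest.write()
        return results

    if config.match_segments == "all":
        seg_ids = sorted(spaces)
    elif config.match_segments == "full":
        seg_ids = [1]
    else:
        seg_ids = [int(s) for s in config.match_segments.split(",") if int(s) in spaces]

    sib_scores = {
        sid: project_to_reference(align_to_segment(spaces[sid], sib_adj), spaces[sid])
        for sid in seg_ids
    }
    ident = {
        sid: run_identification(
            sib_scores[sid],
            sib.individual_ids,
            sib.family_id,
            metric=config.metric,
            sigma=spaces[sid].sigma,
            label=str(sid),
        )
        for sid in seg_ids
    }
    results["identification"] = ident
    if "match" in stages:
        rows = []
        for sid, res in ident.items():
            df = res.experiments.copy()
            df.insert(0, "segment", sid)
            df["metric"] = config.metric
            rows.append(df)
        match_tsv = out / "identification.tsv"
        pd.concat(rows).to_csv(match_tsv, sep="\t", index=False)
        curve = cmc(ident[seg_ids[0]])
        cmc_tsv = out / "cmc_full_face.tsv"
        pd.DataFrame({"k_pct": curve.k_pct, "rate": curve.rate}).to_csv(
            cmc_tsv, sep="\t", index=False
        )
        manifest.record(
            "match",
            [match_tsv, cmc_tsv],
            n_experiments=sum(r.n_experiments for r in ident.values()),
            n_segments=len(seg_ids),
        )
    if not {"traits", "gwas"} & set(stages):
        results["manifest"] = manifest.write()
        return results

    fam = pd.Series(list(sib.family_id), index=sib.individual_ids)
    traits = []
    for sid in seg_ids:
        for s1, s2 in select_pairs(
            ident[sid],
            top_rank_fraction=config.top_rank_fraction,
            similarity_percentile=config.similarity_percentile,
        ):
            idx1 = sib.individual_ids.index(s1)
            idx2 = sib.individual_ids.index(s2)
            try:
                traits.append(
                    derive_trait(
                        len(traits) + 1, sid, fam[s1], s1, s2,
                        sib_scores[sid][idx1], sib_scores[sid][idx2],
                    )
                )
            except ValueError:
                warnings.warn(f"degenerate trait skipped for pair ({s1}, {s2}) in segment {sid}")
    results["traits"] = traits

    ref_scores = {
        sid: project_to_reference(align_to_segment(spaces[sid], ref_adj), spaces[sid])
        for sid in seg_ids
    }
    sigmas = {sid: spaces[sid].sigma for sid in seg_ids}
    scores = score_matrix(traits, ref_scores, sigmas) if traits else pd.DataFrame(index=range(ref.n_individuals))
    results["scores"] = scores
    meff = float(len(traits)) if len(traits) < 2 else effective_trait_count(scores)[0]
    meff = max(meff, 1.0)
    results["meff"] = meff

    if "traits" in stages:
        cat = out / "trait_catalog.tsv"
        pd.DataFrame(
            [
                {
                    "trait_id": t.trait_id,
                    "segment_id": t.segment_id,
                    "family_id": t.family_id,
                    "sib1_id": t.sib1_id,
                    "sib2_id": t.sib2_id,
                }
                for t in traits
            ],
            columns=["trait_id", "segment_id", "family_id", "sib1_id", "sib2_id"],
        ).to_csv(cat, sep="\t", index=False)
        sc = out / "trait_scores.tsv"
        scores_out = scores.copy()
        scores_out.insert(0, "individual_id", ref.individual_ids)
        scores_out.to_csv(sc, sep="\t", index=False, float_format="%.6g")
        vec = out / "trait_vectors.npz"
        np.savez_compressed(
            vec, **{f"trait{t.trait_id}": t.vector for t in traits},
            trait_ids=np.array([t.trait_id for t in traits]),
        )
        # selection-bias bookkeeping over all pairs of the sib cohort
        from .matching import enumerate_pairs

        selected_keys = {(t.sib1_id, t.sib2_id) for t in traits}
        sex = pd.Series(sib.covariates["sex"].to_numpy(), index=sib.individual_ids)
        age = pd.Series(sib.covariates["age"].to_numpy(), index=sib.individual_ids)
        pair_rows = []
        for a, b in enumerate_pairs(sib.individual_ids, sib.family_id):
            key = tuple(sorted((a, b)))
            pair_rows.append(
                {
                    "selected": key in selected_keys,
                    "same_sex": sex[a] == sex[b],
                    "age_gap": abs(age[a] - age[b]),
                }
            )
        bias = selection_bias_checks(pd.DataFrame(pair_rows))
        bias_path = out / "selection_bias.json"
        bias_path.write_text(json.dumps(bias, indent=1))
        manifest.record(
            "traits", [cat, sc, vec, bias_path], n_traits=len(traits), meff=meff
        )

    if "gwas" in stages and len(traits):
        is_male = ref.covariates["sex"].to_numpy() == 1
        chrom = ref.snp_info["chrom"].to_numpy()
        halves = np.array_split(np.arange(ref.n_individuals), max(config.n_meta_cohorts, 1))
        per_cohort = []
        for ci, rows_idx in enumerate(halves):
            resid, tested = sfgwas.residualize_genotypes(
                ref.genotypes[rows_idx],
                ref_design.iloc[rows_idx],
                chrom=chrom,
                is_male=is_male[rows_idx],
                n_components=config.plsr_components,
            )
            per_cohort.append(
                sfgwas.regress_many(
                    scores.iloc[rows_idx],
                    resid,
                    snp_info=ref.snp_info,
                    cohort=f"cohort{ci + 1}",
                    tested=tested,
                )
            )
        assoc = pd.concat(per_cohort, ignore_index=True)
        meta = sfgwas.ivw_meta(assoc)
        gw, sw = sfgwas.significance_thresholds(meff)
        peaks = sfgwas.group_peaks(meta, threshold=config.genome_wide_p, window=config.grouping_window)
        results.update(assoc=assoc, meta=meta, peaks=peaks, thresholds=(gw, sw))

        assoc_tsv = out / "assoc_per_cohort.tsv"
        assoc.to_csv(assoc_tsv, sep="\t", index=False, float_format="%.6g")
        meta_tsv = out / "assoc_meta.tsv"
        meta.to_csv(meta_tsv, sep="\t", index=False, float_format="%.6g")
        peak_rows = []
        resid_all, _ = sfgwas.residualize_genotypes(
            ref.genotypes, ref_design, chrom=chrom, is_male=is_male,
            n_components=config.plsr_components,
        )
        snp_pos = {s: i for i, s in enumerate(ref.snp_info["snp_id"])}
        for pk in peaks:
            r2, _ = sfgwas.variance_explained(
                scores[pk.best_trait].to_numpy(), resid_all[:, snp_pos[pk.lead_snp]]
            )
            peak_rows.append(
                {
                    "peak_id": pk.peak_id,
                    "chrom": pk.chrom,
                    "lead_snp": pk.lead_snp,
                    "lead_pos": pk.lead_pos,
                    "best_p": pk.best_p,
                    "best_trait": pk.best_trait,
                    "n_snps": len(pk.member_snps),
                    "lead_r2": float(r2[0]),
                }
            )
        peaks_tsv = out / "peaks.tsv"
        pd.DataFrame(
            peak_rows,
            columns=["peak_id", "chrom", "lead_snp", "lead_pos", "best_p", "best_trait", "n_snps", "lead_r2"],
        ).to_csv(peaks_tsv, sep="\t", index=False, float_format="%.6g")
        thr_path = out / "thresholds.json"
        thr_path.write_text(json.dumps({"genome_wide": gw, "study_wide": sw, "meff": meff}, indent=1))
        manifest.record(
            "gwas",
            [assoc_tsv, meta_tsv, peaks_tsv, thr_path],
            n_tests=len(meta),
            n_peaks=len(peaks),
        )

    results["manifest"] = manifest.write()
    return results
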