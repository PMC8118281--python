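"""File formats: landmark tables, PLY, covariates, VCF, hierarchy JSON, and
the portable array container for shape spaces and trait vectors.

Conventions
-----------
* Landmark table: TSV, one row per individual, first column ``individual_id``
  then columns ``x1 y1 z1 x2 y2 z2 ...`` (mm).
* Covariates: TSV with a header; ``individual_id`` plus typed columns.
* Genotypes: uncompressed VCF v4.2 with GT (hard calls) or DS (dosages);
  1-based positions. Written by :func:`write_vcf`, read with cyvcf2.
* Hierarchy: JSON list of nodes (id, parent, children, landmark indices).
* Array container: NumPy ``.npz`` with documented keys (see
  :func:`save_segment_spaces`).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import SegmentHierarchy, SegmentNode, SegmentShapeSpace

__all__ = [
    "write_landmark_table",
    "read_landmark_table",
    "write_ply",
    "read_ply",
    "write_covariates",
    "read_covariates",
    "write_vcf",
    "read_vcf",
    "hierarchy_to_json",
    "hierarchy_from_json",
    "save_segment_spaces",
    "load_segment_spaces",
]


def write_landmark_table(path, configurations: np.ndarray, individual_ids) -> None:
    configs = np.asarray(configurations, dtype=float)
    n, L, _ = configs.shape
    cols = [f"{ax}{i + 1}" for i in range(L) for ax in ("x", "y", "z")]
    df = pd.DataFrame(configs.reshape(n, -1), columns=cols)
    df.insert(0, "individual_id", list(individual_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_landmark_table(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: missing individual_id column")
    ids = df["individual_id"].astype(str).tolist()
    coords = df.drop(columns="individual_id").to_numpy(dtype=float)
    if coords.shape[1] % 3:
        raise ValueError(f"{path}: coordinate columns not a multiple of 3")
    return coords.reshape(len(df), -1, 3), ids


def write_ply(path, points: np.ndarray) -> None:
    """ASCII PLY point cloud of one landmark configuration."""
    import trimesh

    trimesh.PointCloud(np.asarray(points, dtype=float)).export(
        str(path), file_type="ply", encoding="ascii"
    )


def read_ply(path) -> np.ndarray:
    import trimesh

    loaded = trimesh.load(str(path), process=False)
    return np.asarray(loaded.vertices, dtype=float)


def write_covariates(path, covariates: pd.DataFrame, individual_ids=None) -> None:
    df = covariates.copy()
    if individual_ids is not None and "individual_id" not in df.columns:
        df.insert(0, "individual_id", list(individual_ids))
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(
    path,
    dosages: np.ndarray,
    snp_info: pd.DataFrame,
    individual_ids,
) -> None:
    """Write hard-call dosages as an uncompressed VCF (GT field).

    SNPs are sorted by (chromosome, position); dosage d in {0, 1, 2} becomes
    GT 0/0, 0/1, 1/1.
    """
    D = np.asarray(dosages)
    order = snp_info.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(snp_info["chrom"].astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, individual_ids))
            + "\n"
        )
        for j in order:
            row = snp_info.loc[j]
            calls = "\t".join(gt[int(d)] for d in D[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read dosages from a VCF (DS field if present, else GT hard calls)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).ravel()
        else:
            g = np.asarray(var.genotypes)[:, :2]
            d = np.where((g < 0).any(axis=1), np.nan, g.clip(min=0).sum(axis=1)).astype(float)
        dosage_cols.append(d)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
    info = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    info["maf"] = np.minimum(dosages.mean(axis=0) / 2.0, 1 - dosages.mean(axis=0) / 2.0)
    # readers downstream assume positions sorted within chromosome
    for _, idx in info.groupby("chrom").groups.items():
        pos = info.loc[idx, "pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            warnings.warn(f"{path}: unsorted positions; sorting")
            order = info.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
            info = info.loc[order].reset_index(drop=True)
            dosages = dosages[:, order]
            break
    return dosages, info, samples


def hierarchy_to_json(hierarchy: SegmentHierarchy, path=None) -> str:
    payload = {
        "depth": hierarchy.depth,
        "n_landmarks": hierarchy.n_landmarks,
        "nodes": [
            {
                "id": node.node_id,
                "parent": node.parent_id,
                "children": list(node.child_ids) if node.child_ids else None,
                "landmarks": node.landmark_indices.tolist(),
                "truncated": node.truncated,
            }
            for node in sorted(hierarchy.nodes.values(), key=lambda n: n.node_id)
        ],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def hierarchy_from_json(source) -> SegmentHierarchy:
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        payload = json.loads(Path(source).read_text())
    else:
        payload = json.loads(source)
    nodes = {
        n["id"]: SegmentNode(
            node_id=n["id"],
            landmark_indices=np.asarray(n["landmarks"], dtype=int),
            parent_id=n["parent"],
            child_ids=tuple(n["children"]) if n["children"] else None,
            truncated=n.get("truncated", False),
        )
        for n in payload["nodes"]
    }
    return SegmentHierarchy(nodes=nodes, depth=payload["depth"], n_landmarks=payload["n_landmarks"])


def save_segment_spaces(path, spaces: dict[int, SegmentShapeSpace]) -> None:
    """Portable array container for per-segment shape spaces.

    Keys per segment id ``s``: ``seg{s}_landmarks``, ``seg{s}_consensus``,
    ``seg{s}_mean``, ``seg{s}_evec``, ``seg{s}_eval``, ``seg{s}_meta``
    (= [n_retained, with_scaling]).
    """
    arrays: dict[str, np.ndarray] = {"segment_ids": np.array(sorted(spaces))}
    for sid, sp in spaces.items():
        arrays[f"seg{sid}_landmarks"] = sp.landmark_indices
        arrays[f"seg{sid}_consensus"] = sp.consensus
        arrays[f"seg{sid}_mean"] = sp.mean_shape
        arrays[f"seg{sid}_evec"] = sp.eigenvectors
        arrays[f"seg{sid}_eval"] = sp.eigenvalues
        arrays[f"seg{sid}_meta"] = np.array([sp.n_retained, int(sp.with_scaling)])
    np.savez_compressed(path, **arrays)


def load_segment_spaces(path) -> dict[int, SegmentShapeSpace]:
    data = np.load(path)
    spaces = {}
    for sid in data["segment_ids"]:
        sid = int(sid)
        meta = data[f"seg{sid}_meta"]
        spaces[sid] = SegmentShapeSpace(
            segment_id=sid,
            landmark_indices=data[f"seg{sid}_landmarks"],
            consensus=data[f"seg{sid}_consensus"],
            mean_shape=data[f"seg{sid}_mean"],
            eigenvectors=data[f"seg{sid}_evec"],
            eigenvalues=data[f"seg{sid}_eval"],
            n_retained=int(meta[0]),
            with_scaling=bool(meta[1]),
        )
    return spaces
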