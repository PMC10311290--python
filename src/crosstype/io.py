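"""Readers and writers for the pipeline's on-disk formats.

Expression data travel as AnnData h5ad or an MTX directory (matrix.mtx +
genes.tsv + barcodes.tsv + metadata.tsv); protein embeddings as TSV
(gene id followed by the vector); BLAST hits as 12-column outfmt-6 tables;
the match graph and type correspondence as TSV; shared feature matrices and
model checkpoints as HDF5/NPZ containers; metrics as JSON.
"""

from __future__ import annotations

import json
import hashlib
import os
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_space import ExpressionDataset, SharedFeatureMatrix
from .gene_matching import BlastHit, GeneMatch, GeneMatchGraph, ProteinEmbeddingSet
from .model import ModelConfig, TrainedModel, feature_order_hash
from .transfer import MatchResult, TypeCorrespondence


# --------------------------------------------------------------------------- expression

def write_expression_h5ad(X: ExpressionDataset, path: str | Path) -> None:
    X.to_anndata().write_h5ad(Path(path))


def read_expression_h5ad(path: str | Path, species: str,
                         cell_type_key: str = "cell_type",
                         layer: str | None = None) -> ExpressionDataset:
    import anndata as ad

    return ExpressionDataset.from_anndata(ad.read_h5ad(Path(path)), species,
                                          cell_type_key, layer)


def write_expression_mtx(X: ExpressionDataset, outdir: str | Path) -> None:
    """MTX bundle: matrix.mtx (genes x cells), genes.tsv, barcodes.tsv, metadata.tsv."""
    from scipy import io as sio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(X.counts.T))
    pd.Series(list(X.gene_ids)).to_csv(outdir / "genes.tsv", sep="\t",
                                       index=False, header=False)
    pd.Series(list(X.cell_ids)).to_csv(outdir / "barcodes.tsv", sep="\t",
                                       index=False, header=False)
    pd.DataFrame({"cell_id": X.cell_ids, "cell_type": X.cell_types}).to_csv(
        outdir / "metadata.tsv", sep="\t", index=False)


def read_expression_mtx(indir: str | Path, species: str) -> ExpressionDataset:
    from scipy import io as sio

    indir = Path(indir)
    counts = np.asarray(sio.mmread(str(indir / "matrix.mtx")).todense()).T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t").set_index("cell_id")
    types = meta.loc[barcodes, "cell_type"].tolist()
    return ExpressionDataset(species, counts.astype(np.int64), genes, barcodes, types)


# --------------------------------------------------------------------------- embeddings

def write_embeddings_tsv(E: ProteinEmbeddingSet, path: str | Path) -> None:
    """One row per gene (isoform rows repeat the gene id)."""
    with open(path, "w") as fh:
        for gid in E.gene_ids:
            for row in E.vectors[gid]:
                fh.write(gid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_embeddings_tsv(path: str | Path, species: str) -> ProteinEmbeddingSet:
    rows: dict[str, list[list[float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed embedding row at line {ln}")
            if ln == 1:
                try:
                    [float(x) for x in parts[1:]]
                except ValueError:
                    continue  # header line
            try:
                vec = [float(x) for x in parts[1:]]
            except ValueError as err:
                raise ValueError(f"{path}: malformed embedding row at line {ln}") from err
            rows.setdefault(parts[0], []).append(vec)
    return ProteinEmbeddingSet(species, {g: np.array(v) for g, v in rows.items()})


def write_residue_embeddings_h5(mats: dict, path: str | Path) -> None:
    """One L x D matrix per gene, keyed by gene id."""
    import h5py

    with h5py.File(path, "w") as f:
        for gid, m in mats.items():
            f.create_dataset(gid, data=np.asarray(m.matrix))


def read_residue_embeddings_h5(path: str | Path) -> dict:
    import h5py

    from .gene_matching import ResidueEmbeddingMatrix

    out = {}
    with h5py.File(path, "r") as f:
        for gid in f:
            out[gid] = ResidueEmbeddingMatrix(gid, f[gid][()])
    return out


# --------------------------------------------------------------------------- BLAST

BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_blast_outfmt6(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column outfmt-6 table; only qseqid/sseqid/evalue/bitscore used."""
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}: expected 12 columns at line {ln}, "
                                 f"got {len(parts)}")
            try:
                hits.append(BlastHit(parts[0], parts[1],
                                     float(parts[10]), float(parts[11])))
            except ValueError as err:
                raise ValueError(f"{path}: malformed numeric field at line {ln}") from err
    return hits


def write_blast_outfmt6(hits: list[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fields = [h.query, h.subject, "0", "0", "0", "0", "0", "0", "0", "0",
                      repr(h.evalue), repr(h.bitscore)]
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------- match graph

def write_match_graph_tsv(g: GeneMatchGraph, path: str | Path) -> None:
    g.to_dataframe().to_csv(path, sep="\t", index=False)


def read_match_graph_tsv(path: str | Path, species_a: str = "A",
                         species_b: str = "B") -> GeneMatchGraph:
    df = pd.read_csv(path, sep="\t")
    edges = [GeneMatch(r.gene_a, r.gene_b, float(r.distance), float(r.weight), r.source)
             for r in df.itertuples()]
    return GeneMatchGraph(edges, species_a, species_b)


# --------------------------------------------------------------------------- correspondence

def write_correspondence_tsv(corr: TypeCorrespondence, path: str | Path) -> None:
    rows = [(a, b, "") for a, b in corr.pairs]
    rows += [(t, "", "A") for t in sorted(corr.species_specific_a)]
    rows += [("", t, "B") for t in sorted(corr.species_specific_b)]
    pd.DataFrame(rows, columns=["type_a", "type_b", "species_specific"]).to_csv(
        path, sep="\t", index=False)


def read_correspondence_tsv(path: str | Path) -> TypeCorrespondence:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs, spec_a, spec_b = [], set(), set()
    for r in df.itertuples():
        flag = str(r.species_specific)
        if flag == "A":
            spec_a.add(r.type_a)
        elif flag == "B":
            spec_b.add(r.type_b)
        else:
            pairs.append((r.type_a, r.type_b))
    return TypeCorrespondence(pairs, spec_a, spec_b)


# --------------------------------------------------------------------------- shared features

def write_shared_features_h5(S: SharedFeatureMatrix, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=S.values)
        f.attrs["species"] = S.species
        f.create_dataset("feature_ids", data=np.array(S.feature_ids, dtype="S"))
        f.create_dataset("origin", data=np.array(S.origin, dtype="S"))
        f.create_dataset("cell_ids", data=np.array(S.cell_ids, dtype="S"))
        f.create_dataset("cell_types", data=np.array(S.cell_types, dtype="S"))


def read_shared_features_h5(path: str | Path) -> SharedFeatureMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        def dec(name):
            return [x.decode() for x in f[name][()]]
        return SharedFeatureMatrix(
            str(f.attrs["species"]), f["values"][()],
            dec("feature_ids"), dec("origin"), dec("cell_ids"), dec("cell_types"))


# --------------------------------------------------------------------------- model checkpoint

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file NPZ checkpoint: weights + JSON header + feature hash."""
    header = {
        "config": asdict(model.config),
        "feature_ids": model.feature_ids,
        "types_a": model.types_a,
        "types_b": model.types_b,
        "feature_hash": model.feature_hash,
        "log": model.log,
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays["class_weights_a"] = model.class_weights_a
    arrays["class_weights_b"] = model.class_weights_b
    np.savez(path, header=json.dumps(header), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["header"]))
    model = TrainedModel(
        params={k[len("param_"):]: data[k] for k in data.files
                if k.startswith("param_")},
        config=ModelConfig(**header["config"]),
        feature_ids=header["feature_ids"],
        types_a=header["types_a"],
        types_b=header["types_b"],
        class_weights_a=data["class_weights_a"],
        class_weights_b=data["class_weights_b"],
        log=header["log"],
    )
    if model.feature_ids and feature_order_hash(model.feature_ids) != header["feature_hash"]:
        raise ValueError("feature-order hash mismatch in checkpoint")
    return model


# --------------------------------------------------------------------------- results & manifest

def write_match_result(result: MatchResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.combined_frame().to_csv(outdir / "combined_matrix.tsv", sep="\t")
    pd.DataFrame(result.m_a_to_b, index=result.types_a,
                 columns=result.types_b).to_csv(outdir / "matrix_a_to_b.tsv", sep="\t")
    pd.DataFrame(result.m_b_to_a, index=result.types_b,
                 columns=result.types_a).to_csv(outdir / "matrix_b_to_a.tsv", sep="\t")
    for name, frame in (("transferred_a.csv", result.transferred_a),
                        ("transferred_b.csv", result.transferred_b)):
        if frame is not None:
            frame.to_csv(outdir / name, index=False)
    metrics = {
        "ads": result.ads,
        "recall": result.recall,
        "per_pair_scores": {f"{a}|{b}": s for (a, b), s in result.per_pair_scores.items()},
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(outdir: str | Path, config: dict, seed: int,
                       inputs: list[str | Path]) -> None:
    """Machine-readable record of one CLI run: config, seed, versions, input hashes."""
    import anndata
    import scanpy
    import scipy

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "anndata": anndata.__version__,
            "scanpy": scanpy.__version__,
        },
        "input_hashes": {str(p): file_sha256(p) for p in inputs
                         if p and os.path.isfile(p)},
    }
    Path(outdir).mkdir(parents=True, exist_ok=True)
    (Path(outdir) / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
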