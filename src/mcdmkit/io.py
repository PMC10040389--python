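"""Readers and writers for the pipeline's text formats.

GMT pathway collections (with a signed-gene dialect ``SYMBOL:+1`` /
``SYMBOL:-1``), TSV DEG tables, ligand-target prior edge lists with ligand
annotations, expression matrices (MTX + gene/cell metadata TSV, or dense
CSV), and MCDM graph exports.  All delimited text is tab-separated UTF-8
with a mandatory header row; readers reject malformed input rather than
coerce it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .enrichment import DEG_COLUMNS, PathwayDB
from .interactions import LigandTargetPrior

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_deg_table",
    "write_deg_table",
    "read_prior",
    "write_prior",
    "read_matrix",
    "write_matrix",
    "write_mcdm",
    "read_mcdm",
]


def read_gmt(path) -> PathwayDB:
    """Read a GMT file (name, description, genes), signed dialect accepted."""
    sets: dict[str, set[str]] = {}
    signs: dict[str, dict[str, int]] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, _desc, *tokens = parts
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate pathway {name!r}")
        genes, sgn = set(), {}
        for tok in tokens:
            if not tok:
                continue
            if ":" in tok:
                sym, _, s = tok.rpartition(":")
                if s not in ("+1", "-1", "1"):
                    raise ValueError(f"{path}:{lineno}: bad signed token {tok!r}")
                genes.add(sym)
                sgn[sym] = 1 if s in ("+1", "1") else -1
            else:
                genes.add(tok)
        if not genes:
            raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
        sets[name] = genes
        if sgn:
            signs[name] = sgn
    if not sets:
        import warnings

        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return PathwayDB(sets=sets, signs=signs, source=str(path))


def write_gmt(db: PathwayDB, path) -> None:
    """Write a PathwayDB as GMT; signed dialect used where signs exist."""
    lines = []
    for name in sorted(db.sets):
        sgn = db.signs.get(name, {})
        tokens = [
            f"{g}:{'+1' if sgn[g] > 0 else '-1'}" if g in sgn else g
            for g in sorted(db.sets[name])
        ]
        lines.append("\t".join([name, db.source or "na", *tokens]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_deg_table(path) -> pd.DataFrame:
    """Read a DEG table TSV with required columns gene/logFC/pvalue/fdr/dataset."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DEG columns {sorted(missing)}")
    return df[list(DEG_COLUMNS)]


def write_deg_table(table: pd.DataFrame, path) -> None:
    table[list(DEG_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_prior(edges_path, annot_path=None) -> LigandTargetPrior:
    """Read a (ligand, gene, weight) edge list plus optional ligand annotations.

    The annotation TSV needs columns ``ligand``, ``location``,
    ``molecule_class``.
    """
    edges = pd.read_csv(edges_path, sep="\t")
    need = {"ligand", "gene", "weight"}
    if not need <= set(edges.columns):
        raise ValueError(f"{edges_path}: needs columns {sorted(need)}")
    location, mol = {}, {}
    if annot_path is not None:
        annot = pd.read_csv(annot_path, sep="\t")
        if not {"ligand", "location", "molecule_class"} <= set(annot.columns):
            raise ValueError(f"{annot_path}: needs ligand/location/molecule_class columns")
        location = dict(zip(annot["ligand"], annot["location"]))
        mol = dict(zip(annot["ligand"], annot["molecule_class"]))
    return LigandTargetPrior.from_edges(edges, location=location, molecule_class=mol)


def write_prior(prior: LigandTargetPrior, edges_path, annot_path=None) -> None:
    rows = []
    for lig in prior.ligands:
        row = prior.potential.loc[lig]
        for g in sorted(row.index[row > 0]):
            rows.append((lig, g, float(row[g])))
    pd.DataFrame(rows, columns=["ligand", "gene", "weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if annot_path is not None:
        pd.DataFrame(
            {
                "ligand": prior.ligands,
                "location": [prior.location.get(l, "other") for l in prior.ligands],
                "molecule_class": [prior.molecule_class.get(l, "other") for l in prior.ligands],
            }
        ).to_csv(annot_path, sep="\t", index=False)


def read_matrix(matrix_path, genes_path=None, cells_path=None) -> ad.AnnData:
    """Read an expression matrix.

    Either an MTX file (genes x cells) with gene and cell-metadata TSVs, or
    a dense CSV/TSV (genes x cells, gene ids in the first column).
    Duplicate gene ids and dimension mismatches are errors.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input needs gene and cell metadata tables")
        x = spio.mmread(matrix_path).tocsr()
        genes = pd.read_csv(genes_path, sep="\t")
        cells = pd.read_csv(cells_path, sep="\t", index_col=0)
        if x.shape != (len(genes), len(cells)):
            raise ValueError(
                f"dimension mismatch: matrix {x.shape} vs {len(genes)} genes x {len(cells)} cells"
            )
        gene_ids = genes.iloc[:, 0].astype(str)
        if gene_ids.duplicated().any():
            raise ValueError("duplicate gene ids")
        adata = ad.AnnData(X=x.T.toarray(), obs=cells, var=pd.DataFrame(index=gene_ids.to_numpy()))
        return adata
    df = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    obs = pd.DataFrame(index=df.columns.astype(str))
    if cells_path is not None:
        obs = pd.read_csv(cells_path, sep="\t", index_col=0)
        if not obs.index.astype(str).equals(pd.Index(df.columns.astype(str))):
            raise ValueError("cell metadata does not match matrix columns")
    return ad.AnnData(X=df.T.to_numpy(dtype=float), obs=obs, var=pd.DataFrame(index=df.index.astype(str)))


def write_matrix(adata: ad.AnnData, matrix_path, genes_path, cells_path, layer=None) -> None:
    """Write an AnnData as MTX (genes x cells) + gene/cell TSVs."""
    x = adata.layers[layer] if layer else adata.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    spio.mmwrite(str(matrix_path), sparse.csr_matrix(np.asarray(x).T))
    pd.DataFrame({"gene": list(adata.var_names)}).to_csv(genes_path, sep="\t", index=False)
    adata.obs.to_csv(cells_path, sep="\t")


def write_mcdm(graph: nx.MultiDiGraph, edge_path, json_path=None) -> None:
    """Export an MCDM as a TSV edge list (and optionally a JSON graph)."""
    rows = []
    for u, v, data in graph.edges(data=True):
        rows.append(
            {
                "sender_organ": u[0],
                "sender_celltype": u[1],
                "ligand": data["ligand"],
                "receiver_organ": v[0],
                "receiver_celltype": v[1],
                "n_targets": len(data["targets"]),
                "pcc": data["activity"],
                "targets": ";".join(sorted(data["targets"])),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "sender_organ", "sender_celltype", "ligand", "receiver_organ",
            "receiver_celltype", "n_targets", "pcc", "targets",
        ],
    ).to_csv(edge_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "nodes": [
                {"organ": n[0], "cell_type": n[1], "n_cells": d.get("n_cells", 0)}
                for n, d in graph.nodes(data=True)
            ],
            "edges": rows,
        }
        Path(json_path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_mcdm(edge_path) -> nx.MultiDiGraph:
    """Read an MCDM edge-list TSV back into a multigraph."""
    df = pd.read_csv(edge_path, sep="\t")
    g = nx.MultiDiGraph()
    for _, r in df.iterrows():
        u = (r["sender_organ"], r["sender_celltype"])
        v = (r["receiver_organ"], r["receiver_celltype"])
        targets = frozenset(str(r["targets"]).split(";")) if pd.notna(r["targets"]) else frozenset()
        g.add_edge(u, v, key=r["ligand"], ligand=r["ligand"], targets=targets,
                   activity=float(r["pcc"]))
    return g
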