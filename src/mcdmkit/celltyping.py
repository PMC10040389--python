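"""Reference-based cell typing with purity-escalated community detection.

Cells pass QC filters, are embedded in a low-dimensional latent space, and
each bulk reference profile is projected into single-cell scale via its
best-matching cell (highest Spearman correlation) and a monotonic
(isotonic) regression.  Cells and projected references are clustered
together with the Leiden algorithm; the resolution is raised until every
cluster is pure (>= 70% of its cells sharing the same best-matching
reference type), and each cluster is labeled with its dominant type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import TruncatedSVD
from sklearn.isotonic import IsotonicRegression
from sklearn.neighbors import NearestNeighbors

from .enrichment import adjust

__all__ = [
    "qc_filter",
    "Embedding",
    "embed",
    "match_reference",
    "best_reference_per_cell",
    "project_reference",
    "cluster_and_label",
    "find_markers",
]


def qc_filter(
    matrix,
    min_reads: int = 10_000,
    min_transcripts: int = 400,
    min_genes: int = 200,
    max_mito: float = 0.20,
    max_transcripts: int = 6_000,
    min_gene_prevalence: float = 0.10,
):
    """Quality-filter cells, then genes.

    Cells need >= ``min_reads`` reads, ``min_transcripts``..``max_transcripts``
    transcripts (high counts flag likely duplicates), >= ``min_genes``
    detected genes and < ``max_mito`` mitochondrial fraction.  Genes must
    then be detected in >= ``min_gene_prevalence`` of the retained cells.
    Idempotent: a second application removes nothing.
    """
    obs = matrix.obs
    crit = {
        "reads": obs["reads"] >= min_reads,
        "transcripts_low": obs["transcripts"] >= min_transcripts,
        "transcripts_high": obs["transcripts"] <= max_transcripts,
        "genes": obs["genes_detected"] >= min_genes,
        "mito": obs["mito_fraction"] < max_mito,
    }
    keep = np.ones(matrix.n_obs, dtype=bool)
    for mask in crit.values():
        keep &= mask.to_numpy()
    if not keep.any():
        removed = {k: int((~m).sum()) for k, m in crit.items()}
        raise ValueError(f"all cells removed by QC; removal counts {removed}")
    out = matrix[keep].copy()
    x = out.layers["counts"] if "counts" in out.layers else out.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    prevalence = (np.asarray(x) > 0).mean(axis=0)
    out = out[:, prevalence >= min_gene_prevalence].copy()
    return out


@dataclass
class Embedding:
    """A fitted linear embedding that can project new profiles."""

    model: TruncatedSVD
    coords: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return self.model.transform(np.asarray(values, dtype=float))


def embed(matrix, dim: int = 32, seed: int = 0, method=None) -> Embedding:
    """Embed cells into a ``dim``-dimensional latent space.

    Default is truncated SVD on the normalized layer (a pluggable stand-in
    for a trained autoencoder latent space); pass ``method`` as a callable
    ``(values, dim, seed) -> Embedding`` to substitute another embedding.
    Deterministic given the seed.
    """
    if dim > min(matrix.n_obs, matrix.n_vars):
        raise ValueError(f"dim={dim} exceeds min(genes, cells)")
    x = matrix.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    x = np.asarray(x, dtype=float)
    if method is not None:
        return method(x, dim, seed)
    model = TruncatedSVD(n_components=dim, random_state=seed)
    coords = model.fit_transform(x)
    return Embedding(model=model, coords=coords)


def _spearman_matrix(ref: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """references x cells Spearman correlations (average ranks)."""
    r_ref = stats.rankdata(ref, axis=1)
    r_cells = stats.rankdata(cells, axis=1)
    r_ref = r_ref - r_ref.mean(axis=1, keepdims=True)
    r_cells = r_cells - r_cells.mean(axis=1, keepdims=True)
    denom = np.sqrt((r_ref**2).sum(axis=1))[:, None] * np.sqrt((r_cells**2).sum(axis=1))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return (r_ref @ r_cells.T) / denom


def match_reference(matrix, reference: pd.DataFrame) -> dict[str, str]:
    """Best-matching cell per reference profile (highest Spearman rho).

    ``reference`` is genes x cell types.  Correlations use the shared-gene
    intersection; ties break to the lowest cell index.  Zero-variance
    vectors make a (reference, cell) pair undefined and it is skipped.
    """
    shared = [g for g in matrix.var_names if g in reference.index]
    if not shared:
        raise ValueError("no shared genes between matrix and reference")
    cells = _matrix_values(matrix, shared)
    ref = reference.loc[shared].T.to_numpy(dtype=float)
    rho = _spearman_matrix(ref, cells)
    out: dict[str, str] = {}
    names = list(matrix.obs_names)
    for i, label in enumerate(reference.columns):
        row = rho[i]
        if np.all(np.isnan(row)):
            warnings.warn(f"reference {label!r}: all pairs undefined; skipped", stacklevel=2)
            continue
        best = int(np.nanargmax(row))
        out[label] = names[best]
    if not out:
        raise ValueError("every (reference, cell) pair was undefined")
    return out


def best_reference_per_cell(matrix, reference: pd.DataFrame) -> pd.Series:
    """Best-matching reference type per cell (highest Spearman rho)."""
    shared = [g for g in matrix.var_names if g in reference.index]
    if not shared:
        raise ValueError("no shared genes between matrix and reference")
    cells = _matrix_values(matrix, shared)
    ref = reference.loc[shared].T.to_numpy(dtype=float)
    rho = _spearman_matrix(ref, cells)
    labels = [reference.columns[int(i)] for i in np.nanargmax(rho, axis=0)]
    return pd.Series(labels, index=matrix.obs_names)


def _matrix_values(matrix, genes) -> np.ndarray:
    x = matrix[:, genes].X
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def project_reference(
    reference: pd.DataFrame,
    matrix,
    matches: Mapping[str, str],
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Project bulk reference profiles into single-cell scale.

    Per reference type: a least-squares non-decreasing (isotonic)
    regression with the reference values as input and the natural log of
    the matched cell's back-transformed expression as output; the result
    is ``round(exp(fitted))`` per gene.  Zeros are clipped at ``eps``
    before the log.
    """
    shared = [g for g in matrix.var_names if g in reference.index]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes")
    out = {}
    for label, cell in matches.items():
        x = reference.loc[shared, label].to_numpy(dtype=float)
        expr = _matrix_values(matrix[[cell]], shared)[0]
        linear = np.power(10.0, expr) - 1.0
        y = np.log(np.clip(linear, eps, None))
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        fitted = iso.fit_transform(x, y)
        out[label] = np.round(np.exp(fitted))
    return pd.DataFrame(out, index=shared)


def _leiden(adj_sources, adj_targets, n_vertices, resolution, seed):
    g = ig.Graph(n=n_vertices, edges=list(zip(adj_sources, adj_targets)), directed=False)
    g.simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.array(part.membership)


def cluster_and_label(
    cell_latents: np.ndarray,
    ref_latents: np.ndarray,
    cell_matches: pd.Series | np.ndarray,
    ref_labels: list[str],
    k_neighbors: int = 30,
    start_resolution: float = 0.5,
    resolution_step: float = 0.1,
    purity_threshold: float = 0.70,
    max_resolution: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Joint Leiden clustering of cells and reference points, with purity escalation.

    ``cell_matches`` is each cell's best-matching reference type (computed
    once on expression, not per resolution).  Starting at
    ``start_resolution``, the Leiden resolution is raised by
    ``resolution_step`` until every cluster's purity -- the fraction of its
    cells sharing the modal match -- reaches ``purity_threshold``.  Cells
    take their cluster's modal ("dominant") reference type as label.
    Reference points join the k-NN graph with unit weight but are excluded
    from the purity denominator.
    """
    cell_matches = np.asarray(cell_matches)
    n_cells = cell_latents.shape[0]
    pts = np.vstack([cell_latents, ref_latents])
    k = min(k_neighbors, pts.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pts)
    _, idx = nn.kneighbors(pts)
    src = np.repeat(np.arange(pts.shape[0]), k)
    dst = idx[:, :k].ravel()

    resolution = start_resolution
    while True:
        membership = _leiden(src, dst, pts.shape[0], resolution, seed)
        cl_cells = membership[:n_cells]
        purities, modal = {}, {}
        for c in np.unique(cl_cells):
            types = cell_matches[cl_cells == c]
            vals, counts = np.unique(types, return_counts=True)
            best = int(np.argmax(counts))
            modal[c] = vals[best]
            purities[c] = counts[best] / counts.sum()
        worst = min(purities.values())
        if worst >= purity_threshold:
            break
        if resolution + resolution_step > max_resolution + 1e-9:
            raise RuntimeError(
                f"purity {worst:.2f} below threshold {purity_threshold} at "
                f"max_resolution={max_resolution}"
            )
        resolution += resolution_step
    return pd.DataFrame(
        {
            "cluster": cl_cells,
            "label": [modal[c] for c in cl_cells],
            "purity": [purities[c] for c in cl_cells],
            "resolution": resolution,
        }
    )


def find_markers(matrix, labels: pd.Series | Mapping[str, str], fdr: float = 0.05) -> pd.DataFrame:
    """Marker genes per label: rank-sum test label vs all other cells.

    Returns one row per (label, gene) with log fold change (label vs rest,
    back-transformed means, pseudocount 1) and BH FDR.  Labels with fewer
    than 3 cells are skipped with a warning.
    """
    labels = pd.Series(labels).reindex(matrix.obs_names)
    x = matrix.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    x = np.asarray(x, dtype=float)
    frames = []
    for lab in sorted(labels.dropna().unique()):
        mask = (labels == lab).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"label {lab!r} has <3 cells; skipped", stacklevel=2)
            continue
        if (~mask).sum() < 1:
            continue
        a, b = x[mask], x[~mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        p = np.where(np.isnan(np.asarray(res.pvalue, float)), 1.0, res.pvalue)
        lin_a = np.power(10.0, a).mean(axis=0)
        lin_b = np.power(10.0, b).mean(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "label": lab,
                    "gene": list(matrix.var_names),
                    "logFC": np.log2(lin_a / lin_b),
                    "pvalue": p,
                    "fdr": adjust(p, "BH"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["label", "gene", "logFC", "pvalue", "fdr"])
    return pd.concat(frames, ignore_index=True)
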