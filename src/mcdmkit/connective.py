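"""Connective pathway analysis: programs of gene-sharing pathways.

Pathways are restricted to genes differentially expressed somewhere in a
group of datasets, compared pairwise by Jaccard similarity of those
restricted sets, and clustered hierarchically on 1-Jaccard distance with
Ward linkage.  Cutting the dendrogram at the top yields *programs*; cutting
each program's subtree yields *subprograms*.  Each pathway is then labeled
activated / inhibited / no_direction / not_significant per group by the
majority of significant directional calls, and the fraction of pathways
whose state flips between groups quantifies the on/off contrast.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import (
    EnrichmentResult,
    PathwayDB,
    adjust,
    fisher_enrich,
    significant_genes,
)

__all__ = [
    "ProgramTree",
    "PathwayLabel",
    "pathway_deg_sets",
    "jaccard_matrix",
    "cluster_pathways",
    "cut_tree",
    "label_pathway",
    "label_all",
    "opposing_fraction",
    "gwas_enrichment",
    "program_overlap",
    "export_tree",
    "parse_newick",
]


@dataclass
class ProgramTree:
    """Dendrogram over pathways with program/subprogram assignments."""

    leaves: list[str]
    linkage: np.ndarray  # scipy linkage matrix (Ward on 1-Jaccard)
    distance: pd.DataFrame  # 1-Jaccard, symmetric, zero diagonal
    programs: dict[str, str] = field(default_factory=dict)
    subprograms: dict[str, str] = field(default_factory=dict)
    tie_break: str = "smallest leaf index"


@dataclass
class PathwayLabel:
    pathway: str
    group: str
    label: str  # activated | inhibited | no_direction | not_significant
    n_activated: int
    n_inhibited: int
    n_nodir: int
    n_total_significant: int


def pathway_deg_sets(
    deg_tables: Mapping[str, pd.DataFrame],
    pathway_db: PathwayDB,
    group: Sequence[str],
    fdr: float = 0.05,
) -> dict[str, set[str]]:
    """Restrict each pathway to genes DE in at least one dataset of the group.

    Pathways whose restricted set is empty are dropped with a warning.
    """
    if not group:
        raise ValueError("empty dataset group")
    deg_union: set[str] = set()
    for ds in group:
        deg_union |= significant_genes(deg_tables[ds], fdr=fdr)
    out: dict[str, set[str]] = {}
    dropped = []
    for pid in sorted(pathway_db.sets):
        restricted = pathway_db.sets[pid] & deg_union
        if restricted:
            out[pid] = restricted
        else:
            dropped.append(pid)
    if dropped:
        warnings.warn(
            f"{len(dropped)} pathways dropped (no DEG overlap): {dropped[:5]}...",
            stacklevel=2,
        )
    return out


def jaccard_matrix(sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Pairwise Jaccard similarity |A∩B| / |A∪B| between gene sets."""
    ids = sorted(sets)
    frozen = {i: set(sets[i]) for i in ids}
    for i in ids:
        if not frozen[i]:
            raise ValueError(f"set {i!r} is empty: Jaccard undefined")
    n = len(ids)
    mat = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = frozen[ids[a]], frozen[ids[b]]
            mat[a, b] = mat[b, a] = len(sa & sb) / len(sa | sb)
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_pathways(similarity: pd.DataFrame) -> ProgramTree:
    """Hierarchical Ward clustering on 1-Jaccard distances.

    Uses the squared-distance Lance-Williams update on the precomputed
    distance matrix (the hclust ``ward.D2`` convention).  Merge ties are
    broken deterministically by smallest leaf index (scipy's ordering).
    """
    if len(similarity) < 2:
        raise ValueError("need at least 2 pathways to cluster")
    dist = 1.0 - similarity
    np.fill_diagonal(dist.values, 0.0)
    condensed = squareform(dist.to_numpy(), checks=False)
    link = hierarchy.linkage(condensed, method="ward")
    return ProgramTree(leaves=list(similarity.index), linkage=link, distance=dist)


def _subtree_cut(link: np.ndarray, leaf_idx: list[int], k: int) -> dict[int, int]:
    """Cut the subtree spanning ``leaf_idx`` into ``k`` clusters.

    Removes the k-1 highest merges internal to the subtree; returns leaf
    index -> cluster number.
    """
    leaf_set = set(leaf_idx)
    n = link.shape[0] + 1
    internal = []  # (height, node_id, child ids) merges fully inside the subtree
    node_members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for m, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        node = n + m
        node_members[node] = node_members[a] | node_members[b]
        if node_members[node] <= leaf_set:
            internal.append((h, node, a, b))
    # keep merges below the k-1 highest
    internal.sort(key=lambda t: (t[0], t[1]))
    kept = internal[: max(len(internal) - (k - 1), 0)]
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for _, node, a, b in kept:
        ra = find(min(node_members[a]))
        rb = find(min(node_members[b]))
        parent.setdefault(ra, ra)
        parent.setdefault(rb, rb)
        parent[max(ra, rb)] = min(ra, rb)
    return {i: find(i) for i in leaf_idx}


def cut_tree(
    tree: ProgramTree, k_top: int = 2, k_sub: int | Mapping[str, int] = 10
) -> ProgramTree:
    """Cut into programs and per-program subprograms.

    Labels are ``P{i}`` / ``SP{i}.{j}``, ordered by subtree size
    descending.  ``k_sub`` may be a single count or a per-program mapping;
    it is capped at the program's leaf count.
    """
    n = len(tree.leaves)
    if k_top > n:
        raise ValueError(f"k_top={k_top} exceeds leaf count {n}")
    top = _subtree_cut(tree.linkage, list(range(n)), k_top)
    by_root: dict[int, list[int]] = {}
    for leaf, root in top.items():
        by_root.setdefault(root, []).append(leaf)
    ordered = sorted(by_root.values(), key=lambda ls: (-len(ls), min(ls)))
    programs: dict[str, str] = {}
    subprograms: dict[str, str] = {}
    for i, leaves in enumerate(ordered, start=1):
        pname = f"P{i}"
        for leaf in leaves:
            programs[tree.leaves[leaf]] = pname
        want = k_sub.get(pname, 1) if isinstance(k_sub, Mapping) else k_sub
        want = max(1, min(want, len(leaves)))
        sub = _subtree_cut(tree.linkage, leaves, want)
        by_sub: dict[int, list[int]] = {}
        for leaf, root in sub.items():
            by_sub.setdefault(root, []).append(leaf)
        sub_ordered = sorted(by_sub.values(), key=lambda ls: (-len(ls), min(ls)))
        for j, sleaves in enumerate(sub_ordered, start=1):
            sname = f"SP{i}.{j}"
            for leaf in sleaves:
                subprograms[tree.leaves[leaf]] = sname
    return ProgramTree(
        leaves=tree.leaves,
        linkage=tree.linkage,
        distance=tree.distance,
        programs=programs,
        subprograms=subprograms,
        tie_break=tree.tie_break,
    )


def label_pathway(
    enrichments: Sequence[EnrichmentResult], alpha: float = 0.05
) -> PathwayLabel:
    """Activation label of one pathway across one group's datasets.

    Among datasets with p < alpha: count activated (z > 0), inhibited
    (z < 0) and direction-less (z undefined or 0) calls.  Majority of the
    directional calls decides; ties with at least one directional call, or
    only direction-less significances, give ``no_direction``; no
    significant dataset gives ``not_significant``.
    """
    sig = [e for e in enrichments if e.p < alpha]
    n_act = sum(1 for e in sig if e.z is not None and e.z > 0)
    n_inh = sum(1 for e in sig if e.z is not None and e.z < 0)
    n_nodir = len(sig) - n_act - n_inh
    if not sig:
        label = "not_significant"
    elif n_act > n_inh:
        label = "activated"
    elif n_inh > n_act:
        label = "inhibited"
    else:
        label = "no_direction"
    first = enrichments[0] if enrichments else None
    return PathwayLabel(
        pathway=first.pathway if first else "",
        group="",
        label=label,
        n_activated=n_act,
        n_inhibited=n_inh,
        n_nodir=n_nodir,
        n_total_significant=len(sig),
    )


def label_all(
    enrichments: Sequence[EnrichmentResult],
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> dict[tuple[str, str], PathwayLabel]:
    """Label every (pathway, group) from a flat enrichment list."""
    by_pathway: dict[str, list[EnrichmentResult]] = {}
    for e in enrichments:
        by_pathway.setdefault(e.pathway, []).append(e)
    out: dict[tuple[str, str], PathwayLabel] = {}
    for pid in sorted(by_pathway):
        for grp, datasets in groups.items():
            subset = [e for e in by_pathway[pid] if e.dataset in set(datasets)]
            lab = label_pathway(subset, alpha=alpha)
            lab.pathway = pid
            lab.group = grp
            out[(pid, grp)] = lab
    return out


def opposing_fraction(
    labels_a: Mapping[str, str], labels_b: Mapping[str, str], members: Iterable[str]
) -> float:
    """Fraction of member pathways with opposing states between two groups.

    Opposing means activated in one group and inhibited in the other, or
    significant (any label other than not_significant) in one and
    not_significant in the other.  Symmetric in the two groups.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("empty member set")
    n_opp = 0
    for pid in members:
        a, b = labels_a[pid], labels_b[pid]
        flip = {a, b} == {"activated", "inhibited"}
        onoff = ("not_significant" in (a, b)) and a != b
        if flip or onoff:
            n_opp += 1
    return n_opp / len(members)


def gwas_enrichment(
    program_genes: Iterable[str],
    gwas_set: Iterable[str],
    deg_tables: Mapping[str, pd.DataFrame],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """GWAS-gene enrichment of a program, per dataset.

    Per dataset: right-tailed Fisher test of the program's genes restricted
    to that dataset's DEGs against the GWAS set, with all the dataset's
    DEGs as background; BH across datasets.
    """
    prog = set(program_genes)
    gwas = set(gwas_set)
    rows = []
    for ds in sorted(deg_tables):
        degs = significant_genes(deg_tables[ds], fdr=fdr)
        if not degs:
            warnings.warn(f"dataset {ds!r} has no DEGs; skipped", stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, odds, k = fisher_enrich(prog & degs, gwas, degs)
        rows.append({"dataset": ds, "p": p, "odds_ratio": odds, "n_overlap": k})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = adjust(df["p"], "BH")
    return df


def program_overlap(
    partition_a: Mapping[str, str],
    partition_b: Mapping[str, str],
    background: Iterable[str],
    mode: str = "pathway",
    gene_content_a: Mapping[str, Iterable[str]] | None = None,
    gene_content_b: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Cross-partition cluster overlap, right-tailed Fisher + BH.

    ``mode='pathway'`` tests shared pathway ids directly; ``mode='gene'``
    tests the gene content of each cluster (for collections whose pathway
    names do not match), in which case per-cluster gene sets must be
    supplied.  ``background`` is the shared pathway (or gene) universe.
    """
    bg = set(background)
    if mode == "pathway":
        items_a = {c: {p for p, cl in partition_a.items() if cl == c} for c in set(partition_a.values())}
        items_b = {c: {p for p, cl in partition_b.items() if cl == c} for c in set(partition_b.values())}
        if not (set().union(*items_a.values()) <= bg and set().union(*items_b.values()) <= bg):
            raise ValueError("partitions contain items outside the background universe")
    elif mode == "gene":
        if gene_content_a is None or gene_content_b is None:
            raise ValueError("gene mode needs per-cluster gene sets")
        items_a = {c: set(g) & bg for c, g in gene_content_a.items()}
        items_b = {c: set(g) & bg for c, g in gene_content_b.items()}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for ca in sorted(items_a):
        for cb in sorted(items_b):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, odds, k = fisher_enrich(items_a[ca], items_b[cb], bg)
            rows.append(
                {"cluster_a": ca, "cluster_b": cb, "p": p, "odds_ratio": odds, "n_overlap": k}
            )
    df = pd.DataFrame(rows)
    df["fdr"] = adjust(df["p"], "BH")
    return df


# --- Newick export ----------------------------------------------------------


def export_tree(tree: ProgramTree) -> tuple[str, pd.DataFrame]:
    """Serialize the dendrogram as Newick plus an assignment table.

    Branch lengths are merge-height differences, so leaf depth equals the
    root merge height.
    """
    n = len(tree.leaves)
    link = tree.linkage

    def height(node: int) -> float:
        return 0.0 if node < n else float(link[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        if node < n:
            return f"{tree.leaves[node]}:{parent_h:.6g}"
        a, b = int(link[node - n, 0]), int(link[node - n, 1])
        h = height(node)
        return f"({render(a, h)},{render(b, h)}):{parent_h - h:.6g}"

    root = n + link.shape[0] - 1
    h = height(root)
    a, b = int(link[-1, 0]), int(link[-1, 1])
    newick = f"({render(a, h)},{render(b, h)});"
    rows = [
        {
            "pathway": pid,
            "program": tree.programs.get(pid, ""),
            "subprogram": tree.subprograms.get(pid, ""),
        }
        for pid in tree.leaves
    ]
    return newick, pd.DataFrame(rows)


def parse_newick(newick: str):
    """Parse a Newick string into a Bio.Phylo tree (the module's reader)."""
    from Bio import Phylo

    return Phylo.read(_io.StringIO(newick), "newick")
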