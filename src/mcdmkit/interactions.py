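"""Cell-cell interaction inference and multicellular disease models.

An interaction is one (sender cell type, UR/ligand, receiver cell type)
triple: the ligand is expressed by the sender and its regulatory-potential
profile is positively correlated (Pearson) with the receiver's DEG
membership.  Within one organ these interactions form a multicellular
disease model (MCDM, a directed multigraph over cell types); across organs,
restricted to extracellular-space ligands that can travel through blood,
they form the multi-organ MCDM (MO-MCDM).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust

__all__ = [
    "LigandTargetPrior",
    "CellPopulation",
    "expressed_genes",
    "ligand_activity",
    "infer_targets",
    "build_mcdm",
    "build_mo_mcdm",
    "rank_urs",
    "ur_target_severity",
    "prioritize_organs",
    "bootstrap_deg_counts",
]


@dataclass
class LigandTargetPrior:
    """Weighted ligand -> target-gene regulatory-potential prior.

    ``potential`` is a ligands x genes nonnegative weight matrix;
    ``location`` marks ligands found in extracellular space (transportable
    through blood); ``molecule_class`` carries the UR category used for
    candidate filtering.
    """

    potential: pd.DataFrame
    location: dict[str, str] = field(default_factory=dict)
    molecule_class: dict[str, str] = field(default_factory=dict)
    home_program: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.potential.to_numpy() < 0).any():
            raise ValueError("regulatory-potential weights must be nonnegative")
        if (self.potential.sum(axis=1) <= 0).any():
            raise ValueError("every ligand needs at least one positive-weight gene")

    @classmethod
    def from_edges(
        cls,
        edges: pd.DataFrame,
        location: Mapping[str, str] | None = None,
        molecule_class: Mapping[str, str] | None = None,
        home_program: Mapping[str, str] | None = None,
    ) -> "LigandTargetPrior":
        """Build from a (ligand, gene, weight) edge list."""
        mat = edges.pivot_table(
            index="ligand", columns="gene", values="weight", fill_value=0.0, aggfunc="sum"
        ).sort_index()
        return cls(
            potential=mat,
            location=dict(location or {}),
            molecule_class=dict(molecule_class or {}),
            home_program=dict(home_program or {}),
        )

    @property
    def ligands(self) -> list[str]:
        return list(self.potential.index)

    @property
    def genes(self) -> set[str]:
        return set(self.potential.columns)

    def targets_of(self, ligand: str) -> set[str]:
        """Positive-weight target genes of one ligand."""
        if ligand not in self.potential.index:
            raise KeyError(f"unknown ligand {ligand!r}")
        row = self.potential.loc[ligand]
        return set(row.index[row > 0])

    def secreted(self) -> set[str]:
        return {l for l, loc in self.location.items() if loc == "extracellular space"}

    def with_targets(self, ligand: str, weights: Mapping[str, float]) -> "LigandTargetPrior":
        """Copy of the prior with one ligand's target weights replaced."""
        mat = self.potential.copy()
        for g in weights:
            if g not in mat.columns:
                mat[g] = 0.0
        mat.loc[ligand] = 0.0
        for g, w in weights.items():
            mat.loc[ligand, g] = w
        return LigandTargetPrior(
            potential=mat,
            location=dict(self.location),
            molecule_class=dict(self.molecule_class),
            home_program=dict(self.home_program),
        )


@dataclass
class CellPopulation:
    """Per-(organ, cell type) inputs to interaction inference."""

    expressed: set[str]
    degs: set[str]
    n_cells: int = 0


def expressed_genes(values: pd.DataFrame | np.ndarray, genes: Sequence[str] | None = None,
                    threshold: float = 1e-5) -> set[str]:
    """Expressed genes of one cell population.

    ``values`` is cells x genes on the normalized log10(x+1) scale; each
    gene whose mean back-transformed expression (10^x - 1) reaches
    ``threshold`` is called expressed.  Warns when the result falls outside
    the 5,000-10,000 band recommended for interaction inference.
    """
    if isinstance(values, pd.DataFrame):
        genes = list(values.columns)
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if genes is None:
            raise ValueError("gene names required with an array input")
    if arr.shape[0] == 0:
        raise ValueError("empty cell population")
    mean_linear = (np.power(10.0, arr) - 1.0).mean(axis=0)
    out = {g for g, m in zip(genes, mean_linear) if m >= threshold}
    if not 5000 <= len(out) <= 10000:
        warnings.warn(
            f"{len(out)} expressed genes, outside the recommended 5,000-10,000 band",
            stacklevel=2,
        )
    return out


def ligand_activity(
    deg_genes: Iterable[str],
    receiver_expressed: Iterable[str],
    prior: LigandTargetPrior,
) -> pd.Series:
    """Per-ligand activity: Pearson correlation of prior potential with DEG membership.

    The candidate universe is the receiver's expressed genes intersected
    with the prior's gene space; the response is the 0/1 DEG-membership
    vector over that universe.  Ligands whose correlation is undefined
    (zero variance on either side) are dropped with a warning.
    """
    universe = sorted(set(receiver_expressed) & prior.genes)
    if not universe:
        raise ValueError("empty candidate universe (expressed ∩ prior genes)")
    y = np.array([1.0 if g in set(deg_genes) else 0.0 for g in universe])
    out = {}
    if y.std() == 0:
        warnings.warn("constant DEG-membership vector; all ligands skipped", stacklevel=2)
        return pd.Series(out, dtype=float)
    pot = prior.potential[universe]
    for lig in prior.ligands:
        x = pot.loc[lig].to_numpy(dtype=float)
        if x.std() == 0:
            warnings.warn(f"ligand {lig!r} has zero-variance potential; skipped", stacklevel=2)
            continue
        out[lig] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, dtype=float)


def infer_targets(
    ligand: str,
    deg_genes: Iterable[str],
    prior: LigandTargetPrior,
    top_k: int = 200,
) -> set[str]:
    """DEGs among the ligand's ``top_k`` highest-potential genes.

    Weight ties at the k-boundary are all included, so the result is
    independent of column order.
    """
    row = prior.potential.loc[ligand] if ligand in prior.potential.index else None
    if row is None:
        raise KeyError(f"unknown ligand {ligand!r}")
    pos = row[row > 0].sort_values(ascending=False)
    if len(pos) > top_k:
        cutoff = pos.iloc[top_k - 1]
        pos = pos[pos >= cutoff]
    return set(deg_genes) & set(pos.index)


def _infer_edges(
    graph: nx.MultiDiGraph,
    senders: Mapping[tuple[str, str], CellPopulation],
    receivers: Mapping[tuple[str, str], CellPopulation],
    prior: LigandTargetPrior,
    pcc_min: float,
    top_k: int,
    ligand_whitelist: set[str] | None = None,
    cross_organ_only: bool = False,
) -> None:
    for s_node, sender in sorted(senders.items()):
        for r_node, receiver in sorted(receivers.items()):
            if cross_organ_only and s_node[0] == r_node[0]:
                continue
            if not receiver.degs:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    act = ligand_activity(receiver.degs, receiver.expressed, prior)
                except ValueError:
                    continue
            for lig in act.index:
                if ligand_whitelist is not None and lig not in ligand_whitelist:
                    continue
                if lig not in sender.expressed:
                    continue
                if act[lig] <= pcc_min:
                    continue
                targets = infer_targets(lig, receiver.degs, prior, top_k=top_k)
                if not targets:
                    continue
                graph.add_edge(
                    s_node, r_node, key=lig,
                    ligand=lig, targets=frozenset(targets), activity=float(act[lig]),
                )


def build_mcdm(
    populations: Mapping[str | tuple[str, str], CellPopulation],
    prior: LigandTargetPrior,
    organ: str = "organ",
    pcc_min: float = 0.0,
    top_k: int = 200,
) -> nx.MultiDiGraph:
    """Multicellular disease model for one organ.

    ``populations`` maps cell-type id (or (organ, cell type)) to its
    expressed-gene set, DEG set and cell count (see
    :func:`expressed_genes` and the DEG intake).  Every ordered
    sender -> receiver pair, self-pairs (autocrine loops) included, is
    tested; edges require the ligand expressed in the sender and activity
    above ``pcc_min``.
    """
    pops: dict[tuple[str, str], CellPopulation] = {}
    for key, pop in populations.items():
        node = key if isinstance(key, tuple) else (organ, key)
        pops[node] = pop
    if len(pops) == 1:
        warnings.warn("single cell type: graph will contain self-loops only", stacklevel=2)
    graph = nx.MultiDiGraph()
    for node, pop in sorted(pops.items()):
        graph.add_node(
            node, n_cells=pop.n_cells,
            expressed=frozenset(pop.expressed), degs=frozenset(pop.degs),
        )
    _infer_edges(graph, pops, pops, prior, pcc_min, top_k)
    return graph


def build_mo_mcdm(
    mcdms: Sequence[nx.MultiDiGraph],
    prior: LigandTargetPrior,
    pcc_min: float = 0.0,
    top_k: int = 200,
) -> nx.MultiDiGraph:
    """Multi-organ MCDM: cross-organ edges by extracellular-space ligands.

    Pools the node populations of the per-organ models and infers
    interactions between all ordered pairs of nodes in *different* organs,
    keeping only ligands located in extracellular space (blood
    transportable).  Within-organ edges are excluded.
    """
    pops: dict[tuple[str, str], CellPopulation] = {}
    graph = nx.MultiDiGraph()
    for g in mcdms:
        for node, attrs in g.nodes(data=True):
            pops[node] = CellPopulation(
                expressed=set(attrs["expressed"]),
                degs=set(attrs["degs"]),
                n_cells=attrs.get("n_cells", 0),
            )
    for node, pop in sorted(pops.items()):
        graph.add_node(
            node, n_cells=pop.n_cells,
            expressed=frozenset(pop.expressed), degs=frozenset(pop.degs),
        )
    _infer_edges(
        graph, pops, pops, prior, pcc_min, top_k,
        ligand_whitelist=prior.secreted(), cross_organ_only=True,
    )
    return graph


def rank_urs(graph: nx.MultiDiGraph) -> pd.DataFrame:
    """Rank URs of an MCDM/MO-MCDM.

    Primary key: total downstream target genes summed over the UR's edges
    (each receiver counted separately); secondary key: number of distinct
    (organ, cell type) receivers; final tie-break: UR id.
    """
    totals: dict[str, int] = {}
    receivers: dict[str, set] = {}
    for u, v, data in graph.edges(data=True):
        lig = data["ligand"]
        totals[lig] = totals.get(lig, 0) + len(data["targets"])
        receivers.setdefault(lig, set()).add(v)
    rows = [
        {"ur": lig, "n_targets": totals[lig], "n_receivers": len(receivers[lig])}
        for lig in totals
    ]
    if not rows:
        return pd.DataFrame(columns=["ur", "n_targets", "n_receivers", "rank"])
    df = pd.DataFrame(rows).sort_values(
        ["n_targets", "n_receivers", "ur"], ascending=[False, False, True],
        kind="mergesort",
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def ur_target_severity(
    matrix,
    targets: Iterable[str],
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Test UR-target expression against disease-severity groups.

    Each cell is standardized to mean 0 / sd 1 over all genes, the mean
    standardized expression of the target genes is computed per cell, and
    all severity-group pairs are compared with two-sided Wilcoxon rank-sum
    tests, Holm-adjusted within the family.
    """
    genes = [g for g in matrix.var_names if g in set(targets)]
    if not genes:
        raise ValueError("target set does not intersect measured genes")
    groups = {k: list(v) for k, v in groups.items()}
    sized = {k: v for k, v in groups.items() if len(v) >= 3}
    if len(sized) < 2:
        raise ValueError("need at least 2 groups with >= 3 cells")
    x = matrix.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    idx = {c: i for i, c in enumerate(matrix.obs_names)}
    gcols = [list(matrix.var_names).index(g) for g in genes]
    score = {k: z[np.ix_([idx[c] for c in v], gcols)].mean(axis=1) for k, v in sized.items()}
    rows = []
    for a, b in itertools.combinations(sorted(sized), 2):
        res = stats.mannwhitneyu(score[a], score[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    df["p_holm"] = adjust(df["p"], "Holm")
    return df


def bootstrap_deg_counts(
    matrix,
    organ_col: str = "organ",
    state_col: str = "disease_state",
    sick: str = "sick",
    healthy: str = "healthy",
    n_cells: int = 40,
    n_rounds: int = 10,
    seed: int = 0,
    fdr: float = 0.05,
) -> dict[str, list[int]]:
    """Bootstrap DEG counts per organ for organ prioritization.

    For each organ, ``n_cells`` cells are resampled with replacement from
    each of the sick and healthy groups for ``n_rounds`` rounds, a
    rank-sum DE test is run on each round, and the number of genes at
    FDR < ``fdr`` is recorded.
    """
    from .enrichment import simple_de

    rng = np.random.default_rng(seed)
    out: dict[str, list[int]] = {}
    obs = matrix.obs
    for organ in sorted(obs[organ_col].unique()):
        cells_s = list(obs.index[(obs[organ_col] == organ) & (obs[state_col] == sick)])
        cells_h = list(obs.index[(obs[organ_col] == organ) & (obs[state_col] == healthy)])
        if not cells_s or not cells_h:
            continue
        counts = []
        for _ in range(n_rounds):
            a = list(rng.choice(cells_s, size=n_cells, replace=True))
            b = list(rng.choice(cells_h, size=n_cells, replace=True))
            tab = simple_de(matrix, a, b, dataset=organ)
            counts.append(int((tab["fdr"] < fdr).sum()))
        out[organ] = counts
    return out


def prioritize_organs(
    deg_counts_per_bootstrap: Mapping[str, Sequence[int]],
    n_keep: int = 5,
    statistic: str = "median",
    quality_cells: Mapping[str, int] | None = None,
    min_quality_cells: int = 25,
) -> list[str]:
    """Rank organs by bootstrap DEG counts and keep the top ``n_keep``.

    Organs with ``quality_cells`` at or below ``min_quality_cells`` (too
    few cells passing the 10,000-read criterion) are excluded before
    ranking.  The cross-round statistic is the median (configurable to
    mean).
    """
    stat = np.median if statistic == "median" else np.mean
    eligible = {
        organ: counts
        for organ, counts in deg_counts_per_bootstrap.items()
        if len(counts) >= 1
        and (quality_cells is None or quality_cells.get(organ, 0) > min_quality_cells)
    }
    ranked = sorted(eligible, key=lambda o: (-float(stat(eligible[o])), o))
    if len(ranked) < n_keep:
        warnings.warn(
            f"only {len(ranked)} organs eligible (< n_keep={n_keep}); returning all",
            stacklevel=2,
        )
    return ranked[:n_keep]
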