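"""Core enrichment statistics shared by every pipeline stage.

Gene-set enrichment is a right-tailed Fisher exact test (hypergeometric
tail) on the 2x2 table formed by a query set, a target set and an explicit
background universe.  Directional pathway activation is summarized by a
consistency z score over signed pathway annotations, evidence across
datasets is pooled with Fisher's method, and multiplicity is handled with
Benjamini-Hochberg or Holm corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayDB",
    "EnrichmentResult",
    "fisher_enrich",
    "activation_z",
    "ur_activation_z",
    "enrich_all",
    "combine_fisher",
    "adjust",
    "cap_degs",
    "simple_de",
    "significant_genes",
]

#: columns every differential-expression (DEG) table must carry.
DEG_COLUMNS = ("gene", "logFC", "pvalue", "fdr", "dataset")


@dataclass
class PathwayDB:
    """A pathway gene-set collection, optionally with activation signs.

    ``signs[pathway][gene]`` is the expected direction (+1/-1) of ``gene``
    when the pathway is activated; signs are only defined on member genes.
    """

    sets: dict[str, set[str]]
    signs: dict[str, dict[str, int]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
        for pid, sgn in self.signs.items():
            extra = set(sgn) - self.sets.get(pid, set())
            if extra:
                raise ValueError(
                    f"pathway {pid!r} carries signs for non-member genes {sorted(extra)[:3]}"
                )

    @property
    def genes(self) -> set[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """One (pathway, dataset) enrichment record."""

    pathway: str
    dataset: str
    p: float
    odds_ratio: float
    z: float | None
    n_overlap: int
    significant: bool = False


def fisher_enrich(
    query: Iterable[str], target: Iterable[str], background: Iterable[str]
) -> tuple[float, float, int]:
    """Right-tailed Fisher exact test of ``query`` against ``target``.

    The 2x2 table is (overlap, query-only, target-only, neither) inside
    ``background``.  Returns ``(p, odds_ratio, n_overlap)``.  The p-value is
    the exact hypergeometric upper tail; the odds ratio is the sample OR
    with a 0.5 Haldane correction applied only when a cell is zero (the
    p-value is never corrected).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    q = set(query) & bg
    t = set(target) & bg
    if not q:
        warnings.warn("empty query set: p = 1 by convention", stacklevel=2)
        return 1.0, np.nan, 0
    k = len(q & t)
    n_bg, n_q, n_t = len(bg), len(q), len(t)
    # P(X >= k) for X ~ Hypergeom(N=n_bg, K=n_t, n=n_q)
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_t, n_q))
    p = min(p, 1.0)
    a, b, c, d = k, n_q - k, n_t - k, n_bg - n_q - n_t + k
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return p, float(odds), k


def activation_z(
    pathway_signs: Mapping[str, int], deg_table: pd.DataFrame
) -> float | None:
    """Directional activation score of a signed pathway given a DEG table.

    Over pathway genes that are DEGs and carry a sign annotation, a DEG is
    *consistent* when sign(logFC) equals the annotation.  The score is
    ``(n_consistent - n_inconsistent) / sqrt(n_consistent + n_inconsistent)``;
    ``None`` (undefined) when no signed gene overlaps the DEGs.
    """
    if not pathway_signs or deg_table.empty:
        return None
    fc = deg_table.set_index("gene")["logFC"]
    fc = fc[~fc.index.duplicated()]
    common = [g for g in pathway_signs if g in fc.index and fc[g] != 0]
    if not common:
        return None
    obs = np.sign(fc[common].to_numpy())
    exp = np.array([pathway_signs[g] for g in common])
    n_cons = int((obs == exp).sum())
    n_incons = len(common) - n_cons
    return (n_cons - n_incons) / np.sqrt(len(common))


def ur_activation_z(targets: Iterable[str], deg_table: pd.DataFrame) -> float | None:
    """Activation z of an upstream regulator from its downstream targets.

    Targets are expected to move up when the UR is active, so the score is
    the all-(+1)-signed :func:`activation_z` over the UR's target genes.
    """
    return activation_z({g: 1 for g in targets}, deg_table)


def significant_genes(deg_table: pd.DataFrame, fdr: float = 0.05) -> set[str]:
    """Genes called differentially expressed at the given FDR cutoff."""
    return set(deg_table.loc[deg_table["fdr"] < fdr, "gene"])


def enrich_all(
    deg_tables: Mapping[str, pd.DataFrame],
    pathway_db: PathwayDB,
    alpha: float = 0.05,
    background: Mapping[str, Iterable[str]] | Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Fisher enrichment + activation z for every (dataset, pathway) pair.

    ``background`` is the measured-gene universe: a per-dataset mapping, one
    shared iterable, or ``None`` (falls back to pathway genes plus the
    dataset's own genes).  Significance is flagged at raw ``p < alpha``; no
    FDR is applied at this stage.
    """
    results: list[EnrichmentResult] = []
    for ds in sorted(deg_tables):
        table = deg_tables[ds]
        degs = significant_genes(table)
        if not degs:
            warnings.warn(f"dataset {ds!r} has no DEGs; all p = 1", stacklevel=2)
        if background is None:
            bg: set[str] = pathway_db.genes | set(table["gene"])
        elif isinstance(background, Mapping):
            bg = set(background[ds])
        else:
            bg = set(background)
        for pid in sorted(pathway_db.sets):
            genes = pathway_db.sets[pid]
            if degs:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p, odds, k = fisher_enrich(degs, genes, bg)
            else:
                p, odds, k = 1.0, np.nan, 0
            z = activation_z(pathway_db.signs.get(pid, {}), table)
            results.append(
                EnrichmentResult(pid, ds, p, odds, z, k, significant=p < alpha)
            )
    return results


def combine_fisher(p_list: Sequence[float]) -> float:
    """Combine independent p-values with Fisher's method.

    ``X2 = -2 sum(ln p_i)`` referred to chi-square with ``2k`` degrees of
    freedom; returns the upper-tail probability.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def adjust(p_list: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg or Holm."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return p
    key = {"BH": "fdr_bh", "Holm": "holm", "holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def cap_degs(deg_table: pd.DataFrame, n: int = 5000) -> pd.DataFrame:
    """Keep the ``n`` lowest-FDR rows of a DEG table.

    FDR ties at the boundary are broken by larger absolute log fold change,
    then by gene id, so the cap is deterministic.
    """
    if len(deg_table) <= n:
        return deg_table
    order = deg_table.assign(_absfc=-deg_table["logFC"].abs()).sort_values(
        ["fdr", "_absfc", "gene"], kind="mergesort"
    )
    return order.head(n).drop(columns="_absfc")


def simple_de(
    matrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    dataset: str = "de",
    layer: str | None = None,
) -> pd.DataFrame:
    """Rank-sum differential expression between two cell groups.

    A lightweight per-gene two-sided Wilcoxon rank-sum test on the
    normalized layer of an AnnData, with BH FDR and a log2 fold change of
    back-transformed group means (pseudocount 1).  Returns a full table with
    one row per gene (use :func:`significant_genes` to threshold).
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    sub_a = matrix[list(group_a)]
    sub_b = matrix[list(group_b)]
    xa = _dense(sub_a, layer)
    xb = _dense(sub_b, layer)
    genes = list(matrix.var_names)
    method = "exact" if max(xa.shape[0], xb.shape[0]) <= 25 else "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided", method=method)
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    # back-transform log10(x+1) to linear scale for the fold change
    lin_a = np.power(10.0, xa).mean(axis=0)
    lin_b = np.power(10.0, xb).mean(axis=0)
    logfc = np.log2(lin_a / lin_b)
    fdr = adjust(pvals, "BH")
    return pd.DataFrame(
        {"gene": genes, "logFC": logfc, "pvalue": pvals, "fdr": fdr, "dataset": dataset}
    )


def _dense(adata, layer: str | None) -> np.ndarray:
    x = adata.layers[layer] if layer else adata.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)
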