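"""Synthetic ground-truth generators for every pipeline stage.

The generators plant known structure -- pathway programs with controlled
gene sharing, upstream regulators (URs) with program-biased target sets,
DEG tables driven by active URs, negative-binomial count matrices with
known cell types, and treatment cohorts with a designated "takeover" UR --
so that every downstream inference step can be scored against truth
without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .enrichment import DEG_COLUMNS, PathwayDB
from .interactions import LigandTargetPrior

__all__ = [
    "SyntheticTruth",
    "generate_pathway_db",
    "generate_prior",
    "generate_deg_tables",
    "generate_expression",
    "generate_treatment_cohort",
    "inflammation_scenario",
    "takeover_scenario",
]

MOLECULE_CLASSES = (
    "cytokine",
    "growth factor",
    "G-protein coupled receptor",
    "ligand-dependent nuclear receptor",
    "transmembrane receptor",
    "other",
)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators; the acceptance oracle.

    ``ur_activity`` maps ``(group_id, ur_id)`` to +1 (active, up), -1
    (active, down) or 0 (inactive).  Regenerating with the same seed
    reproduces every field bit-identically.
    """

    program_of_pathway: dict[str, str] = field(default_factory=dict)
    ur_activity: dict[tuple[str, str], int] = field(default_factory=dict)
    ur_targets: dict[str, set[str]] = field(default_factory=dict)
    cell_labels: dict[str, str] = field(default_factory=dict)
    takeover_ur: str | None = None
    seed: int = 0
    gene_universe: set[str] = field(default_factory=set)


def _check(cond: bool, what: str) -> None:
    if not cond:
        raise ValueError(f"invalid configuration: {what}")


def generate_pathway_db(
    n_programs: int = 2,
    pathways_per_program: int = 10,
    genes_per_pathway: int = 50,
    within_share: float = 0.5,
    between_share: float = 0.05,
    seed: int = 0,
    n_filler_genes: int = 0,
    positive_sign_fraction: float = 0.8,
) -> tuple[PathwayDB, SyntheticTruth]:
    """Plant programs of gene-sharing pathways.

    Pathways within a program share on expectation ``within_share`` of
    their genes (a program-wide core), and pathways across programs share
    ``between_share`` (a globally shared block).  Every gene gets a +-1
    activation-direction sign; ``positive_sign_fraction`` of genes are
    annotated +1 (rise under pathway activation), matching the skew of
    curated signed collections and keeping a pathway's directional call
    stable under resampling of its DEG overlap.  ``n_filler_genes`` adds
    measured genes that belong to no pathway, widening the background
    universe the way a genome-wide assay does.
    """
    _check(n_programs >= 2, "n_programs must be >= 2")
    _check(pathways_per_program >= 2, "pathways_per_program must be >= 2")
    _check(genes_per_pathway >= 5, "genes_per_pathway must be >= 5")
    _check(0 <= between_share < within_share <= 1, "within_share must exceed between_share")
    rng = np.random.default_rng(seed)

    n_between = round(between_share * genes_per_pathway)
    n_core = round(within_share * genes_per_pathway) - n_between
    n_private = genes_per_pathway - n_core - n_between

    counter = 0

    def new_genes(n: int) -> list[str]:
        nonlocal counter
        out = [f"G{counter + i:05d}" for i in range(n)]
        counter += n
        return out

    shared = new_genes(n_between)
    sets: dict[str, set[str]] = {}
    truth = SyntheticTruth(seed=seed)
    for p in range(n_programs):
        prog = f"P{p + 1}"
        core = new_genes(n_core)
        for j in range(pathways_per_program):
            pid = f"PW{p + 1}.{j + 1:02d}"
            private = new_genes(n_private)
            sets[pid] = set(shared) | set(core) | set(private)
            truth.program_of_pathway[pid] = prog
    new_genes(n_filler_genes)
    universe = [f"G{i:05d}" for i in range(counter)]
    p_pos = positive_sign_fraction
    gene_sign = {
        g: int(s)
        for g, s in zip(universe, rng.choice([-1, 1], size=counter, p=[1 - p_pos, p_pos]))
    }
    signs = {pid: {g: gene_sign[g] for g in genes} for pid, genes in sets.items()}
    truth.gene_universe = set(universe)
    db = PathwayDB(sets=sets, signs=signs, source="synthetic")
    return db, truth


def generate_prior(
    pathway_db: PathwayDB,
    n_ligands: int = 6,
    targets_per_ligand: int = 40,
    secreted_fraction: float = 1.0,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    pref_within: float = 0.8,
) -> LigandTargetPrior:
    """Draw a ligand->target regulatory-potential prior over the pathway genes.

    Each ligand is seeded on one program (round-robin) and draws
    ``pref_within`` of its targets from that program's genes, the rest from
    elsewhere in the universe.  The first ``floor(secreted_fraction *
    n_ligands)`` ligands are flagged as located in extracellular space.
    When ``truth`` is given, ``truth.ur_targets`` is filled in.
    """
    if not pathway_db.sets:
        raise ValueError("empty pathway_db")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.gene_universe) if truth is not None and truth.gene_universe else sorted(pathway_db.genes)
    _check(targets_per_ligand <= len(universe), "targets_per_ligand exceeds gene universe")

    if truth is not None and truth.program_of_pathway:
        programs = sorted(set(truth.program_of_pathway.values()))
        pool = {
            prog: sorted(
                set().union(
                    *(
                        pathway_db.sets[pid]
                        for pid, pr in truth.program_of_pathway.items()
                        if pr == prog
                    )
                )
            )
            for prog in programs
        }
    else:
        programs = sorted(pathway_db.sets)
        pool = {pid: sorted(genes) for pid, genes in pathway_db.sets.items()}

    ligands = [f"UR{i + 1:02d}" for i in range(n_ligands)]
    n_secreted = math.floor(secreted_fraction * n_ligands)
    rows = []
    location, mol_class, home = {}, {}, {}
    for i, lig in enumerate(ligands):
        prog = programs[i % len(programs)]
        home[lig] = prog
        inside = pool[prog]
        outside = sorted(set(universe) - set(inside))
        n_in = min(round(pref_within * targets_per_ligand), len(inside))
        n_out = min(targets_per_ligand - n_in, len(outside))
        n_in = targets_per_ligand - n_out
        picked = list(rng.choice(inside, size=n_in, replace=False))
        if n_out:
            picked += list(rng.choice(outside, size=n_out, replace=False))
        weights = rng.uniform(0.5, 1.5, size=len(picked))
        for g, w in zip(picked, weights):
            rows.append((lig, g, float(w)))
        location[lig] = "extracellular space" if i < n_secreted else "other"
        mol_class[lig] = str(rng.choice(MOLECULE_CLASSES))
        if truth is not None:
            truth.ur_targets[lig] = set(picked)
    edges = pd.DataFrame(rows, columns=["ligand", "gene", "weight"])
    return LigandTargetPrior.from_edges(edges, location=location, molecule_class=mol_class, home_program=home)


def _planted_pvals(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    # Beta(0.01, 1) truncated to (0, 0.05): inverse-CDF sampling.
    u = rng.uniform(size=n)
    p = 0.05 * u ** (1.0 / 0.01)
    p = np.clip(p, np.finfo(float).tiny, None)
    fdr = np.minimum(10.0 * p, 0.049)
    return p, fdr


def generate_deg_tables(
    truth: SyntheticTruth,
    prior: LigandTargetPrior,
    groups: Sequence[str],
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
    include_nonsignificant: bool = False,
) -> dict[str, pd.DataFrame]:
    """DEG tables driven by the planted UR activity.

    For each group, targets of active URs become DEGs whose sign matches
    the UR's direction (each dropped independently at ``fn_rate``);
    non-target genes become DEGs at ``fp_rate`` with random sign.  Planted
    and false-positive rows all carry FDR < 0.05.  With
    ``include_nonsignificant=True`` the remaining universe genes are added
    as null rows (p ~ U(0.05, 1)) so the table doubles as the measured
    background.
    """
    for (grp, ur), act in truth.ur_activity.items():
        if act != 0 and ur not in prior.ligands:
            raise ValueError(f"unknown UR id {ur!r} in ur_activity")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.gene_universe) if truth.gene_universe else sorted(prior.genes)
    tables: dict[str, pd.DataFrame] = {}
    for grp in groups:
        sign_of: dict[str, int] = {}
        for (g, ur), act in sorted(truth.ur_activity.items()):
            if g != grp or act == 0:
                continue
            for t in sorted(prior.targets_of(ur)):
                if rng.uniform() < fn_rate:
                    continue
                sign_of.setdefault(t, act)
        non_targets = [g for g in universe if g not in sign_of]
        if fp_rate > 0:
            hits = rng.uniform(size=len(non_targets)) < fp_rate
            for g, h in zip(non_targets, hits):
                if h:
                    sign_of[g] = int(rng.choice([-1, 1]))
        genes = sorted(sign_of)
        p, fdr = _planted_pvals(rng, len(genes))
        logfc = np.array([sign_of[g] for g in genes]) * rng.uniform(1.0, 3.0, len(genes))
        tab = pd.DataFrame(
            {"gene": genes, "logFC": logfc, "pvalue": p, "fdr": fdr, "dataset": grp}
        )
        if include_nonsignificant:
            rest = sorted(set(universe) - set(genes))
            pn = rng.uniform(0.05, 1.0, len(rest))
            null = pd.DataFrame(
                {
                    "gene": rest,
                    "logFC": rng.normal(0, 0.1, len(rest)),
                    "pvalue": pn,
                    "fdr": np.minimum(1.0, pn * 1.5),
                    "dataset": grp,
                }
            )
            tab = pd.concat([tab, null], ignore_index=True)
        tables[grp] = tab[list(DEG_COLUMNS)]
    return tables


def generate_expression(
    cell_types: Sequence[str],
    n_cells_per_type: int | Sequence[int] = 100,
    n_genes: int = 200,
    dispersion: float = 0.3,
    separation: float = 2.0,
    seed: int = 0,
) -> tuple[ad.AnnData, pd.DataFrame, SyntheticTruth]:
    """Negative-binomial counts with known cell-type labels.

    Counts follow NB(mean mu, variance mu + dispersion * mu^2) with
    cell-type mean vectors whose pairwise log-scale distance scales with
    ``separation``.  Returns the AnnData (X = log10(CP10K + 1), raw counts
    in ``layers['counts']``), a noiseless per-type reference profile
    (genes x types), and the truth with per-cell labels.
    """
    _check(separation > 0, "separation must be > 0")
    _check(dispersion > 0, "dispersion must be > 0")
    rng = np.random.default_rng(seed)
    if isinstance(n_cells_per_type, int):
        n_cells_per_type = [n_cells_per_type] * len(cell_types)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.normal(1.0, 0.5, size=n_genes)
    n_sig = max(3, n_genes // 10)
    mu = {}
    for t, ct in enumerate(cell_types):
        shift = np.zeros(n_genes)
        sig = rng.choice(n_genes, size=n_sig, replace=False)
        shift[sig] = separation * rng.choice([-1.0, 1.0], size=n_sig)
        mu[ct] = np.exp(base + shift)
    r = 1.0 / dispersion
    counts, labels, cell_ids = [], [], []
    for ct, n_cells in zip(cell_types, n_cells_per_type):
        for i in range(n_cells):
            lam = rng.gamma(shape=r, scale=mu[ct] / r)
            counts.append(rng.poisson(lam))
            cid = f"{ct}_{i:04d}"
            cell_ids.append(cid)
            labels.append(ct)
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = np.log10(counts / totals * 1e4 + 1.0)
    obs = pd.DataFrame(
        {
            "organ": "synthetic",
            "subject": "s1",
            "disease_state": "healthy",
            "severity": 0,
            "reads": (counts.sum(axis=1) * 10).astype(int),
            "transcripts": counts.sum(axis=1).astype(int),
            "genes_detected": (counts > 0).sum(axis=1).astype(int),
            "mito_fraction": 0.01,
            "true_type": labels,
        },
        index=cell_ids,
    )
    adata = ad.AnnData(X=norm, obs=obs, var=pd.DataFrame(index=genes))
    adata.layers["counts"] = counts
    reference = pd.DataFrame({ct: mu[ct] for ct in cell_types}, index=genes)
    truth = SyntheticTruth(seed=seed, cell_labels=dict(zip(cell_ids, labels)))
    truth.gene_universe = set(genes)
    return adata, reference, truth


# --- treatment cohorts ------------------------------------------------------

COHORT_CONTRASTS = (
    "resp_vs_ctrl",
    "nonresp_vs_ctrl",
    "resp_after_vs_ctrl",
    "nonresp_after_vs_ctrl",
    "nonresp_after_vs_resp_after",
)


def _rows(rng, genes_signs: Mapping[str, float], dataset: str) -> pd.DataFrame:
    genes = sorted(genes_signs)
    p, fdr = _planted_pvals(rng, len(genes))
    return pd.DataFrame(
        {
            "gene": genes,
            "logFC": [genes_signs[g] for g in genes],
            "pvalue": p,
            "fdr": fdr,
            "dataset": dataset,
        }
    )


def generate_treatment_cohort(
    truth: SyntheticTruth,
    prior: LigandTargetPrior,
    anchor_ur: str,
    takeover_ur: str | None,
    overlap: float = 0.7,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Responder/non-responder cohort with a planted takeover UR.

    The anchor UR (the treated target, e.g. an anti-TNF scenario) drives
    its targets up in both arms before treatment; after treatment its
    effect vanishes in responders.  The designated ``takeover_ur``
    satisfies all three takeover criteria by construction -- same-sign
    activation z in both arms, stronger own fold change in non-responders
    vs control, and a significant same-direction fold change in treated
    non-responders vs treated responders -- while every other UR violates
    at least one.  ``takeover_ur=None`` plants no takeover.
    """
    if anchor_ur not in prior.ligands:
        raise ValueError(f"unknown anchor UR {anchor_ur!r}")
    anchor_targets = prior.targets_of(anchor_ur)
    if takeover_ur is not None:
        if takeover_ur not in prior.ligands:
            raise ValueError(f"unknown takeover UR {takeover_ur!r}")
        share = len(prior.targets_of(takeover_ur) & anchor_targets) / len(anchor_targets)
        if share + 1e-12 < overlap:
            raise ValueError(
                f"takeover UR shares only {share:.2f} of anchor targets (< overlap {overlap})"
            )
    rng = np.random.default_rng(seed)
    truth.takeover_ur = takeover_ur

    others = [u for u in sorted(prior.ligands) if u not in (anchor_ur, takeover_ur)]
    up = lambda: float(rng.uniform(1.0, 2.0))  # noqa: E731

    tabs: dict[str, dict[str, float]] = {c: {} for c in COHORT_CONTRASTS}

    def put(contrast: str, gene: str, fc: float) -> None:
        tabs[contrast][gene] = fc

    # anchor: active both arms before treatment, silenced in responders after;
    # its own FC is NOT significant in treated nonresp-vs-resp (fails c3).
    for t in sorted(anchor_targets):
        put("resp_vs_ctrl", t, up())
        put("nonresp_vs_ctrl", t, up())
        put("nonresp_after_vs_ctrl", t, up())
    put("resp_vs_ctrl", anchor_ur, 2.0)
    put("nonresp_vs_ctrl", anchor_ur, 2.1)

    if takeover_ur is not None:
        for t in sorted(prior.targets_of(takeover_ur)):
            put("resp_vs_ctrl", t, tabs["resp_vs_ctrl"].get(t, up()))
            put("nonresp_vs_ctrl", t, tabs["nonresp_vs_ctrl"].get(t, up()))
            put("nonresp_after_vs_resp_after", t, up())
        put("resp_vs_ctrl", takeover_ur, 0.5)
        put("nonresp_vs_ctrl", takeover_ur, 1.5)  # c2: 1.5 > 0.5
        put("nonresp_after_vs_resp_after", takeover_ur, 1.2)  # c3

    # decoys cycle through the three failure modes
    for i, ur in enumerate(others):
        mode = i % 3
        targets = sorted(prior.targets_of(ur))
        if mode == 0:  # c1 fails: opposite activation signs across arms
            for t in targets:
                put("resp_vs_ctrl", t, tabs["resp_vs_ctrl"].get(t, up()))
                put("nonresp_vs_ctrl", t, tabs["nonresp_vs_ctrl"].get(t, -up()))
            put("resp_vs_ctrl", ur, 0.8)
            put("nonresp_vs_ctrl", ur, 1.2)
            put("nonresp_after_vs_resp_after", ur, 0.9)
        elif mode == 1:  # c2 fails: weaker FC in non-responders
            for t in targets:
                put("resp_vs_ctrl", t, tabs["resp_vs_ctrl"].get(t, up()))
                put("nonresp_vs_ctrl", t, tabs["nonresp_vs_ctrl"].get(t, up()))
            put("resp_vs_ctrl", ur, 1.4)
            put("nonresp_vs_ctrl", ur, 0.6)
            put("nonresp_after_vs_resp_after", ur, 0.9)
        else:  # c3 fails: no significant after-treatment contrast row
            for t in targets:
                put("resp_vs_ctrl", t, tabs["resp_vs_ctrl"].get(t, up()))
                put("nonresp_vs_ctrl", t, tabs["nonresp_vs_ctrl"].get(t, up()))
            put("resp_vs_ctrl", ur, 0.7)
            put("nonresp_vs_ctrl", ur, 1.3)

    return {c: _rows(rng, d, c)[list(DEG_COLUMNS)] for c, d in tabs.items()}


# --- ready-made scenarios ---------------------------------------------------


@dataclass
class Scenario:
    """A fully wired synthetic study: inputs plus their ground truth."""

    pathway_db: PathwayDB
    truth: SyntheticTruth
    prior: LigandTargetPrior
    deg_tables: dict[str, pd.DataFrame]
    groups: dict[str, list[str]]


def inflammation_scenario(
    seed: int = 0,
    n_datasets_per_group: int = 4,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    pathways_per_program: int = 10,
    genes_per_pathway: int = 50,
    targets_per_ligand: int = 40,
    n_ligands: int = 6,
    mixed_off: bool = True,
) -> Scenario:
    """Two-program inflamed vs non-inflamed study.

    Program P1 is the pro-inflammatory program: its seeded URs are active
    in every "inflamed" dataset and (with ``mixed_off``) inactive in the
    "non-inflamed" datasets.  Program P2 is neutral: its URs stay active in
    both groups, so its pathways keep the same activation profile.
    """
    db, truth = generate_pathway_db(
        n_programs=2,
        pathways_per_program=pathways_per_program,
        genes_per_pathway=genes_per_pathway,
        within_share=0.5,
        between_share=0.05,
        seed=seed,
        n_filler_genes=4500,
    )
    prior = generate_prior(
        db,
        n_ligands=n_ligands,
        targets_per_ligand=targets_per_ligand,
        secreted_fraction=1.0,
        seed=seed + 1,
        truth=truth,
    )
    pro = [u for u in sorted(prior.ligands) if prior.home_program.get(u) == "P1"]
    neutral = [u for u in sorted(prior.ligands) if prior.home_program.get(u) == "P2"]
    inflamed = [f"inflamed_{i + 1}" for i in range(n_datasets_per_group)]
    quiet = [f"noninflamed_{i + 1}" for i in range(n_datasets_per_group)]
    for ds in inflamed:
        for u in pro:
            truth.ur_activity[(ds, u)] = 1
        for u in neutral:
            truth.ur_activity[(ds, u)] = 1
    for ds in quiet:
        for u in pro:
            truth.ur_activity[(ds, u)] = 0 if mixed_off else -1
        for u in neutral:
            truth.ur_activity[(ds, u)] = 1
    tables = generate_deg_tables(
        truth, prior, inflamed + quiet, fp_rate=fp_rate, fn_rate=fn_rate, seed=seed + 2
    )
    return Scenario(db, truth, prior, tables, {"inflamed": inflamed, "noninflamed": quiet})


def multi_organ_scenario(
    seed: int = 0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    n_ligands: int = 6,
    n_planted: int = 2,
    organs: Sequence[str] = ("joint", "muscle"),
    cell_types: Sequence[str] = ("Tcell", "Macrophage", "Fibroblast"),
):
    """Multi-organ study for MCDM/MO-MCDM inference.

    Plants ``n_planted`` secreted URs active (+1) in every (organ, cell
    type) population; the remaining ligands stay inactive decoys.  Returns
    ``(pathway_db, truth, prior, populations, planted)`` where
    ``populations`` maps (organ, cell type) to its expressed-gene set, DEG
    set and cell count.
    """
    from .enrichment import significant_genes
    from .interactions import CellPopulation

    db, truth = generate_pathway_db(seed=seed, n_filler_genes=500)
    prior = generate_prior(
        db, n_ligands=n_ligands, targets_per_ligand=40, secreted_fraction=1.0,
        seed=seed + 1, truth=truth, pref_within=0.9,
    )
    planted = sorted(prior.ligands)[:n_planted]
    datasets = [f"{o}|{c}" for o in organs for c in cell_types]
    for ds in datasets:
        for ur in planted:
            truth.ur_activity[(ds, ur)] = 1
    tables = generate_deg_tables(
        truth, prior, datasets, fp_rate=fp_rate, fn_rate=fn_rate, seed=seed + 2
    )
    universe = truth.gene_universe | set(prior.ligands)
    pops = {}
    for ds in datasets:
        organ, ct = ds.split("|")
        pops[(organ, ct)] = CellPopulation(
            expressed=set(universe), degs=significant_genes(tables[ds]), n_cells=100
        )
    return db, truth, prior, pops, planted


def takeover_scenario(seed: int = 0, with_takeover: bool = True, n_ligands: int = 8):
    """Anti-TNF-style cohort with a planted backup UR.

    Builds a two-program collection, seeds every UR on program P1 with
    targets_per_ligand drawn with strong within-program preference, then
    rewrites the takeover UR's target set to share 80% of the anchor's
    targets.  Returns ``(scenario_inputs, cohort_tables, anchor, takeover)``.
    """
    db, truth = generate_pathway_db(seed=seed, n_filler_genes=1000)
    prior = generate_prior(
        db, n_ligands=n_ligands, targets_per_ligand=40,
        secreted_fraction=1.0, seed=seed + 1, truth=truth, pref_within=0.9,
    )
    ligs = sorted(prior.ligands)
    anchor, takeover = ligs[0], (ligs[1] if with_takeover else None)
    if takeover is not None:
        rng = np.random.default_rng(seed + 2)
        anchor_t = sorted(prior.targets_of(anchor))
        n_share = round(0.8 * len(anchor_t))
        keep = list(rng.choice(anchor_t, size=n_share, replace=False))
        own = sorted(set(prior.targets_of(takeover)) - set(anchor_t))
        new = set(keep) | set(own[: 40 - n_share])
        prior = prior.with_targets(takeover, {g: 1.0 for g in sorted(new)})
        truth.ur_targets[takeover] = new
    for ur in ligs:
        prior.molecule_class[ur] = "cytokine"
    cohort = generate_treatment_cohort(
        truth, prior, anchor_ur=anchor, takeover_ur=takeover, overlap=0.7, seed=seed + 3
    )
    return Scenario(db, truth, prior, cohort, {"cohort": list(COHORT_CONTRASTS)}), anchor, takeover
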