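"""Upstream regulators of programs, treatment response, and takeover URs.

Links URs to pathway programs/subprograms by Fisher enrichment of their
downstream targets among the program's DEG-restricted genes, combines
evidence across datasets with Fisher's method, identifies the subprograms
affected by a treatment, and runs the backup-UR "takeover" procedure: a
candidate UR can take over the downstream effect of an inhibited anchor UR
(e.g. TNF under anti-TNF therapy) when its targets are enriched among the
anchor's targets in at least one program and its activation/fold-change
pattern in non-responders follows three criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import adjust, combine_fisher, fisher_enrich, ur_activation_z
from .interactions import LigandTargetPrior

__all__ = [
    "UR_CLASSES",
    "ur_program_enrichment",
    "filter_ur_classes",
    "affected_subprograms",
    "takeover_enrichment",
    "TakeoverAssessment",
    "takeover_criteria",
    "assess_takeover",
]

#: UR molecule classes considered as candidate regulators.
UR_CLASSES = (
    "G-protein coupled receptor",
    "cytokine",
    "growth factor",
    "ligand-dependent nuclear receptor",
    "transmembrane receptor",
)


def ur_program_enrichment(
    ur_targets: Mapping[str, Mapping[str, set[str]]],
    program_genes: Mapping[str, Iterable[str]],
    background: Iterable[str],
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Map URs to programs/subprograms with per-dataset Fisher tests.

    ``ur_targets[ur][dataset]`` is the UR's downstream target set in that
    dataset (its prior targets among the dataset's DEGs); ``background``
    is all genes entering connective pathway analysis.  Per group,
    per-dataset p-values are combined with Fisher's method, BH-adjusted
    over all (UR, program) pairs within the group, and ranked by combined
    FDR ascending (ties by UR then program id).
    """
    bg = set(background)
    frames = []
    for group, datasets in groups.items():
        rows = []
        for ur in sorted(ur_targets):
            per_ds = ur_targets[ur]
            if not any(per_ds.get(ds) for ds in datasets):
                warnings.warn(f"UR {ur!r} has no targets in group {group!r}; skipped",
                              stacklevel=2)
                continue
            for prog in sorted(program_genes):
                pg = set(program_genes[prog])
                ps = []
                for ds in datasets:
                    q = set(per_ds.get(ds, set())) & bg
                    if not q:
                        ps.append(1.0)
                        continue
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p, _, _ = fisher_enrich(q, pg, bg)
                    ps.append(p)
                rows.append(
                    {
                        "group": group,
                        "ur": ur,
                        "program": prog,
                        "p_values": ps,
                        "combined_p": combine_fisher(ps),
                    }
                )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["fdr"] = adjust(df["combined_p"], "BH")
        df = df.sort_values(["fdr", "ur", "program"], kind="mergesort").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["group", "ur", "program", "p_values", "combined_p", "fdr", "rank"]
        )
    return pd.concat(frames, ignore_index=True)


def filter_ur_classes(
    urs: Iterable[str],
    prior: LigandTargetPrior,
    allowed: Sequence[str] = UR_CLASSES,
) -> list[str]:
    """Keep URs whose molecule class is in ``allowed``.

    URs without a class annotation are dropped with a warning.
    """
    allowed_set = set(allowed)
    out = []
    for ur in urs:
        cls = prior.molecule_class.get(ur)
        if cls is None:
            warnings.warn(f"UR {ur!r} lacks a molecule-class annotation; dropped",
                          stacklevel=2)
            continue
        if cls in allowed_set:
            out.append(ur)
    return out


def affected_subprograms(
    response_pathways: Iterable[str],
    program_members: Mapping[str, Iterable[str]],
    background_pathways: Iterable[str],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Programs/subprograms enriched for treatment-response pathways.

    ``response_pathways`` are the pathways significantly enriched in the
    responder-vs-untreated contrast; each program/subprogram is tested by
    right-tailed Fisher against its member pathways with all clustered
    pathways as background, BH-adjusted; FDR < ``fdr_cut`` flags it
    "affected".
    """
    resp = set(response_pathways)
    bg = set(background_pathways)
    if not resp:
        warnings.warn("empty response-pathway set: everything non-affected", stacklevel=2)
    rows = []
    for prog in sorted(program_members):
        members = set(program_members[prog]) & bg
        if resp:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, odds, k = fisher_enrich(resp & bg, members, bg)
        else:
            p, odds, k = 1.0, np.nan, 0
        rows.append({"program": prog, "p": p, "odds_ratio": odds, "n_overlap": k})
    df = pd.DataFrame(rows)
    df["fdr"] = adjust(df["p"], "BH")
    df["affected"] = df["fdr"] < fdr_cut
    return df


def takeover_enrichment(
    alt_targets: Iterable[str],
    anchor_targets: Iterable[str],
    program_genes: Mapping[str, Iterable[str]],
) -> pd.Series:
    """Per-program enrichment of an alternative UR among the anchor's targets.

    Within each program the universe is the program's genes; the query is
    the alternative UR's targets and the target set the anchor's targets,
    both restricted to the program.  Programs without anchor targets are
    skipped.
    """
    alt = set(alt_targets)
    anchor = set(anchor_targets)
    out = {}
    for prog in sorted(program_genes):
        genes = set(program_genes[prog])
        if not (anchor & genes):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, _, _ = fisher_enrich(alt & genes, anchor & genes, genes)
        out[prog] = p
    return pd.Series(out, dtype=float)


@dataclass
class TakeoverAssessment:
    """Evaluation of one candidate backup UR against the three criteria."""

    ur: str
    enrichment_p: dict[str, float]
    enrichment_fdr: dict[str, float]
    z_responders: float | None
    z_nonresponders: float | None
    fc_resp_vs_ctrl: float
    fc_nonresp_vs_ctrl: float
    fc_nonresp_vs_resp_after: float
    fdr_nonresp_vs_resp_after: float
    c1: bool = False
    c2: bool = False
    c3: bool = False
    enriched: bool = False
    prioritized: bool = False
    reason: str = ""


def takeover_criteria(
    assessment: TakeoverAssessment,
    fdr_cut: float = 0.05,
    strict_c2: bool = True,
) -> TakeoverAssessment:
    """Apply the three takeover criteria to an assembled assessment.

    c1: the activation z is similarly positive or negative in responders
    and non-responders (same nonzero sign).  c2: the UR's own fold change
    is higher (positive z) or lower (negative z) in non-responders vs
    control than in responders vs control; with ``strict_c2=False`` a
    sign-crossing to >= 0 (resp. <= 0) also passes.  c3: a significant
    (FDR < ``fdr_cut``) positive (positive z) or negative (negative z)
    fold change in treated non-responders vs treated responders.
    Prioritized requires enrichment in >= 1 program plus all of c1-c3.
    """
    a = assessment
    if a.z_responders is None or a.z_nonresponders is None:
        a.reason = "undefined activation z (no DEG targets)"
        a.c1 = a.c2 = a.c3 = a.prioritized = False
        return a
    sign_r = np.sign(a.z_responders)
    sign_n = np.sign(a.z_nonresponders)
    a.c1 = bool(sign_r == sign_n and sign_r != 0)
    direction = sign_n
    if direction > 0:
        a.c2 = a.fc_nonresp_vs_ctrl > a.fc_resp_vs_ctrl or (
            not strict_c2 and a.fc_resp_vs_ctrl < 0 <= a.fc_nonresp_vs_ctrl
        )
        a.c3 = a.fc_nonresp_vs_resp_after > 0 and a.fdr_nonresp_vs_resp_after < fdr_cut
    elif direction < 0:
        a.c2 = a.fc_nonresp_vs_ctrl < a.fc_resp_vs_ctrl or (
            not strict_c2 and a.fc_resp_vs_ctrl > 0 >= a.fc_nonresp_vs_ctrl
        )
        a.c3 = a.fc_nonresp_vs_resp_after < 0 and a.fdr_nonresp_vs_resp_after < fdr_cut
    else:
        a.c2 = a.c3 = False
    a.enriched = any(f < fdr_cut for f in a.enrichment_fdr.values())
    a.prioritized = a.enriched and a.c1 and a.c2 and a.c3
    return a


def _gene_row(table: pd.DataFrame, gene: str) -> tuple[float, float]:
    """(logFC, fdr) for a gene; absent rows are a determinate non-call."""
    hit = table.loc[table["gene"] == gene]
    if hit.empty:
        return 0.0, 1.0
    return float(hit["logFC"].iloc[0]), float(hit["fdr"].iloc[0])


def assess_takeover(
    cohort: Mapping[str, pd.DataFrame],
    prior: LigandTargetPrior,
    anchor_ur: str,
    program_genes: Mapping[str, Iterable[str]],
    allowed_classes: Sequence[str] = UR_CLASSES,
    fdr_cut: float = 0.05,
    strict_c2: bool = True,
) -> list[TakeoverAssessment]:
    """Run the full takeover procedure over all alternative URs.

    ``cohort`` holds the five contrast DEG tables (see
    :data:`mcdmkit.synthetic.COHORT_CONTRASTS`).  Candidates are every
    prior ligand except the anchor, restricted to the allowed molecule
    classes.  Enrichment p-values are BH-adjusted across all (UR, program)
    pairs before the >= 1-program significance precondition.
    """
    anchor_targets = prior.targets_of(anchor_ur)
    candidates = [u for u in sorted(prior.ligands) if u != anchor_ur]
    candidates = filter_ur_classes(candidates, prior, allowed_classes)
    enrich: dict[str, pd.Series] = {}
    flat: list[tuple[str, str, float]] = []
    for ur in candidates:
        ps = takeover_enrichment(prior.targets_of(ur), anchor_targets, program_genes)
        enrich[ur] = ps
        for prog, p in ps.items():
            flat.append((ur, prog, p))
    fdrs = adjust([p for _, _, p in flat], "BH") if flat else []
    fdr_of = {(ur, prog): f for (ur, prog, _), f in zip(flat, fdrs)}

    out = []
    resp = cohort["resp_vs_ctrl"]
    nonresp = cohort["nonresp_vs_ctrl"]
    after = cohort["nonresp_after_vs_resp_after"]
    for ur in candidates:
        targets = prior.targets_of(ur)
        fc_r, _ = _gene_row(resp, ur)
        fc_n, _ = _gene_row(nonresp, ur)
        fc_a, fdr_a = _gene_row(after, ur)
        a = TakeoverAssessment(
            ur=ur,
            enrichment_p=dict(enrich[ur]),
            enrichment_fdr={p: fdr_of[(ur, p)] for p in enrich[ur].index},
            z_responders=ur_activation_z(targets, resp),
            z_nonresponders=ur_activation_z(targets, nonresp),
            fc_resp_vs_ctrl=fc_r,
            fc_nonresp_vs_ctrl=fc_n,
            fc_nonresp_vs_resp_after=fc_a,
            fdr_nonresp_vs_resp_after=fdr_a,
        )
        out.append(takeover_criteria(a, fdr_cut=fdr_cut, strict_c2=strict_c2))
    return out
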