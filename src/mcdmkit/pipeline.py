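"""End-to-end orchestration of the synthetic study.

Runs the full flow -- synthetic inputs, enrichment, connective pathway
analysis, activation labeling, UR-program mapping and the takeover
procedure -- from one validated configuration, writing every artifact plus
a manifest (inputs, seed, parameter hash) so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import connective, io, synthetic, urprograms
from .enrichment import enrich_all

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    out_dir: str
    seed: int = 0
    alpha: float = 0.05
    fdr: float = 0.05
    pcc_min: float = 0.0
    top_k: int = 200
    purity: float = 0.70
    expressed_cutoff: float = 1e-5
    k_top: int = 2
    k_sub: int = 2
    n_datasets_per_group: int = 4
    fp_rate: float = 0.0
    fn_rate: float = 0.0

    def __post_init__(self) -> None:
        checks = {
            "alpha": 0 < self.alpha <= 1,
            "fdr": 0 < self.fdr <= 1,
            "purity": 0 < self.purity <= 1,
            "top_k": self.top_k >= 1,
            "k_top": self.k_top >= 1,
            "k_sub": self.k_sub >= 1,
            "fp_rate": 0 <= self.fp_rate < 1,
            "fn_rate": 0 <= self.fn_rate < 1,
            "expressed_cutoff": self.expressed_cutoff >= 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"configuration values out of range: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the synthetic study end to end and write artifacts + manifest.

    Stages: synthetic generation -> pathway enrichment per dataset ->
    connective pathway analysis (Jaccard/Ward, programs, labels, opposing
    fractions) -> UR-program mapping -> takeover procedure.  Returns the
    result bundle; rerunning with the same config reproduces the manifest
    hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen = synthetic.inflammation_scenario(
        seed=config.seed,
        n_datasets_per_group=config.n_datasets_per_group,
        fp_rate=config.fp_rate,
        fn_rate=config.fn_rate,
    )
    io.write_gmt(scen.pathway_db, out / "pathways.gmt")
    io.write_prior(scen.prior, out / "prior_edges.tsv", out / "prior_annot.tsv")
    for ds, tab in scen.deg_tables.items():
        io.write_deg_table(tab, out / f"deg_{ds}.tsv")

    background = sorted(scen.truth.gene_universe)
    enrichments = enrich_all(
        scen.deg_tables, scen.pathway_db, alpha=config.alpha, background=background
    )
    deg_sets = connective.pathway_deg_sets(
        scen.deg_tables, scen.pathway_db, [ds for g in scen.groups.values() for ds in g]
    )
    sim = connective.jaccard_matrix(deg_sets)
    tree = connective.cut_tree(
        connective.cluster_pathways(sim), k_top=config.k_top, k_sub=config.k_sub
    )
    newick, assignments = connective.export_tree(tree)
    (out / "programs.nwk").write_text(newick, encoding="utf-8")
    assignments.to_csv(out / "programs.tsv", sep="\t", index=False)

    labels = connective.label_all(enrichments, scen.groups, alpha=config.alpha)
    label_rows = [asdict(l) for l in labels.values()]
    opposing = {}
    for prog in sorted(set(tree.programs.values())):
        members = [p for p, pr in tree.programs.items() if pr == prog]
        la = {p: labels[(p, "inflamed")].label for p in members}
        lb = {p: labels[(p, "noninflamed")].label for p in members}
        opposing[prog] = connective.opposing_fraction(la, lb, members)

    program_genes = {
        prog: set().union(*(deg_sets[p] for p in tree.programs if tree.programs[p] == prog))
        for prog in sorted(set(tree.programs.values()))
    }
    all_ds = [ds for g in scen.groups.values() for ds in g]
    from .enrichment import significant_genes

    ur_targets = {
        ur: {ds: scen.prior.targets_of(ur) & significant_genes(scen.deg_tables[ds])
             for ds in all_ds}
        for ur in scen.prior.ligands
    }
    clustered_genes = set().union(*deg_sets.values())
    ur_map = urprograms.ur_program_enrichment(
        ur_targets, program_genes, clustered_genes, scen.groups
    )
    ur_map.drop(columns="p_values").to_csv(out / "ur_programs.tsv", sep="\t", index=False)

    cohort_scen, anchor, takeover = synthetic.takeover_scenario(seed=config.seed)
    cohort_sets = {
        pid: genes for pid, genes in cohort_scen.pathway_db.sets.items()
    }
    prog_genes_cohort = {
        prog: set().union(
            *(cohort_sets[p] for p, pr in cohort_scen.truth.program_of_pathway.items() if pr == prog)
        )
        for prog in sorted(set(cohort_scen.truth.program_of_pathway.values()))
    }
    assessments = urprograms.assess_takeover(
        cohort_scen.deg_tables, cohort_scen.prior, anchor, prog_genes_cohort,
        fdr_cut=config.fdr,
    )
    prioritized = [a.ur for a in assessments if a.prioritized]

    bundle = {
        "opposing_fraction": opposing,
        "n_enrichments": len(enrichments),
        "n_pathways_clustered": len(deg_sets),
        "programs": dict(tree.programs),
        "ur_program_hits": ur_map.loc[ur_map["fdr"] < config.fdr, ["group", "ur", "program"]]
        .to_dict("records"),
        "takeover_prioritized": prioritized,
        "planted_takeover": takeover,
        "labels": label_rows,
    }
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "param_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [
            "synthetic", "enrichment", "connective", "labeling", "ur_programs", "takeover",
        ],
        "counts": {
            "datasets": len(all_ds),
            "pathways": len(scen.pathway_db),
            "pathways_clustered": len(deg_sets),
            "urs": len(scen.prior.ligands),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True),
                                       encoding="utf-8")
    (out / "results.json").write_text(json.dumps(bundle, indent=1, sort_keys=True, default=str),
                                      encoding="utf-8")
    return bundle
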