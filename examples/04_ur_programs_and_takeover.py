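"""Map URs to programs and screen for a backup ("takeover") UR.

First, per-dataset Fisher enrichment of each UR's downstream targets in
each program's genes is combined with Fisher's method and BH-adjusted;
planted (UR, program) pairs surface at FDR < 0.05.  Second, an anti-TNF
style responder/non-responder cohort with a planted takeover UR is
screened with the three takeover criteria.
"""

from mcdmkit import synthetic as syn
from mcdmkit.connective import pathway_deg_sets
from mcdmkit.enrichment import significant_genes
from mcdmkit.urprograms import assess_takeover, ur_program_enrichment

scen = syn.inflammation_scenario(seed=1, n_datasets_per_group=3)
all_ds = [d for g in scen.groups.values() for d in g]
deg_sets = pathway_deg_sets(scen.deg_tables, scen.pathway_db, all_ds)
program_genes = {
    pr: set().union(
        *(deg_sets[p] for p in deg_sets if scen.truth.program_of_pathway[p] == pr)
    )
    for pr in ("P1", "P2")
}
ur_targets = {
    ur: {ds: scen.prior.targets_of(ur) & significant_genes(scen.deg_tables[ds])
         for ds in scen.groups["inflamed"]}
    for ur in scen.prior.ligands
}
mapping = ur_program_enrichment(
    ur_targets, program_genes, set().union(*program_genes.values()),
    {"inflamed": scen.groups["inflamed"]},
)
print("UR -> program mapping (combined p, BH FDR):")
print(mapping[["ur", "program", "combined_p", "fdr", "rank"]].to_string(index=False))
print("planted homes:", scen.prior.home_program)
# each UR should map to its home program at FDR < 0.05 and to no other.

cohort, anchor, takeover = syn.takeover_scenario(seed=1)
pg = {
    pr: set().union(
        *(cohort.pathway_db.sets[p]
          for p, q in cohort.truth.program_of_pathway.items() if q == pr)
    )
    for pr in ("P1", "P2")
}
assessments = assess_takeover(cohort.deg_tables, cohort.prior, anchor, pg)
print(f"\nanchor UR (treated target): {anchor}; planted takeover: {takeover}")
for a in assessments:
    print(f"  {a.ur}: c1={a.c1} c2={a.c2} c3={a.c3} enriched={a.enriched} "
          f"-> prioritized={a.prioritized}")
# exactly one UR -- the planted takeover -- satisfies enrichment plus all
# three criteria (same-sign activation z, stronger fold change in
# non-responders, significant post-treatment contrast).
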