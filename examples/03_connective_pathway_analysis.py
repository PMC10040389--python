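"""Connective pathway analysis: programs, activation labels, on/off contrast.

An inflamed group (pro-inflammatory and housekeeping URs active) is
compared with a non-inflamed group (pro-inflammatory URs off).  Pathways
restricted to group DEGs are clustered on 1-Jaccard distance (Ward), the
dendrogram is cut into programs, every pathway is labeled per group, and
the opposing fraction quantifies which program behaves as an on/off
switch.
"""

from mcdmkit import synthetic as syn
from mcdmkit.connective import (
    cluster_pathways,
    cut_tree,
    export_tree,
    gwas_enrichment,
    jaccard_matrix,
    label_all,
    opposing_fraction,
    pathway_deg_sets,
)
from mcdmkit.enrichment import enrich_all

scen = syn.inflammation_scenario(seed=1)
background = sorted(scen.truth.gene_universe)

enrichments = enrich_all(scen.deg_tables, scen.pathway_db, background=background)
all_datasets = [d for g in scen.groups.values() for d in g]
deg_sets = pathway_deg_sets(scen.deg_tables, scen.pathway_db, all_datasets)
tree = cut_tree(cluster_pathways(jaccard_matrix(deg_sets)), k_top=2, k_sub=2)
newick, assignments = export_tree(tree)
print(assignments.groupby("program").size().rename("pathways").to_string())

labels = label_all(enrichments, scen.groups)
for program in sorted(set(tree.programs.values())):
    members = [p for p, pr in tree.programs.items() if pr == program]
    la = {p: labels[(p, "inflamed")].label for p in members}
    lb = {p: labels[(p, "noninflamed")].label for p in members}
    frac = opposing_fraction(la, lb, members)
    print(f"{program}: opposing fraction inflamed vs non-inflamed = {frac:.2f}")
# a fraction near 1 marks the pro-inflammatory program switching on/off
# between the groups; near 0 marks a program active in both.

p1_genes = set().union(*(deg_sets[p] for p in tree.programs if tree.programs[p] == "P1"))
gwas = sorted(p1_genes)[::2]  # a GWAS set overlapping the program
hits = gwas_enrichment(p1_genes, gwas,
                       {d: scen.deg_tables[d] for d in scen.groups["inflamed"]})
print("GWAS enrichment of P1 (per inflamed dataset):")
print(hits.to_string(index=False))
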