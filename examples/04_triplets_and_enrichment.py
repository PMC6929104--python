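"""Tri-omics triplets and enrichment against a DE-restricted background.

A metabolic gene becomes a tri-omics triplet when it changes significantly,
a validated microRNA regulator moves the opposite way, and an adjacent
metabolite (substrate/product/transported) also changes.  Separately,
enrichment of miRNA-targeted genes is tested against *all DE genes* rather
than the whole genome, asking whether microRNAs single out specific
processes among the genes that changed.
"""

from mirconcord import (
    DERecord,
    GeneKey,
    MetaboliteRecord,
    TargetInteraction,
    find_consistent_connections,
    find_triomics_triplets,
    hypergeom_enrich,
    parse_mirna_name,
)

# A glutamate-transporter-style case: gene up in the primed-like state,
# its miRNA regulator down, the transported metabolite also shifted.
gene_de = [DERecord(GeneKey("SLC1A2", "human"), 3.55, 1e-6, "rnaseq")]
mirna_de = [DERecord(parse_mirna_name("hsa-miR-199b-3p"), -2.5, 1e-4, "mirnaseq")]
edges = [TargetInteraction(parse_mirna_name("hsa-miR-199b-3p"),
                           GeneKey("SLC1A2", "human"), "Luciferase reporter assay")]
metabolites = [MetaboliteRecord("glutamate", 0.95, 0.01, "metabolomics")]
adjacency = [("SLC1A2", "glutamate", "transported")]

connections = find_consistent_connections(mirna_de, gene_de, edges)
triplets = find_triomics_triplets(gene_de, connections, metabolites, adjacency)
for t in triplets:
    mets = ", ".join(f"{m} ({d})" for m, d, _ in t.linked_metabolites)
    print(f"triplet: {t.gene} {t.gene_direction}; opposed by "
          f"{', '.join(sorted(t.opposing_mirnas))}; metabolites: {mets}")

# Enrichment: 10 miRNA-targeted DE genes, 6 of them in one pathway, tested
# against the 40-gene DE background (not the genome).
background = {f"G{i}" for i in range(40)}
study = {f"G{i}" for i in range(10)}
term_map = {"PATH:polyamine": {f"G{i}" for i in range(6)} | {"G30", "G31"}}
for r in hypergeom_enrich(study, background, term_map):
    print(f"{r.term_id}: {r.k}/{r.n} study vs {r.K}/{r.N} background, "
          f"p={r.p:.3g}, q={r.q:.3g}")

# A small p means the targeted genes concentrate in the pathway beyond what
# the DE background alone explains.
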