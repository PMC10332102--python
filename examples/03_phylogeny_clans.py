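"""NJ phylogeny with bootstrap supports, plus clan assignment.

Aligns the identified family proteins progressively, builds a
neighbor-joining tree on Poisson-corrected distances, bootstraps the
internal splits, and assigns each single-domain gene to a clan (A1-A6 /
B1-B6) by its nearest labelled reference ancestor.
"""

from familyscope.family_identification import identify_family
from familyscope.phylogeny import assign_clans, bootstrap_support, progressive_align
from familyscope.synthetic_data import generate_transcriptome

_, proteins, truth = generate_transcriptome(
    seed=5, n_erf=6, n_dreb=4, n_ap2=1, n_rav=1, n_negative=0, n_incomplete=0
)
assignments = identify_family(proteins)
family_ids = [g for g, a in assignments.items() if a.subfamily != "excluded"]

msa = progressive_align(proteins.subset(family_ids))
tree = bootstrap_support(msa, n_replicates=100, seed=11)
print("NJ tree (supports = % of 100 bootstrap replicates):")
print(tree.to_newick())

overrides = {
    g: assignments[g].subfamily
    for g in family_ids
    if assignments[g].subfamily in ("AP2", "RAV")
}
clans = assign_clans(
    proteins.subset(family_ids), truth.references, truth.reference_clans, overrides
)
print("\nclan assignments (margin = distance gap to the runner-up clan):")
for call in clans:
    true_clan = truth.genes.set_index("gene_id").loc[call.gene_id, "clan"]
    print(f"  {call.gene_id:10s} -> {call.clan:4s} (margin {call.margin:.3f}, "
          f"truth {true_clan})")
# High bootstrap supports mark reliable splits; every gene maps back to the
# clan of the ancestor it was simulated from.
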