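"""Identify AP2/ERF family members in a (synthetic) transcriptome.

Generates a small transcriptome with planted AP2/B3 domains, scans every
protein with the bundled domain models, classifies each gene into
ERF / DREB / AP2 / RAV (or excludes it), and prints per-gene properties.
"""

from familyscope.family_identification import (
    compute_protein_properties,
    identify_family,
)
from familyscope.synthetic_data import generate_transcriptome

cds, proteins, truth = generate_transcriptome(
    seed=7, n_erf=6, n_dreb=4, n_ap2=2, n_rav=2, n_negative=3, n_incomplete=2
)
assignments = identify_family(proteins)

print(f"{'gene':10s} {'subfamily':10s} {'res14/19':9s} {'orf_bp':>6s} "
      f"{'aa':>5s} {'MW_Da':>9s} {'pI':>5s}")
for gene_id, _ in proteins:
    call = assignments[gene_id]
    props = compute_protein_properties(cds[gene_id])
    diag = "/".join(call.diagnostic) if call.diagnostic else "-"
    print(f"{gene_id:10s} {call.subfamily:10s} {diag:9s} {props.orf_length:6d} "
          f"{props.protein_length:5d} {props.molecular_weight:9.1f} "
          f"{props.isoelectric_point:5.2f}")

counts = {}
for call in assignments.values():
    counts[call.subfamily] = counts.get(call.subfamily, 0) + 1
print("\nsubfamily counts:", counts)
# Genes with one complete AP2 domain split into ERF (Ala/Asp at domain
# positions 14/19) vs DREB (Val/Glu); two AP2 domains -> AP2 subfamily;
# AP2 + B3 -> RAV; truncated-domain decoys and domain-free genes are excluded.
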