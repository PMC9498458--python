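"""Gene order, the Lepidoptera tRNA rearrangement, junctions, strand census."""

from mitocomp import (
    GenomeTemplate, classify_rearrangement, gene_order, generate_genome,
    junctions, strand_census,
)
from mitocomp.simulate import apply_tdrl

derived = generate_genome(GenomeTemplate.default(), seed=1)
ancestral = generate_genome(GenomeTemplate.default(rearranged=False), seed=1)

report = classify_rearrangement(gene_order(derived), gene_order(ancestral))
print("Lepidoptera-type TDRL detected:", report.lepidoptera_tdrl)
print("displaced genes:", report.displaced_genes)

# the TDRL operation itself turns the ancestral block into the derived one
print("apply_tdrl reproduces it:",
      classify_rearrangement(gene_order(apply_tdrl(ancestral)),
                             gene_order(ancestral)).lepidoptera_tdrl)

j = junctions(derived, include_cr=True)
print(f"{j.n_overlaps} overlaps ({j.total_overlap_bp} bp total), "
      f"{j.n_spacers} spacers ({j.total_spacer_bp} bp total)")
lo = j.longest_overlap
print(f"longest overlap: {lo.upstream}/{lo.downstream}, {lo.length} bp")

census = strand_census(derived)
print(f"strand census: {census.majority_total} genes on the majority strand, "
      f"{census.minority_total} on the minority strand")
# Moth mitogenomes put 23 genes (9 PCGs + 14 tRNAs) on the majority strand
# and 14 (4 PCGs + 8 tRNAs + 2 rRNAs) on the minority strand.
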