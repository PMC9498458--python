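"""Start/stop codon classes and relative synonymous codon usage (RSCU)."""

from mitocomp import (
    GenomeTemplate, classify_start_stop, codon_counts, extract_gene_sequence,
    generate_genome, rscu, trim_terminal_stop,
)

genome = generate_genome(GenomeTemplate.default(), seed=1)
pcgs = [f for f in genome.features if f.gene_class == "PCG"]

print("gene   start  class             stop")
cdss = []
for f in sorted(pcgs, key=lambda f: f.canonical_name):
    cds = extract_gene_sequence(genome, f)
    e = classify_start_stop(cds)
    print(f"{f.canonical_name:<6} {e.start_codon}    {e.start_class:<17} {e.stop_class}")
    cdss.append(trim_terminal_stop(cds))

counts, _ = codon_counts(cdss)
table = rscu(counts)
print(f"\ntop codon families (of {table.total_codons} codons):")
print(table.family_usage().head(5).to_string())
print(f"RSCU(UUA) = {table.rscu['TTA']:.2f}   missing codons: {len(table.missing_codons)}")
# UUA(Leu) dominates codon usage in these AT-rich genomes (RSCU ~ 5);
# truncated stops (T / TA) are completed to UAA by polyadenylation.
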