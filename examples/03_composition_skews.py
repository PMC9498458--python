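"""Base composition and AT/GC strand-asymmetry skews per codon position."""

from mitocomp import GenomeTemplate, base_composition, generate_genome, skew_table

genome = generate_genome(GenomeTemplate.default(), seed=1)
p = base_composition(genome.sequence)
print(f"whole genome: A {p.a_pct:.1f}%  T {p.t_pct:.1f}%  C {p.c_pct:.1f}%  "
      f"G {p.g_pct:.1f}%  (AT {p.at_pct:.1f}%)")

df = skew_table(genome)
concat = df.loc[(genome.identifier, "concatenated")]
for pos in ("1", "2", "3", "123"):
    row = concat.loc[pos]
    print(f"codon position {pos:>3}: AT-skew {row['AT_skew']:+.4f}  "
          f"GC-skew {row['GC_skew']:+.4f}")

# AT-skew = (A-T)/(A+T): negative values mean an excess of T over A.  In
# moth PCGs the pooled skew is clearly negative, driven by the 2nd and 3rd
# codon positions, while 1st positions sit near zero — the generator's
# codon sampling reproduces that stratified pattern.
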