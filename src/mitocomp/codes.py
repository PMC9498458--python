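"""Genetic-code helpers for the invertebrate mitochondrial code.

All codon statistics in this package run under NCBI translation table 5
(invertebrate mitochondrial): TGA encodes Trp, AGA/AGG encode Ser, ATA
encodes Met, and the stop set is {TAA, TAG}, leaving exactly 62 sense
codons.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

INVERTEBRATE_MITO = 5

_BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(_BASES, repeat=3))

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N", "-": "-"}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def is_transition(b1: str, b2: str) -> bool:
    """True when b1->b2 is a purine<->purine or pyrimidine<->pyrimidine change."""
    return b1 != b2 and (
        (b1 in PURINES and b2 in PURINES) or (b1 in PYRIMIDINES and b2 in PYRIMIDINES)
    )


class GeneticCode:
    """A genetic code with synonymous-family structure derived from Biopython."""

    def __init__(self, table_id: int = INVERTEBRATE_MITO):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.id = table_id
        self.name = table.names[0]
        self.stop_codons: frozenset[str] = frozenset(table.stop_codons)
        self.amino_acid: dict[str, str] = dict(table.forward_table)
        self.sense_codons: tuple[str, ...] = tuple(
            c for c in ALL_CODONS if c not in self.stop_codons
        )
        fams: dict[str, list[str]] = {}
        for codon in self.sense_codons:
            fams.setdefault(self.amino_acid[codon], []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(cs) for aa, cs in fams.items()
        }
        self.degeneracy: dict[str, int] = {
            c: len(self.families[self.amino_acid[c]]) for c in self.sense_codons
        }

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str:
        return self.amino_acid[codon]

    def synonymous(self, c1: str, c2: str) -> bool:
        return self.amino_acid[c1] == self.amino_acid[c2]


_CODE_CACHE: dict[int, GeneticCode] = {}


def get_code(table_id: int = INVERTEBRATE_MITO) -> GeneticCode:
    if table_id not in _CODE_CACHE:
        _CODE_CACHE[table_id] = GeneticCode(table_id)
    return _CODE_CACHE[table_id]


#: canonical start codons: the ATN class plus alternatives seen in moth PCGs
ATN_STARTS = frozenset({"ATA", "ATT", "ATG", "ATC"})
ALTERNATIVE_STARTS = frozenset({"TTG", "CGA", "AAG", "AAA"})


def to_rna(codon: str) -> str:
    """DNA codon to the RNA-style label used in codon-usage reports (TTA -> UUA)."""
    return codon.replace("T", "U")
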