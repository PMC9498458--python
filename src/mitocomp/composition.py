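"""Base composition and strand-asymmetry skew statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C): signed measures of
the compositional asymmetry between the two strands.  A positive AT-skew
means an excess of A relative to T.  Skews are computed for whole genomes,
individual genes (on the coding strand), concatenated PCG sets and codon
position strata (1st/2nd/3rd/123).  N and gap characters are excluded from
both numerator and denominator; an undefined skew (zero denominator) is
reported as missing, never as a division failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genomes import PCG_NAMES, Alignment, MitoGenome, extract_gene_sequence

__all__ = [
    "CompositionProfile",
    "DegenerateSequenceError",
    "FrameError",
    "base_composition",
    "skew",
    "codon_position_split",
    "skew_table",
]


class DegenerateSequenceError(ValueError):
    """Empty or all-ambiguous sequence: no composition can be reported."""


class FrameError(ValueError):
    """A coding sequence whose length violates the reading frame."""


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts with derived percentages and skews for one sequence set."""

    a: int
    c: int
    g: int
    t: int
    n_excluded: int = 0

    def __add__(self, other: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.n_excluded + other.n_excluded,
        )

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.total

    @property
    def a_pct(self) -> float:
        return self._pct(self.a)

    @property
    def t_pct(self) -> float:
        return self._pct(self.t)

    @property
    def c_pct(self) -> float:
        return self._pct(self.c)

    @property
    def g_pct(self) -> float:
        return self._pct(self.g)

    @property
    def at_pct(self) -> float:
        return self._pct(self.a + self.t)

    @property
    def gc_pct(self) -> float:
        return self._pct(self.c + self.g)

    @property
    def at_skew(self) -> float:
        """(A - T)/(A + T); NaN when A + T = 0."""
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else math.nan

    @property
    def gc_skew(self) -> float:
        """(G - C)/(G + C); NaN when G + C = 0."""
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else math.nan


def base_composition(seq: str) -> CompositionProfile:
    """Count bases in a sequence over {A,C,G,T,N}; N and gaps are excluded."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN-")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    profile = CompositionProfile(
        a=seq.count("A"), c=seq.count("C"), g=seq.count("G"), t=seq.count("T"),
        n_excluded=seq.count("N") + seq.count("-"),
    )
    if profile.total == 0:
        raise DegenerateSequenceError("empty or all-ambiguous sequence")
    return profile


def skew(profile: CompositionProfile) -> tuple[float, float]:
    """(AT-skew, GC-skew) for a profile; NaN marks an undefined skew."""
    return profile.at_skew, profile.gc_skew


def codon_position_split(cds: str) -> tuple[str, str, str]:
    """Split an in-frame CDS into its 1st, 2nd and 3rd codon-position strata."""
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    return cds[0::3], cds[1::3], cds[2::3]


_POSITIONS = ("1", "2", "3", "123")


def _profile_rows(set_name: str, cds: str) -> dict[str, CompositionProfile]:
    p1, p2, p3 = codon_position_split(cds)
    return {
        "1": base_composition(p1),
        "2": base_composition(p2),
        "3": base_composition(p3),
        "123": base_composition(cds),
    }


def skew_table(
    genomes: list[MitoGenome] | MitoGenome,
) -> pd.DataFrame:
    """Per-gene and concatenated-PCG composition/skews at codon positions.

    PCG sequences are taken on the coding strand and trimmed to complete
    codons (a truncated terminal stop of 1–2 nt is dropped).  Rows are keyed
    by (genome, gene, position) with position in {1, 2, 3, 123}; the
    ``concatenated`` gene row pools all annotated PCGs.  Genomes missing a
    PCG have that row omitted; the missing set is recorded in
    ``df.attrs["missing"]``.
    """
    if isinstance(genomes, MitoGenome):
        genomes = [genomes]
    records = []
    missing: dict[str, list[str]] = {}
    for genome in genomes:
        concat = []
        for gene in PCG_NAMES:
            if not genome.has_feature(gene):
                missing.setdefault(genome.identifier, []).append(gene)
                continue
            cds = extract_gene_sequence(genome, genome.feature_by_name(gene))
            cds = cds[: len(cds) - len(cds) % 3]
            concat.append(cds)
            for pos, prof in _profile_rows(gene, cds).items():
                records.append((genome.identifier, gene, pos, prof))
        if concat:
            for pos, prof in _profile_rows("concatenated", "".join(concat)).items():
                records.append((genome.identifier, "concatenated", pos, prof))
    df = pd.DataFrame(
        [
            (
                gid, gene, pos, p.a, p.c, p.g, p.t,
                p.at_pct, p.gc_pct, p.at_skew, p.gc_skew,
            )
            for gid, gene, pos, p in records
        ],
        columns=[
            "genome", "gene", "position", "A", "C", "G", "T",
            "AT_pct", "GC_pct", "AT_skew", "GC_skew",
        ],
    ).set_index(["genome", "gene", "position"])
    df.attrs["missing"] = missing
    return df
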