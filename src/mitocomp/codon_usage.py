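"""Start/stop codon classification, codon counting and RSCU.

Insect mitochondrial PCGs typically start with ATN codons but tolerate
alternatives (TTG, CGA, AAG, AAA), and frequently end on a truncated stop
("T" or "TA") completed to TAA by polyadenylation of the polycistronic
transcript.  Relative synonymous codon usage, RSCU(c) = count(c) divided by
the mean count over c's synonymous family, is computed over the 62 sense
codons of the invertebrate mitochondrial code; terminal stops are excluded
from counting while start codons are counted as ordinary codons.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .codes import ALTERNATIVE_STARTS, ATN_STARTS, get_code, to_rna

__all__ = [
    "StartStopEntry",
    "CodonUsageTable",
    "classify_start_stop",
    "trim_terminal_stop",
    "codon_counts",
    "rscu",
]

#: a truncated stop is only credible when the downstream feature begins
#: within this many bp (polyadenylation-completion rationale)
MAX_TRUNCATED_STOP_GAP = 5


@dataclass(frozen=True)
class StartStopEntry:
    """Start/stop classification of one protein-coding gene."""

    start_codon: str
    start_class: str  # "ATN" or "alternative(XXX)" or "other(XXX)"
    stop_codon: str  # TAA | TAG | TA | T | ""
    stop_class: str  # "TAA" | "TAG" | "truncated TA" | "truncated T" | "incomplete/unknown"
    complete: bool
    internal_stops: tuple[int, ...] = ()  # codon indices of in-frame stops

    @property
    def truncated(self) -> bool:
        return self.stop_class.startswith("truncated")


def classify_start_stop(
    cds: str,
    genetic_code: int = 5,
    downstream_gap: int | None = None,
) -> StartStopEntry:
    """Classify the initiation and termination codons of a CDS.

    ``cds`` is on the coding strand, untrimmed.  A length of 0 mod 3 with a
    terminal TAA/TAG is a complete stop; 2 mod 3 ending in TA or 1 mod 3
    ending in T is a truncated stop — unless ``downstream_gap`` (distance to
    the next feature in transcript order, when known) exceeds
    ``MAX_TRUNCATED_STOP_GAP``, in which case the stop is
    "incomplete/unknown".  In-frame internal stop codons trigger a
    pseudogene warning and are recorded.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError(f"CDS too short to classify ({len(cds)} nt)")
    code = get_code(genetic_code)

    start = cds[:3]
    if start in ATN_STARTS:
        start_class = "ATN"
    elif start in ALTERNATIVE_STARTS:
        start_class = f"alternative({start})"
    else:
        start_class = f"other({start})"

    mod = len(cds) % 3
    stop_codon, stop_class, complete = "", "incomplete/unknown", False
    if mod == 0 and cds[-3:] in code.stop_codons:
        stop_codon, stop_class, complete = cds[-3:], cds[-3:], True
    elif mod == 2 and cds[-2:] == "TA":
        stop_codon, stop_class = "TA", "truncated TA"
    elif mod == 1 and cds[-1] == "T":
        stop_codon, stop_class = "T", "truncated T"
    if stop_class.startswith("truncated") and downstream_gap is not None:
        if downstream_gap > MAX_TRUNCATED_STOP_GAP:
            stop_codon, stop_class = "", "incomplete/unknown"
    if stop_class == "incomplete/unknown":
        warnings.warn(f"CDS has no recognizable (truncated) stop codon (len {len(cds)})")

    n_full = len(cds) // 3
    last_checked = n_full - 1 if (mod == 0 and complete) else n_full
    internal = tuple(
        i for i in range(1, last_checked)
        if cds[3 * i:3 * i + 3] in code.stop_codons
    )
    if internal:
        warnings.warn(f"in-frame internal stop codon(s) at codon index {list(internal)}")
    return StartStopEntry(start, start_class, stop_codon, stop_class, complete, internal)


def trim_terminal_stop(cds: str, genetic_code: int = 5) -> str:
    """Remove a complete or truncated terminal stop; trim to whole codons."""
    cds = cds.upper()
    code = get_code(genetic_code)
    mod = len(cds) % 3
    if mod == 0 and len(cds) >= 3 and cds[-3:] in code.stop_codons:
        return cds[:-3]
    if mod == 2 and cds.endswith("TA"):
        return cds[:-2]
    if mod == 1 and cds.endswith("T"):
        return cds[:-1]
    return cds[: len(cds) - mod]


class FrameError(ValueError):
    pass


def codon_counts(cds_set: list[str], genetic_code: int = 5) -> tuple[Counter, int]:
    """Pooled codon counts over a set of in-frame CDS (stops pre-trimmed).

    Returns ``(counts, n_skipped)`` where codons containing N or gaps are
    skipped and tallied in ``n_skipped``.
    """
    counts: Counter = Counter()
    skipped = 0
    for idx, cds in enumerate(cds_set):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise FrameError(f"CDS #{idx}: length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                skipped += 1
    return counts, skipped


@dataclass
class CodonUsageTable:
    """Codon counts, RSCU values and amino-acid usage for one gene set."""

    counts: dict[str, int]
    rscu: dict[str, float]
    aa_usage: dict[str, int]
    missing_codons: tuple[str, ...]
    stop_counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def family_usage(self, genetic_code: int = 5) -> pd.Series:
        """Total usage per codon family, labelled 'Aa (XXX)' RNA-style by its
        most-used codon (the presentation used for codon-family bar charts)."""
        code = get_code(genetic_code)
        rows = {}
        for aa, codons in code.families.items():
            top = max(codons, key=lambda c: (self.counts.get(c, 0), c))
            rows[f"{aa} ({to_rna(top)})"] = sum(self.counts.get(c, 0) for c in codons)
        return pd.Series(rows).sort_values(ascending=False)

    def as_frame(self, genetic_code: int = 5) -> pd.DataFrame:
        code = get_code(genetic_code)
        recs = [
            (to_rna(c), c, code.translate(c), self.counts.get(c, 0), self.rscu[c])
            for c in code.sense_codons
        ]
        return pd.DataFrame(
            recs, columns=["codon_rna", "codon_dna", "amino_acid", "count", "RSCU"]
        ).set_index("codon_rna")


def rscu(counts: Counter | dict[str, int], genetic_code: int = 5) -> CodonUsageTable:
    """RSCU over sense codons: count / (synonymous-family mean count).

    Families with zero total usage get missing (NaN) RSCU values, not 0;
    RSCU is 0 exactly for absent codons of an observed family.  Stop codons
    present in ``counts`` are tracked separately and excluded from RSCU.
    """
    code = get_code(genetic_code)
    stop_counts = {c: counts[c] for c in code.stop_codons if counts.get(c)}
    sense = {c: counts.get(c, 0) for c in code.sense_codons}
    values: dict[str, float] = {}
    aa_usage: dict[str, int] = {}
    for aa, codons in code.families.items():
        total = sum(sense[c] for c in codons)
        aa_usage[aa] = total
        if total == 0:
            for c in codons:
                values[c] = math.nan
        else:
            mean = total / len(codons)
            for c in codons:
                values[c] = sense[c] / mean
    missing = tuple(sorted(c for c in code.sense_codons if sense[c] == 0))
    return CodonUsageTable(
        counts=sense,
        rscu=values,
        aa_usage=aa_usage,
        missing_codons=missing,
        stop_counts=stop_counts,
    )
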