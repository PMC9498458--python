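"""Genome architecture: gene order, rearrangements, junctions, strand census.

Moth mitogenomes share the derived trnM-trnI-trnQ tRNA block where the
ancestral insect arrangement is trnI-trnQ-trnM; the translocation is the
classic Lepidoptera-specific outcome of a tandem duplication–random loss
(TDRL) event.  Besides gene order, the economy of the molecule shows in
its junctions: consecutive genes overlap (ATP8/ATP6 and trnC/trnW in
essentially all species, trnL1/rrnL with the longest overlaps) or are
separated by short intergenic spacers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genomes import MitoGenome

__all__ = [
    "GeneOrder",
    "RearrangementReport",
    "Junction",
    "JunctionReport",
    "StrandCensus",
    "AnnotationError",
    "ComparabilityError",
    "TopologyError",
    "gene_order",
    "classify_rearrangement",
    "junctions",
    "strand_census",
    "ANCESTRAL_INSECT_BLOCK",
    "LEPIDOPTERA_BLOCK",
]

ANCESTRAL_INSECT_BLOCK = ("trnI", "trnQ", "trnM")
LEPIDOPTERA_BLOCK = ("trnM", "trnI", "trnQ")


class AnnotationError(ValueError):
    """Duplicate or inconsistent gene annotations."""


class ComparabilityError(ValueError):
    """Two gene orders that cannot be compared (different gene sets)."""


class TopologyError(ValueError):
    """Feature topology that junction analysis cannot handle (nesting)."""


@dataclass(frozen=True)
class GeneOrder:
    """Circular gene order as (name, strand) entries in a canonical rotation.

    The rotation is anchored at COX1 when present (else the
    lexicographically smallest name) so that equal circular orders compare
    equal as tuples.
    """

    entries: tuple[tuple[str, int], ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def contains_block(self, block: tuple[str, ...]) -> bool:
        """True if ``block`` occurs as a contiguous run of names (circularly)."""
        names = self.names
        if len(block) > len(names):
            return False
        doubled = names + names
        k = len(block)
        return any(doubled[i:i + k] == tuple(block) for i in range(len(names)))

    @staticmethod
    def _anchor(entries: list[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
        names = [n for n, _ in entries]
        anchor = "COX1" if "COX1" in names else min(names)
        i = names.index(anchor)
        return tuple(entries[i:] + entries[:i])


def gene_order(genome: MitoGenome) -> GeneOrder:
    """Gene order around the circle, anchored at a deterministic reference gene."""
    if not genome.features:
        raise AnnotationError(f"{genome.identifier}: no features")
    feats = sorted(genome.features, key=lambda f: (f.start % genome.length, f.end))
    names = [f.canonical_name for f in feats]
    dups = {n for n in names if names.count(n) > 1 and not n.endswith("?")}
    if dups:
        raise AnnotationError(f"{genome.identifier}: duplicate gene names {sorted(dups)}")
    entries = [(f.canonical_name, f.strand) for f in feats]
    return GeneOrder(GeneOrder._anchor(entries))


@dataclass(frozen=True)
class RearrangementReport:
    identical: bool
    conserved_blocks: tuple[tuple[tuple[str, int], ...], ...]
    displaced_genes: tuple[str, ...]
    lepidoptera_tdrl: bool


def _lcs_keep(a: list, b: list) -> list[bool]:
    """Which entries of ``a`` belong to one longest common subsequence with ``b``."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            dp[i][j] = (
                dp[i + 1][j + 1] + 1 if a[i] == b[j] else max(dp[i + 1][j], dp[i][j + 1])
            )
    keep = [False] * n
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            keep[i] = True
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def classify_rearrangement(observed: GeneOrder, reference: GeneOrder) -> RearrangementReport:
    """Compare two circular gene orders at block level.

    Displaced genes are those outside a longest common subsequence of the
    two orders; maximal runs of kept genes form the conserved blocks.  The
    trnM translocation (ancestral trnI-trnQ-trnM -> derived trnM-trnI-trnQ)
    is flagged as the Lepidoptera-type TDRL when and only when that block
    permutation is present and the orders otherwise agree.
    """
    if set(observed.names) != set(reference.names):
        only_obs = set(observed.names) - set(reference.names)
        only_ref = set(reference.names) - set(observed.names)
        raise ComparabilityError(
            f"gene sets differ (only observed: {sorted(only_obs)}, "
            f"only reference: {sorted(only_ref)})"
        )
    if observed.entries == reference.entries:
        return RearrangementReport(True, (observed.entries,), (), False)

    obs = list(observed.entries)
    ref = list(reference.entries)
    keep = _lcs_keep(obs, ref)
    displaced = tuple(n for (n, _), k in zip(obs, keep) if not k)
    blocks: list[tuple[tuple[str, int], ...]] = []
    run: list[tuple[str, int]] = []
    for entry, k in zip(obs, keep):
        if k:
            run.append(entry)
        elif run:
            blocks.append(tuple(run))
            run = []
    if run:
        blocks.append(tuple(run))

    def _without(order: GeneOrder, name: str) -> tuple[tuple[str, int], ...]:
        entries = [e for e in order.entries if e[0] != name]
        return GeneOrder._anchor(entries)

    tdrl = (
        observed.contains_block(LEPIDOPTERA_BLOCK)
        and reference.contains_block(ANCESTRAL_INSECT_BLOCK)
        and _without(observed, "trnM") == _without(reference, "trnM")
    )
    return RearrangementReport(False, tuple(blocks), displaced, tdrl)


@dataclass(frozen=True)
class Junction:
    upstream: str
    downstream: str
    relationship: str  # overlap | spacer | abutting
    length: int
    cr_adjacent: bool


@dataclass
class JunctionReport:
    """All consecutive-gene junctions around the circle, with pooled totals.

    Totals exclude the two control-region-adjacent junctions unless
    ``include_cr`` is set: partial control regions make CR-flanking gaps
    assembly artifacts rather than biology.
    """

    rows: list[Junction]
    include_cr: bool = False

    def _counted(self) -> list[Junction]:
        return [j for j in self.rows if self.include_cr or not j.cr_adjacent]

    @property
    def overlaps(self) -> list[Junction]:
        return [j for j in self._counted() if j.relationship == "overlap"]

    @property
    def spacers(self) -> list[Junction]:
        return [j for j in self._counted() if j.relationship == "spacer"]

    @property
    def n_overlaps(self) -> int:
        return len(self.overlaps)

    @property
    def total_overlap_bp(self) -> int:
        return sum(j.length for j in self.overlaps)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def total_spacer_bp(self) -> int:
        return sum(j.length for j in self.spacers)

    @property
    def longest_overlap(self) -> Junction | None:
        return max(self.overlaps, key=lambda j: j.length, default=None)

    def get(self, upstream: str, downstream: str) -> Junction:
        for j in self.rows:
            if j.upstream == upstream and j.downstream == downstream:
                return j
        raise KeyError((upstream, downstream))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(j.upstream, j.downstream, j.relationship, j.length, j.cr_adjacent)
             for j in self.rows],
            columns=["upstream", "downstream", "relationship", "length_bp", "cr_adjacent"],
        )


def junctions(genome: MitoGenome, include_cr: bool = False) -> JunctionReport:
    """Overlap/spacer/abutting relationships between consecutive genes.

    Junctions are defined on genomic position alone, pooling both strands.
    Nested features (one fully inside another) are rejected.
    """
    L = genome.length
    feats = sorted(genome.features, key=lambda f: (f.start % L, f.end))
    for a, b in zip(feats, feats[1:]):
        if b.end <= a.end and b.start >= a.start:
            raise TopologyError(
                f"nested features: {b.canonical_name} inside {a.canonical_name}"
            )
    rows: list[Junction] = []
    n = len(feats)
    for i, a in enumerate(feats):
        b = feats[(i + 1) % n]
        if i + 1 < n:
            gap = b.start - a.end
        else:
            gap = b.start + L - a.end  # wrap around the origin
        if gap < 0:
            rel, length = "overlap", -gap
        elif gap > 0:
            rel, length = "spacer", gap
        else:
            rel, length = "abutting", 0
        cr_adj = "control_region" in (a.gene_class, b.gene_class)
        rows.append(Junction(a.canonical_name, b.canonical_name, rel, length, cr_adj))
    return JunctionReport(rows, include_cr=include_cr)


@dataclass
class StrandCensus:
    """Gene counts per (strand, gene class), with per-strand totals."""

    counts: dict[tuple[int, str], int] = field(default_factory=dict)

    def total(self, strand: int) -> int:
        return sum(v for (s, _), v in self.counts.items() if s == strand)

    def get(self, strand: int, gene_class: str) -> int:
        return self.counts.get((strand, gene_class), 0)

    @property
    def majority_total(self) -> int:
        return self.total(1)

    @property
    def minority_total(self) -> int:
        return self.total(-1)

    def as_frame(self) -> pd.DataFrame:
        classes = sorted({c for _, c in self.counts} | {"PCG", "tRNA", "rRNA"})
        data = {
            "majority(+)": [self.get(1, c) for c in classes],
            "minority(-)": [self.get(-1, c) for c in classes],
        }
        df = pd.DataFrame(data, index=pd.Index(classes, name="gene_class"))
        df.loc["total"] = [self.majority_total, self.minority_total]
        return df


def strand_census(genome: MitoGenome) -> StrandCensus:
    census = StrandCensus()
    for f in genome.features:
        if f.gene_class == "control_region":
            continue
        key = (f.strand, f.gene_class)
        census.counts[key] = census.counts.get(key, 0) + 1
    return census
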