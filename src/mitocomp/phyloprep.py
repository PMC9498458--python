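"""Phylogenetic matrix preparation: block filtering, concatenation, NJ sanity tree.

Per-gene codon alignments are cleaned with a conserved-block filter in the
style of Gblocks (columns classified by majority-residue fraction; long
nonconserved stretches removed; blocks trimmed to highly conserved flanks;
short blocks dropped), concatenated into a supermatrix with per-gene and
per-codon-position partition definitions, and exported as FASTA, relaxed
PHYLIP or NEXUS with charsets.  A neighbor-joining tree on K2P or TN93
distances serves as a quick sanity check of the matrix; model selection
and ML/Bayesian inference are downstream tools' business.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

from .genomes import Alignment
from .saturation import k2p_distance, tn93_distance

__all__ = [
    "BlockFilterParams",
    "Partition",
    "Supermatrix",
    "SaturatedPairError",
    "conserved_block_filter",
    "concatenate",
    "nj_tree",
    "write_matrix",
    "read_fasta_matrix",
    "codon_pairwise_align",
]


@dataclass(frozen=True)
class BlockFilterParams:
    """Column-filtering thresholds (Gblocks-like semantics).

    A column is conserved when its majority residue occurs in strictly more
    than ``conserved_fraction`` of the sequences (highly conserved:
    ``highly_conserved_fraction``).  Runs of contiguous nonconserved
    columns longer than ``max_nonconserved_run`` are removed, remaining
    blocks are trimmed until they start and end on highly conserved
    columns, and blocks shorter than ``min_block_length`` are dropped.
    ``gap_policy``: ``none`` (any gap makes a column nonconserved),
    ``half`` (more than half gaps does), ``all`` (gaps ignored).
    """

    conserved_fraction: float = 0.5
    highly_conserved_fraction: float = 0.85
    max_nonconserved_run: int = 8
    min_block_length: int = 10
    gap_policy: str = "none"

    def __post_init__(self) -> None:
        if not (0.5 <= self.conserved_fraction <= self.highly_conserved_fraction <= 1.0):
            raise ValueError("require 0.5 <= conserved <= highly_conserved <= 1")
        if self.max_nonconserved_run < 1 or self.min_block_length < 1:
            raise ValueError("run and block lengths must be >= 1")
        if self.gap_policy not in ("none", "half", "all"):
            raise ValueError(f"unknown gap policy {self.gap_policy!r}")


def _classify_columns(aln: Alignment, params: BlockFilterParams) -> list[str]:
    """Per-column label: 'nonconserved', 'conserved' or 'highly'."""
    n = aln.n_rows
    labels = []
    for i in range(aln.length):
        col = aln.column(i)
        gaps = sum(1 for c in col if c == "-")
        if params.gap_policy == "none" and gaps > 0:
            labels.append("nonconserved")
            continue
        if params.gap_policy == "half" and gaps > n / 2:
            labels.append("nonconserved")
            continue
        residues = [c for c in col if c != "-"]
        top = max((residues.count(b) for b in set(residues)), default=0)
        frac = top / n
        if frac > params.highly_conserved_fraction:
            labels.append("highly")
        elif frac > params.conserved_fraction:
            labels.append("conserved")
        else:
            labels.append("nonconserved")
    return labels


def conserved_block_filter(
    aln: Alignment, params: BlockFilterParams | None = None
) -> tuple[Alignment, list[int]]:
    """Keep conserved blocks of an alignment; return (filtered, kept columns).

    The kept-column map is strictly increasing, permitting coordinate
    lift-over; residues are never edited or reordered.  An empty result
    produces a warning and an empty alignment.
    """
    if aln.n_rows < 4:
        raise ValueError("block filtering requires at least 4 sequences")
    params = params or BlockFilterParams()
    labels = _classify_columns(aln, params)
    L = aln.length

    # gap policy applies first: violating columns are removed outright
    removed = [False] * L
    n = aln.n_rows
    for i in range(L):
        gaps = sum(1 for c in aln.column(i) if c == "-")
        if (params.gap_policy == "none" and gaps > 0) or (
            params.gap_policy == "half" and gaps > n / 2
        ):
            removed[i] = True
    i = 0
    while i < L:
        if labels[i] == "nonconserved":
            j = i
            while j < L and labels[j] == "nonconserved":
                j += 1
            if j - i > params.max_nonconserved_run:
                for k in range(i, j):
                    removed[k] = True
            i = j
        else:
            i += 1

    kept: list[int] = []
    i = 0
    while i < L:
        if removed[i]:
            i += 1
            continue
        j = i
        while j < L and not removed[j]:
            j += 1
        block = list(range(i, j))
        while block and labels[block[0]] != "highly":
            block.pop(0)
        while block and labels[block[-1]] != "highly":
            block.pop()
        if len(block) >= params.min_block_length:
            kept.extend(block)
        i = j

    if not kept:
        warnings.warn(f"{aln.gene_name}: all columns filtered out")
    rows = [(t, "".join(s[i] for i in kept)) for t, s in aln.rows]
    return Alignment(aln.gene_name, rows), kept


@dataclass(frozen=True)
class Partition:
    """One charset: 1-based inclusive matrix coordinates, optional codon stride."""

    gene: str
    codon_position: int | None
    start: int
    end: int

    @property
    def label(self) -> str:
        if self.codon_position is None:
            return self.gene
        return f"{self.gene}_pos{self.codon_position}"

    @property
    def charset_range(self) -> str:
        if self.codon_position is None:
            return f"{self.start}-{self.end}"
        return f"{self.start}-{self.end}\\3"


@dataclass
class Supermatrix:
    """Concatenated multi-gene alignment with partition definitions."""

    rows: dict[str, str]
    gene_partitions: list[Partition]
    codon_partitions: list[Partition] = field(default_factory=list)
    taxon_family: dict[str, str] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def partitions(self) -> list[Partition]:
        return self.gene_partitions + self.codon_partitions

    def validate(self) -> None:
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"unequal row lengths {sorted(lens)}")
        pos = 1
        for p in self.gene_partitions:
            if p.start != pos or p.end < p.start:
                raise ValueError(f"partitions do not tile: {p} at expected start {pos}")
            pos = p.end + 1
        if self.gene_partitions and pos - 1 != self.length:
            raise ValueError(
                f"partitions cover {pos - 1} of {self.length} columns"
            )


def concatenate(
    alignments: dict[str, Alignment],
    gene_order: list[str] | None = None,
    taxon_family: dict[str, str] | None = None,
) -> Supermatrix:
    """Append per-gene alignments into a supermatrix.

    Taxa missing from a gene receive gap runs.  Partition records are
    emitted per gene and, for codon-aligned genes, per codon position.
    """
    order = gene_order or sorted(alignments)
    taxa = sorted({t for g in order for t in alignments[g].taxa})
    parts_gene: list[Partition] = []
    parts_codon: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for gene in order:
        aln = alignments[gene]
        L = aln.length
        for t in taxa:
            try:
                chunks[t].append(aln.get(t))
            except KeyError:
                chunks[t].append("-" * L)
        parts_gene.append(Partition(gene, None, pos, pos + L - 1))
        if L % 3 == 0 and L > 0:
            for p in (1, 2, 3):
                parts_codon.append(Partition(gene, p, pos + p - 1, pos + L - 1))
        pos += L
    matrix = Supermatrix(
        rows={t: "".join(chunks[t]) for t in taxa},
        gene_partitions=parts_gene,
        codon_partitions=parts_codon,
        taxon_family=dict(taxon_family or {}),
    )
    matrix.validate()
    return matrix


# --- neighbor joining -------------------------------------------------------


class SaturatedPairError(ValueError):
    pass


def _distance_matrix(matrix: Supermatrix, distance: str):
    dist_fn = {"K2P": k2p_distance, "TN93": tn93_distance}[distance]
    taxa = matrix.taxa
    n = len(taxa)
    d = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            v = dist_fn(matrix.rows[taxa[i]], matrix.rows[taxa[j]])
            if math.isnan(v):
                raise SaturatedPairError(
                    f"distance undefined (saturated) for pair ({taxa[i]}, {taxa[j]})"
                )
            d[i][j] = d[j][i] = v
    return taxa, d


def nj_tree(matrix: Supermatrix, distance: str = "K2P") -> str:
    """Neighbor-joining tree on pairwise-deletion distances, as unrooted newick.

    Ties in the Q criterion break on the lowest (i, j) index pair; negative
    branch lengths are clamped to 0 with the deficit moved to the sibling
    edge.
    """
    taxa, d = _distance_matrix(matrix, distance)
    if len(taxa) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [f"{_sanitize(t)}" for t in taxa]
    active = list(range(len(taxa)))
    dist = {(i, j): d[i][j] for i in range(len(taxa)) for j in range(len(taxa))}
    next_id = len(taxa)
    labels: dict[int, str] = {i: nodes[i] for i in active}

    def D(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))] if i != j else 0.0

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D(i, k) for k in active) for i in active}
        best = None
        best_q = math.inf
        for a_idx, i in enumerate(active):
            for j in active[a_idx + 1:]:
                q = (r - 2) * D(i, j) - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D(i, j) + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D(i, j) - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_id
        next_id += 1
        labels[new] = f"({labels[i]}:{li:.6f},{labels[j]}:{lj:.6f})"
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D(i, k) + D(j, k) - D(i, j))
            dist[(min(new, k), max(new, k))] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new]

    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
        lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
        lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
        return f"({labels[a]}:{la:.6f},{labels[b]}:{lb:.6f},{labels[c]}:{lc:.6f});"
    raise AssertionError("unreachable")


# --- export -----------------------------------------------------------------


def _sanitize(name: str) -> str:
    clean = re.sub(r"[^A-Za-z0-9_.|-]", "_", name)
    if clean != name:
        warnings.warn(f"taxon name {name!r} sanitized to {clean!r}")
    return clean


def write_matrix(matrix: Supermatrix, fmt: str, path) -> None:
    """Write a supermatrix as FASTA, relaxed PHYLIP, or NEXUS with charsets.

    Output is byte-stable for a fixed input (taxa in stored order,
    LF line endings).
    """
    fmt = fmt.lower()
    taxa = matrix.taxa
    with open(path, "w", newline="\n") as fh:
        if fmt == "fasta":
            for t in taxa:
                fh.write(f">{_sanitize(t)}\n{matrix.rows[t]}\n")
        elif fmt == "phylip":
            fh.write(f"{len(taxa)} {matrix.length}\n")
            width = max(len(_sanitize(t)) for t in taxa) + 2
            for t in taxa:
                fh.write(f"{_sanitize(t):<{width}}{matrix.rows[t]}\n")
        elif fmt == "nexus":
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(taxa)} NCHAR={matrix.length};\n")
            fh.write("  FORMAT DATATYPE=DNA GAP=- MISSING=N;\n  MATRIX\n")
            width = max(len(_sanitize(t)) for t in taxa) + 2
            for t in taxa:
                fh.write(f"    {_sanitize(t):<{width}}{matrix.rows[t]}\n")
            fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
            for p in matrix.partitions:
                fh.write(f"  CHARSET {p.label} = {p.charset_range};\n")
            fh.write("END;\n")
        else:
            raise ValueError(f"unknown format {fmt!r} (fasta, phylip, nexus)")


def read_fasta_matrix(path) -> dict[str, str]:
    """Read a FASTA supermatrix back into a taxon -> sequence mapping."""
    rows: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    rows[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        rows[name] = "".join(chunks)
    return rows


# --- codon-aware pairwise alignment ----------------------------------------


def codon_pairwise_align(
    cds1: str, cds2: str, gap_penalty: float = -4.0
) -> tuple[str, str]:
    """Global pairwise alignment of two in-frame CDS at codon granularity.

    Needleman–Wunsch over codon units: substituting one codon for another
    scores the number of matching bases (0–3); inserting a codon gap costs
    ``gap_penalty``.  Gaps are therefore always length-3, keeping both
    output sequences in frame.  This is a convenience for unaligned
    same-gene CDS pairs; multiple alignment is out of scope.
    """
    for s in (cds1, cds2):
        if len(s) % 3 != 0:
            raise ValueError("codon alignment requires in-frame sequences")
    a = [cds1[i:i + 3] for i in range(0, len(cds1), 3)]
    b = [cds2[i:i + 3] for i in range(0, len(cds2), 3)]
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    back = [[0] * (m + 1) for _ in range(n + 1)]  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        score[i][0] = i * gap_penalty
        back[i][0] = 1
    for j in range(1, m + 1):
        score[0][j] = j * gap_penalty
        back[0][j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            match = sum(x == y for x, y in zip(ai, bj))
            diag = score[i - 1][j - 1] + match
            up = score[i - 1][j] + gap_penalty
            left = score[i][j - 1] + gap_penalty
            best = max(diag, up, left)
            score[i][j] = best
            back[i][j] = 0 if best == diag else (1 if best == up else 2)
    out1: list[str] = []
    out2: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = back[i][j]
        if move == 0 and i > 0 and j > 0:
            out1.append(a[i - 1])
            out2.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == 1 and i > 0:
            out1.append(a[i - 1])
            out2.append("---")
            i -= 1
        else:
            out1.append("---")
            out2.append(b[j - 1])
            j -= 1
    return "".join(reversed(out1)), "".join(reversed(out2))
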