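"""Synthetic annotated mitogenomes and evolved gene alignments.

The generator emulates the architecture of moth (Lepidoptera) mitogenomes:
a circular molecule of ~15.2 kb carrying 13 PCGs, 22 tRNAs, 2 rRNAs and a
control region, 78–82% A+T, the derived trnM-trnI-trnQ tRNA block, a fixed
junction plan with conserved overlaps (ATP8/ATP6, trnC/trnW, and a 25 bp
trnL1/rrnL overlap), and per-gene start/stop codon plans including
truncated stops.  PCGs are valid ORFs under the invertebrate mitochondrial
code.  Sequence evolution along a tree uses an HKY-like proposal kernel
with proposal-rejection selection: proposals creating stops are rejected,
nonsynonymous proposals are accepted with probability omega, synonymous
proposals always — exact enough for rate-ranking studies while staying
auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .codes import complement, get_code, is_transition, reverse_complement
from .codon_usage import trim_terminal_stop
from .genomes import Alignment, GeneFeature, MitoGenome, gene_class_of

__all__ = [
    "GenomeTemplate",
    "EvolutionParams",
    "TemplateError",
    "generate_genome",
    "apply_tdrl",
    "evolve_genes",
    "simulate_neutral_alignment",
    "family_study_tree",
    "random_binary_tree",
]

_BASES = "ACGT"


class TemplateError(ValueError):
    """An infeasible genome template (junction plan vs gene lengths)."""


# (name, strand, length) around the circle, control region last.
_DEFAULT_GENES: tuple[tuple[str, int, int], ...] = (
    ("trnM", 1, 68), ("trnI", 1, 65), ("trnQ", -1, 69),
    ("ND2", 1, 1023),
    ("trnW", 1, 67), ("trnC", -1, 66), ("trnY", -1, 65),
    ("COX1", 1, 1534),
    ("trnL2", 1, 67),
    ("COX2", 1, 683),
    ("trnK", 1, 70), ("trnD", 1, 67),
    ("ATP8", 1, 165), ("ATP6", 1, 678), ("COX3", 1, 789),
    ("trnG", 1, 65),
    ("ND3", 1, 354),
    ("trnA", 1, 66), ("trnR", 1, 64), ("trnN", 1, 65),
    ("trnS1", 1, 67), ("trnE", 1, 65), ("trnF", -1, 66),
    ("ND5", -1, 1736),
    ("trnH", -1, 65),
    ("ND4", -1, 1339), ("ND4L", -1, 291),
    ("trnT", 1, 64), ("trnP", -1, 65),
    ("ND6", 1, 531), ("CYTB", 1, 1140),
    ("trnS2", 1, 68),
    ("ND1", -1, 936),
    ("trnL1", -1, 67), ("rrnL", -1, 1398), ("trnV", -1, 65), ("rrnS", -1, 779),
    ("CR", 1, 380),
)

# junction plan: gap in bp between consecutive genes (negative = overlap);
# junctions not listed abut exactly.
_DEFAULT_GAPS: dict[tuple[str, str], int] = {
    ("trnQ", "ND2"): 45,
    ("ND2", "trnW"): -2,
    ("trnW", "trnC"): -8,
    ("trnC", "trnY"): -2,
    ("trnY", "COX1"): 3,
    ("ATP8", "ATP6"): -7,
    ("ATP6", "COX3"): -1,
    ("trnR", "trnN"): -1,
    ("trnS1", "trnE"): 2,
    ("trnE", "trnF"): 1,
    ("ND4L", "trnT"): -1,
    ("trnT", "trnP"): -1,
    ("trnS2", "ND1"): 20,
    ("trnL1", "rrnL"): -25,
}

#: start codons per PCG (ATN for most; the alternatives seen in moths)
_DEFAULT_STARTS: dict[str, str] = {
    "ND2": "ATT", "COX1": "CGA", "COX2": "ATG", "ATP8": "ATT", "ATP6": "ATG",
    "COX3": "ATG", "ND3": "ATT", "ND5": "ATT", "ND4": "ATG", "ND4L": "ATG",
    "ND6": "ATA", "CYTB": "ATG", "ND1": "TTG",
}

#: stop plan per PCG: TAA/TAG complete, or truncated "TA"/"T"
_DEFAULT_STOPS: dict[str, str] = {
    "ND2": "TAA", "COX1": "T", "COX2": "TA", "ATP8": "TAA", "ATP6": "TAA",
    "COX3": "TAA", "ND3": "TAG", "ND5": "TA", "ND4": "T", "ND4L": "TAG",
    "ND6": "TAA", "CYTB": "TAA", "ND1": "TAG",
}


@dataclass(frozen=True)
class GenomeTemplate:
    """Blueprint for one synthetic mitogenome.

    ``genes`` lists (canonical name, strand, length) in genomic order with
    the control region last; ``junction_gaps`` gives the signed gap at each
    named junction (negative = overlap; unlisted junctions abut).
    ``rearranged`` selects the derived Lepidoptera trnM-trnI-trnQ block
    (the default) or the ancestral insect trnI-trnQ-trnM.
    """

    genes: tuple[tuple[str, int, int], ...] = _DEFAULT_GENES
    junction_gaps: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_GAPS)
    )
    target_at: float = 0.80
    rearranged: bool = True
    start_plan: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_STARTS))
    stop_plan: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_STOPS))
    tta_boost: float = 6.0
    pos3_t_bias: float = 2.0
    identifier: str = "synthetic_mitogenome"
    taxon_family: str | None = None

    def __post_init__(self) -> None:
        classes = [gene_class_of(n) for n, _, _ in self.genes]
        counts = {c: classes.count(c) for c in set(classes)}
        if (counts.get("PCG"), counts.get("tRNA"), counts.get("rRNA"),
                counts.get("control_region")) != (13, 22, 2, 1):
            raise TemplateError(
                f"need 13 PCG + 22 tRNA + 2 rRNA + 1 CR, got {counts}"
            )
        if not 0.70 <= self.target_at <= 0.90:
            raise TemplateError("target AT fraction must lie in [0.70, 0.90]")
        lengths = {n: l for n, _, l in self.genes}
        for (a, b), gap in self.junction_gaps.items():
            if gap < 0 and -gap >= min(lengths.get(a, 1), lengths.get(b, 1)):
                raise TemplateError(f"overlap at ({a}, {b}) exceeds a gene length")

    @property
    def ordered_genes(self) -> tuple[tuple[str, int, int], ...]:
        if self.rearranged:
            return self.genes
        # ancestral arrangement: swap the leading trnM-trnI-trnQ block back
        names = [g[0] for g in self.genes]
        i_m, i_i, i_q = names.index("trnM"), names.index("trnI"), names.index("trnQ")
        if (i_i, i_q) != (i_m + 1, i_m + 2):
            raise TemplateError("ancestral layout needs a contiguous trnM-trnI-trnQ block")
        genes = list(self.genes)
        block = [genes[i_i], genes[i_q], genes[i_m]]
        genes[i_m:i_m + 3] = block
        return tuple(genes)

    @classmethod
    def default(cls, **kwargs) -> "GenomeTemplate":
        return cls(**kwargs)

    @classmethod
    def randomized(cls, seed: int) -> "GenomeTemplate":
        """A seeded random variant: jittered lengths, gaps and AT target."""
        rng = np.random.default_rng(seed)
        genes = []
        for name, strand, length in _DEFAULT_GENES:
            cls_ = gene_class_of(name)
            if cls_ == "tRNA":
                length += int(rng.integers(-4, 5))
            elif cls_ == "rRNA":
                length += int(rng.integers(-50, 51))
            elif cls_ == "control_region":
                length = int(rng.integers(300, 601))
            genes.append((name, strand, length))
        # the ATP8/ATP6 overlap stays at its conserved 7 bp: its size is
        # coupled to the fixed stop/start codon geometry of the two genes
        gaps = dict(_DEFAULT_GAPS)
        gaps[("trnW", "trnC")] = -int(rng.integers(1, 13))
        gaps[("trnL1", "rrnL")] = -int(rng.integers(10, 31))
        gaps[("trnQ", "ND2")] = int(rng.integers(0, 61))
        gaps[("trnS2", "ND1")] = int(rng.integers(0, 31))
        gaps[("trnS1", "trnE")] = int(rng.integers(0, 16))
        return cls(
            genes=tuple(genes),
            junction_gaps=gaps,
            target_at=float(rng.uniform(0.78, 0.82)),
            rearranged=bool(rng.integers(0, 2)),
            identifier=f"synthetic_mitogenome_{seed}",
        )


# --- sequence sampling machinery -------------------------------------------


def _base_weights(target_at: float, skew_a: float = 0.52, skew_c: float = 0.60):
    """Per-base sampling weights hitting the AT target with mild A>T, C>G skew."""
    at, gc = target_at, 1.0 - target_at
    return {
        "A": at * skew_a, "T": at * (1 - skew_a),
        "C": gc * skew_c, "G": gc * (1 - skew_c),
    }


class _CodonSampler:
    def __init__(self, template: GenomeTemplate, genetic_code: int = 5):
        self.code = get_code(genetic_code)
        w = _base_weights(template.target_at)
        w3 = dict(w)
        w3["T"] *= template.pos3_t_bias  # third positions enriched in T
        self.codons = list(self.code.sense_codons)
        weights = []
        for c in self.codons:
            wt = w[c[0]] * w[c[1]] * w3[c[2]]
            if c == "TTA":
                wt *= template.tta_boost
            weights.append(wt)
        self.weights = np.array(weights)
        self.weights /= self.weights.sum()
        bw = np.array([w[b] for b in _BASES])
        self.base_probs = bw / bw.sum()

    def sample_bulk(self, rng: np.random.Generator, k: int) -> list[str]:
        idx = rng.choice(len(self.codons), size=k, p=self.weights)
        return [self.codons[i] for i in idx]

    def sample_constrained(self, rng: np.random.Generator, fixed: dict[int, str]) -> str:
        """One sense codon consistent with fixed positions {0,1,2} -> base."""
        mask = [
            all(c[p] == b for p, b in fixed.items()) for c in self.codons
        ]
        probs = self.weights * np.array(mask)
        total = probs.sum()
        if total == 0:
            raise _Infeasible(f"no sense codon matches constraints {fixed}")
        i = rng.choice(len(self.codons), p=probs / total)
        return self.codons[i]

    def sample_bases(self, rng: np.random.Generator, k: int) -> str:
        idx = rng.choice(4, size=k, p=self.base_probs)
        return "".join(_BASES[i] for i in idx)


class _Infeasible(Exception):
    pass


def _layout(template: GenomeTemplate):
    """Feature coordinates from the gene order and junction plan."""
    genes = template.ordered_genes
    gaps = template.junction_gaps
    spans = []
    pos = 0
    for i, (name, strand, length) in enumerate(genes):
        spans.append((name, strand, pos, pos + length))
        if i + 1 < len(genes):
            nxt = genes[i + 1][0]
            pos = pos + length + gaps.get((name, nxt), 0)
            if pos < 0:
                raise TemplateError(f"junction plan pushes {nxt} before the origin")
    total = spans[-1][3] + gaps.get((genes[-1][0], genes[0][0]), 0)
    return spans, total


def _stop_tail(stop: str) -> str:
    """Coding-sequence tail implied by a stop plan entry."""
    if stop in ("TAA", "TAG"):
        return stop
    if stop in ("TA", "T"):
        return stop
    raise TemplateError(f"unknown stop plan entry {stop!r}")


def _write(genome: list[str], pos: int, base: str) -> None:
    genome[pos] = base


def _generate_once(template: GenomeTemplate, rng: np.random.Generator) -> MitoGenome:
    sampler = _CodonSampler(template)
    spans, L = _layout(template)
    genome: list[str] = [""] * L
    by_name = {name: (name, strand, s, e) for name, strand, s, e in spans}

    # pre-fix start codons of plus-strand PCGs whose 5' end is overlapped by
    # the previous gene, so the upstream sampler produces consistent bases
    prefixed: dict[int, str] = {}
    for i, (name, strand, s, e) in enumerate(spans[:-1]):
        nxt_name, nxt_strand, ns, ne = spans[i + 1]
        overlap = e - ns
        if overlap <= 0 or gene_class_of(nxt_name) != "PCG":
            continue
        if nxt_strand == 1:
            start = template.start_plan[nxt_name]
            for k in range(min(overlap, 3)):
                prefixed[ns + k] = start[k]
        else:
            tail = _stop_tail(template.stop_plan[nxt_name])
            # minority strand: genomic start holds the reverse complement of
            # the coding 3' tail
            rc = reverse_complement(tail)
            for k in range(min(overlap, len(rc))):
                prefixed[ns + k] = rc[k]

    for name, strand, s, e in spans:
        span = e - s
        if gene_class_of(name) != "PCG":
            todo = [g % L for g in range(s, e) if not genome[g % L]]
            for g in todo:
                if g in prefixed:
                    genome[g] = prefixed[g]
            todo = [g for g in todo if not genome[g]]
            for g, b in zip(todo, sampler.sample_bases(rng, len(todo))):
                genome[g] = b
            continue
        # protein-coding gene: build coding-position constraints
        fixed: dict[int, str] = {}
        for g in range(s, e):
            base = genome[g % L] or prefixed.get(g, "")
            if base:
                cp = (g - s) if strand == 1 else (span - 1 - (g - s))
                fixed[cp] = base if strand == 1 else complement(base)
        start = template.start_plan[name]
        for k in range(3):
            if fixed.get(k, start[k]) != start[k]:
                raise _Infeasible(f"{name}: start codon conflicts with overlap")
            fixed[k] = start[k]
        tail = _stop_tail(template.stop_plan[name])
        rem = span % 3
        if tail in ("TAA", "TAG"):
            if rem != 0:
                raise TemplateError(f"{name}: complete stop needs length % 3 == 0")
        elif len(tail) != rem:
            raise TemplateError(
                f"{name}: truncated stop {tail!r} needs length % 3 == {len(tail)}"
            )
        for k, b in enumerate(tail):
            cp = span - len(tail) + k
            if fixed.get(cp, b) != b:
                raise _Infeasible(f"{name}: stop codon conflicts with overlap")
            fixed[cp] = b
        n_full = span // 3
        coding: list[str] = []
        stop_codon_index = n_full - 1 if (rem == 0) else None
        for ci in range(n_full):
            cfix = {p: fixed[3 * ci + p] for p in range(3) if 3 * ci + p in fixed}
            if ci == stop_codon_index:
                codon = tail  # planned complete stop
                for p, b in cfix.items():
                    if codon[p] != b:
                        raise _Infeasible(f"{name}: stop codon conflict")
            elif cfix:
                codon = sampler.sample_constrained(rng, cfix)
            else:
                codon = None  # fill in bulk below
            coding.append(codon)
        free_idx = [i for i, c in enumerate(coding) if c is None]
        for i, codon in zip(free_idx, sampler.sample_bulk(rng, len(free_idx))):
            coding[i] = codon
        cds = "".join(coding) + (tail if rem else "")
        assert len(cds) == span
        segment = cds if strand == 1 else reverse_complement(cds)
        for k, b in enumerate(segment):
            genome[(s + k) % L] = b

    todo = [g for g in range(L) if not genome[g]]  # intergenic spacers
    for g, b in zip(todo, sampler.sample_bases(rng, len(todo))):
        genome[g] = b

    # tune realized AT% toward the target by flipping bases outside PCG spans
    pcg_mask = np.zeros(L, dtype=bool)
    for name, strand, s, e in spans:
        if gene_class_of(name) == "PCG":
            for g in range(s, e):
                pcg_mask[g % L] = True
    seq = np.array(genome)
    at_now = int(np.isin(seq, ["A", "T"]).sum())
    delta = round(template.target_at * L) - at_now
    if delta > 0:
        pool = np.flatnonzero(~pcg_mask & np.isin(seq, ["C", "G"]))
        pick = rng.choice(pool, size=min(delta, len(pool)), replace=False)
        seq[pick] = rng.choice(["A", "T"], size=len(pick), p=[0.52, 0.48])
    elif delta < 0:
        pool = np.flatnonzero(~pcg_mask & np.isin(seq, ["A", "T"]))
        pick = rng.choice(pool, size=min(-delta, len(pool)), replace=False)
        seq[pick] = rng.choice(["C", "G"], size=len(pick), p=[0.60, 0.40])

    features = [
        GeneFeature(name, gene_class_of(name), s, e, strand, wraps_origin=e > L)
        for name, strand, s, e in spans
    ]
    genome_obj = MitoGenome(
        identifier=template.identifier,
        sequence="".join(seq),
        features=features,
        is_circular=True,
        taxon_family=template.taxon_family,
    )
    genome_obj.validate()
    return genome_obj


def generate_genome(template: GenomeTemplate, seed: int) -> MitoGenome:
    """Sample a concrete annotated genome from a template, deterministically.

    The junction plan is realized exactly; PCGs are valid ORFs with the
    planned start/stop classes; realized AT% lands within ~0.5 of the
    target.  The same (template, seed) always yields the same genome.
    """
    for attempt in range(25):
        rng = np.random.default_rng((seed, attempt))
        try:
            return _generate_once(template, rng)
        except _Infeasible:
            continue
    raise TemplateError("could not realize template (overlap constraints unsatisfiable)")


class TDRLError(ValueError):
    pass


def apply_tdrl(genome: MitoGenome) -> MitoGenome:
    """Rewrite an ancestral trnI-trnQ-trnM block to the derived trnM-trnI-trnQ.

    Models the tandem duplication–random loss outcome: the trnM segment is
    excised and reinserted before trnI; coordinates shift consistently and
    the genome length is unchanged.  Requires the three tRNAs contiguous,
    in ancestral order, and non-overlapping.
    """
    try:
        f_i = genome.feature_by_name("trnI")
        f_q = genome.feature_by_name("trnQ")
        f_m = genome.feature_by_name("trnM")
    except KeyError as exc:
        raise TDRLError(f"missing tRNA: {exc}") from exc
    ordered = sorted(genome.features, key=lambda f: f.start)
    idx = {f.canonical_name: i for i, f in enumerate(ordered)}
    if not (idx["trnQ"] == idx["trnI"] + 1 and idx["trnM"] == idx["trnQ"] + 1):
        raise TDRLError("ancestral trnI-trnQ-trnM block not contiguous")
    if not (f_i.end <= f_q.start and f_q.end <= f_m.start):
        raise TDRLError("block tRNAs overlap; rearrangement undefined")
    s = f_i.start
    seq = genome.sequence
    chunk_i = seq[f_i.start:f_q.start]
    chunk_q = seq[f_q.start:f_m.start]
    chunk_m = seq[f_m.start:f_m.end]
    new_seq = seq[:s] + chunk_m + chunk_i + chunk_q + seq[f_m.end:]
    assert len(new_seq) == genome.length
    new_feats = []
    for f in genome.features:
        if f.canonical_name == "trnM":
            new_feats.append(replace(f, start=s, end=s + f.span))
        elif f.canonical_name in ("trnI", "trnQ"):
            new_feats.append(
                replace(f, start=f.start + f_m.span, end=f.end + f_m.span)
            )
        else:
            new_feats.append(f)
    return MitoGenome(
        genome.identifier, new_seq, new_feats, genome.is_circular, genome.taxon_family
    )


# --- sequence evolution -----------------------------------------------------


@dataclass(frozen=True)
class EvolutionParams:
    """Evolution settings: tree, per-gene rates and selection, HKY kernel.

    Branch lengths are expected proposed substitutions per site before
    selective rejection; synonymous divergence therefore tracks branch
    length while nonsynonymous divergence is thinned by omega.
    """

    tree: str
    seed: int = 0
    gene_rate: dict[str, float] = field(default_factory=dict)
    gene_omega: dict[str, float] = field(default_factory=dict)
    default_omega: float = 0.1
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.40, 0.12, 0.08, 0.40)
    genetic_code: int = 5
    include_rrna: bool = True

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.gene_omega.values()) or self.default_omega <= 0:
            raise ValueError("omega must be > 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


class _Kernel:
    """Per-base proposal distributions of an HKY-like mutation kernel."""

    def __init__(self, kappa: float, freqs):
        f = dict(zip(_BASES, freqs))
        self.alts: dict[str, tuple[str, ...]] = {}
        self.cum: dict[str, np.ndarray] = {}
        for b in _BASES:
            alts = tuple(x for x in _BASES if x != b)
            w = np.array([f[x] * (kappa if is_transition(b, x) else 1.0) for x in alts])
            self.alts[b] = alts
            self.cum[b] = np.cumsum(w / w.sum())

    def propose(self, base: str, u: float) -> str:
        return self.alts[base][int(np.searchsorted(self.cum[base], u))]


def _evolve_codons(
    codons: list[str], n_prop: int, omega: float, kernel: _Kernel,
    code, rng: np.random.Generator,
) -> list[str]:
    if n_prop == 0:
        return list(codons)
    out = list(codons)
    nsites = 3 * len(out)
    sites = rng.integers(0, nsites, size=n_prop)
    u_base = rng.random(n_prop)
    u_sel = rng.random(n_prop)
    for k in range(n_prop):
        ci, p = divmod(int(sites[k]), 3)
        old = out[ci]
        nb = kernel.propose(old[p], u_base[k])
        new = old[:p] + nb + old[p + 1:]
        if code.is_stop(new):
            continue
        if code.amino_acid[new] != code.amino_acid[old] and u_sel[k] >= omega:
            continue
        out[ci] = new
    return out


def _evolve_bases(
    seq: str, n_prop: int, kernel: _Kernel, rng: np.random.Generator
) -> str:
    if n_prop == 0:
        return seq
    out = list(seq)
    sites = rng.integers(0, len(out), size=n_prop)
    u = rng.random(n_prop)
    for k in range(n_prop):
        i = int(sites[k])
        if out[i] in kernel.alts:
            out[i] = kernel.propose(out[i], u[k])
    return "".join(out)


def _parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def evolve_genes(
    root: MitoGenome, params: EvolutionParams
) -> tuple[dict[str, Alignment], str]:
    """Evolve each PCG (and optionally the rRNAs) along a tree.

    Returns ``(alignments, tree_newick)``: one gap-free in-frame alignment
    per gene, rows ordered by taxon name.  PCG root sequences are the
    genome's coding sequences trimmed of their (possibly truncated)
    terminal stop.  Deterministic for a fixed seed.
    """
    from .genomes import extract_gene_sequence

    tree = _parse_tree(params.tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")
    code = get_code(params.genetic_code)
    kernel = _Kernel(params.kappa, params.base_freqs)
    rng = np.random.default_rng((params.seed, 0xE70))

    gene_names = [f.canonical_name for f in root.features if f.gene_class == "PCG"]
    if params.include_rrna:
        gene_names += [f.canonical_name for f in root.features if f.gene_class == "rRNA"]

    alignments: dict[str, Alignment] = {}
    for gene in gene_names:
        feat = root.feature_by_name(gene)
        raw = extract_gene_sequence(root, feat)
        is_pcg = feat.gene_class == "PCG"
        mult = params.gene_rate.get(gene, 1.0)
        omega = params.gene_omega.get(gene, params.default_omega)
        if is_pcg:
            cds = trim_terminal_stop(raw, params.genetic_code)
            state0 = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            nsites = 3 * len(state0)
        else:
            state0 = raw
            nsites = len(raw)
        states: dict[int, object] = {}
        rows = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                state = state0
            else:
                parent = states[id(node.parent_node)]
                bl = node.edge.length or 0.0
                n_prop = int(rng.poisson(bl * mult * nsites))
                if is_pcg:
                    state = _evolve_codons(parent, n_prop, omega, kernel, code, rng)
                else:
                    state = _evolve_bases(parent, n_prop, kernel, rng)
            states[id(node)] = state
            if node.is_leaf():
                seq = "".join(state) if is_pcg else state
                rows.append((node.taxon.label, seq))
        rows.sort(key=lambda r: r[0])
        alignments[gene] = Alignment(gene, rows)
    return alignments, params.tree


def simulate_neutral_alignment(
    tree: str,
    length: int,
    seed: int,
    kappa: float = 2.0,
    base_freqs: tuple[float, float, float, float] = (0.40, 0.12, 0.08, 0.40),
    gene_name: str = "locus",
) -> Alignment:
    """Neutral nucleotide evolution of an iid root sequence along a tree."""
    rng = np.random.default_rng((seed, 0x5E0))
    kernel = _Kernel(kappa, base_freqs)
    root_seq = "".join(
        _BASES[i] for i in rng.choice(4, size=length, p=np.array(base_freqs))
    )
    t = _parse_tree(tree)
    states: dict[int, str] = {}
    rows = []
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            state = root_seq
        else:
            bl = node.edge.length or 0.0
            n_prop = int(rng.poisson(bl * length))
            state = _evolve_bases(states[id(node.parent_node)], n_prop, kernel, rng)
        states[id(node)] = state
        if node.is_leaf():
            rows.append((node.taxon.label, state))
    rows.sort(key=lambda r: r[0])
    return Alignment(gene_name, rows)


# --- study-design tree builders ---------------------------------------------


def family_study_tree(
    n_families: int = 6,
    taxa_per_family: int = 4,
    within: float = 0.06,
    stem: float = 0.05,
    long_family: int | None = None,
    long_factor: float = 2.0,
) -> tuple[str, dict[str, str]]:
    """A star-of-families tree with balanced subtrees, plus taxon->family map.

    Family ``long_family`` (0-based index) gets all its branch lengths
    multiplied by ``long_factor`` — the elevated-synonymous-rate lineage of
    the study design.
    """
    subtrees = []
    groups: dict[str, str] = {}
    for fi in range(n_families):
        fam = f"F{fi + 1}"
        scale = long_factor if fi == long_family else 1.0
        b = within * scale
        taxa = [f"{fam}_t{j + 1}" for j in range(taxa_per_family)]
        for t in taxa:
            groups[t] = fam
        tips = [f"{t}:{b:.6f}" for t in taxa]
        # balanced pairing, then a ladder for any odd remainder
        while len(tips) > 1:
            merged = []
            for i in range(0, len(tips) - 1, 2):
                merged.append(f"({tips[i]},{tips[i + 1]}):{b:.6f}")
            if len(tips) % 2:
                merged[-1] = f"({merged[-1]},{tips[-1]}):{b:.6f}"
            tips = merged
        subtrees.append(f"({tips[0]}):{stem * scale:.6f}"
                        if taxa_per_family > 1 else f"{tips[0]}:{stem * scale:.6f}")
    newick = "(" + ",".join(subtrees) + ");"
    return newick, groups


def random_binary_tree(
    n_taxa: int,
    seed: int,
    terminal_range: tuple[float, float] = (0.05, 0.15),
    internal_range: tuple[float, float] = (0.02, 0.08),
) -> str:
    """A random binary topology with uniform branch lengths, as newick."""
    rng = np.random.default_rng((seed, 0x73E))
    nodes = [
        f"t{i + 1}:{rng.uniform(*terminal_range):.6f}" for i in range(n_taxa)
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(f"({a},{b}):{rng.uniform(*internal_range):.6f}")
    return f"({nodes[0]},{nodes[1]});"
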