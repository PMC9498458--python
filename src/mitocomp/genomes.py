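"""Domain types and I/O for annotated mitochondrial genomes.

The unit of analysis is the :class:`MitoGenome`: a circular molecule of
~15–16 kb carrying 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and a
control region.  Internally all coordinates are 0-based half-open; GenBank's
1-based inclusive convention is converted at the I/O boundary.  Features may
wrap the replication origin, in which case ``end`` exceeds the genome length
and interval arithmetic runs on doubled coordinates.

Gene names are normalised into a controlled vocabulary (COX1–3, CYTB,
ND1–6, ND4L, ATP6, ATP8, rrnL, rrnS, trnX with trnL1/trnL2/trnS1/trnS2,
CR) so that every downstream stage can key on canonical names.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codes import reverse_complement

__all__ = [
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "GeneFeature",
    "MitoGenome",
    "Alignment",
    "CanonicalizationError",
    "MitoFormatError",
    "normalize_gene_name",
    "gene_class_of",
    "extract_gene_sequence",
    "read_genbank",
    "write_genbank",
    "read_fasta_alignment",
    "write_fasta_alignment",
]

PCG_NAMES = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)
_AA1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Lys": "K", "Met": "M",
    "Phe": "F", "Pro": "P", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Leu": "L", "Ser": "S",
}
TRNA_NAMES = tuple(
    sorted(
        ["trn%s" % a for a in "ARNDCQEGHIKMFPTWYV"] + ["trnL1", "trnL2", "trnS1", "trnS2"]
    )
)
RRNA_NAMES = ("rrnL", "rrnS")
CONTROL_REGION = "CR"

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region")


class CanonicalizationError(ValueError):
    """A gene name that cannot be mapped to the controlled vocabulary."""


class MitoFormatError(ValueError):
    """An input file that cannot be parsed as an annotated mitogenome."""


def gene_class_of(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES or name.startswith("trn"):
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == CONTROL_REGION:
        return "control_region"
    raise CanonicalizationError(f"no gene class for {name!r}")


def _build_synonyms() -> dict[str, str]:
    syn: dict[str, str] = {}

    def add(canonical: str, *names: str) -> None:
        for n in names:
            syn[n.lower().replace(" ", "").replace("-", "").replace("_", "")] = canonical

    add("COX1", "cox1", "coi", "co1", "coxi", "cox I",
        "cytochrome c oxidase subunit i", "cytochrome c oxidase subunit 1",
        "cytochrome oxidase subunit i", "cytochrome oxidase subunit 1")
    add("COX2", "cox2", "coii", "co2", "coxii",
        "cytochrome c oxidase subunit ii", "cytochrome c oxidase subunit 2",
        "cytochrome oxidase subunit ii", "cytochrome oxidase subunit 2")
    add("COX3", "cox3", "coiii", "co3", "coxiii",
        "cytochrome c oxidase subunit iii", "cytochrome c oxidase subunit 3",
        "cytochrome oxidase subunit iii", "cytochrome oxidase subunit 3")
    add("CYTB", "cytb", "cob", "cyt b", "cytochrome b", "cytochrome b apoenzyme")
    for i in (1, 2, 3, 4, 5, 6):
        add(f"ND{i}", f"nd{i}", f"nad{i}", f"nadh{i}",
            f"nadh dehydrogenase subunit {i}")
    add("ND4L", "nd4l", "nad4l", "nadh dehydrogenase subunit 4l")
    add("ATP6", "atp6", "atpase6", "atpase 6", "atp synthase f0 subunit 6",
        "atp synthase subunit 6")
    add("ATP8", "atp8", "atpase8", "atpase 8", "atp synthase f0 subunit 8",
        "atp synthase subunit 8")
    add("rrnL", "rrnl", "16s", "16s rrna", "16s ribosomal rna", "lrrna", "l-rrna",
        "large subunit ribosomal rna", "rrn16")
    add("rrnS", "rrns", "12s", "12s rrna", "12s ribosomal rna", "srrna", "s-rrna",
        "small subunit ribosomal rna", "rrn12")
    add("CR", "cr", "dloop", "d-loop", "control region", "at rich region",
        "atrich region", "a+t rich region", "putative control region",
        "misc_feature")
    for aa3, aa1 in _AA1.items():
        if aa1 in ("L", "S"):
            continue
        add(f"trn{aa1}", f"trn{aa1}", f"trna-{aa3}", f"trna {aa3}", f"trn{aa3}")
    # two leucine and two serine tRNAs, disambiguated by anticodon class
    add("trnL1", "trnl1", "trna-leu(cun)", "trna-leu (cun)", "trnl(cun)",
        "trna-leu(tag)", "trnl(tag)")
    add("trnL2", "trnl2", "trna-leu(uur)", "trna-leu (uur)", "trnl(uur)",
        "trna-leu(taa)", "trnl(taa)")
    add("trnS1", "trns1", "trna-ser(agn)", "trna-ser (agn)", "trns(agn)",
        "trna-ser(gct)", "trns(gct)", "trna-ser(tct)")
    add("trnS2", "trns2", "trna-ser(ucn)", "trna-ser (ucn)", "trns(ucn)",
        "trna-ser(tga)", "trns(tga)")
    return syn


_SYNONYMS = _build_synonyms()


def normalize_gene_name(raw: str) -> str:
    """Map a free-form gene label onto the canonical controlled vocabulary.

    Matching is case-insensitive and ignores spaces, hyphens and
    underscores (``"COI" -> "COX1"``, ``"l-rRNA" -> "rrnL"``,
    ``"D-loop" -> "CR"``).  Ambiguous leucine/serine tRNA labels without an
    anticodon qualifier, and unknown labels, raise
    :class:`CanonicalizationError` listing near matches.
    """
    if not raw or not raw.strip():
        raise CanonicalizationError("empty gene name")
    key = raw.lower().replace(" ", "").replace("-", "").replace("_", "")
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    if key in ("trnl", "trnaleu", "trns", "trnaser"):
        which = "trnL1/trnL2" if "l" in key[:4] else "trnS1/trnS2"
        raise CanonicalizationError(
            f"{raw!r} is ambiguous: two copies exist; specify the anticodon ({which})"
        )
    near = difflib.get_close_matches(key, _SYNONYMS.keys(), n=3, cutoff=0.6)
    hint = f"; near matches: {sorted(set(_SYNONYMS[n] for n in near))}" if near else ""
    raise CanonicalizationError(f"unknown gene name {raw!r}{hint}")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: canonical identity, class, span and strand.

    ``start``/``end`` are 0-based half-open; for origin-wrapping features
    ``end`` may exceed the genome length (``wraps_origin`` set), so the
    span length is always ``end - start``.  ``strand`` is +1 for the
    majority (heavy) strand and -1 for the minority (light) strand.
    """

    canonical_name: str
    gene_class: str
    start: int
    end: int
    strand: int = 1
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.canonical_name}: end must exceed start")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """A circular annotated mitochondrial genome."""

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True
    taxon_family: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise MitoFormatError(
                f"{self.identifier}: ambiguity codes beyond N not supported: {sorted(bad)}"
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, canonical_name: str) -> GeneFeature:
        for f in self.features:
            if f.canonical_name == canonical_name:
                return f
        raise KeyError(canonical_name)

    def has_feature(self, canonical_name: str) -> bool:
        return any(f.canonical_name == canonical_name for f in self.features)

    def validate(self) -> None:
        L = self.length
        if L == 0:
            raise MitoFormatError("empty sequence")
        n_cr = sum(1 for f in self.features if f.gene_class == "control_region")
        if n_cr > 1:
            raise MitoFormatError("more than one control region")
        seen: dict[str, int] = {}
        for f in self.features:
            if not (0 <= f.start < L and f.start < f.end <= 2 * L):
                raise MitoFormatError(f"{f.canonical_name}: span outside [0, 2L)")
            if f.end > L and not f.wraps_origin:
                raise MitoFormatError(f"{f.canonical_name}: end beyond length but not wrapping")
            if not f.canonical_name.endswith("?"):
                seen[f.canonical_name] = seen.get(f.canonical_name, 0) + 1
        dups = [n for n, c in seen.items() if c > 1]
        if dups:
            raise MitoFormatError(f"duplicate gene annotations: {dups}")


def extract_gene_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Gene sequence on its coding strand (reverse-complemented for strand -1).

    Origin-wrapping features concatenate the tail and head segments via the
    doubled-coordinate representation; the result has length ``end - start``.
    """
    L = genome.length
    if not (0 <= feature.start < L and feature.start < feature.end <= 2 * L):
        raise ValueError(
            f"{feature.canonical_name}: coordinates outside [0, 2*length)"
        )
    doubled = genome.sequence + genome.sequence
    seq = doubled[feature.start:feature.end]
    return reverse_complement(seq) if feature.strand == -1 else seq


# --- GenBank I/O ------------------------------------------------------------

_FEATURE_KEY_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                      "misc_feature": "control_region", "D-loop": "control_region"}


def _feature_name(bio_feature) -> str | None:
    quals = bio_feature.qualifiers
    candidates = []
    for key in ("gene", "product", "note", "standard_name"):
        candidates.extend(quals.get(key, []))
    # anticodon-based trnL/trnS disambiguation when a plain label is ambiguous
    anticodons = [a.upper() for a in quals.get("anticodon", [])]
    for raw in candidates:
        try:
            return normalize_gene_name(raw)
        except CanonicalizationError as exc:
            if "ambiguous" in str(exc):
                for ac in anticodons:
                    ac3 = ac.split("POS:")[-1].strip("() ").split(",")[-1].replace("SEQ:", "")
                    try:
                        return normalize_gene_name(f"{raw}({ac3})")
                    except CanonicalizationError:
                        continue
            continue
    return None


def read_genbank(path) -> list[MitoGenome]:
    """Parse a GenBank flat file into one :class:`MitoGenome` per record.

    1-based inclusive GenBank locations become 0-based half-open;
    ``complement(...)`` sets strand -1; ``join(...)`` locations running
    through the origin set ``wraps_origin`` with ``end > length``.
    Features whose name cannot be canonicalized are kept with the class
    inferred from the feature key and a ``?``-suffixed name, with a warning.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # pragma: no cover - biopython error classes vary
        raise MitoFormatError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise MitoFormatError(f"no GenBank records in {path}")
    genomes = []
    for rec in records:
        feats: list[GeneFeature] = []
        L = len(rec.seq)
        for bf in rec.features:
            if bf.type not in _FEATURE_KEY_CLASS:
                continue
            loc = bf.location
            strand = -1 if loc.strand == -1 else 1
            parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
            parts = sorted(parts, key=lambda p: int(p.start))
            wraps = False
            if len(parts) == 2 and int(parts[-1].end) == L and int(parts[0].start) == 0:
                start = int(parts[-1].start)
                end = start + sum(int(p.end) - int(p.start) for p in parts)
                wraps = True
            else:
                start, end = int(loc.start), int(loc.end)
            name = _feature_name(bf)
            if name is None:
                inferred = _FEATURE_KEY_CLASS[bf.type]
                label = (bf.qualifiers.get("gene") or bf.qualifiers.get("product") or ["?"])[0]
                warnings.warn(
                    f"{rec.id}: cannot canonicalize feature {label!r} at {start}; "
                    f"keeping as {label}? with class {inferred}"
                )
                feats.append(GeneFeature(f"{label}?", inferred, start, end, strand, wraps))
                continue
            feats.append(GeneFeature(name, gene_class_of(name), start, end, strand, wraps))
        genome = MitoGenome(
            identifier=rec.id or rec.name,
            sequence=str(rec.seq),
            features=feats,
            is_circular=rec.annotations.get("topology", "circular") == "circular",
        )
        genome.validate()
        genomes.append(genome)
    return genomes


def write_genbank(genome: MitoGenome, path) -> None:
    """Write a genome back to a GenBank flat file (inverse of :func:`read_genbank`)."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace(" ", "_"),
        description=f"{genome.identifier} mitochondrion",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.is_circular else "linear",
        },
    )
    key_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control_region": "misc_feature"}
    L = genome.length
    for f in genome.features:
        if f.wraps_origin and f.end > L:
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, strand=f.strand),
                 SimpleLocation(0, f.end - L, strand=f.strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        quals = {"gene": [f.canonical_name]}
        if f.gene_class == "control_region":
            quals["note"] = ["putative control region"]
        rec.features.append(SeqFeature(loc, type=key_of[f.gene_class], qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# --- Alignments -------------------------------------------------------------


@dataclass
class Alignment:
    """A per-gene alignment: (taxon, gapped sequence) rows over {A,C,G,T,N,-}."""

    gene_name: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.rows:
            lens = {len(s) for _, s in self.rows}
            if len(lens) > 1:
                raise ValueError(f"{self.gene_name}: unequal row lengths {sorted(lens)}")
            taxa = [t for t, _ in self.rows]
            if len(set(taxa)) != len(taxa):
                raise ValueError(f"{self.gene_name}: duplicate taxon ids")
        self.rows = [(t, s.upper()) for t, s in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.rows]

    def get(self, taxon: str) -> str:
        for t, s in self.rows:
            if t == taxon:
                return s
        raise KeyError(taxon)

    def column(self, i: int) -> str:
        return "".join(s[i] for _, s in self.rows)

    def is_codon_aligned(self) -> bool:
        return self.length % 3 == 0


def read_fasta_alignment(path, gene_name: str | None = None) -> Alignment:
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise MitoFormatError(f"no FASTA records in {path}")
    import os

    name = gene_name or os.path.splitext(os.path.basename(str(path)))[0]
    return Alignment(name, rows)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.rows:
            fh.write(f">{taxon}\n{seq}\n")


def rotate_genome(genome: MitoGenome, offset: int) -> MitoGenome:
    """Rotate a circular genome by ``offset`` bp (utility for invariance checks)."""
    L = genome.length
    offset %= L
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        start = (f.start - offset) % L
        end = start + f.span
        feats.append(replace(f, start=start, end=end, wraps_origin=end > L))
    return MitoGenome(genome.identifier, seq, feats, genome.is_circular, genome.taxon_family)
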