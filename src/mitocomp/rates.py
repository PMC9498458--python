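"""Synonymous/nonsynonymous substitution rates by the Nei–Gojobori (1986) method.

For a codon, each of the nine single-base mutations is scored as synonymous
or nonsynonymous under the genetic code; mutations to stop codons are
treated as nonsynonymous so that every codon contributes exactly
s + n = 3 sites.  Between two codons differing at k >= 2 positions, observed
differences are averaged over all k! mutational pathways with equal weight,
discarding pathways that pass through a stop codon (the remaining pathways
are re-weighted equally).  The proportions pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected, d = -(3/4) ln(1 - 4p/3); proportions >= 3/4 are
saturated and reported as missing.  omega = Ka/Ks indexes selective
pressure (purifying when < 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import pandas as pd

from .codes import GeneticCode, get_code
from .genomes import Alignment

__all__ = [
    "RateEstimate",
    "FamilyRateSummary",
    "syn_nonsyn_sites",
    "ng86_pair",
    "family_rate_summary",
]

_BASES = "ACGT"


class SiteError(ValueError):
    """Stop or ambiguous codon passed to site counting."""


def _site_table(code: GeneticCode) -> dict[str, tuple[float, float]]:
    table = {}
    for codon in code.sense_codons:
        s = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1:]
                if not code.is_stop(mutant) and code.synonymous(codon, mutant):
                    s += 1.0 / 3.0
        table[codon] = (s, 3.0 - s)
    return table


def _pair_table(code: GeneticCode) -> dict[tuple[str, str], tuple[float, float]]:
    """Pathway-averaged (Sd, Nd) for every ordered pair of distinct sense codons."""
    table = {}
    for c1, c2 in combinations(code.sense_codons, 2):
        diffs = [i for i in range(3) if c1[i] != c2[i]]
        paths = []
        for order in permutations(diffs):
            cur = c1
            steps = []
            ok = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if code.is_stop(nxt):
                    ok = False
                    break
                steps.append((cur, nxt))
                cur = nxt
            if ok:
                paths.append(steps)
        if not paths:  # all pathways blocked by stops: fall back to unrestricted
            for order in permutations(diffs):
                cur = c1
                steps = []
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                    steps.append((cur, nxt))
                    cur = nxt
                paths.append(steps)
        sd = nd = 0.0
        for steps in paths:
            for a, b in steps:
                if not code.is_stop(a) and not code.is_stop(b) and code.synonymous(a, b):
                    sd += 1.0 / len(paths)
                else:
                    nd += 1.0 / len(paths)
        table[(c1, c2)] = (sd, nd)
        table[(c2, c1)] = (sd, nd)
    return table


_SITE_CACHE: dict[int, dict] = {}
_PAIR_CACHE: dict[int, dict] = {}


def _tables(genetic_code: int):
    if genetic_code not in _SITE_CACHE:
        code = get_code(genetic_code)
        _SITE_CACHE[genetic_code] = _site_table(code)
        _PAIR_CACHE[genetic_code] = _pair_table(code)
    return _SITE_CACHE[genetic_code], _PAIR_CACHE[genetic_code]


def syn_nonsyn_sites(codon: str, genetic_code: int = 5) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) of one codon; s + n = 3."""
    codon = codon.upper()
    sites, _ = _tables(genetic_code)
    if codon not in sites:
        raise SiteError(f"{codon!r} is not a sense codon of table {genetic_code}")
    return sites[codon]


def _jc(p: float) -> float:
    """Jukes–Cantor distance; NaN at/beyond the p = 3/4 saturation bound."""
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class RateEstimate:
    """Pairwise NG86 estimate for one gene and one taxon pair."""

    gene: str | None
    pair: tuple[str, str] | None
    n_codons: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    omega: float


def ng86_pair(
    cds1: str,
    cds2: str,
    genetic_code: int = 5,
    gene: str | None = None,
    pair: tuple[str, str] | None = None,
) -> RateEstimate:
    """NG86 Ka/Ks between two aligned in-frame coding sequences.

    Codons containing gaps, N, or a stop in either sequence are deleted
    pairwise.  S and N are averaged over the two sequences.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2):
        raise ValueError(f"length mismatch: {len(cds1)} vs {len(cds2)}")
    if len(cds1) % 3 != 0:
        raise ValueError(f"length {len(cds1)} not divisible by 3")
    sites, pairs = _tables(genetic_code)
    s1 = s2 = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3], cds2[i:i + 3]
        if a not in sites or b not in sites:
            continue  # pairwise deletion of ambiguous/gapped/stop codons
        n_codons += 1
        s1 += sites[a][0]
        s2 += sites[b][0]
        if a != b:
            d = pairs[(a, b)]
            sd += d[0]
            nd += d[1]
    if n_codons == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks, ka = _jc(ps), _jc(pn)
    if math.isnan(ks) or math.isnan(ka) or ks == 0.0:
        omega = math.nan
    else:
        omega = ka / ks
    return RateEstimate(gene, pair, n_codons, S, N, sd, nd, ps, pn, ks, ka, omega)


# --- group-aggregated rates -------------------------------------------------


def _consensus(aln: Alignment, taxa: list[str]) -> str:
    cols = []
    seqs = [aln.get(t) for t in taxa]
    for i in range(aln.length):
        col = [s[i] for s in seqs if s[i] in _BASES]
        cols.append(max(set(col), key=lambda b: (col.count(b), b)) if col else "N")
    return "".join(cols)


@dataclass
class FamilyRateSummary:
    """Per gene x family mean Ka, Ks and omega under a comparison design.

    ``design`` is one of ``within-family`` (mean over all within-family
    pairs; the default), ``vs-outgroup`` (each family member against every
    outgroup taxon) or ``consensus`` (family majority-consensus sequences
    compared pairwise between families).
    """

    table: pd.DataFrame  # columns: gene, family, n_pairs, n_undefined, mean_ka, mean_ks, mean_omega
    design: str
    pair_estimates: list[RateEstimate]

    def gene_means(self) -> pd.DataFrame:
        """Per-gene means pooled over all pairwise estimates."""
        recs = {}
        for est in self.pair_estimates:
            recs.setdefault(est.gene, []).append(est)
        rows = []
        for gene, ests in recs.items():
            ka = [e.ka for e in ests if not math.isnan(e.ka)]
            ks = [e.ks for e in ests if not math.isnan(e.ks)]
            om = [e.omega for e in ests if not math.isnan(e.omega)]
            rows.append(
                (gene,
                 sum(ka) / len(ka) if ka else math.nan,
                 sum(ks) / len(ks) if ks else math.nan,
                 sum(om) / len(om) if om else math.nan)
            )
        return pd.DataFrame(rows, columns=["gene", "mean_ka", "mean_ks", "mean_omega"]).set_index("gene")

    def top_gene_by_omega(self) -> str:
        return self.gene_means()["mean_omega"].idxmax()

    def bottom_gene_by_omega(self) -> str:
        return self.gene_means()["mean_omega"].idxmin()

    def family_means(self) -> pd.DataFrame:
        """Per-family means pooled over genes (from the per-family table)."""
        return self.table.groupby("family")[["mean_ka", "mean_ks", "mean_omega"]].mean()

    def top_family_by_ks(self) -> str:
        return self.family_means()["mean_ks"].idxmax()

    def top_family_by_omega(self) -> str:
        return self.family_means()["mean_omega"].idxmax()


def _mean(vals: list[float]) -> float:
    return sum(vals) / len(vals) if vals else math.nan


def family_rate_summary(
    alignments: dict[str, Alignment],
    groups: dict[str, str],
    design: str = "within-family",
    outgroup: str | None = None,
    genetic_code: int = 5,
) -> FamilyRateSummary:
    """Aggregate NG86 estimates per gene and taxon family.

    ``groups`` maps taxon id to family label.  Families with fewer than two
    members are excluded with a warning (within-family design).  Undefined
    pairwise estimates (saturated or Ks = 0) are excluded from means and
    counted.
    """
    if design not in ("within-family", "vs-outgroup", "consensus"):
        raise ValueError(f"unknown design {design!r}")
    families: dict[str, list[str]] = {}
    for taxon, fam in sorted(groups.items()):
        families.setdefault(fam, []).append(taxon)
    if design == "within-family":
        small = [f for f, taxa in families.items() if len(taxa) < 2]
        for f in small:
            warnings.warn(f"family {f!r} has <2 taxa; excluded from within-family design")
            del families[f]
    if design == "vs-outgroup" and outgroup not in families:
        raise ValueError("vs-outgroup design requires an 'outgroup' family label present in groups")

    rows = []
    estimates: list[RateEstimate] = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        present = set(aln.taxa)
        if design == "consensus":
            cons = {
                fam: _consensus(aln, [t for t in taxa if t in present])
                for fam, taxa in families.items()
                if any(t in present for t in taxa)
            }
            fam_pairs: dict[str, list[RateEstimate]] = {f: [] for f in cons}
            for f1, f2 in combinations(sorted(cons), 2):
                est = ng86_pair(cons[f1], cons[f2], genetic_code, gene=gene, pair=(f1, f2))
                estimates.append(est)
                fam_pairs[f1].append(est)
                fam_pairs[f2].append(est)
            items = fam_pairs.items()
        else:
            items = []
            for fam, taxa in sorted(families.items()):
                taxa = [t for t in taxa if t in present]
                if design == "within-family":
                    pair_list = list(combinations(taxa, 2))
                else:  # vs-outgroup
                    if fam == outgroup:
                        continue
                    pair_list = [(t, o) for t in taxa for o in families[outgroup] if o in present]
                ests = []
                for t1, t2 in pair_list:
                    est = ng86_pair(
                        aln.get(t1), aln.get(t2), genetic_code, gene=gene, pair=(t1, t2)
                    )
                    ests.append(est)
                    estimates.append(est)
                items.append((fam, ests))
        for fam, ests in items:
            defined = [e for e in ests if not math.isnan(e.omega)]
            rows.append(
                {
                    "gene": gene,
                    "family": fam,
                    "n_pairs": len(ests),
                    "n_undefined": len(ests) - len(defined),
                    "mean_ka": _mean([e.ka for e in ests if not math.isnan(e.ka)]),
                    "mean_ks": _mean([e.ks for e in ests if not math.isnan(e.ks)]),
                    "mean_omega": _mean([e.omega for e in defined]),
                }
            )
    table = pd.DataFrame(rows)
    return FamilyRateSummary(table=table, design=design, pair_estimates=estimates)
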