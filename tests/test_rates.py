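"""Nei–Gojobori Ka/Ks estimation against an exhaustive-pathway brute force."""

import math
from itertools import permutations

import numpy as np
import pytest

from mitocomp.codes import get_code
from mitocomp.genomes import Alignment
from mitocomp.rates import (
    SiteError,
    family_rate_summary,
    ng86_pair,
    syn_nonsyn_sites,
)

CODE = get_code(5)
_BASES = "ACGT"


# --- independent brute-force oracle ----------------------------------------


def oracle_sites(codon):
    """Enumerate all nine single-base mutations; stops count as nonsynonymous."""
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut not in CODE.stop_codons and CODE.amino_acid[mut] == CODE.amino_acid[codon]:
                s += 1 / 3
    return s, 3 - s


def oracle_pair_diffs(c1, c2):
    """Average (Sd, Nd) over all stop-free mutational pathways, explicitly."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur, steps, ok = c1, [], True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in CODE.stop_codons:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            if CODE.amino_acid[a] == CODE.amino_acid[b]:
                sd += 1 / len(paths)
            else:
                nd += 1 / len(paths)
    return sd, nd


def oracle_estimate(cds1, cds2):
    s1 = s2 = sd = nd = 0.0
    n = len(cds1) // 3
    for i in range(n):
        a, b = cds1[3 * i:3 * i + 3], cds2[3 * i:3 * i + 3]
        s1 += oracle_sites(a)[0]
        s2 += oracle_sites(b)[0]
        d = oracle_pair_diffs(a, b)
        sd += d[0]
        nd += d[1]
    S = (s1 + s2) / 2
    return S, 3 * n - S, sd, nd


# ---------------------------------------------------------------------------


def test_fourfold_codon_sites():
    assert syn_nonsyn_sites("GGA") == (1.0, 2.0)


def test_twofold_codon_sites():
    s, n = syn_nonsyn_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_met_family_includes_ata_interchange():
    # under the invertebrate mito code ATG<->ATA are both Met
    s, _ = syn_nonsyn_sites("ATG")
    assert s >= 1 / 3


def test_all_sense_codons_match_enumeration_oracle():
    for codon in CODE.sense_codons:
        assert syn_nonsyn_sites(codon) == pytest.approx(oracle_sites(codon))
        s, n = syn_nonsyn_sites(codon)
        assert s + n == pytest.approx(3.0)


def test_stop_codon_rejected():
    with pytest.raises(SiteError):
        syn_nonsyn_sites("TAA")


def test_identical_sequences():
    e = ng86_pair("ATGGCT", "ATGGCT")
    assert e.ks == e.ka == 0.0
    assert math.isnan(e.omega)


def test_worked_example_nine_ttt_vs_one_ttc():
    e = ng86_pair("TTT" * 9, "TTT" * 8 + "TTC")
    assert e.s_sites == pytest.approx(3.0)
    assert e.sd == pytest.approx(1.0)
    assert e.nd == pytest.approx(0.0)
    assert e.ps == pytest.approx(1 / 3)
    assert e.ks == pytest.approx(0.4408, abs=5e-5)
    assert e.ka == 0.0


def test_symmetry_and_site_conservation():
    rng = np.random.default_rng(11)
    codons = list(CODE.sense_codons)
    for _ in range(30):
        n = int(rng.integers(1, 31))
        a = "".join(rng.choice(codons, n))
        b = "".join(rng.choice(codons, n))
        e1, e2 = ng86_pair(a, b), ng86_pair(b, a)
        assert (e1.ks, e1.ka, e1.sd, e1.nd) == (e2.ks, e2.ka, e2.sd, e2.nd)
        assert e1.s_sites + e1.n_sites == pytest.approx(3 * e1.n_codons)


def test_matches_brute_force_on_random_pairs():
    rng = np.random.default_rng(5)
    codons = list(CODE.sense_codons)
    for _ in range(100):
        n = int(rng.integers(1, 4))
        a = "".join(rng.choice(codons, n))
        b = "".join(rng.choice(codons, n))
        e = ng86_pair(a, b)
        S, N, sd, nd = oracle_estimate(a, b)
        assert e.s_sites == pytest.approx(S, abs=1e-12)
        assert e.n_sites == pytest.approx(N, abs=1e-12)
        assert e.sd == pytest.approx(sd, abs=1e-12)
        assert e.nd == pytest.approx(nd, abs=1e-12)


def test_gap_and_n_codons_pairwise_deleted():
    e = ng86_pair("ATG---TTT", "ATGGCTTTC")
    assert e.n_codons == 2
    e2 = ng86_pair("ATGNNTTTT", "ATGGCTTTC")
    assert e2.n_codons == 2


def test_input_errors():
    with pytest.raises(ValueError, match="mismatch"):
        ng86_pair("ATG", "ATGGCT")
    with pytest.raises(ValueError, match="divisible"):
        ng86_pair("ATGG", "ATGC")


def test_family_summary_all_identical_alignment():
    aln = Alignment("COX1", [(f"t{i}", "ATGGCTTTA" * 5) for i in range(4)])
    groups = {f"t{i}": "F1" for i in range(4)}
    summary = family_rate_summary({"COX1": aln}, groups)
    row = summary.table.iloc[0]
    assert row["mean_ka"] == 0.0 and row["mean_ks"] == 0.0
    assert row["n_undefined"] == row["n_pairs"]  # omega 0/0 undefined


def test_family_with_single_taxon_excluded():
    aln = Alignment("COX1", [("a", "ATGGCT"), ("b", "ATGGCT"), ("c", "ATGGCT")])
    groups = {"a": "F1", "b": "F1", "c": "F2"}
    with pytest.warns(UserWarning, match="F2"):
        summary = family_rate_summary({"COX1": aln}, groups)
    assert set(summary.table["family"]) == {"F1"}


def test_alternative_designs_run():
    rows = [(f"t{i}", "ATGGCTTTAGCTAAT") for i in range(4)] + [
        ("o1", "ATGGCATTAGCAAAT"), ("o2", "ATGGCATTGGCAAAT")
    ]
    aln = Alignment("COX1", rows)
    groups = {"t0": "F1", "t1": "F1", "t2": "F2", "t3": "F2",
              "o1": "OUT", "o2": "OUT"}
    vs = family_rate_summary({"COX1": aln}, groups, design="vs-outgroup", outgroup="OUT")
    assert set(vs.table["family"]) == {"F1", "F2"}
    cons = family_rate_summary({"COX1": aln}, groups, design="consensus")
    assert len(cons.table) == 3
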