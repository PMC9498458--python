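"""Block filtering, supermatrix concatenation, NJ and format export."""

import numpy as np
import pytest

from mitocomp.genomes import Alignment
from mitocomp.phyloprep import (
    BlockFilterParams,
    Partition,
    SaturatedPairError,
    Supermatrix,
    codon_pairwise_align,
    concatenate,
    conserved_block_filter,
    nj_tree,
    read_fasta_matrix,
    write_matrix,
)


def _aln(rows):
    return Alignment("g", [("t%d" % i, r) for i, r in enumerate(rows)])


# --- independent straightforward re-implementation of the column rules ------


def oracle_filter(aln, params):
    n = aln.n_rows
    L = aln.length
    labels = []
    for i in range(L):
        col = [s[i] for _, s in aln.rows]
        gaps = col.count("-")
        if (params.gap_policy == "none" and gaps) or (
            params.gap_policy == "half" and gaps > n / 2
        ):
            labels.append(0)
            continue
        residues = [c for c in col if c != "-"]
        top = max((residues.count(b) for b in set(residues)), default=0)
        labels.append(2 if top / n > params.highly_conserved_fraction
                      else 1 if top / n > params.conserved_fraction else 0)
    keep = [True] * L
    for i in range(L):
        col = [s[i] for _, s in aln.rows]
        gaps = col.count("-")
        if (params.gap_policy == "none" and gaps) or (
            params.gap_policy == "half" and gaps > n / 2
        ):
            keep[i] = False
    i = 0
    while i < L:
        if labels[i] == 0:
            j = i
            while j < L and labels[j] == 0:
                j += 1
            if j - i > params.max_nonconserved_run:
                for k in range(i, j):
                    keep[k] = False
            i = j
        else:
            i += 1
    kept = []
    i = 0
    while i < L:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < L and keep[j]:
            j += 1
        block = list(range(i, j))
        while block and labels[block[0]] != 2:
            block.pop(0)
        while block and labels[block[-1]] != 2:
            block.pop()
        if len(block) >= params.min_block_length:
            kept.extend(block)
        i = j
    return kept


def test_identical_alignment_unchanged():
    aln = _aln(["ACGTACGTACGTACGT"] * 5)
    filtered, kept = conserved_block_filter(aln)
    assert kept == list(range(16))
    assert filtered.rows == aln.rows


def test_gap_column_removed_under_none_policy():
    rows = ["ACGTACGTACGTACG", "ACGTACGTACGTACG", "ACGTACGTACGTACG", "ACG-ACGTACGTACG"]
    filtered, kept = conserved_block_filter(
        _aln(rows), BlockFilterParams(max_nonconserved_run=0 + 1, min_block_length=3)
    )
    assert 3 not in kept


def test_hypervariable_island_removed_and_matches_oracle():
    rng = np.random.default_rng(0)
    n, L = 8, 60
    base = "".join("ACGT"[k] for k in rng.integers(0, 4, L))
    rows = []
    for _ in range(n):
        row = list(base)
        for i in range(24, 36):  # 12-column hypervariable island
            row[i] = "ACGT"[rng.integers(0, 4)]
        rows.append("".join(row))
    params = BlockFilterParams(conserved_fraction=0.7, max_nonconserved_run=8,
                               min_block_length=10)
    aln = _aln(rows)
    filtered, kept = conserved_block_filter(aln, params)
    assert kept == oracle_filter(aln, params)
    assert not set(range(24, 36)) <= set(kept)


@pytest.mark.parametrize("seed", range(5))
def test_filter_matches_oracle_on_random_alignments(seed):
    rng = np.random.default_rng(seed)
    n, L = 8, 120
    rows = []
    base = "".join("ACGT"[k] for k in rng.integers(0, 4, L))
    for _ in range(n):
        row = [c if rng.random() > 0.25 else "ACGT-"[rng.integers(0, 5)] for c in base]
        rows.append("".join(row))
    for policy in ("none", "half", "all"):
        params = BlockFilterParams(max_nonconserved_run=4, min_block_length=5,
                                   gap_policy=policy)
        aln = _aln(rows)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, kept = conserved_block_filter(aln, params)
        assert kept == oracle_filter(aln, params)
        assert kept == sorted(kept)  # strictly increasing lift-over map


def test_concatenate_tiling_and_gap_fill():
    a = Alignment("g1", [("x", "ATGGCT"), ("y", "ATGGCA")])
    b = Alignment("g2", [("x", "TTA"), ("z", "TTG")])
    m = concatenate({"g1": a, "g2": b}, ["g1", "g2"])
    assert m.length == 9
    assert m.rows["y"] == "ATGGCA---"
    assert m.rows["z"] == "------TTG"
    assert [(p.start, p.end) for p in m.gene_partitions] == [(1, 6), (7, 9)]
    # codon partitions tile each gene with stride 3
    g1_parts = [p for p in m.codon_partitions if p.gene == "g1"]
    assert [(p.codon_position, p.start, p.end) for p in g1_parts] == [
        (1, 1, 6), (2, 2, 6), (3, 3, 6)
    ]
    assert sum(p.end - p.start + 1 for p in m.gene_partitions) == m.length


def test_duplicate_taxon_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        Alignment("g1", [("x", "ATG"), ("x", "ATG")])


def _matrix_from(rows):
    L = len(next(iter(rows.values())))
    return Supermatrix(rows=rows, gene_partitions=[Partition("g", None, 1, L)])


def test_nj_three_taxa_closed_form():
    rows = {"a": "A" * 100, "b": "A" * 90 + "C" * 10, "c": "A" * 80 + "C" * 20}
    tree = nj_tree(_matrix_from(rows))
    assert tree.count(",") == 2 and tree.endswith(";")


def test_nj_recovers_additive_four_taxon_topology():
    # distances from tree ((a:1,b:2):1,(c:3,d:4)) scaled small; emulate with
    # sequences is hard, so check via a four-point-condition dataset of
    # diverged sequences generated on a known topology
    from mitocomp.simulate import simulate_neutral_alignment

    nwk = "((a:0.08,b:0.08):0.06,(c:0.08,d:0.08):0.06);"
    aln = simulate_neutral_alignment(nwk, 4000, seed=1)
    m = concatenate({"locus": aln})
    tree = nj_tree(m)
    # a,b must be siblings: the newick contains them inside one parenthesis
    import re

    pairs = re.findall(r"\(([a-d]):[\d.]+,([a-d]):[\d.]+\)", tree)
    assert any(set(p) == {"a", "b"} or set(p) == {"c", "d"} for p in pairs)


def test_nj_zero_matrix_gives_zero_lengths():
    rows = {t: "ACGT" * 10 for t in "abcd"}
    tree = nj_tree(_matrix_from(rows))
    import re

    lengths = [float(x) for x in re.findall(r":([\d.]+)", tree)]
    assert all(x == 0 for x in lengths)


def test_nj_saturated_pair_raises():
    rows = {"a": "A" * 60, "b": "G" * 60, "c": "C" * 60}
    with pytest.raises(SaturatedPairError):
        nj_tree(_matrix_from(rows))


def test_write_phylip_header_and_nexus_charsets(tmp_path):
    a = Alignment("g1", [("x", "ATGGCT"), ("y", "ATGGCA")])
    m = concatenate({"g1": a}, ["g1"])
    phy = tmp_path / "m.phy"
    write_matrix(m, "phylip", phy)
    assert phy.read_text().splitlines()[0] == "2 6"
    nex = tmp_path / "m.nex"
    write_matrix(m, "nexus", nex)
    text = nex.read_text()
    assert text.count("CHARSET") == len(m.partitions) == 4
    assert "g1_pos2 = 2-6\\3;" in text


def test_fasta_round_trip(tmp_path):
    a = Alignment("g1", [("x", "ATGGCT"), ("y", "AT--CA")])
    m = concatenate({"g1": a}, ["g1"])
    path = tmp_path / "m.fasta"
    write_matrix(m, "fasta", path)
    assert read_fasta_matrix(path) == m.rows


def test_write_is_byte_stable(tmp_path, default_genome):
    a = Alignment("g1", [("x", "ATGGCT"), ("y", "ATGGCA")])
    m = concatenate({"g1": a}, ["g1"])
    p1, p2 = tmp_path / "a.nex", tmp_path / "b.nex"
    write_matrix(m, "nexus", p1)
    write_matrix(m, "nexus", p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_codon_pairwise_align_inserts_triplet_gaps():
    a = "ATGGCTTTAAAT"
    b = "ATGTTAAAT"  # missing the GCT codon
    ga, gb = codon_pairwise_align(a, b)
    assert len(ga) == len(gb) == 12
    assert ga == a
    assert "---" in gb
    assert gb.replace("-", "") == b
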