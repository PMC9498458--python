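"""Start/stop classification, codon counting and RSCU."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.codes import get_code
from mitocomp.codon_usage import (
    classify_start_stop,
    codon_counts,
    rscu,
    trim_terminal_stop,
)

CODE = get_code(5)


def test_complete_taa_stop_and_atn_start():
    entry = classify_start_stop("ATG" + "GCT" * 5 + "TAA")
    assert entry.start_class == "ATN"
    assert entry.stop_class == "TAA" and entry.complete


def test_alternative_ttg_start():
    entry = classify_start_stop("TTG" + "GCT" * 5 + "TAG")
    assert entry.start_class == "alternative(TTG)"
    assert entry.stop_class == "TAG"


def test_truncated_t_stop():
    entry = classify_start_stop("ATA" + "GCT" * 5 + "T")
    assert entry.stop_class == "truncated T" and not entry.complete


def test_truncated_ta_stop():
    entry = classify_start_stop("ATT" + "GCT" * 5 + "TA")
    assert entry.stop_class == "truncated TA"


def test_truncated_stop_needs_close_downstream_feature():
    cds = "ATA" + "GCT" * 5 + "T"
    assert classify_start_stop(cds, downstream_gap=3).stop_class == "truncated T"
    with pytest.warns(UserWarning, match="stop"):
        far = classify_start_stop(cds, downstream_gap=40)
    assert far.stop_class == "incomplete/unknown"


def test_internal_stop_warns_as_pseudogene():
    cds = "ATG" + "TAA" + "GCT" * 4 + "TAA"
    with pytest.warns(UserWarning, match="internal stop"):
        entry = classify_start_stop(cds)
    assert entry.internal_stops == (1,)


def test_every_cds_gets_exactly_one_stop_class():
    from contextlib import nullcontext

    classes = set()
    for tail in ("TAA", "TAG", "TA", "T", "GGG", "GG"):
        cds = "ATG" + "GCT" * 4 + tail
        with pytest.warns(UserWarning) if tail in ("GGG", "GG") else nullcontext():
            entry = classify_start_stop(cds)
        classes.add(entry.stop_class)
    assert classes == {"TAA", "TAG", "truncated TA", "truncated T", "incomplete/unknown"}


@pytest.mark.parametrize(
    "cds, trimmed",
    [
        ("ATGGCTTAA", "ATGGCT"),
        ("ATGGCTTA", "ATGGCT"),
        ("ATGGCTT", "ATGGCT"),
        ("ATGGCTGGA", "ATGGCTGGA"),
    ],
)
def test_trim_terminal_stop(cds, trimmed):
    assert trim_terminal_stop(cds) == trimmed


def test_codon_counts_and_n_skipping():
    counts, skipped = codon_counts(["ATGTTA"])
    assert counts == {"ATG": 1, "TTA": 1} and skipped == 0
    counts, skipped = codon_counts(["ATGNNA"])
    assert counts == {"ATG": 1} and skipped == 1
    counts, _ = codon_counts([])
    assert sum(counts.values()) == 0
    with pytest.raises(Exception, match="divisible"):
        codon_counts(["ATGTT"])


def test_rscu_uniform_and_biased_families():
    # 4-fold family with equal usage -> all RSCU 1
    gly = {c: 2 for c in CODE.families["G"]}
    table = rscu(gly)
    assert all(table.rscu[c] == pytest.approx(1.0) for c in CODE.families["G"])
    # 2-fold family with counts (3, 1) -> 1.5 and 0.5
    lys = {"AAA": 3, "AAG": 1}
    table = rscu(lys)
    assert table.rscu["AAA"] == pytest.approx(1.5)
    assert table.rscu["AAG"] == pytest.approx(0.5)


def test_unobserved_family_is_missing_not_zero():
    table = rscu({"AAA": 3, "AAG": 1})
    for c in CODE.families["G"]:
        assert math.isnan(table.rscu[c])
        assert c in table.missing_codons
    # absent codon of an observed family is exactly 0
    table2 = rscu({"AAA": 4})
    assert table2.rscu["AAG"] == 0.0


@given(
    st.dictionaries(
        st.sampled_from(CODE.sense_codons), st.integers(min_value=0, max_value=50),
        max_size=30,
    )
)
@settings(max_examples=60, deadline=None)
def test_rscu_family_sums_equal_degeneracy(counts):
    table = rscu(counts)
    for aa, codons in CODE.families.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total > 0:
            assert sum(table.rscu[c] for c in codons) == pytest.approx(len(codons))


def test_position1_counts_reconcile_with_composition_split():
    from mitocomp.composition import codon_position_split

    cds = "ATGTTAGCTAAT"
    counts, _ = codon_counts([cds])
    p1, _, _ = codon_position_split(cds)
    for base in "ACGT":
        from_codons = sum(v for c, v in counts.items() if c[0] == base)
        assert from_codons == p1.count(base)


def test_genome_codon_usage_enriched_in_tta(default_genome):
    """The UUA-biased generator shows up as the top codon family."""
    from mitocomp.genomes import extract_gene_sequence

    cdss = [
        trim_terminal_stop(extract_gene_sequence(default_genome, f))
        for f in default_genome.features
        if f.gene_class == "PCG"
    ]
    counts, _ = codon_counts(cdss)
    table = rscu(counts)
    fam = table.family_usage()
    assert fam.index[0] == "L (UUA)"
    assert table.rscu["TTA"] > 3.0
    top5 = set(fam.index[:6])
    assert {"I (AUU)", "F (UUU)"} <= top5
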