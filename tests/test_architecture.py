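"""Gene order, rearrangement detection, junctions and strand census."""

from itertools import combinations

import numpy as np
import pytest

from mitocomp.architecture import (
    ANCESTRAL_INSECT_BLOCK,
    LEPIDOPTERA_BLOCK,
    ComparabilityError,
    GeneOrder,
    TopologyError,
    classify_rearrangement,
    gene_order,
    junctions,
    strand_census,
)
from mitocomp.genomes import GeneFeature, MitoGenome, rotate_genome


def test_gene_order_contains_derived_trna_block(default_genome):
    order = gene_order(default_genome)
    assert len(order) == 38
    assert order.contains_block(LEPIDOPTERA_BLOCK)
    assert not order.contains_block(ANCESTRAL_INSECT_BLOCK)


def test_gene_order_single_gene():
    g = MitoGenome("g", "ACGT" * 25, features=[GeneFeature("rrnS", "rRNA", 0, 50)])
    assert len(gene_order(g)) == 1


@pytest.mark.parametrize("offset", [1, 500, 7000, 15000])
def test_gene_order_and_junctions_rotation_invariant(default_genome, offset):
    rotated = rotate_genome(default_genome, offset)
    assert gene_order(rotated) == gene_order(default_genome)
    j0 = junctions(default_genome, include_cr=True)
    j1 = junctions(rotated, include_cr=True)
    assert sorted((r.upstream, r.downstream, r.relationship, r.length) for r in j0.rows) \
        == sorted((r.upstream, r.downstream, r.relationship, r.length) for r in j1.rows)


def test_identity_yields_empty_report(default_genome):
    order = gene_order(default_genome)
    rep = classify_rearrangement(order, order)
    assert rep.identical and not rep.displaced_genes and not rep.lepidoptera_tdrl


def test_trnm_translocation_flagged(default_genome, ancestral_genome):
    rep = classify_rearrangement(gene_order(default_genome), gene_order(ancestral_genome))
    assert rep.lepidoptera_tdrl
    assert rep.displaced_genes == ("trnM",)
    # swapping observed/reference still shows a displacement but the
    # derived-pattern flag is direction-aware
    back = classify_rearrangement(gene_order(ancestral_genome), gene_order(default_genome))
    assert not back.identical and not back.lepidoptera_tdrl


def test_gene_set_mismatch_rejected(default_genome):
    small = GeneOrder((("COX1", 1), ("COX2", 1)))
    with pytest.raises(ComparabilityError):
        classify_rearrangement(gene_order(default_genome), small)


def _brute_max_common_subsequence(a, b):
    """Largest gene subset appearing in the same relative order in both."""
    best = 0
    n = len(a)
    for r in range(n, 0, -1):
        for keep in combinations(range(n), r):
            sub = [a[i] for i in keep]
            it = iter(b)
            if all(x in it for x in sub):
                return r
    return best


@pytest.mark.parametrize("seed", range(6))
def test_displaced_set_matches_brute_force_on_small_permutations(seed):
    """Displaced genes = complement of a longest common block arrangement."""
    rng = np.random.default_rng(seed)
    genes = ["trnA", "trnR", "trnN", "trnD", "trnC"]
    perm = list(rng.permutation(genes))
    ref = GeneOrder(GeneOrder._anchor([(g, 1) for g in genes]))
    obs = GeneOrder(GeneOrder._anchor([(g, 1) for g in perm]))
    rep = classify_rearrangement(obs, ref)
    brute = _brute_max_common_subsequence(list(obs.entries), list(ref.entries))
    assert len(rep.displaced_genes) == len(genes) - brute


@pytest.mark.parametrize(
    "spans, expected",
    [
        ([(0, 10), (8, 20)], ("overlap", 2)),
        ([(0, 10), (10, 20)], ("abutting", 0)),
        ([(0, 10), (13, 20)], ("spacer", 3)),
    ],
)
def test_junction_classification(spans, expected):
    feats = [
        GeneFeature(name, "tRNA", s, e)
        for name, (s, e) in zip(["trnA", "trnR"], spans)
    ]
    g = MitoGenome("g", "A" * 30, features=feats)
    rep = junctions(g, include_cr=True)
    first = rep.get("trnA", "trnR")
    assert (first.relationship, first.length) == expected


def test_configured_overlaps_recovered(default_genome):
    """The generator's junction plan is echoed exactly by the report."""
    rep = junctions(default_genome, include_cr=True)
    assert rep.get("ATP8", "ATP6").length == 7
    assert rep.get("trnL1", "rrnL").length == 25
    assert rep.get("trnW", "trnC").relationship == "overlap"
    assert rep.longest_overlap.length == 25


def test_nested_features_rejected():
    g = MitoGenome(
        "g", "A" * 100,
        features=[GeneFeature("rrnL", "rRNA", 0, 50), GeneFeature("trnV", "tRNA", 10, 20)],
    )
    with pytest.raises(TopologyError, match="trnV"):
        junctions(g)


def test_cr_junctions_excluded_from_totals_by_default(default_genome):
    incl = junctions(default_genome, include_cr=True)
    excl = junctions(default_genome, include_cr=False)
    assert len(incl.rows) == len(excl.rows)  # rows always listed
    cr_junctions = [j for j in incl.rows if j.cr_adjacent]
    assert len(cr_junctions) == 2
    assert excl.n_overlaps + excl.n_spacers <= incl.n_overlaps + incl.n_spacers


def test_strand_census_canonical_layout(default_genome):
    census = strand_census(default_genome)
    assert census.minority_total == 14
    assert census.majority_total == 23
    assert (census.get(-1, "PCG"), census.get(-1, "tRNA"), census.get(-1, "rRNA")) == (4, 8, 2)
    assert (census.get(1, "PCG"), census.get(1, "tRNA")) == (9, 14)


def test_strand_census_edge_cases():
    g = MitoGenome("g", "A" * 40, features=[GeneFeature("trnM", "tRNA", 0, 10, 1)])
    assert strand_census(g).minority_total == 0
    empty = MitoGenome("g", "A" * 40)
    census = strand_census(empty)
    assert census.minority_total == census.majority_total == 0


def test_junction_conservation_identity(default_genome):
    """sum(spans) - overlaps + spacers = genome length, exactly."""
    rep = junctions(default_genome, include_cr=True)
    spans = sum(f.span for f in default_genome.features)
    assert spans - rep.total_overlap_bp + rep.total_spacer_bp == default_genome.length
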