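"""The synthetic mitogenome generator and sequence-evolution machinery."""

import numpy as np
import pytest

from mitocomp.architecture import gene_order, junctions, strand_census
from mitocomp.codes import get_code, is_transition
from mitocomp.composition import base_composition
from mitocomp.genomes import extract_gene_sequence
from mitocomp.simulate import (
    EvolutionParams,
    GenomeTemplate,
    TDRLError,
    TemplateError,
    apply_tdrl,
    evolve_genes,
    family_study_tree,
    generate_genome,
)


def test_default_genome_gene_inventory(default_genome):
    classes = [f.gene_class for f in default_genome.features]
    assert classes.count("PCG") == 13
    assert classes.count("tRNA") == 22
    assert classes.count("rRNA") == 2
    assert classes.count("control_region") == 1
    assert 15_000 <= default_genome.length <= 16_000


def test_same_seed_reproduces_byte_identical_genome():
    t = GenomeTemplate.default()
    g1, g2 = generate_genome(t, seed=7), generate_genome(t, seed=7)
    assert g1.sequence == g2.sequence and g1.features == g2.features


def test_different_seeds_differ():
    t = GenomeTemplate.default()
    assert generate_genome(t, seed=1).sequence != generate_genome(t, seed=2).sequence


def test_at_target_hit_within_half_percent():
    for target in (0.72, 0.80, 0.86):
        g = generate_genome(GenomeTemplate.default(target_at=target), seed=3)
        assert abs(base_composition(g.sequence).at_pct - 100 * target) < 0.5


def test_template_validation():
    genes = list(GenomeTemplate.default().genes)[:-2]
    with pytest.raises(TemplateError):
        GenomeTemplate(genes=tuple(genes))
    with pytest.raises(TemplateError):
        GenomeTemplate.default(target_at=0.5)
    gaps = dict(GenomeTemplate.default().junction_gaps)
    gaps[("trnM", "trnI")] = -200
    with pytest.raises(TemplateError, match="overlap"):
        GenomeTemplate.default(junction_gaps=gaps)


def test_pcgs_are_clean_orfs(default_genome):
    code = get_code(5)
    from mitocomp.codon_usage import trim_terminal_stop

    for f in default_genome.features:
        if f.gene_class != "PCG":
            continue
        cds = trim_terminal_stop(extract_gene_sequence(default_genome, f))
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        assert all(c in code.sense_codons for c in codons), f.canonical_name


def test_randomized_templates_keep_invariants():
    for seed in range(5):
        t = GenomeTemplate.randomized(seed)
        g = generate_genome(t, seed=seed)
        g.validate()
        rep = junctions(g, include_cr=True)
        spans = sum(f.span for f in g.features)
        assert spans - rep.total_overlap_bp + rep.total_spacer_bp == g.length
        census = strand_census(g)
        assert census.minority_total == 14 and census.majority_total == 23


def test_apply_tdrl_round_trip(ancestral_genome):
    derived = apply_tdrl(ancestral_genome)
    assert derived.length == ancestral_genome.length
    from mitocomp.architecture import classify_rearrangement

    rep = classify_rearrangement(gene_order(derived), gene_order(ancestral_genome))
    assert rep.lepidoptera_tdrl
    # junction lengths away from the block are preserved
    j0 = junctions(ancestral_genome, include_cr=True)
    j1 = junctions(derived, include_cr=True)
    assert j0.get("ATP8", "ATP6").length == j1.get("ATP8", "ATP6").length
    assert j0.get("trnL1", "rrnL").length == j1.get("trnL1", "rrnL").length


def test_apply_tdrl_requires_ancestral_block(default_genome):
    with pytest.raises(TDRLError):
        apply_tdrl(default_genome)


def test_evolution_zero_branch_keeps_root(default_genome):
    params = EvolutionParams(tree="(a:0.0,b:0.0);", seed=1, include_rrna=False)
    alns, _ = evolve_genes(default_genome, params)
    from mitocomp.codon_usage import trim_terminal_stop

    for gene, aln in alns.items():
        root = trim_terminal_stop(
            extract_gene_sequence(default_genome, default_genome.feature_by_name(gene))
        )
        assert aln.get("a") == aln.get("b") == root


def test_evolution_deterministic_and_seed_sensitive(default_genome):
    params = EvolutionParams(tree="(a:0.1,b:0.1);", seed=5, include_rrna=False)
    a1, _ = evolve_genes(default_genome, params)
    a2, _ = evolve_genes(default_genome, params)
    assert all(a1[g].rows == a2[g].rows for g in a1)
    b, _ = evolve_genes(default_genome, EvolutionParams(tree="(a:0.1,b:0.1);", seed=6,
                                                        include_rrna=False))
    assert any(a1[g].rows != b[g].rows for g in a1)


def test_alignments_stay_in_frame_and_gap_free(default_genome):
    nwk, _ = family_study_tree(2, 2)
    alns, _ = evolve_genes(default_genome, EvolutionParams(tree=nwk, seed=2))
    code = get_code(5)
    for gene, aln in alns.items():
        if gene in ("rrnL", "rrnS"):
            continue
        assert aln.length % 3 == 0
        for _, seq in aln.rows:
            assert "-" not in seq
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert codons <= set(code.sense_codons)


def test_omega_must_be_positive():
    with pytest.raises(ValueError, match="omega"):
        EvolutionParams(tree="(a:1,b:1);", gene_omega={"COX1": 0.0})


def _ts_tv_counts(s1, s2):
    ts = tv = 0
    for a, b in zip(s1, s2):
        if a != b:
            if is_transition(a, b):
                ts += 1
            else:
                tv += 1
    return ts, tv


def test_transition_bias_increases_with_kappa(default_genome):
    ratios = []
    for kappa in (1.0, 2.0, 4.0, 8.0):
        params = EvolutionParams(
            tree="(a:0.3,b:0.3);", seed=11, kappa=kappa, include_rrna=True
        )
        alns, _ = evolve_genes(default_genome, params)
        aln = alns["rrnL"]
        ts, tv = _ts_tv_counts(aln.get("a"), aln.get("b"))
        ratios.append(ts / max(tv, 1))
    assert ratios == sorted(ratios)
    assert ratios[-1] > ratios[0]


def test_estimator_consistency_at_neutrality(default_genome):
    """omega = 1 simulations recover Ka/Ks near 1 (mean over replicates)."""
    from mitocomp.rates import ng86_pair

    omegas = []
    for rep in range(20):
        params = EvolutionParams(
            tree="(a:0.15,b:0.15);", seed=100 + rep, kappa=1.0,
            base_freqs=(0.25, 0.25, 0.25, 0.25),  # NG86 assumes equal rates
            gene_omega={"COX1": 1.0}, include_rrna=False,
        )
        alns, _ = evolve_genes(default_genome, params)
        e = ng86_pair(alns["COX1"].get("a"), alns["COX1"].get("b"))
        omegas.append(e.omega)
    mean = sum(omegas) / len(omegas)
    assert abs(mean - 1.0) < 0.15


def test_per_gene_rate_multipliers_order_ks(default_genome):
    from mitocomp.rates import ng86_pair

    params = EvolutionParams(
        tree="(a:0.1,b:0.1);", seed=21,
        gene_rate={"ATP8": 5.0, "COX1": 0.2}, include_rrna=False,
    )
    alns, _ = evolve_genes(default_genome, params)
    ks = {
        g: ng86_pair(alns[g].get("a"), alns[g].get("b")).ks
        for g in ("ATP8", "CYTB", "COX1")
    }
    assert ks["ATP8"] > ks["CYTB"] > ks["COX1"]
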