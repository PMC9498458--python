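"""End-to-end comparative-mitogenomics pipeline and report emission.

``run_pipeline`` ties the stages together — genomes in (GenBank files or
the synthetic generator), reports out: composition tables, per-gene skew
tables, junction/strand reports, start/stop and RSCU tables, per-family
rate summaries, saturation diagnostics and a ready-to-run supermatrix with
a neighbor-joining sanity tree.  Reports are TSV with a JSON manifest
sidecar (schema version, seed, input hashes); rounding is applied only at
the report layer, in-memory values keep full precision.  Reruns of the
same configuration produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import architecture, composition, codon_usage, phyloprep, rates, saturation
from .genomes import MitoGenome, extract_gene_sequence, read_genbank
from .simulate import (
    EvolutionParams,
    GenomeTemplate,
    evolve_genes,
    family_study_tree,
    generate_genome,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("mitocomp")

SCHEMA_VERSION = "1.0"
ALL_STAGES = (
    "genomes", "architecture", "composition", "codon_usage",
    "rates", "saturation", "matrix",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With no ``genbank_paths`` the synthetic generator supplies
    ``n_genomes`` genomes from ``template`` (seeds derived from ``seed``),
    and gene alignments for the rate/saturation/matrix stages come from
    simulated evolution over a family study design.
    """

    outdir: str = "mitocomp_out"
    genbank_paths: tuple[str, ...] = ()
    template: GenomeTemplate | None = None
    n_genomes: int = 3
    stages: tuple[str, ...] = ALL_STAGES
    genetic_code: int = 5
    seed: int = 1
    include_cr: bool = False
    design: str = "within-family"
    block_params: phyloprep.BlockFilterParams = field(
        default_factory=phyloprep.BlockFilterParams
    )
    matrix_format: str = "nexus"
    n_families: int = 6
    taxa_per_family: int = 4
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    failed_stages: list[str]

    @property
    def ok(self) -> bool:
        return not self.failed_stages

    def artifact(self, name: str) -> Path:
        return self.outdir / self.manifest["artifacts"][name]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.4f") -> None:
    df.to_csv(path, sep="\t", float_format=float_format, lineterminator="\n")


def _load_genomes(config: RunConfig) -> list[MitoGenome]:
    if config.genbank_paths:
        genomes: list[MitoGenome] = []
        for p in config.genbank_paths:
            genomes.extend(read_genbank(p))
        return genomes
    template = config.template or GenomeTemplate.default()
    genomes = []
    for i in range(config.n_genomes):
        t = template
        if t.identifier == "synthetic_mitogenome":
            from dataclasses import replace as _replace

            t = _replace(t, identifier=f"synthetic_{i + 1}")
        genomes.append(generate_genome(t, seed=config.seed * 1000 + i))
    return genomes


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the configured stages and emit the report bundle.

    Any stage failure is recorded in the manifest and reflected in
    ``PipelineResult.failed_stages``; completed artifacts are kept.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage_status: dict[str, str] = {}
    failed: list[str] = []

    genomes: list[MitoGenome] = []
    alignments = None
    groups: dict[str, str] = {}

    def _stage(name: str, fn) -> None:
        if name not in config.stages:
            stage_status[name] = "skipped"
            return
        try:
            fn()
            stage_status[name] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log.exception("stage %s failed", name)
            stage_status[name] = f"failed: {exc}"
            failed.append(name)

    def s_genomes() -> None:
        nonlocal genomes
        genomes = _load_genomes(config)
        rows = [
            (g.identifier, g.length, len(g.features), g.taxon_family or "")
            for g in genomes
        ]
        df = pd.DataFrame(
            rows, columns=["genome", "length_bp", "n_features", "family"]
        ).set_index("genome")
        _write_tsv(df, outdir / "genomes.tsv")
        artifacts["genomes"] = "genomes.tsv"

    def s_architecture() -> None:
        rows = []
        order_lines = []
        census_rows = []
        if config.genbank_paths:
            reference = None
        else:
            from dataclasses import replace as _replace

            anc = _replace(
                config.template or GenomeTemplate.default(), rearranged=False
            )
            reference = architecture.gene_order(generate_genome(anc, seed=config.seed))
        for g in genomes:
            rep = architecture.junctions(g, include_cr=config.include_cr)
            for j in rep.rows:
                rows.append((g.identifier, j.upstream, j.downstream,
                             j.relationship, j.length, j.cr_adjacent))
            order = architecture.gene_order(g)
            order_lines.append(
                g.identifier + "\t" + " ".join(
                    f"{n}{'-' if s == -1 else ''}" for n, s in order.entries
                )
            )
            census = architecture.strand_census(g)
            census_rows.append(
                (g.identifier, census.get(1, "PCG"), census.get(1, "tRNA"),
                 census.get(1, "rRNA"), census.get(-1, "PCG"),
                 census.get(-1, "tRNA"), census.get(-1, "rRNA"),
                 census.majority_total, census.minority_total)
            )
            if reference is not None:
                r = architecture.classify_rearrangement(order, reference)
                order_lines[-1] += f"\tlepidoptera_tdrl={r.lepidoptera_tdrl}"
        df = pd.DataFrame(rows, columns=[
            "genome", "upstream", "downstream", "relationship", "length_bp", "cr_adjacent"
        ]).set_index("genome")
        _write_tsv(df, outdir / "junctions.tsv")
        (outdir / "gene_order.txt").write_text("\n".join(order_lines) + "\n")
        cdf = pd.DataFrame(census_rows, columns=[
            "genome", "PCG_majority", "tRNA_majority", "rRNA_majority",
            "PCG_minority", "tRNA_minority", "rRNA_minority",
            "total_majority", "total_minority",
        ]).set_index("genome")
        _write_tsv(cdf, outdir / "strand_census.tsv")
        artifacts["junctions"] = "junctions.tsv"
        artifacts["gene_order"] = "gene_order.txt"
        artifacts["strand_census"] = "strand_census.tsv"

    def s_composition() -> None:
        rows = []
        for g in genomes:
            p = composition.base_composition(g.sequence)
            rows.append((g.identifier, g.length, round(p.a_pct, 1), round(p.t_pct, 1),
                         round(p.c_pct, 1), round(p.g_pct, 1),
                         round(p.at_pct, 1), round(p.gc_pct, 1)))
        df = pd.DataFrame(rows, columns=[
            "genome", "length_bp", "A_pct", "T_pct", "C_pct", "G_pct", "AT_pct", "GC_pct"
        ]).set_index("genome")
        _write_tsv(df, outdir / "composition.tsv", float_format="%.1f")
        skews = composition.skew_table(genomes)
        _write_tsv(skews.round({"AT_pct": 1, "GC_pct": 1, "AT_skew": 4, "GC_skew": 4}),
                   outdir / "skew_table.tsv")
        artifacts["composition"] = "composition.tsv"
        artifacts["skew_table"] = "skew_table.tsv"

    def s_codon_usage() -> None:
        ss_rows = []
        rscu_frames = []
        for g in genomes:
            cdss = []
            feats = sorted(
                (f for f in g.features if f.gene_class == "PCG"),
                key=lambda f: f.canonical_name,
            )
            for f in feats:
                cds = extract_gene_sequence(g, f)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    entry = codon_usage.classify_start_stop(cds, config.genetic_code)
                ss_rows.append((g.identifier, f.canonical_name, entry.start_codon,
                                entry.start_class, entry.stop_codon, entry.stop_class,
                                entry.complete))
                cdss.append(codon_usage.trim_terminal_stop(cds, config.genetic_code))
            counts, skipped = codon_usage.codon_counts(cdss, config.genetic_code)
            table = codon_usage.rscu(counts, config.genetic_code)
            frame = table.as_frame(config.genetic_code)
            frame.insert(0, "genome", g.identifier)
            rscu_frames.append(frame)
        df = pd.DataFrame(ss_rows, columns=[
            "genome", "gene", "start_codon", "start_class",
            "stop_codon", "stop_class", "stop_complete",
        ]).set_index("genome")
        _write_tsv(df, outdir / "start_stop.tsv")
        _write_tsv(pd.concat(rscu_frames), outdir / "rscu.tsv", float_format="%.3f")
        artifacts["start_stop"] = "start_stop.tsv"
        artifacts["rscu"] = "rscu.tsv"

    def _ensure_alignments() -> None:
        nonlocal alignments, groups
        if alignments is not None:
            return
        nwk, groups = family_study_tree(config.n_families, config.taxa_per_family)
        params = EvolutionParams(tree=nwk, seed=config.seed)
        alignments, _ = evolve_genes(genomes[0], params)

    def s_rates() -> None:
        _ensure_alignments()
        pcg_alns = {g: a for g, a in alignments.items() if a.is_codon_aligned()}
        summary = rates.family_rate_summary(
            pcg_alns, groups, design=config.design, genetic_code=config.genetic_code
        )
        _write_tsv(summary.table.set_index(["gene", "family"]),
                   outdir / "rates_by_family.tsv")
        _write_tsv(summary.gene_means(), outdir / "rates_by_gene.tsv")
        artifacts["rates_by_family"] = "rates_by_family.tsv"
        artifacts["rates_by_gene"] = "rates_by_gene.tsv"

    def s_saturation() -> None:
        _ensure_alignments()
        pcg = {g: a for g, a in alignments.items() if a.is_codon_aligned()}
        matrix = phyloprep.concatenate(pcg, sorted(pcg))
        from .genomes import Alignment

        concat = Alignment("concatenated", [(t, matrix.rows[t]) for t in matrix.taxa])
        iss_rows = []
        curve_frames = []
        for stratum in (1, 2, 3, "all"):
            r = saturation.iss(concat, stratum)
            iss_rows.append((r.stratum, r.mean_entropy, r.saturated_entropy,
                             r.iss, r.n_sequences, r.n_sites))
            curve_frames.append(saturation.ts_tv_curve(concat, stratum))
        df = pd.DataFrame(iss_rows, columns=[
            "stratum", "mean_entropy", "saturated_entropy", "Iss",
            "n_sequences", "n_sites",
        ]).set_index("stratum")
        _write_tsv(df, outdir / "iss.tsv")
        _write_tsv(pd.concat(curve_frames).set_index(["taxon1", "taxon2"]),
                   outdir / "ts_tv_curve.tsv")
        artifacts["iss"] = "iss.tsv"
        artifacts["ts_tv_curve"] = "ts_tv_curve.tsv"

    def s_matrix() -> None:
        _ensure_alignments()
        pcg = {g: a for g, a in alignments.items() if a.is_codon_aligned()}
        filtered = {}
        for gene in sorted(pcg):
            f, _kept = phyloprep.conserved_block_filter(pcg[gene], config.block_params)
            if f.length:
                filtered[gene] = f
        matrix = phyloprep.concatenate(filtered, sorted(filtered), groups)
        ext = {"fasta": "fasta", "phylip": "phy", "nexus": "nex"}[config.matrix_format]
        mpath = outdir / f"supermatrix.{ext}"
        phyloprep.write_matrix(matrix, config.matrix_format, mpath)
        tree = phyloprep.nj_tree(matrix, distance="K2P")
        (outdir / "nj_tree.nwk").write_text(tree + "\n")
        parts = pd.DataFrame(
            [(p.gene, p.codon_position or 0, p.start, p.end)
             for p in matrix.partitions],
            columns=["gene", "codon_position", "start", "end"],
        ).set_index("gene")
        _write_tsv(parts, outdir / "partitions.tsv")
        artifacts["supermatrix"] = f"supermatrix.{ext}"
        artifacts["nj_tree"] = "nj_tree.nwk"
        artifacts["partitions"] = "partitions.tsv"

    _stage("genomes", s_genomes)
    if not genomes and any(
        s in config.stages for s in ALL_STAGES[1:]
    ):
        genomes = _load_genomes(config)
    _stage("architecture", s_architecture)
    _stage("composition", s_composition)
    _stage("codon_usage", s_codon_usage)
    _stage("rates", s_rates)
    _stage("saturation", s_saturation)
    _stage("matrix", s_matrix)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "genetic_code": config.genetic_code,
        "stages": stage_status,
        "inputs": {
            str(p): _sha256(Path(p)) for p in config.genbank_paths
        } or {"generator": f"template seed {config.seed}"},
        "artifacts": dict(sorted(artifacts.items())),
        "artifact_hashes": {
            name: _sha256(outdir / fname) for name, fname in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(outdir=outdir, manifest=manifest, failed_stages=failed)
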