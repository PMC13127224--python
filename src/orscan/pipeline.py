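"""End-to-end orchestration: search -> call -> annotate -> summarize ->
motifs -> classify, with the paper-shaped report files.

Stages are plain functions over in-memory objects (:func:`analyze`);
:func:`run_pipeline` is the file-based wrapper that reads FASTA inputs,
executes the stages and writes a run directory. Every threshold actually
applied is echoed to ``run.log`` so summary tables are auditable, and the
whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clusters import (
    ORCluster,
    RepertoireSummary,
    assign_clusters,
    summarize_repertoire,
    write_clusters,
    write_summary_tables,
)
from .gene_models import ORGeneModel, call_genes
from .motifs import MotifModel, discover_top_motifs, write_motifs
from .phylo import (
    GroupAssignment,
    assign_groups,
    detect_expansion,
    distance_matrix,
    nj_tree,
    write_expansion,
    write_groups,
)
from .search import (
    DEFAULT_CHAIN_GAP,
    DEFAULT_MAX_EVALUE,
    CandidateLocus,
    Hsp,
    chain_and_select,
    scan_genome,
)
from .seqio import AnnotationRecord, SequenceRecord, parse_fasta, write_annotations
from .simulate import TruthRecord
from .topology import annotate_models

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str = ""
    queries: str = ""
    decoys: str = ""
    references: str = ""
    out_dir: str = "orscan_run"
    species: str = "sample"
    max_evalue: float = DEFAULT_MAX_EVALUE
    chain_gap: int = DEFAULT_CHAIN_GAP
    flank: int = 1_500
    cluster_gap: int = 1_000_000
    n_motifs: int = 5
    width_grid: tuple[int, ...] | None = None
    require_7tm: bool = False
    tree_classify: bool = False
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    hsps: list[Hsp]
    loci: list[CandidateLocus]
    genes: list[ORGeneModel]
    clusters: list[ORCluster]
    summary: RepertoireSummary
    motifs: list[MotifModel] = field(default_factory=list)
    assignment: GroupAssignment | None = None
    expansion: dict | None = None
    tree_newick: str | None = None


def analyze(
    genome: list[SequenceRecord],
    queries: list[SequenceRecord],
    decoys: list[SequenceRecord] | None = None,
    references: list[SequenceRecord] | None = None,
    reference_counts: dict[str, list[int]] | None = None,
    chrom_sizes: dict[str, float] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all stages on in-memory records and return every product."""
    cfg = config or PipelineConfig()

    logger.info("search: %d queries vs %d records, E <= %g", len(queries), len(genome), cfg.max_evalue)
    hsps = scan_genome(queries, genome, max_evalue=cfg.max_evalue)
    loci = chain_and_select(hsps, max_chain_gap=cfg.chain_gap)
    logger.info("search: %d HSPs -> %d candidate loci", len(hsps), len(loci))

    genes = call_genes(loci, genome, queries, decoys or [], flank=cfg.flank)
    annotate_models(genes)
    if cfg.require_7tm:
        before = len(genes)
        genes = [g for g in genes if g.topology_ok]
        logger.info("strict 7TM mode: %d of %d models kept", len(genes), before)

    if chrom_sizes is None:
        chrom_sizes = {rec.id: len(rec.seq) / 1e6 for rec in genome}

    assignment = None
    tree_newick = None
    if references:
        functional_recs = [
            SequenceRecord(g.id, g.peptide) for g in genes if g.status == "functional"
        ]
        if functional_recs:
            mode = "tree" if cfg.tree_classify else "nearest"
            assignment = assign_groups(functional_recs, references, mode=mode)
            for g in genes:
                g.group = assignment.groups.get(g.id)
            if len(functional_recs) + len(references) >= 3:
                dm = distance_matrix(functional_recs + list(references))
                tree_newick = nj_tree(dm)

    clusters = assign_clusters(genes, max_gap=cfg.cluster_gap)
    summary = summarize_repertoire(genes, chrom_sizes)
    logger.info(
        "called %d genes (%s); %d clusters",
        summary.total,
        ", ".join(f"{k}={v}" for k, v in summary.species_counts.items() if k != "total"),
        len(clusters),
    )

    functional_peps = [g.peptide for g in genes if g.status == "functional"]
    functional_ids = [g.id for g in genes if g.status == "functional"]
    motifs = []
    if len(functional_peps) >= 2:
        motifs = discover_top_motifs(
            functional_peps,
            n_motifs=cfg.n_motifs,
            width_grid=cfg.width_grid,
            seed=cfg.seed,
            ids=functional_ids,
        )
        logger.info("motifs: %s", ", ".join(m.consensus for m in motifs))

    expansion = None
    if assignment and assignment.groups and reference_counts:
        expansion = detect_expansion(assignment, reference_counts)

    return PipelineResult(hsps, loci, genes, clusters, summary, motifs, assignment, expansion, tree_newick)


def genes_to_annotations(genes: list[ORGeneModel]) -> list[AnnotationRecord]:
    return [
        AnnotationRecord(
            seq_id=g.chrom,
            start=g.cds_start,
            end=g.cds_end,
            strand=g.strand,
            feature_type="gene",
            attributes={
                "ID": g.id,
                "status": g.status,
                "defects": ",".join(sorted(g.defects)) or "none",
                "tm_count": g.tm_count,
                "group": g.group or "NA",
            },
        )
        for g in genes
    ]


def write_genes_tsv(genes: list[ORGeneModel], path: str) -> None:
    cols = [
        "id", "chrom", "start", "end", "strand", "status", "defects", "length_aa",
        "tm_count", "topology_ok", "sequons", "group", "best_query", "verify_score",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        g.id, g.chrom, g.cds_start, g.cds_end, g.strand, g.status,
                        ",".join(sorted(g.defects)) or "none", g.length_aa,
                        g.tm_count, g.topology_ok,
                        ",".join(str(s) for s in g.sequons) or ".",
                        g.group or "NA", g.best_query, g.verify_score,
                    ]
                )
                + "\n"
            )


def run_pipeline(config: PipelineConfig) -> Path:
    """File-based pipeline run; returns the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("orscan")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        logger.info("orscan %s", __version__)
        logger.info("config: %s", config)
        genome = parse_fasta(config.genome, "nucleotide")
        queries = parse_fasta(config.queries, "protein")
        decoys = parse_fasta(config.decoys, "protein") if config.decoys else []
        references = (
            parse_fasta(config.references, "protein") if config.references else []
        )

        stage = "analyze"
        result = analyze(genome, queries, decoys, references, config=config)

        stage = "write outputs"
        write_annotations(genes_to_annotations(result.genes), out / "genes.gff3", "GFF3")
        write_genes_tsv(result.genes, str(out / "genes.tsv"))
        write_summary_tables(result.summary, str(out / "rep"), species=config.species)
        write_clusters(result.clusters, str(out / "clusters.tsv"))
        if result.motifs:
            (out / "motifs").mkdir(exist_ok=True)
            write_motifs(result.motifs, str(out / "motifs" / "motifs"))
        if result.tree_newick:
            (out / "tree.nwk").write_text(result.tree_newick + "\n")
        if result.assignment:
            write_groups(result.assignment, str(out / "groups.tsv"))
        if result.expansion:
            write_expansion(result.expansion, str(out / "expansion.tsv"))
        logger.info("pipeline complete: %s", out)
        return out
    except Exception:
        logger.exception("pipeline failed at stage: %s", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def score_against_truth(genes: list[ORGeneModel], truth: list[TruthRecord]) -> dict:
    """Planted-truth recovery: per-gene match by coordinate overlap on the
    same chromosome and strand, status compared against truth.

    Returns recovery (matched fraction), status accuracy among matches,
    and the overall fraction of planted genes called with correct status.
    """
    matched = 0
    correct = 0
    confusion: dict[tuple[str, str], int] = {}
    for t in truth:
        hit = None
        for g in genes:
            if (
                g.chrom == t.chrom
                and g.strand == t.strand
                and g.cds_start < t.end
                and t.start < g.cds_end
            ):
                hit = g
                break
        if hit is not None:
            matched += 1
            confusion[(t.true_status, hit.status)] = (
                confusion.get((t.true_status, hit.status), 0) + 1
            )
            if hit.status == t.true_status:
                correct += 1
    n = len(truth)
    return {
        "n_truth": n,
        "n_matched": matched,
        "recovery": matched / n if n else 0.0,
        "status_accuracy": correct / matched if matched else 0.0,
        "correct_fraction": correct / n if n else 0.0,
        "confusion": confusion,
    }
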