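"""Chromosomal clustering, orientation analysis and repertoire summaries.

A cluster is a maximal chain of OR genes on one chromosome in which
consecutive genes (sorted by start) are separated by strictly less than
1 Mb, measured between nearest gene edges. A cluster whose members all
share one transcriptional orientation (and has at least two members) is
flagged as a candidate tandem-duplication array.

Repertoire summaries mirror the two standard report shapes: a species
row of category counts with percentages, and a per-chromosome
composition table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .gene_models import ORGeneModel, STATUSES

DEFAULT_CLUSTER_GAP = 1_000_000


@dataclass
class ORCluster:
    chrom: str
    members: list[str]
    span: tuple[int, int]
    orientation_fraction: float = 1.0
    tandem_flag: bool = False
    family_composition: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class RepertoireSummary:
    species_counts: dict
    species_percentages: dict
    per_chromosome: pd.DataFrame

    @property
    def total(self) -> int:
        return self.species_counts["total"]


def pct(count: int, total: int) -> float:
    """Percentage rounded half-up to two decimals; 0 for an empty total."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def assign_clusters(
    genes: list[ORGeneModel], max_gap: int = DEFAULT_CLUSTER_GAP
) -> list[ORCluster]:
    """Single-linkage chaining of genes per chromosome.

    Consecutive genes whose nearest-edge distance is < ``max_gap`` join
    one cluster (a 1,000,000-bp gap does NOT join under the default).
    Singletons form clusters of size 1.
    """
    by_chrom: dict[str, list[ORGeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    clusters: list[ORCluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda g: (g.cds_start, g.cds_end, g.id))
        current: list[ORGeneModel] = []
        current_end = None
        for g in members:
            if current and g.cds_start - current_end >= max_gap:
                clusters.append(_make_cluster(chrom, current))
                current = []
                current_end = None
            current.append(g)
            current_end = g.cds_end if current_end is None else max(current_end, g.cds_end)
        if current:
            clusters.append(_make_cluster(chrom, current))
    return clusters


def _make_cluster(chrom: str, members: list[ORGeneModel]) -> ORCluster:
    cluster = ORCluster(
        chrom=chrom,
        members=[g.id for g in members],
        span=(min(g.cds_start for g in members), max(g.cds_end for g in members)),
    )
    frac, tandem = orientation_consistency(cluster, members)
    cluster.orientation_fraction = frac
    cluster.tandem_flag = tandem
    comp: dict[str, int] = {}
    for g in members:
        if g.group:
            comp[g.group] = comp.get(g.group, 0) + 1
    cluster.family_composition = comp
    return cluster


def orientation_consistency(
    cluster: ORCluster, genes: list[ORGeneModel]
) -> tuple[float, bool]:
    """Majority-strand share and the tandem-array flag (all members on
    one strand, at least two members)."""
    lookup = {g.id: g for g in genes}
    strands = [lookup[m].strand for m in cluster.members]
    plus = strands.count("+")
    frac = max(plus, len(strands) - plus) / len(strands)
    return frac, frac == 1.0 and len(strands) >= 2


def summarize_repertoire(
    genes: list[ORGeneModel],
    chrom_sizes: dict[str, float] | None = None,
) -> RepertoireSummary:
    """Species-level and per-chromosome counts with 2-decimal percentages.

    ``chrom_sizes`` maps chromosome name to size in Mb (reporting field
    only). Raises on a gene with unknown status.
    """
    for g in genes:
        if g.status not in STATUSES:
            raise ValueError(f"gene {g.id} has unknown status {g.status!r}")
    if not genes:
        warnings.warn("empty gene list: reporting an all-zero summary")

    counts = {s: sum(1 for g in genes if g.status == s) for s in STATUSES}
    counts["total"] = len(genes)
    percentages = {s: pct(counts[s], counts["total"]) for s in STATUSES}

    chroms = sorted({g.chrom for g in genes} | set(chrom_sizes or {}))
    rows = []
    for chrom in chroms:
        sub = [g for g in genes if g.chrom == chrom]
        row = {
            "chromosome": chrom,
            "size_mb": (chrom_sizes or {}).get(chrom, float("nan")),
            "functional": sum(1 for g in sub if g.status == "functional"),
            "partial": sum(1 for g in sub if g.status == "partial"),
            "pseudogene": sum(1 for g in sub if g.status == "pseudogene"),
            "total": len(sub),
        }
        rows.append(row)
    per_chrom = pd.DataFrame(
        rows, columns=["chromosome", "size_mb", "functional", "partial", "pseudogene", "total"]
    )
    return RepertoireSummary(counts, percentages, per_chrom)


def summary_from_counts(functional: int, partial: int, pseudogene: int) -> dict:
    """Summary-only entry point: category counts in, the species summary
    row out (counts, total and printed-style percentages)."""
    total = functional + partial + pseudogene
    return {
        "functional": functional,
        "partial": partial,
        "pseudogene": pseudogene,
        "total": total,
        "functional_pct": pct(functional, total),
        "partial_pct": pct(partial, total),
        "pseudogene_pct": pct(pseudogene, total),
    }


def species_table_row(species: str, summary: RepertoireSummary) -> str:
    """Render one species row in the 'count (pct)' report style."""
    c, p = summary.species_counts, summary.species_percentages
    return "\t".join(
        [
            species,
            f"{c['functional']} ({p['functional']:.2f})",
            f"{c['partial']} ({p['partial']:.2f})",
            f"{c['pseudogene']} ({p['pseudogene']:.2f})",
            str(c["total"]),
        ]
    )


def write_summary_tables(
    summary: RepertoireSummary,
    out_prefix: str,
    species: str = "synthetic",
) -> tuple[str, str]:
    """Write the species-row table and the per-chromosome table as TSV."""
    t1 = f"{out_prefix}.table1.tsv"
    t2 = f"{out_prefix}.table2.tsv"
    with open(t1, "w") as fh:
        fh.write(
            "species\tfunctional (%)\tpartial (%)\tpseudogene (%)\ttotal\n"
        )
        fh.write(species_table_row(species, summary) + "\n")
    summary.per_chromosome.to_csv(t2, sep="\t", index=False)
    return t1, t2


def write_clusters(clusters: list[ORCluster], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tn_genes\torientation_fraction\ttandem_flag\t"
            "members\tfamily_composition\n"
        )
        for c in clusters:
            comp = ",".join(f"{k}:{v}" for k, v in sorted(c.family_composition.items()))
            fh.write(
                f"{c.chrom}\t{c.span[0]}\t{c.span[1]}\t{len(c)}\t"
                f"{c.orientation_fraction:.4f}\t{c.tandem_flag}\t"
                f"{','.join(c.members)}\t{comp or '.'}\n"
            )
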