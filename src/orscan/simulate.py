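"""Synthetic genomes with planted OR gene truth.

The generator emulates the repertoire structure the pipeline targets:
multi-chromosome assemblies carrying oriented tandem clusters of
single-exon OR-like genes embedded in random background sequence. Each
cluster expands one group-specific template; copies diverge by a per-copy
amino-acid substitution rate and are independently pseudogenized (one
premature stop or a 1-nt frameshift, chosen uniformly, placed in the
middle 60% of the CDS so it falls inside alignable sequence) or truncated
(one third of the CDS removed from the start or stop end). A truth table
records every planted gene, so recovery, status accuracy and cluster
statistics can all be scored against ground truth.

Templates are built to OR architecture: ~307 aa, seven 21-aa hydrophobic
stretches separated by hydrophilic loops, the canonical "MAYDRYVAIC"
block after the third helix, and at least one N-X-S/T sequon near the N
terminus. Group templates differ in their randomized loop and helix
composition (well above 25% divergence), so group assignment is
well-posed. Back-translation draws synonymous codons uniformly.

Everything is driven by one seeded generator: the same spec and seed
reproduce byte-identical FASTA and truth outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .seqio import AnnotationRecord, SequenceRecord, revcomp

MOTIF_BLOCK = "MAYDRYVAIC"
SEQUON_BLOCK = "NGT"

TM_ALPHABET = "ILVF"
TM_WEIGHTS = (0.35, 0.35, 0.2, 0.1)
LOOP_ALPHABET = "GSTNQDEKR"
LOOP_WEIGHTS = (0.2, 0.2, 0.15, 0.1, 0.1, 0.0625, 0.0625, 0.0625, 0.0625)

TM_LEN = 21
LOOP_LEN = 20
N_TM = 7

AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GROUP_CYCLE = ("delta", "zeta", "eta", "beta", "gamma", "epsilon", "kappa")

_table = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)
STOP_CODONS = tuple(sorted(_table.stop_codons))


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic genome."""

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    gc: float = 0.41
    n_templates: int = 3
    n_clusters: int = 3
    copies_per_cluster: int = 10
    intergene_gap: tuple[int, int] = (6_000, 25_000)
    cluster_separation: int = 50_000
    p_pseudo: float = 0.06
    p_partial: float = 0.03
    aa_divergence: float = 0.05
    orientation_mode: str = "same"
    seed: int = 0

    def __post_init__(self):
        for name in ("gc", "p_pseudo", "p_partial", "aa_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_pseudo + self.p_partial > 1.0:
            raise ValueError("p_pseudo + p_partial must be <= 1")
        if self.orientation_mode not in ("same", "mixed"):
            raise ValueError("orientation_mode must be 'same' or 'mixed'")
        if self.intergene_gap[0] > self.intergene_gap[1] or self.intergene_gap[0] < 0:
            raise ValueError("invalid intergene_gap range")


@dataclass
class TruthRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    true_status: str
    template_id: str
    group_label: str
    cluster_id: str


def _stable_int(label: str) -> int:
    return zlib.crc32(label.encode())


def make_or_template(group_label: str, seed: int = 0) -> tuple[str, str]:
    """Deterministic (peptide, CDS) template for one OR group.

    The peptide carries seven hydrophobic helices, the conserved
    "MAYDRYVAIC" block after helix 3, and an N-terminal N-G-T sequon; the
    CDS starts with ATG and ends with a single stop codon.
    """
    rng = np.random.default_rng([seed, _stable_int(group_label)])

    def loop(n: int) -> str:
        return "".join(rng.choice(list(LOOP_ALPHABET), size=n, p=LOOP_WEIGHTS))

    def helix() -> str:
        return "".join(rng.choice(list(TM_ALPHABET), size=TM_LEN, p=TM_WEIGHTS))

    nterm = loop(19)
    nterm = nterm[:5] + SEQUON_BLOCK + nterm[8:]
    parts = ["M", nterm]
    for i in range(N_TM):
        parts.append(helix())
        if i < N_TM - 1:
            lp = loop(LOOP_LEN)
            if i == 2:  # canonical block at the helix-3 / loop junction
                lp = MOTIF_BLOCK + lp[len(MOTIF_BLOCK):]
            parts.append(lp)
    parts.append(loop(LOOP_LEN))
    peptide = "".join(parts)
    cds = back_translate(peptide, rng) + str(rng.choice(STOP_CODONS))
    return peptide, cds


def back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice."""
    return "".join(str(rng.choice(CODONS_BY_AA[aa])) for aa in peptide)


def mutate_peptide(peptide: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitutions at the given rate; the initial methionine is
    kept so divergence never silently removes the start codon."""
    out = list(peptide)
    for i in range(1, len(out)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = str(rng.choice(choices))
    return "".join(out)


def _lesion_pseudo(cds: str, rng: np.random.Generator) -> str:
    """One premature stop or a 1-nt frameshift, in the middle 60%."""
    n_codons = len(cds) // 3 - 1  # exclude the terminal stop
    lo, hi = int(n_codons * 0.2), int(n_codons * 0.8)
    if rng.random() < 0.5:
        c = int(rng.integers(lo, hi))
        stop = str(rng.choice(STOP_CODONS))
        return cds[: 3 * c] + stop + cds[3 * c + 3 :]
    pos = int(rng.integers(3 * lo, 3 * hi))
    if rng.random() < 0.5:
        base = str(rng.choice(list("ACGT")))
        return cds[:pos] + base + cds[pos:]
    return cds[:pos] + cds[pos + 1 :]


def _lesion_partial(cds: str, rng: np.random.Generator) -> str:
    """Remove one third of the CDS from the start (ATG lost) or the stop
    end (terminal stop lost)."""
    n_codons = len(cds) // 3
    cut = n_codons // 3
    if rng.random() < 0.5:
        return cds[3 * cut :]
    return cds[: 3 * (n_codons - cut)]


def _random_background(length: int, gc: float, rng: np.random.Generator) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes())


def generate_genome(
    spec: SimulationSpec,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate a genome with planted OR clusters and its truth table."""
    rng = np.random.default_rng(spec.seed)

    group_cycle = [DEFAULT_GROUP_CYCLE[i % len(DEFAULT_GROUP_CYCLE)] for i in range(spec.n_templates)]
    templates = {
        g: make_or_template(g, spec.seed) for g in dict.fromkeys(group_cycle)
    }

    # materialize every cluster (gene sequences, strands, truth skeletons)
    clusters = []
    for ci in range(spec.n_clusters):
        group = group_cycle[ci % len(group_cycle)]
        peptide, _ = templates[group]
        cluster_strand = "+" if rng.random() < 0.5 else "-"
        genes = []
        for gi in range(spec.copies_per_cluster):
            copy_pep = mutate_peptide(peptide, spec.aa_divergence, rng)
            cds = back_translate(copy_pep, rng) + str(rng.choice(STOP_CODONS))
            u = rng.random()
            if u < spec.p_pseudo:
                cds, status = _lesion_pseudo(cds, rng), "pseudogene"
            elif u < spec.p_pseudo + spec.p_partial:
                cds, status = _lesion_partial(cds, rng), "partial"
            else:
                status = "functional"
            strand = (
                cluster_strand
                if spec.orientation_mode == "same"
                else ("+" if rng.random() < 0.5 else "-")
            )
            genes.append((cds, strand, status))
        gaps = [
            int(rng.integers(spec.intergene_gap[0], spec.intergene_gap[1] + 1))
            for _ in range(len(genes) - 1)
        ]
        length = sum(len(g[0]) for g in genes) + sum(gaps)
        clusters.append(
            {"id": f"cluster{ci}", "group": group, "genes": genes, "gaps": gaps, "length": length}
        )

    # assign clusters to chromosomes round-robin and place them
    per_chrom: dict[int, list[dict]] = {c: [] for c in range(spec.n_chromosomes)}
    for ci, cluster in enumerate(clusters):
        per_chrom[ci % spec.n_chromosomes].append(cluster)

    genome: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = _random_background(spec.chrom_length, spec.gc, rng)
        members = per_chrom[c]
        need = sum(cl["length"] for cl in members) + spec.cluster_separation * (
            len(members) + 1
        )
        if need > spec.chrom_length:
            raise ValueError(
                f"planted genes exceed chromosome capacity on {chrom}: "
                f"need {need} bp of {spec.chrom_length}"
            )
        free = spec.chrom_length - need
        shares = rng.random(len(members) + 1)
        shares = (shares / shares.sum() * free).astype(int) if len(members) else []
        cursor = 0
        for mi, cluster in enumerate(members):
            cursor += spec.cluster_separation + int(shares[mi])
            offset = cursor
            for gi, ((cds, strand, status), gap) in enumerate(
                zip(cluster["genes"], cluster["gaps"] + [0])
            ):
                planted = cds if strand == "+" else revcomp(cds)
                seq[offset : offset + len(planted)] = planted.encode()
                truth.append(
                    TruthRecord(
                        gene_id=f"{cluster['id']}_g{gi}",
                        chrom=chrom,
                        start=offset,
                        end=offset + len(planted),
                        strand=strand,
                        true_status=status,
                        template_id=f"template_{cluster['group']}",
                        group_label=cluster["group"],
                        cluster_id=cluster["id"],
                    )
                )
                offset += len(planted) + gap
            cursor += cluster["length"]
        genome.append(SequenceRecord(chrom, seq.decode()))
    return genome, truth


# --- companion input sets --------------------------------------------------


def make_query_set(
    groups: list[str], seed: int = 0, divergence: float = 0.15
) -> list[SequenceRecord]:
    """Cross-species-like OR queries: one diverged copy per group."""
    out = []
    for g in dict.fromkeys(groups):
        peptide, _ = make_or_template(g, seed)
        rng = np.random.default_rng([seed + 1, _stable_int(g)])
        out.append(SequenceRecord(f"query_{g}", mutate_peptide(peptide, divergence, rng)))
    return out


def make_reference_set(
    groups: list[str], seed: int = 0, per_group: int = 2, divergence: float = 0.05
) -> list[SequenceRecord]:
    """Labelled reference OR proteins, headers tagged ``group=<label>``."""
    out = []
    for g in dict.fromkeys(groups):
        peptide, _ = make_or_template(g, seed)
        for i in range(per_group):
            rng = np.random.default_rng([seed + 2, _stable_int(g), i])
            out.append(
                SequenceRecord(
                    f"ref_{g}_{i}|group={g}",
                    mutate_peptide(peptide, divergence, rng),
                )
            )
    return out


def make_decoys(n: int = 5, length: int = 300, seed: int = 0) -> list[SequenceRecord]:
    """Random non-OR decoy peptides for candidate verification."""
    rng = np.random.default_rng([seed + 3, 977])
    return [
        SequenceRecord(f"decoy{i}", "".join(rng.choice(list(AA20), size=length)))
        for i in range(n)
    ]


def truth_to_annotations(truth: list[TruthRecord]) -> list[AnnotationRecord]:
    return [
        AnnotationRecord(
            seq_id=t.chrom,
            start=t.start,
            end=t.end,
            strand=t.strand,
            feature_type="gene",
            attributes={
                "ID": t.gene_id,
                "status": t.true_status,
                "template": t.template_id,
                "group": t.group_label,
                "cluster": t.cluster_id,
            },
        )
        for t in truth
    ]


def write_truth_tsv(truth: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstart\tend\tstrand\ttrue_status\ttemplate_id\t"
            "group_label\tcluster_id\n"
        )
        for t in truth:
            fh.write(
                f"{t.gene_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.true_status}\t{t.template_id}\t{t.group_label}\t{t.cluster_id}\n"
            )
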