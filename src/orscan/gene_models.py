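"""OR gene model construction and three-way status classification.

A candidate locus is turned into a single-exon gene model by extending its
envelope and locating the in-frame ORF that best overlaps the aligned
region (reading frame taken from the best HSP). Coding defects are then
scored:

* ``premature_stop`` — an in-frame stop interrupts the aligned coding
  span before the aligned query end (the query aligns convincingly on
  both sides of the stop);
* ``frameshift`` — colinear HSPs of the same query switch reading frame
  on one strand;
* ``missing_start`` / ``missing_stop`` — no ATG precedes the aligned
  region, or no stop codon terminates it within the extended region;
* ``too_short`` — an otherwise intact ORF of <= 250 aa.

Status follows the three-way rule: any ORF-disrupting defect (premature
stop, frameshift) makes a pseudogene; otherwise any boundary defect or a
short ORF makes a partial gene; otherwise the model is functional (> 250
aa intact ORF). Disruptive defects take precedence when defects co-occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .search import CandidateLocus, Hsp, local_align
from .seqio import SequenceRecord, revcomp, translate

logger = logging.getLogger(__name__)

DEFECTS = ("premature_stop", "frameshift", "missing_start", "missing_stop", "too_short")
STATUSES = ("functional", "partial", "pseudogene")

MIN_FUNCTIONAL_AA = 250  # functional requires strictly more than this
DEFAULT_FLANK = 1_500
MIN_SIDE_SCORE = 60  # alignment evidence required on each side of a stop

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ORGeneModel:
    id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    peptide: str
    length_aa: int
    defects: set = field(default_factory=set)
    status: str = ""
    tm_count: int = -1
    topology_ok: bool = False
    sequons: list = field(default_factory=list)
    group: str | None = None
    verify_score: int = 0
    best_query: str = ""


def _inframe_stops(s: str, phase: int) -> list[int]:
    return [p for p in range(phase, len(s) - 2, 3) if s[p : p + 3] in _STOP_CODONS]


@dataclass
class _LocusFrame:
    """Strand-local view of a locus: region sequence on the gene strand,
    anchor reading-frame phase and the best-query alignment envelope."""

    s: str
    region_start: int
    region_end: int
    phase: int
    env0: int
    env1: int
    anchor: Hsp


def _locus_frame(locus: CandidateLocus, genome: SequenceRecord, flank: int) -> _LocusFrame:
    region_start = max(0, locus.g_start - flank)
    region_end = min(len(genome.seq), locus.g_end + flank)
    raw = genome.seq[region_start:region_end]
    s = raw if locus.strand == "+" else revcomp(raw)

    best_hsps = [h for h in locus.hsps if h.query_id == locus.best_query]
    anchor = min(best_hsps, key=lambda h: (h.evalue, -h.aligned_length, h.query_id))
    if locus.strand == "+":
        env0 = min(h.g_start for h in best_hsps) - region_start
        env1 = max(h.g_end for h in best_hsps) - region_start
        phase = (anchor.g_start - region_start) % 3
    else:
        env0 = region_end - max(h.g_end for h in best_hsps)
        env1 = region_end - min(h.g_start for h in best_hsps)
        phase = (region_end - anchor.g_end) % 3
    return _LocusFrame(s, region_start, region_end, phase, env0, env1, anchor)


def _select_orf(s: str, phase: int, env0: int, env1: int) -> tuple[int, int, int | None]:
    """The stop-free in-frame interval overlapping the aligned envelope
    the most. Returns (start, end, stop_pos); ``stop_pos`` is None when
    the interval runs off the region without a terminating stop."""
    stops = _inframe_stops(s, phase)
    intervals: list[tuple[int, int, int | None]] = []
    prev = phase
    for p in stops:
        intervals.append((prev, p, p))
        prev = p + 3
    tail_end = phase + 3 * ((len(s) - phase) // 3)
    if prev < tail_end:
        intervals.append((prev, tail_end, None))

    def overlap(iv: tuple[int, int, int | None]) -> int:
        return max(0, min(env1, iv[1]) - max(env0, iv[0]))

    return max(intervals, key=lambda iv: (overlap(iv), iv[1] - iv[0]))


def build_gene_model(
    locus: CandidateLocus,
    genome: SequenceRecord,
    flank: int = DEFAULT_FLANK,
) -> ORGeneModel:
    """Build a draft gene model for a candidate locus.

    The locus envelope is extended by ``flank`` bp on both sides; on the
    locus strand the gene is the maximal in-frame ORF overlapping the
    aligned region: from the first ATG after the previous in-frame stop
    (region edge if none) to the first downstream stop.
    """
    if locus.chrom != genome.id or locus.g_end > len(genome.seq) or locus.g_start < 0:
        raise ValueError(
            f"locus {locus.chrom}:{locus.g_start}-{locus.g_end} outside genome record {genome.id}"
        )
    if flank < 0:
        raise ValueError("flank must be >= 0")

    frame = _locus_frame(locus, genome, flank)
    iv_start, iv_end, stop_pos = _select_orf(frame.s, frame.phase, frame.env0, frame.env1)

    defects: set[str] = set()
    if stop_pos is None:
        defects.add("missing_stop")
        cds_end_local = iv_end
    else:
        cds_end_local = iv_end + 3  # include the stop codon

    # first in-frame ATG preceding the aligned region (15-codon jitter
    # tolerated); an ATG deep inside the alignment is not a gene start
    limit = min(iv_end, frame.env1, frame.env0 + 45) - 3
    atg = next(
        (p for p in range(iv_start, limit + 1, 3) if frame.s[p : p + 3] == "ATG"),
        None,
    )
    if atg is None:
        defects.add("missing_start")
        cds_start_local = iv_start
    else:
        cds_start_local = atg

    peptide = translate(frame.s[cds_start_local:iv_end])

    if locus.strand == "+":
        cds_start = frame.region_start + cds_start_local
        cds_end = frame.region_start + cds_end_local
    else:
        cds_start = frame.region_end - cds_end_local
        cds_end = frame.region_end - cds_start_local

    return ORGeneModel(
        id=f"{locus.chrom}:{cds_start}-{cds_end}({locus.strand})",
        chrom=locus.chrom,
        strand=locus.strand,
        cds_start=cds_start,
        cds_end=cds_end,
        peptide=peptide,
        length_aa=len(peptide),
        defects=defects,
        best_query=locus.best_query,
    )


def detect_defects(
    locus: CandidateLocus,
    model: ORGeneModel,
    genome: SequenceRecord,
    flank: int = DEFAULT_FLANK,
    queries: dict[str, str] | None = None,
    max_frameshift_gap: int = 1_000,
    query_overlap_tol: int = 20,
    min_side_score: int = MIN_SIDE_SCORE,
) -> set:
    """Score coding defects for a draft model built from ``locus``.

    ``queries`` maps query id to peptide; when given, a stop inside the
    aligned envelope only counts as premature if the best query aligns
    with score >= ``min_side_score`` on each side of it, which rejects
    stops sitting in noisy alignment overhangs. The draft's boundary
    defects are preserved.
    """
    defects = set(model.defects)
    frame = _locus_frame(locus, genome, flank)
    query_seq = (queries or {}).get(locus.best_query)

    # premature stop: an in-frame stop strictly interior to the aligned
    # envelope, with alignment support on both sides
    interior = [
        p
        for p in _inframe_stops(frame.s, frame.phase)
        if frame.env0 + 6 <= p and p + 3 <= frame.env1 - 6
    ]
    for p in interior[:8]:
        if query_seq is None or _supported_both_sides(
            frame, p, query_seq, min_side_score
        ):
            defects.add("premature_stop")
            break

    # frameshift: colinear same-query HSPs that switch frame on one strand
    best_hsps = sorted(
        (h for h in locus.hsps if h.query_id == locus.best_query),
        key=lambda h: h.g_start,
    )
    ordered = best_hsps if locus.strand == "+" else list(reversed(best_hsps))
    for a, b in zip(ordered, ordered[1:]):
        if a.frame == b.frame:
            continue
        gap = (b.g_start - a.g_end) if locus.strand == "+" else (a.g_start - b.g_end)
        advances = b.q_start >= a.q_end - query_overlap_tol and b.q_end > a.q_end
        if advances and -3 * query_overlap_tol <= gap <= max_frameshift_gap:
            defects.add("frameshift")
            break

    if model.length_aa <= MIN_FUNCTIONAL_AA and not defects:
        defects.add("too_short")
    return defects


def _supported_both_sides(
    frame: _LocusFrame, stop: int, query_seq: str, min_score: int
) -> bool:
    """Does the best query align with at least ``min_score`` to the
    translated envelope on each side of the candidate stop?"""
    left_start = frame.env0 + ((frame.phase - frame.env0) % 3)
    left = frame.s[left_start:stop]
    right = frame.s[stop + 3 : frame.env1]
    for segment in (left, right):
        pep = translate(segment).replace("*", "X")
        if len(pep) < 3 or local_align(query_seq, pep).score < min_score:
            return False
    return True


def classify_gene(defects: set, length_aa: int) -> str:
    """Deterministic three-way status from the defect set.

    Pseudogene if any ORF-disrupting defect; else partial if any boundary
    defect or short ORF; else functional (> 250 aa).
    """
    if defects & {"premature_stop", "frameshift"}:
        return "pseudogene"
    if defects & {"missing_start", "missing_stop", "too_short"}:
        return "partial"
    if length_aa <= MIN_FUNCTIONAL_AA:
        return "partial"
    return "functional"


def verify_candidate(
    model: ORGeneModel,
    queries: list[SequenceRecord],
    decoys: list[SequenceRecord],
) -> bool:
    """True iff the peptide aligns better to the OR query set than to the
    decoy (non-OR) set; rejected candidates are logged."""
    if not queries:
        raise ValueError("no queries for verification")
    if not model.peptide:
        return False
    best_q = max(local_align(model.peptide, q.seq).score for q in queries)
    best_d = max((local_align(model.peptide, d.seq).score for d in decoys), default=0)
    model.verify_score = best_q
    if best_q <= best_d:
        logger.info(
            "dropping candidate %s: query score %d <= decoy score %d",
            model.id, best_q, best_d,
        )
        return False
    return True


def call_genes(
    loci: list[CandidateLocus],
    genome: list[SequenceRecord],
    queries: list[SequenceRecord],
    decoys: list[SequenceRecord] | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[ORGeneModel]:
    """Full calling stage: build, score defects, classify, verify and
    deduplicate overlapping same-strand models."""
    decoys = decoys or []
    by_chrom = {rec.id: rec for rec in genome}
    query_map = {q.id: q.seq for q in queries}
    models: list[ORGeneModel] = []
    for locus in loci:
        rec = by_chrom.get(locus.chrom)
        if rec is None:
            raise ValueError(f"locus chromosome {locus.chrom!r} not in genome")
        model = build_gene_model(locus, rec, flank)
        model.defects = detect_defects(locus, model, rec, flank, queries=query_map)
        model.status = classify_gene(model.defects, model.length_aa)
        if model.peptide and not verify_candidate(model, queries, decoys):
            continue
        models.append(model)

    models = _dedup_overlapping(models)
    models.sort(key=lambda m: (m.chrom, m.cds_start, m.strand))
    for i, m in enumerate(models, start=1):
        m.id = f"OR{i:04d}"
    return models


def _dedup_overlapping(models: list[ORGeneModel]) -> list[ORGeneModel]:
    """Keep one model per overlapping same-chromosome, same-strand pile:
    higher verify score first, then longer peptide."""
    kept: list[ORGeneModel] = []
    for m in sorted(
        models, key=lambda m: (-m.verify_score, -m.length_aa, m.chrom, m.cds_start)
    ):
        clash = any(
            k.chrom == m.chrom
            and k.strand == m.strand
            and m.cds_start < k.cds_end
            and k.cds_start < m.cds_end
            for k in kept
        )
        if not clash:
            kept.append(m)
    return kept
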