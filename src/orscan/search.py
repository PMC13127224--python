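"""Translated homology search of protein queries against a genome.

The scan is a seed-and-extend heuristic over all six reading frames:
exact 4-mer amino-acid seeds, ungapped X-drop extension, then affine-gap
local rescoring of surviving candidates (BLOSUM62, gap open 11 / extend 1).
Hit significance is the Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)
with the standard gapped BLOSUM62 constants as defaults; the reported hit
set is filtered at ``max_evalue`` (1e-10 by default).

Exhaustive Smith-Waterman over six frames of a multi-megabase genome is
far too slow in pure Python; the exact DP is kept available through
:func:`local_align` (used by the test oracles) and is what rescoring runs
on each candidate window, so reported scores are exact local-alignment
scores of query versus the spanned subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, six_frame_translate

# default Karlin-Altschul statistics for gapped BLOSUM62 11/1
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_CHAIN_GAP = 5_000

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA20)}
_AA_INDEX["X"] = 20
_AA_INDEX["*"] = 21
_N_CODES = 22
_SEED_K = 4


@dataclass
class Hsp:
    """A high-scoring segment pair between a query protein and one
    translated genomic frame; genomic coordinates are 0-based half-open
    on the forward strand and span a whole number of codons."""

    query_id: str
    chrom: str
    q_start: int
    q_end: int
    g_start: int
    g_end: int
    strand: str
    frame: int
    score: int
    evalue: float
    identity: float

    @property
    def aligned_length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class CandidateLocus:
    """A chained genomic locus supported by one or more HSPs on the same
    chromosome and strand; ``best_query`` follows the lowest-E-value,
    then longest-alignment, then lexicographic rule."""

    chrom: str
    strand: str
    g_start: int
    g_end: int
    best_query: str
    hsps: list[Hsp] = field(default_factory=list)
    frames_used: set = field(default_factory=set)


@dataclass
class LocalAlignment:
    score: int
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    identity: float


def make_aligner(mode: str = "local", gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    """BLOSUM62 affine-gap aligner; a gap of length g costs open+(g-1)*extend."""
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("require gap_open >= gap_extend >= 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with affine gaps (BLOSUM62).

    Returns the maximal score (>= 0), the aligned spans in query and
    subject, and the identity fraction over aligned columns. A pair with
    no positive-scoring alignment yields score 0 and empty spans.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = make_aligner("local", gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return LocalAlignment(0, (0, 0), (0, 0), 0.0)
    aln = aligner.align(query, subject)[0]
    qblocks, sblocks = aln.aligned
    q_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    s_span = (int(sblocks[0][0]), int(sblocks[-1][1]))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    return LocalAlignment(int(score), q_span, s_span, identity)


def estimate_evalue(
    score: float,
    m: int,
    n: int,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    if score < 0 or m < 1 or n < 1:
        raise ValueError("require score >= 0 and m, n >= 1")
    return K * m * n * math.exp(-lam * score)


# --- seeding machinery -----------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(c, 20) for c in seq), dtype=np.int64, count=len(seq))


def _blosum_matrix() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((_N_CODES, _N_CODES), dtype=np.int64)
    rev = {v: k for k, v in _AA_INDEX.items()}
    for i in range(_N_CODES):
        for j in range(_N_CODES):
            out[i, j] = mat[rev.get(i, "X"), rev.get(j, "X")]
    return out


_BLOSUM = _blosum_matrix()


def _kmer_codes(codes: np.ndarray, k: int = _SEED_K) -> tuple[np.ndarray, np.ndarray]:
    """Base-22 packed k-mer codes and validity mask (standard residues only)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(len(codes) - k + 1, dtype=np.int64)
    valid = np.ones(len(codes) - k + 1, dtype=bool)
    for off in range(k):
        window = codes[off : len(codes) - k + 1 + off]
        vals = vals * _N_CODES + window
        valid &= window < 20
    return vals, valid


def _ungapped_extend(
    q: np.ndarray, s: np.ndarray, qpos: int, spos: int, k: int, xdrop: int
) -> tuple[int, int, int, int, int]:
    """Extend an exact k-mer seed without gaps, X-drop termination.

    Returns (q_start, q_end, s_start, s_end, score) of the best segment.
    """
    score = int(_BLOSUM[q[qpos : qpos + k], s[spos : spos + k]].sum())
    best = score
    # extend right
    qi, si = qpos + k, spos + k
    best_q_end, best_s_end = qi, si
    run = score
    while qi < len(q) and si < len(s):
        run += int(_BLOSUM[q[qi], s[si]])
        qi += 1
        si += 1
        if run > best:
            best = run
            best_q_end, best_s_end = qi, si
        elif best - run > xdrop:
            break
    # extend left from the seed start
    run = best
    qi, si = qpos, spos
    best_q_start, best_s_start = qpos, spos
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        run += int(_BLOSUM[q[qi], s[si]])
        if run > best:
            best = run
            best_q_start, best_s_start = qi, si
        elif best - run > xdrop:
            break
    return best_q_start, best_q_end, best_s_start, best_s_end, best


def _frame_to_genomic(aa_start: int, aa_end: int, frame: int, chrom_len: int) -> tuple[int, int]:
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    return chrom_len - (off + 3 * aa_end), chrom_len - (off + 3 * aa_start)


def scan_genome(
    queries: list[SequenceRecord],
    genome: list[SequenceRecord],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
    xdrop: int = 20,
    min_ungapped_score: int = 40,
    rescore_pad: int = 40,
) -> list[Hsp]:
    """Six-frame translated search of ``queries`` against ``genome``.

    The search space for E-values is the total translated genome length in
    amino acids over both strands (2 * length/3 summed over records).
    """
    if not queries:
        raise ValueError("no queries")
    if not genome:
        raise ValueError("no genome records")

    search_space = sum(2 * (len(rec.seq) // 3) for rec in genome)

    # seed index over all queries
    q_codes = [_encode(q.seq) for q in queries]
    seed_index: dict[int, list[tuple[int, int]]] = {}
    for qi, codes in enumerate(q_codes):
        vals, valid = _kmer_codes(codes)
        for pos in np.nonzero(valid)[0]:
            seed_index.setdefault(int(vals[pos]), []).append((qi, int(pos)))
    seed_keys = np.fromiter(seed_index.keys(), dtype=np.int64, count=len(seed_index))

    aligner = make_aligner("local")
    hsps: list[Hsp] = []
    seen: set[tuple] = set()

    for rec in genome:
        chrom_len = len(rec.seq)
        frames = six_frame_translate(rec.seq)
        for frame, subject in frames.items():
            if len(subject) < _SEED_K:
                continue
            s_codes = _encode(subject)
            vals, valid = _kmer_codes(s_codes)
            hit_mask = valid & np.isin(vals, seed_keys)
            hit_positions = np.nonzero(hit_mask)[0]
            covered: dict[tuple[int, int], int] = {}  # (query, diag) -> subject end
            for spos in hit_positions:
                spos = int(spos)
                for qi, qpos in seed_index[int(vals[spos])]:
                    diag = spos - qpos
                    if covered.get((qi, diag), -1) > spos:
                        continue
                    qs, qe, ss, se, score = _ungapped_extend(
                        q_codes[qi], s_codes, qpos, spos, _SEED_K, xdrop
                    )
                    covered[(qi, diag)] = se
                    if score < min_ungapped_score:
                        continue
                    # affine-gap rescoring on a padded window
                    win_start = max(0, ss - rescore_pad)
                    win_end = min(len(subject), se + rescore_pad)
                    window = subject[win_start:win_end]
                    query_seq = queries[qi].seq
                    final = aligner.score(query_seq, window)
                    ev = estimate_evalue(final, len(query_seq), search_space, lam, K)
                    if ev > max_evalue:
                        continue
                    aln = local_align(query_seq, window)
                    aa_start = win_start + aln.s_span[0]
                    aa_end = win_start + aln.s_span[1]
                    g_start, g_end = _frame_to_genomic(aa_start, aa_end, frame, chrom_len)
                    key = (queries[qi].id, rec.id, g_start, g_end, frame)
                    if key in seen:
                        continue
                    seen.add(key)
                    hsps.append(
                        Hsp(
                            query_id=queries[qi].id,
                            chrom=rec.id,
                            q_start=aln.q_span[0],
                            q_end=aln.q_span[1],
                            g_start=g_start,
                            g_end=g_end,
                            strand="+" if frame > 0 else "-",
                            frame=frame,
                            score=aln.score,
                            evalue=estimate_evalue(aln.score, len(query_seq), search_space, lam, K),
                            identity=aln.identity,
                        )
                    )

    hsps = [h for h in hsps if h.evalue <= max_evalue]
    hsps.sort(key=lambda h: (h.chrom, h.g_start, h.query_id))
    return hsps


def chain_and_select(hsps: list[Hsp], max_chain_gap: int = DEFAULT_CHAIN_GAP) -> list[CandidateLocus]:
    """Chain same-chromosome, same-strand HSPs whose genomic gap is below
    ``max_chain_gap`` into candidate loci (single-linkage over the interval
    envelope, which equals the transitive closure of the gap relation).

    Loci from different queries covering the same interval merge; the
    locus records its best query by lowest E-value, then longest aligned
    span, then lexicographic query id.
    """
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.chrom, h.strand), []).append(h)

    loci: list[CandidateLocus] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.g_start, h.g_end, h.query_id))
        current: list[Hsp] = []
        current_end = None
        for h in members:
            if current and h.g_start - current_end >= max_chain_gap:
                loci.append(_make_locus(chrom, strand, current))
                current = []
                current_end = None
            current.append(h)
            current_end = h.g_end if current_end is None else max(current_end, h.g_end)
        if current:
            loci.append(_make_locus(chrom, strand, current))
    loci.sort(key=lambda l: (l.chrom, l.g_start, l.strand))
    return loci


def _make_locus(chrom: str, strand: str, members: list[Hsp]) -> CandidateLocus:
    best = min(members, key=lambda h: (h.evalue, -h.aligned_length, h.query_id))
    return CandidateLocus(
        chrom=chrom,
        strand=strand,
        g_start=min(h.g_start for h in members),
        g_end=max(h.g_end for h in members),
        best_query=best.query_id,
        hsps=list(members),
        frames_used={h.frame for h in members},
    )
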