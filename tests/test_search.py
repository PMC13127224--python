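"""Translated search: alignment, E-values, scanning and chaining."""

import math

import numpy as np
import pytest

from orscan.search import (
    Hsp,
    chain_and_select,
    estimate_evalue,
    local_align,
    scan_genome,
)
from orscan.seqio import SequenceRecord, six_frame_translate

from .oracles import interval_closure, sw_affine_score


class TestLocalAlign:
    def test_self_alignment_blosum62_diagonal(self):
        # sum of diagonal entries M5+A4+Y7+D6+R5+Y7+V4+A4+I4+C9
        res = local_align("MAYDRYVAIC", "MAYDRYVAIC")
        assert res.score == 55
        assert res.q_span == (0, 10) and res.s_span == (0, 10)
        assert res.identity == 1.0

    def test_no_positive_pair_scores_zero(self):
        res = local_align("WWWW", "PPPP")
        assert res.score == 0
        assert res.q_span == (0, 0) and res.s_span == (0, 0)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            local_align("", "MK")

    def test_matches_exhaustive_dp_on_random_pairs(self):
        rng = np.random.default_rng(7)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            a = "".join(rng.choice(aa, size=12))
            b = "".join(rng.choice(aa, size=12))
            assert local_align(a, b).score == sw_affine_score(a, b)


class TestEstimateEvalue:
    def test_worked_value(self):
        assert estimate_evalue(40, 300, 10_000) == pytest.approx(2.83, abs=0.01)

    def test_zero_score_limit(self):
        assert estimate_evalue(0, 300, 10_000) == pytest.approx(0.041 * 300 * 10_000)

    def test_monotone_decreasing_in_score(self):
        evs = [estimate_evalue(s, 300, 10_000) for s in range(0, 100, 7)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_invalid_statistics_error(self):
        with pytest.raises(ValueError):
            estimate_evalue(10, 300, 10_000, lam=-1)


def _plant(cds: str, seed: int, length: int = 30_000, pos: int = 12_000) -> str:
    rng = np.random.default_rng(seed)
    bg = "".join(rng.choice(list("ACGT"), size=length))
    return bg[:pos] + cds + bg[pos + len(cds):]


class TestScanGenome:
    @pytest.fixture(scope="class")
    def planted(self):
        from orscan.simulate import make_or_template

        pep, cds = make_or_template("delta", seed=3)
        return pep, cds

    def test_recovers_planted_gene_forward(self, planted):
        pep, cds = planted
        chrom = SequenceRecord("c", _plant(cds, seed=5))
        hits = scan_genome([SequenceRecord("q", pep)], [chrom])
        assert hits
        cover = [h for h in hits if h.g_start < 12_000 + len(cds) and 12_000 < h.g_end]
        assert cover and all(h.strand == "+" for h in cover)

    def test_recovers_planted_gene_reverse(self, planted):
        from orscan.seqio import revcomp

        pep, cds = planted
        chrom = SequenceRecord("c", _plant(revcomp(cds), seed=5))
        hits = scan_genome([SequenceRecord("q", pep)], [chrom])
        cover = [h for h in hits if h.g_start < 12_000 + len(cds) and 12_000 < h.g_end]
        assert cover and all(h.strand == "-" for h in cover)

    def test_random_background_yields_no_hits(self, planted):
        pep, _ = planted
        rng = np.random.default_rng(0)
        chrom = SequenceRecord("c", "".join(rng.choice(list("ACGT"), size=60_000)))
        assert scan_genome([SequenceRecord("q", pep)], [chrom]) == []

    def test_empty_query_set_errors(self):
        with pytest.raises(ValueError, match="no queries"):
            scan_genome([], [SequenceRecord("c", "ACGTACGT")])

    def test_hsp_frame_consistency(self, sim_bundle):
        """Re-translating each reported genomic span in its stated frame
        reproduces a subject consistent with the score and threshold."""
        genome = {rec.id: rec for rec in sim_bundle.genome}
        for h in sim_bundle.hsps[:40]:
            assert h.evalue <= 1e-10
            assert (h.g_end - h.g_start) % 3 == 0
            rec = genome[h.chrom]
            frames = six_frame_translate(rec.seq[h.g_start:h.g_end])
            subject = frames[1] if h.strand == "+" else frames[-1]
            assert len(subject) == (h.g_end - h.g_start) // 3
            query = next(q for q in sim_bundle.queries if q.id == h.query_id)
            assert local_align(query.seq, subject).score >= h.score


def _hsp(chrom, strand, gs, ge, query="q", evalue=1e-20, qs=0, qe=100):
    return Hsp(query, chrom, qs, qe, gs, ge, strand, 1 if strand == "+" else -1,
               500, evalue, 0.9)


class TestChainAndSelect:
    def test_nearby_hsps_chain(self):
        loci = chain_and_select(
            [_hsp("c", "+", 0, 900), _hsp("c", "+", 3900, 4800)], max_chain_gap=5000
        )
        assert len(loci) == 1
        assert (loci[0].g_start, loci[0].g_end) == (0, 4800)

    def test_far_hsps_split_and_strands_separate(self):
        loci = chain_and_select(
            [_hsp("c", "+", 0, 900), _hsp("c", "+", 6000, 6900), _hsp("c", "-", 0, 900)]
        )
        assert len(loci) == 3

    def test_best_query_prefers_longer_alignment_on_tie(self):
        h1 = _hsp("c", "+", 0, 900, query="short", evalue=1e-30, qs=0, qe=250)
        h2 = _hsp("c", "+", 100, 1000, query="long", evalue=1e-30, qs=0, qe=300)
        loci = chain_and_select([h1, h2])
        assert len(loci) == 1
        assert loci[0].best_query == "long"

    def test_lexicographic_tie_break(self):
        h1 = _hsp("c", "+", 0, 900, query="b")
        h2 = _hsp("c", "+", 100, 1000, query="a")
        assert chain_and_select([h1, h2])[0].best_query == "a"

    def test_empty_input(self):
        assert chain_and_select([]) == []

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(2, 15))
            hsps = []
            intervals = []
            for i in range(n):
                gs = int(rng.integers(0, 100_000))
                ge = gs + int(rng.integers(300, 3000)) * 3
                hsps.append(_hsp("c", "+", gs, ge, query=f"q{i}"))
                intervals.append((gs, ge))
            gap = int(rng.integers(500, 10_000))
            loci = chain_and_select(hsps, max_chain_gap=gap)
            expected = interval_closure(intervals, gap)
            got = sorted(
                (sorted(intervals.index((h.g_start, h.g_end)) for h in l.hsps) for l in loci),
                key=lambda g: g[0],
            )
            assert got == [sorted(s) for s in expected]
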