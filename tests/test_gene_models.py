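"""Gene model construction, defect detection and status classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orscan.gene_models import (
    DEFECTS,
    build_gene_model,
    call_genes,
    classify_gene,
    detect_defects,
    verify_candidate,
)
from orscan.search import chain_and_select, scan_genome
from orscan.seqio import SequenceRecord
from orscan.simulate import make_decoys, make_or_template, mutate_peptide


def _chromosome(cds: str, seed: int = 9, flank: int = 3000) -> tuple[SequenceRecord, int]:
    """Plant a CDS in clean random flanks: an in-frame TAA immediately
    upstream guards against fortuitous upstream ATG extension."""
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), size=flank - 3)) + "TAA"
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return SequenceRecord("chrT", left + cds + right), flank


def _locus_for(cds_chrom: SequenceRecord, peptide: str):
    hits = scan_genome([SequenceRecord("q", peptide)], [cds_chrom])
    loci = chain_and_select(hits)
    assert len(loci) == 1
    return loci[0]


@pytest.fixture(scope="module")
def template():
    return make_or_template("delta", seed=21)  # (peptide, cds)


class TestBuildGeneModel:
    def test_intact_gene_exact_coordinates(self, template):
        pep, cds = template
        chrom, offset = _chromosome(cds)
        model = build_gene_model(_locus_for(chrom, pep), chrom)
        assert (model.cds_start, model.cds_end) == (offset, offset + len(cds))
        assert model.peptide == pep
        assert model.defects == set()

    def test_mutated_start_codon_missing_start(self, template):
        pep, cds = template
        chrom, _ = _chromosome("CTG" + cds[3:])
        model = build_gene_model(_locus_for(chrom, pep), chrom)
        assert "missing_start" in model.defects

    def test_truncated_by_contig_edge_missing_stop(self, template):
        pep, cds = template
        rng = np.random.default_rng(9)
        left = "".join(rng.choice(list("ACGT"), size=2997)) + "TAA"
        chrom = SequenceRecord("chrT", left + cds[:-120])  # no stop before end
        model = build_gene_model(_locus_for(chrom, pep), chrom)
        assert "missing_stop" in model.defects

    def test_locus_outside_genome_errors(self, template):
        pep, cds = template
        chrom, _ = _chromosome(cds)
        locus = _locus_for(chrom, pep)
        with pytest.raises(ValueError, match="outside"):
            build_gene_model(locus, SequenceRecord("other", "ACGTACGT"))


class TestDetectDefects:
    def _defects(self, cds, pep, queries=None):
        chrom, _ = _chromosome(cds)
        locus = _locus_for(chrom, pep)
        model = build_gene_model(locus, chrom)
        qmap = {"q": pep} if queries is None else queries
        return detect_defects(locus, model, chrom, queries=qmap), model

    def test_single_nt_insertion_is_frameshift(self, template):
        pep, cds = template
        broken = cds[:450] + "A" + cds[450:]
        defects, _ = self._defects(broken, pep)
        assert "frameshift" in defects

    def test_premature_stop_at_codon_100(self, template):
        pep, cds = template
        broken = cds[:300] + "TGA" + cds[303:]
        defects, _ = self._defects(broken, pep)
        assert "premature_stop" in defects

    def test_intact_short_gene_too_short(self, template):
        pep, _ = template
        short_pep = pep[:200]
        rng = np.random.default_rng(4)
        from orscan.simulate import back_translate

        cds = back_translate(short_pep, rng) + "TAA"
        defects, model = self._defects(cds, short_pep, queries={"q": short_pep})
        assert model.length_aa <= 250
        assert defects == {"too_short"}


class TestClassifyGene:
    @pytest.mark.parametrize(
        "defects,length,expected",
        [
            (set(), 310, "functional"),
            ({"premature_stop", "missing_start"}, 120, "pseudogene"),
            ({"missing_start"}, 280, "partial"),
            ({"frameshift"}, 300, "pseudogene"),
            ({"too_short"}, 200, "partial"),
            ({"missing_stop", "frameshift"}, 150, "pseudogene"),
        ],
    )
    def test_rules_and_precedence(self, defects, length, expected):
        assert classify_gene(defects, length) == expected

    @settings(derandomize=True, max_examples=80)
    @given(
        defects=st.sets(st.sampled_from(DEFECTS)),
        length=st.integers(1, 400),
    )
    def test_total_and_partitioning(self, defects, length):
        status = classify_gene(defects, length)
        assert status in ("functional", "partial", "pseudogene")
        if status == "functional":
            assert not defects and length > 250


class TestVerifyCandidate:
    def test_mutated_query_copy_accepted(self, template):
        pep, _ = template
        rng = np.random.default_rng(2)
        mutated = mutate_peptide(pep, 0.1, rng)
        model = _model_with(mutated)
        assert verify_candidate(model, [SequenceRecord("q", pep)], make_decoys(seed=2))

    def test_decoy_peptide_rejected(self, template):
        pep, _ = template
        decoys = make_decoys(seed=3)
        model = _model_with(decoys[0].seq)
        assert not verify_candidate(model, [SequenceRecord("q", pep)], decoys)

    def test_identical_to_query_accepted(self, template):
        pep, _ = template
        assert verify_candidate(_model_with(pep), [SequenceRecord("q", pep)], [])

    def test_empty_query_set_errors(self, template):
        pep, _ = template
        with pytest.raises(ValueError):
            verify_candidate(_model_with(pep), [], [])


def _model_with(peptide):
    from orscan.gene_models import ORGeneModel

    return ORGeneModel(
        id="m", chrom="c", strand="+", cds_start=0, cds_end=3 * len(peptide),
        peptide=peptide, length_aa=len(peptide),
    )


class TestCallGenes:
    def test_statuses_partition_called_set(self, sim_bundle):
        genes = sim_bundle.genes
        assert genes
        counts = {s: sum(1 for g in genes if g.status == s) for s in ("functional", "partial", "pseudogene")}
        assert sum(counts.values()) == len(genes)

    def test_no_internal_stops_without_premature_defect(self, sim_bundle):
        for g in sim_bundle.genes:
            if "premature_stop" not in g.defects:
                assert "*" not in g.peptide

    def test_models_do_not_overlap_on_same_strand(self, sim_bundle):
        for a, b in itertools.combinations(sim_bundle.genes, 2):
            if a.chrom == b.chrom and a.strand == b.strand:
                assert a.cds_end <= b.cds_start or b.cds_end <= a.cds_start
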