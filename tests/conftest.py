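"""Shared fixtures: a small seeded simulation bundle reused across tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from orscan.gene_models import call_genes
from orscan.search import chain_and_select, scan_genome
from orscan.simulate import (
    SimulationSpec,
    generate_genome,
    make_decoys,
    make_query_set,
    make_reference_set,
)


@dataclass
class SimBundle:
    spec: SimulationSpec
    genome: list
    truth: list
    queries: list
    decoys: list
    references: list
    hsps: list
    loci: list
    genes: list


@pytest.fixture(scope="session")
def sim_bundle() -> SimBundle:
    """A compact planted-truth genome run through search and calling."""
    spec = SimulationSpec(
        n_chromosomes=2,
        chrom_length=300_000,
        n_clusters=3,
        copies_per_cluster=5,
        p_pseudo=0.2,
        p_partial=0.1,
        seed=11,
    )
    genome, truth = generate_genome(spec)
    groups = sorted({t.group_label for t in truth})
    queries = make_query_set(groups, seed=11)
    decoys = make_decoys(seed=11)
    references = make_reference_set(groups, seed=11)
    hsps = scan_genome(queries, genome)
    loci = chain_and_select(hsps)
    genes = call_genes(loci, genome, queries, decoys)
    return SimBundle(spec, genome, truth, queries, decoys, references, hsps, loci, genes)
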