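"""Distances, neighbor joining and OR group assignment."""

import numpy as np
import pytest

from orscan.phylo import (
    DistanceMatrix,
    GroupAssignment,
    assign_groups,
    detect_expansion,
    distance_matrix,
    nj_tree,
    tree_path_distances,
)
from orscan.seqio import SequenceRecord
from orscan.simulate import make_or_template, make_reference_set, mutate_peptide

from .oracles import nw_affine_score


def random_additive_matrix(n_taxa: int, rng) -> DistanceMatrix:
    """Build a random tree bottom-up, tracking exact leaf-leaf distances."""
    labels = [f"t{i}" for i in range(n_taxa)]
    d = {l: {} for l in labels}
    clusters = [[l] for l in labels]
    depth = {l: 0.0 for l in labels}  # distance from leaf to its cluster root
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for a in clusters[i]:
            for b in clusters[j]:
                dist = depth[a] + bi + depth[b] + bj
                d[a][b] = d[b][a] = dist
        for a in clusters[i]:
            depth[a] += bi
        for b in clusters[j]:
            depth[b] += bj
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    mat = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(n_taxa):
            if a != b:
                mat[a, b] = d[labels[a]][labels[b]]
    return DistanceMatrix(labels, mat)


class TestDistanceMatrix:
    def test_identical_sequences_distance_zero(self):
        dm = distance_matrix([SequenceRecord("a", "MKVL"), SequenceRecord("b", "MKVL")])
        assert dm.d[0, 1] == 0.0

    def test_single_substitution_gapless(self):
        dm = distance_matrix([SequenceRecord("a", "AAAA"), SequenceRecord("b", "AAAT")])
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_symmetry_zero_diagonal_range(self):
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        recs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(aa, size=rng.integers(15, 40))))
            for i in range(6)
        ]
        dm = distance_matrix(recs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert np.all((dm.d >= 0) & (dm.d <= 1))

    def test_global_scores_match_dp_oracle(self):
        from orscan.search import make_aligner

        rng = np.random.default_rng(8)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        aligner = make_aligner("global")
        for _ in range(40):
            a = "".join(rng.choice(aa, size=rng.integers(6, 15)))
            b = "".join(rng.choice(aa, size=rng.integers(6, 15)))
            assert int(aligner.score(a, b)) == nw_affine_score(a, b)

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            distance_matrix([SequenceRecord("a", "MK")])


class TestNjTree:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        dm = DistanceMatrix(["A", "B", "C", "D"], d)
        labels, paths = tree_path_distances(nj_tree(dm))
        assert labels == ["A", "B", "C", "D"]
        np.testing.assert_allclose(paths, d, atol=1e-9)

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
        nwk = nj_tree(dm)
        labels, paths = tree_path_distances(nwk)
        np.testing.assert_allclose(paths, dm.d, atol=1e-9)

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            dm = random_additive_matrix(n, rng)
            labels, paths = tree_path_distances(nj_tree(dm))
            order = [dm.labels.index(l) for l in labels]
            np.testing.assert_allclose(paths, dm.d[np.ix_(order, order)], atol=1e-8)

    def test_agrees_with_skbio_on_additive_input(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(31)
        dm = random_additive_matrix(6, rng)
        labels, ours = tree_path_distances(nj_tree(dm))
        sk_tree = skbio_nj(SkbioDM(dm.d, ids=dm.labels))
        sk = sk_tree.tip_tip_distances(labels)
        np.testing.assert_allclose(ours, np.asarray(sk.data), atol=1e-8)

    def test_too_few_taxa_errors(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


class TestAssignGroups:
    @pytest.fixture(scope="class")
    def refs(self):
        return make_reference_set(["beta", "delta", "eta", "zeta"], seed=6)

    def test_mutated_delta_copy_assigned_delta_type_I(self, refs):
        pep, _ = make_or_template("delta", seed=6)
        gene = SequenceRecord("g", mutate_peptide(pep, 0.05, np.random.default_rng(1)))
        a = assign_groups([gene], refs)
        assert a.groups["g"] == "delta"
        assert a.types["g"] == "I"

    def test_identical_to_eta_reference(self, refs):
        eta_ref = next(r for r in refs if r.id.startswith("ref_eta"))
        gene = SequenceRecord("g", eta_ref.seq)
        a = assign_groups([gene], refs)
        assert a.groups["g"] == "eta"
        assert a.types["g"] == "II"
        assert a.support["g"] == 0.0

    def test_group_type_mapping(self, refs):
        from orscan.phylo import GROUP_TO_TYPE

        assert GROUP_TO_TYPE["zeta"] == "I"
        assert GROUP_TO_TYPE["kappa"] == "II"
        assert GROUP_TO_TYPE["theta"] == "non-OR"

    def test_reference_order_invariance(self, refs):
        pep, _ = make_or_template("zeta", seed=6)
        gene = SequenceRecord("g", mutate_peptide(pep, 0.08, np.random.default_rng(2)))
        a1 = assign_groups([gene], refs)
        a2 = assign_groups([gene], list(reversed(refs)))
        assert a1.groups == a2.groups

    def test_accuracy_on_diverged_copies(self, refs):
        """>= 95% correct at up to 10% divergence from the group template."""
        rng = np.random.default_rng(3)
        genes, truth = [], {}
        for g in ("beta", "delta", "eta", "zeta"):
            pep, _ = make_or_template(g, seed=6)
            for i in range(10):
                gid = f"{g}_{i}"
                genes.append(SequenceRecord(gid, mutate_peptide(pep, 0.10, rng)))
                truth[gid] = g
        a = assign_groups(genes, refs)
        acc = np.mean([a.groups[gid] == truth[gid] for gid in truth])
        assert acc >= 0.95

    def test_tree_mode_matches_truth(self, refs):
        rng = np.random.default_rng(4)
        genes, truth = [], {}
        for g in ("delta", "eta"):
            pep, _ = make_or_template(g, seed=6)
            for i in range(4):
                gid = f"{g}_{i}"
                genes.append(SequenceRecord(gid, mutate_peptide(pep, 0.05, rng)))
                truth[gid] = g
        a = assign_groups(genes, refs, mode="tree")
        assert all(a.groups[gid] == truth[gid] for gid in truth)

    def test_no_references_errors(self):
        with pytest.raises(ValueError):
            assign_groups([SequenceRecord("g", "MKV")], [])


class TestDetectExpansion:
    def test_fivefold_delta_flagged(self):
        a = GroupAssignment({f"g{i}": "delta" for i in range(50)}, {}, {})
        out = detect_expansion(a, {"delta": [10, 10, 10]})
        assert out["delta"] == {"fold": 5.0, "expanded": True}

    def test_parity_not_flagged(self):
        a = GroupAssignment({f"g{i}": "gamma" for i in range(3)}, {}, {})
        out = detect_expansion(a, {"gamma": [3, 3]})
        assert out["gamma"]["fold"] == pytest.approx(1.0)
        assert not out["gamma"]["expanded"]

    def test_planted_fourfold_duplication_only_delta_flagged(self):
        groups = {f"d{i}": "delta" for i in range(40)}
        groups.update({f"z{i}": "zeta" for i in range(9)})
        a = GroupAssignment(groups, {}, {})
        ref = {"delta": [10, 10], "zeta": [10, 10]}
        out = detect_expansion(a, ref)
        assert out["delta"]["expanded"] and not out["zeta"]["expanded"]

    def test_empty_assignment_errors(self):
        with pytest.raises(ValueError):
            detect_expansion(GroupAssignment({}, {}, {}), {})
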