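"""Distance-based phylogeny and OR group classification.

Fish OR repertoires split into two types spanning seven groups: type I
(beta, gamma, delta, epsilon, zeta), which detect water-soluble odorants,
and type II (eta, kappa). Genes are classified by similarity to labelled
reference OR proteins: pairwise global affine-gap alignments (BLOSUM62,
11/1) give an identity-based distance, from which either the nearest
reference or the smallest containing clade of a neighbor-joining tree
assigns the group. Group labels theta and lambda are accepted on
references but reported as non-OR.

The tree is classic neighbor joining (Q-matrix pair selection,
Saitou-Nei branch lengths, negative branches clamped to zero) with
deterministic label-order tie-breaking, exported as newick so an
externally built tree can be substituted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .search import make_aligner
from .seqio import SequenceRecord

TYPE_I = ("beta", "gamma", "delta", "epsilon", "zeta")
TYPE_II = ("eta", "kappa")
NON_OR = ("theta", "lambda")
ALL_GROUPS = TYPE_I + TYPE_II + NON_OR

GROUP_TO_TYPE = {g: "I" for g in TYPE_I}
GROUP_TO_TYPE.update({g: "II" for g in TYPE_II})
GROUP_TO_TYPE.update({g: "non-OR" for g in NON_OR})


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal not zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass
class GroupAssignment:
    groups: dict  # gene_id -> group
    types: dict  # gene_id -> I / II / non-OR
    support: dict  # gene_id -> nearest-reference distance


def parse_group_label(header: str) -> str | None:
    """Extract a group tag of the form ``...|group=delta`` from an id or
    description; returns None when absent."""
    for token in header.replace("|", " ").split():
        if token.startswith("group="):
            group = token[len("group="):].lower()
            if group not in ALL_GROUPS:
                raise ValueError(f"unknown OR group label {group!r}")
            return group
    return None


def distance_matrix(peptides: list[SequenceRecord]) -> DistanceMatrix:
    """Pairwise global-alignment distances: 1 - identities / aligned
    columns (gap-gap columns cannot occur in a pairwise alignment)."""
    if len(peptides) < 2:
        raise ValueError("need at least 2 peptides")
    aligner = make_aligner("global")
    n = len(peptides)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(peptides[i].seq, peptides[j].seq)[0]
            counts = aln.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            dist = 1.0 - counts.identities / columns if columns else 1.0
            d[i, j] = d[j, i] = dist
    return DistanceMatrix([p.id for p in peptides], d)


# --- neighbor joining ------------------------------------------------------


class _Node:
    __slots__ = ("label", "children", "min_leaf")

    def __init__(self, label=None, children=None, min_leaf=None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)
        self.min_leaf = min_leaf if min_leaf is not None else label

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string.

    Exact on additive matrices; ties in the Q matrix break on the
    lexicographically smallest pair of subtree labels. The final three
    nodes join at an unrooted trifurcation using the three-point formulas.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [_Node(label=l) for l in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((nodes[i].min_leaf, nodes[j].min_leaf)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        parent = _Node(
            children=[(nodes[i], li), (nodes[j], lj)],
            min_leaf=min(nodes[i].min_leaf, nodes[j].min_leaf),
        )
        # reuse slot i for the new node; retire j
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    li = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = _Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return root.newick() + ";"


def tree_path_distances(newick: str) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix of a newick tree (testing aid)."""
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = [t.name for t in tips]
    dm = tree.tip_tip_distances([t.name for t in tips])
    return labels, np.asarray(dm.data)


# --- group assignment ------------------------------------------------------


def _reference_groups(references: list[SequenceRecord]) -> dict[str, str]:
    out = {}
    for ref in references:
        group = parse_group_label(ref.id) or parse_group_label(ref.meta or "")
        if group is None:
            raise ValueError(f"reference {ref.id!r} carries no group=<label> tag")
        out[ref.id] = group
    return out


def assign_groups(
    genes: list[SequenceRecord],
    references: list[SequenceRecord],
    mode: str = "nearest",
) -> GroupAssignment:
    """Assign each gene to an OR group using labelled references.

    ``nearest`` (default): the group of the closest reference by
    alignment distance; exact ties resolve to the alphabetically first
    group. ``tree``: the group of the smallest NJ clade containing the
    gene and at least one reference, falling back to nearest-reference
    when that clade mixes groups.
    """
    if not references:
        raise ValueError("no references")
    if not genes:
        return GroupAssignment({}, {}, {})
    ref_groups = _reference_groups(references)

    combined = list(genes) + list(references)
    dm = distance_matrix(combined)
    n_genes = len(genes)
    gene_ids = [g.id for g in genes]
    ref_ids = [r.id for r in references]
    sub = dm.d[:n_genes, n_genes:]

    groups, types, support = {}, {}, {}
    nearest: dict[str, str] = {}
    for gi, gid in enumerate(gene_ids):
        row = sub[gi]
        dmin = row.min()
        candidates = sorted(
            ref_groups[ref_ids[ri]] for ri in np.nonzero(row == dmin)[0]
        )
        nearest[gid] = candidates[0]
        support[gid] = float(dmin)

    if mode == "nearest":
        groups = dict(nearest)
    elif mode == "tree":
        from skbio import TreeNode

        newick = nj_tree(dm)
        tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
        ref_set = set(ref_ids)
        for gid in gene_ids:
            tip = tree.find(gid)
            assigned = None
            node = tip.parent
            while node is not None:
                tip_names = {t.name for t in node.tips()}
                clade_refs = tip_names & ref_set
                if clade_refs:
                    clade_groups = {ref_groups[r] for r in clade_refs}
                    assigned = (
                        clade_groups.pop() if len(clade_groups) == 1 else nearest[gid]
                    )
                    break
                node = node.parent
            groups[gid] = assigned if assigned is not None else nearest[gid]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    types = {gid: GROUP_TO_TYPE[g] for gid, g in groups.items()}
    return GroupAssignment(groups, types, support)


def detect_expansion(
    assignment: GroupAssignment,
    reference_counts: dict[str, list[int]],
    fold_threshold: float = 2.0,
) -> dict[str, dict]:
    """Flag group expansions relative to reference species.

    fold = focal group count / mean per-species reference count, with the
    denominator floored at one gene (pseudo-count) so empty reference
    groups do not blow up. ``expanded`` when fold >= ``fold_threshold``.
    """
    if not assignment.groups:
        raise ValueError("empty assignment")
    focal: dict[str, int] = {}
    for g in assignment.groups.values():
        focal[g] = focal.get(g, 0) + 1
    out = {}
    for group in sorted(set(focal) | set(reference_counts)):
        counts = reference_counts.get(group, [])
        denom = max(1.0, float(np.mean(counts)) if counts else 0.0)
        fold = focal.get(group, 0) / denom
        out[group] = {"fold": float(fold), "expanded": fold >= fold_threshold}
    return out


def write_groups(assignment: GroupAssignment, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tgroup\ttype\tsupport\n")
        for gid in sorted(assignment.groups):
            fh.write(
                f"{gid}\t{assignment.groups[gid]}\t{assignment.types[gid]}\t"
                f"{assignment.support[gid]:.6f}\n"
            )


def write_expansion(expansion: dict[str, dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group\tfold\texpanded\n")
        for group in sorted(expansion):
            e = expansion[group]
            fh.write(f"{group}\t{e['fold']:.4f}\t{e['expanded']}\n")
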