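"""Tree comparison and distance-based tree building.

The congruence question this module answers: does a tree built from one
fast-evolving gene reproduce the topology of the whole-plastome tree?
Agreement is quantified by the Robinson–Foulds (RF) distance — the number
of non-trivial bipartitions (internal edges) present in exactly one of the
two trees — normalized by its maximum over unrooted binary trees with the
same n leaves, 2(n−3), giving a value in [0, 1].

Trees are handled as unrooted leaf-labelled topologies; branch lengths are
accepted on input and ignored for RF.  Tree construction is Saitou–Nei
neighbour joining on p-distances, a fast distance-based stand-in for
likelihood inference that is exact on additive distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeTopology",
    "parse_newick",
    "RFResult",
    "rf_distance",
    "p_distance_matrix",
    "nj_tree",
    "CongruenceResult",
    "congruence_experiment",
]

Bipartition = frozenset  # frozenset({frozenset(side1), frozenset(side2)})


@dataclass(frozen=True)
class TreeTopology:
    """Unrooted leaf-labelled tree, held as its newick string plus the
    derived bipartition set (one per internal edge, trivial splits
    excluded)."""

    newick: str
    leaves: frozenset[str]
    splits: frozenset[Bipartition]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )


def parse_newick(text: str) -> TreeTopology:
    """Parse a newick string into an unrooted topology.

    Branch lengths are accepted (and kept in the stored newick) but play
    no role in comparisons; a degree-2 root is suppressed.  Duplicate leaf
    labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise ValueError("malformed newick: unlabeled leaf")
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return _from_dendropy(tree)


def _from_dendropy(tree: dendropy.Tree) -> TreeTopology:
    tree.collapse_basal_bifurcation()
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits: set[Bipartition] = set()
    seed = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is seed or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        above = leaves - below
        if len(below) >= 2 and len(above) >= 2:
            splits.add(frozenset({below, above}))
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return TreeTopology(newick=newick, leaves=leaves, splits=frozenset(splits))


def bipartitions(t: TreeTopology) -> frozenset[Bipartition]:
    """Non-trivial bipartitions of the topology (one per internal edge)."""
    if t.n_leaves < 4:
        raise ValueError("bipartitions need ≥ 4 leaves")
    return t.splits


@dataclass(frozen=True)
class RFResult:
    """Robinson–Foulds comparison of two trees on the same leaf set."""

    rf: int
    max_rf: int
    normalized: float
    n_leaves: int
    #: normalization constant convention: 2(n−3), the maximum RF between
    #: unrooted *binary* trees; conservative for multifurcating input.
    convention: str = "2(n-3)"


def rf_distance(t1: TreeTopology, t2: TreeTopology) -> RFResult:
    """RF distance |B1 Δ B2| and its 2(n−3)-normalized form."""
    if t1.leaves != t2.leaves:
        only1 = sorted(t1.leaves - t2.leaves)
        only2 = sorted(t2.leaves - t1.leaves)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    rf = len(t1.splits ^ t2.splits)
    n = t1.n_leaves
    max_rf = 2 * (n - 3)
    normalized = rf / max_rf if max_rf > 0 else 0.0
    return RFResult(rf=rf, max_rf=max_rf, normalized=normalized, n_leaves=n)


# ---------------------------------------------------------------------------
# distances and neighbour joining
# ---------------------------------------------------------------------------

def p_distance_matrix(
    alignment: Mapping[str, str] | Sequence,
) -> pd.DataFrame:
    """Pairwise proportion of differing sites (pairwise deletion of
    positions where either sequence has N or a gap)."""
    if isinstance(alignment, Mapping):
        items = list(alignment.items())
    else:
        items = [(r.id, r.sequence) for r in alignment]
    if len(items) < 3:
        raise ValueError("need ≥ 3 sequences")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")
    names = [n for n, _ in items]
    arr = np.frombuffer(
        "".join(s for _, s in items).encode(), dtype="S1"
    ).reshape(len(items), -1)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = both.sum()
            if m == 0:
                raise ValueError(f"no comparable sites between {names[i]} and {names[j]}")
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            d[i, j] = d[j, i] = p
    return pd.DataFrame(d, index=names, columns=names)


def nj_tree(dist: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> TreeTopology:
    """Saitou–Nei neighbour joining on a symmetric distance matrix.

    Deterministic: the joined pair minimizing Q is the lowest-index pair
    among ties.  Metricity is not required, but negative off-diagonal
    entries are rejected.  Exactly inverts additive (tree-realizable)
    distances.
    """
    if isinstance(dist, pd.DataFrame):
        labels = [str(l) for l in dist.index]
        mat = dist.to_numpy(dtype=float)
    else:
        mat = np.asarray(dist, dtype=float)
        labels = [str(l) for l in labels] if labels is not None else [
            f"t{i}" for i in range(len(mat))
        ]
    n = len(labels)
    if n < 4:
        raise ValueError("neighbour joining needs ≥ 4 taxa")
    if mat.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    off = mat[~np.eye(n, dtype=bool)]
    if np.any(off < 0):
        raise ValueError("negative off-diagonal distances")
    nodes = [_quote(l) for l in labels]
    D = mat.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin over row-major flattened Q
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        new_label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_row = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_new[-1, : m - 2] = D_new[: m - 2, -1] = new_row[keep]
        D_new[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new_label]
        D = D_new
    # three remaining nodes join at a single internal vertex
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max((d01 + d02 - d12) / 2, 0.0)
    l1 = max((d01 + d12 - d02) / 2, 0.0)
    l2 = max((d02 + d12 - d01) / 2, 0.0)
    newick = f"({nodes[0]}:{l0:.10g},{nodes[1]}:{l1:.10g},{nodes[2]}:{l2:.10g});"
    return parse_newick(newick)


def _quote(label: str) -> str:
    if any(c in label for c in "():,; \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# congruence experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CongruenceResult:
    """Gene-tree vs genome-tree comparison (and each vs truth if known)."""

    genome_tree: TreeTopology
    gene_tree: TreeTopology
    gene_vs_genome: RFResult
    genome_vs_true: RFResult | None = None
    gene_vs_true: RFResult | None = None


def congruence_experiment(
    genome_aln: Mapping[str, str] | Sequence,
    gene_aln: Mapping[str, str] | Sequence,
    true_tree: TreeTopology | None = None,
) -> CongruenceResult:
    """Build NJ trees from two alignments of the same taxa and compare.

    Mirrors the whole-plastome vs single-gene marker design: the gene
    alignment is typically a small subset of the genome's sites, and the
    normalized RF between the two trees measures how much topology the
    single marker recovers.
    """
    genome_tree = nj_tree(p_distance_matrix(genome_aln))
    gene_tree = nj_tree(p_distance_matrix(gene_aln))
    result = rf_distance(gene_tree, genome_tree)
    vs_true_genome = vs_true_gene = None
    if true_tree is not None:
        vs_true_genome = rf_distance(genome_tree, true_tree)
        vs_true_gene = rf_distance(gene_tree, true_tree)
    return CongruenceResult(
        genome_tree=genome_tree,
        gene_tree=gene_tree,
        gene_vs_genome=result,
        genome_vs_true=vs_true_genome,
        gene_vs_true=vs_true_gene,
    )
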