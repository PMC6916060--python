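"""Distance trees and dated species trees.

Gene trees are built with the Saitou-Nei neighbor-joining algorithm on
Poisson-corrected protein distances, the standard pairing for quick OR
repertoire phylogenetics.  Species trees are rooted, dated (node ages in
million years, tips at 0) and supply the branch durations T used by the
gain/loss rate estimator.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .align import p_distance

POISSON_INF = 1e6  # sentinel for p -> 1 (saturated distance)


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p) between two proteins.

    p is the fraction of differing residues over gap-free aligned columns
    of the best global alignment.  p = 1 maps to a large finite sentinel so
    downstream clustering stays well defined.
    """
    p = p_distance(a, b)
    if p >= 1.0:
        return POISSON_INF
    return -math.log(1.0 - p)


def poisson_from_p(p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p out of range: {p}")
    return POISSON_INF if p >= 1.0 else -math.log(1.0 - p)


def distance_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """All-vs-all Poisson distance matrix, labels in sorted order."""
    labels = sorted(seqs)
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = poisson_distance(seqs[labels[i]], seqs[labels[j]])
    return labels, dm


def neighbor_joining(labels: list[str], dm: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei NJ with a deterministic lowest-index tie-break.

    Returns an unrooted dendropy tree (trifurcating root for n >= 3).
    """
    n = len(labels)
    if dm.shape != (n, n):
        raise ValueError("matrix/label size mismatch")
    if not np.allclose(dm, dm.T) or np.any(np.diag(dm) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    if n == 1:
        return dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    if n == 2:
        root = dendropy.Node()
        for nd in nodes:
            nd.edge.length = dm[0, 1] / 2.0
            root.add_child(nd)
        return dendropy.Tree(taxon_namespace=taxa, seed_node=root)

    D = dm.astype(float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima
        flat = np.argwhere(np.isclose(q, q.min(), rtol=0, atol=1e-12))
        i_s, j_s = min((min(a, b), max(a, b)) for a, b in flat)
        i, j = active[i_s], active[j_s]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # new node reuses slot i
        dnew = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = dnew
        D[active, i] = dnew
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    i, j = active
    root = dendropy.Node()
    half = D[i, j] / 2.0
    for k in (i, j):
        nodes[k].edge.length = D[i, j] - half if k == j else half
        root.add_child(nodes[k])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def nj_from_sequences(seqs: dict[str, str]) -> dendropy.Tree:
    labels, dm = distance_matrix(seqs)
    return neighbor_joining(labels, dm)


# ---------------------------------------------------------------------------
# bootstrap support on NJ trees built from a columnar alignment
# ---------------------------------------------------------------------------

def _p_matrix_from_columns(rows: dict[str, str], labels: list[str]) -> np.ndarray:
    arr = np.array([list(rows[lab]) for lab in labels])
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            ok = (a != "-") & (b != "-")
            tot = int(ok.sum())
            p = float((a[ok] != b[ok]).sum()) / tot if tot else 1.0
            dm[i, j] = dm[j, i] = poisson_from_p(min(p, 1.0))
    return dm


def nj_from_alignment(rows: dict[str, str]) -> dendropy.Tree:
    labels = sorted(rows)
    return neighbor_joining(labels, _p_matrix_from_columns(rows, labels))


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an (un)rooted tree, each as the smaller-side
    leaf set (by sorted-label tuple for determinism)."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return out


def bootstrap_support(rows: dict[str, str], replicates: int, seed: int) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree from a columnar alignment plus bootstrap split supports.

    Columns are resampled with replacement; support is the percentage of
    replicates whose NJ tree contains each split of the full-data tree.
    ``replicates == 0`` flags every support as NaN.
    """
    labels = sorted(rows)
    ncol = len(next(iter(rows.values())))
    if ncol < 2:
        raise ValueError("alignment must have at least 2 columns")
    if any(len(v) != ncol for v in rows.values()):
        raise ValueError("ragged alignment")
    tree = nj_from_alignment(rows)
    splits = bipartitions(tree)
    if replicates == 0:
        return tree, {s: float("nan") for s in splits}
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in splits}
    arr = {lab: np.frombuffer(rows[lab].encode(), dtype="S1") for lab in labels}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        boot = {lab: arr[lab][cols].tobytes().decode() for lab in labels}
        rep_splits = bipartitions(nj_from_alignment(boot))
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        key = min(side, all_taxa - side, key=lambda s: tuple(sorted(s)))
        if key in support:
            nd.label = f"{support[key]:.0f}"
    return tree, support


# ---------------------------------------------------------------------------
# dated species tree
# ---------------------------------------------------------------------------

@dataclass
class DatedSpeciesTree:
    """Rooted species tree with node ages in million years (tips at 0).

    Internal-node Newick labels are read as ages; alternatively a
    node->age mapping (keyed by the sorted tuple of descendant tips) can
    be supplied.  Branch duration T = parent age - child age.
    """

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str, ages: dict | None = None) -> "DatedSpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, rooting="force-rooted",
        )
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                nd.age_my = 0.0
                continue
            key = tuple(sorted(lf.taxon.label for lf in nd.leaf_iter()))
            if ages is not None and key in ages:
                nd.age_my = float(ages[key])
            elif nd.label is not None:
                nd.age_my = float(nd.label)
            else:
                raise ValueError(f"no age for internal node over {key[:3]}...")
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.parent_node.age_my <= nd.age_my:
                raise ValueError("parent age must exceed child age")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "DatedSpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        t = self.tree.clone(depth=1)
        for nd in t.preorder_node_iter():
            if not nd.is_leaf():
                nd.label = f"{nd.age_my:g}"
            if nd.parent_node is not None:
                nd.edge.length = nd.parent_node.age_my - nd.age_my
        s = io.StringIO()
        t.write(file=s, schema="newick", suppress_rooting=True, unquoted_underscores=True)
        return s.getvalue().strip()

    @property
    def taxa(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def branch_duration(self, node) -> float:
        return node.parent_node.age_my - node.age_my

    def node_key(self, node) -> str:
        """Stable branch/node identifier: the tip label, or
        mrca(first,last,n=size) over the clade's sorted leaf set (first,
        last and size identify a clade uniquely within one tree)."""
        if node.is_leaf():
            return node.taxon.label
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        return f"mrca({leaves[0]},{leaves[-1]},n={len(leaves)})"
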