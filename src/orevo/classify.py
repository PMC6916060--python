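"""Class I/II assignment and orthologous gene group (OGG) clustering.

Intact OR proteins are clustered with Markov clustering (MCL) on a
normalized alignment-score graph; clusters with at least two members
become OGGs.  Leftover singletons are re-examined on a bootstrapped NJ
tree (non-OR GPCRs as outgroups): maximal all-singleton clades with
support above the merge floor become additional OGGs, the rest stay
single-gene OGGs.  Pseudogenes and truncated genes are then attached to
the OGG of their best-scoring intact hit.  OGGs are named OGG1-k /
OGG2-k by class and descending intact-member count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import global_alignment, kmer_jaccard, kmer_set, local_score
from .trees import bootstrap_support, nj_from_sequences, poisson_from_p

logger = logging.getLogger(__name__)

DEFAULTS = {
    "mcl_inflation": 1.5,
    "mcl_expansion": 2,
    "edge_floor": 0.35,     # min normalized score for a graph edge
    "kmer_prefilter": 0.02,  # min 4-mer Jaccard before aligning a pair
    "support_floor": 70,    # bootstrap > floor merges singletons
    "class_support": 90,    # clade support used for class assignment trees
    "bootstrap_replicates": 1000,
}


@dataclass
class OGG:
    """An orthologous gene group."""

    name: str = ""
    class_label: str = ""
    intact: dict[str, list[str]] = field(default_factory=dict)  # species -> gene ids
    nonintact: dict[str, list[str]] = field(default_factory=dict)
    mean_similarity: float = float("nan")

    @property
    def intact_ids(self) -> list[str]:
        return sorted(itertools.chain.from_iterable(self.intact.values()))

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.intact.values())


# ---------------------------------------------------------------------------
# distances and similarity
# ---------------------------------------------------------------------------

def quick_p_distance(a: str, b: str) -> float:
    """p-distance; equal-length pairs compare positionally (exact for the
    ungapped full-length proteins this package works with), others through
    a global alignment."""
    if len(a) == len(b) and a:
        return sum(x != y for x, y in zip(a, b)) / len(a)
    from .align import p_distance
    return p_distance(a, b)


def pair_identity(a: str, b: str) -> float:
    return 1.0 - quick_p_distance(a, b)


def ogg_mean_similarity(seqs: list[str], max_pairs: int = 200) -> float:
    """Mean pairwise identity over members (first ``max_pairs`` pairs in
    deterministic order for very large groups)."""
    if len(seqs) < 2:
        return float("nan")
    pairs = list(itertools.islice(itertools.combinations(seqs, 2), max_pairs))
    return float(np.mean([pair_identity(a, b) for a, b in pairs]))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def markov_cluster(adj: np.ndarray, inflation: float = 1.5, expansion: int = 2,
                   max_iter: int = 200, tol: float = 1e-8, prune: float = 1e-6
                   ) -> list[set[int]]:
    """MCL flow simulation on a non-negative symmetric adjacency matrix.

    Returns clusters as sets of node indices (covering all nodes)."""
    n = adj.shape[0]
    if n == 0:
        return []
    M = adj.astype(float).copy()
    np.fill_diagonal(M, np.maximum(M.diagonal(), M.max(axis=0) if n > 1 else 1.0))
    np.fill_diagonal(M, np.where(M.diagonal() > 0, M.diagonal(), 1.0))
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M.copy()
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            break
    # connected components of the limit flow graph
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(M > prune)):
        if i != j:
            g.add_edge(int(i), int(j))
    return [set(c) for c in nx.connected_components(g)]


def cluster_oggs(proteins: dict[str, str], inflation: float | None = None,
                 edge_floor: float | None = None, kmer_prefilter: float | None = None
                 ) -> tuple[list[list[str]], list[str]]:
    """MCL on the normalized local-alignment score graph of intact proteins.

    Returns (clusters of size >= 2, leftover singleton gene ids); the two
    together cover the input exactly once, independent of input order.
    """
    cfg = DEFAULTS
    inflation = cfg["mcl_inflation"] if inflation is None else inflation
    edge_floor = cfg["edge_floor"] if edge_floor is None else edge_floor
    kmer_prefilter = cfg["kmer_prefilter"] if kmer_prefilter is None else kmer_prefilter
    ids = sorted(proteins)
    n = len(ids)
    if n == 0:
        return [], []
    kmers = {i: kmer_set(proteins[i], 4) for i in ids}
    self_score = {i: local_score(proteins[i], proteins[i]) for i in ids}
    adj = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = ids[a], ids[b]
            if kmer_jaccard(kmers[ia], kmers[ib]) < kmer_prefilter:
                continue
            score = local_score(proteins[ia], proteins[ib])
            norm = score / min(self_score[ia], self_score[ib])
            if norm >= edge_floor:
                adj[a, b] = adj[b, a] = norm
    comps = markov_cluster(adj, inflation=inflation)
    clusters, singletons = [], []
    for comp in sorted(comps, key=lambda c: sorted(ids[i] for i in c)):
        members = sorted(ids[i] for i in comp)
        if len(members) >= 2:
            clusters.append(members)
        else:
            singletons.extend(members)
    return clusters, sorted(singletons)


# ---------------------------------------------------------------------------
# star alignment (columnar rows for bootstrap trees)
# ---------------------------------------------------------------------------

def star_alignment(seqs: dict[str, str]) -> dict[str, str]:
    """Project every sequence onto the coordinates of the longest member
    via pairwise global alignments (insertions relative to the reference
    are dropped).  Adequate for column-resampling over near-full-length
    sequences; not a full progressive MSA."""
    ref_id = max(seqs, key=lambda k: (len(seqs[k]), k))
    ref = seqs[ref_id]
    rows = {}
    for sid, seq in seqs.items():
        if sid == ref_id:
            rows[sid] = ref
            continue
        aln = global_alignment(ref, seq)
        row = ["-"] * len(ref)
        for (rs, re_), (cs, ce) in zip(*aln.aligned):
            for k in range(re_ - rs):
                row[rs + k] = seq[cs + k]
        rows[sid] = "".join(row)
    return rows


# ---------------------------------------------------------------------------
# class assignment
# ---------------------------------------------------------------------------

def assign_class(genes: dict[str, str], anchors: dict[str, tuple[str, str]]) -> dict[str, str]:
    """Label each gene Class I or II by the anchor it joins on an NJ tree
    over genes + labeled anchor references.

    Membership is decided by patristic (tree-path) distance to the nearest
    anchor, which is invariant to root placement; with too few sequences
    for a tree the nearest anchor by sequence distance decides instead.
    """
    if not anchors:
        raise ValueError("class anchors required")
    if not genes:
        return {}
    seqs = {**{f"g|{k}": v for k, v in genes.items()},
            **{f"a|{k}": seq for k, (seq, _cls) in anchors.items()}}
    anchor_class = {f"a|{k}": cls for k, (_seq, cls) in anchors.items()}
    out: dict[str, str] = {}
    if len(seqs) >= 4:
        tree = nj_from_sequences(seqs)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for gid in genes:
            best = min(sorted(anchor_class),
                       key=lambda a: pdm.patristic_distance(taxa[f"g|{gid}"], taxa[a]))
            out[gid] = anchor_class[best]
    else:
        logger.info("too few sequences for a tree; using sequence-distance anchors")
        for gid in genes:
            out[gid] = _nearest_anchor_class(genes[gid], anchors)
    return out


def _nearest_anchor_class(seq: str, anchors: dict[str, tuple[str, str]]) -> str:
    best = min(sorted(anchors), key=lambda k: quick_p_distance(seq, anchors[k][0]))
    return anchors[best][1]


# ---------------------------------------------------------------------------
# singleton placement
# ---------------------------------------------------------------------------

def place_singletons(singletons: dict[str, str], outgroup_gpcrs: dict[str, str],
                     support_floor: float = 70, replicates: int = 100, seed: int = 0
                     ) -> tuple[list[list[str]], list[str]]:
    """Merge singleton genes that form well-supported clades.

    A maximal clade consisting only of singletons with bootstrap support
    strictly greater than ``support_floor`` becomes a new OGG; everything
    else stays a single-gene OGG.
    """
    if len(singletons) < 2:
        return [], sorted(singletons)
    seqs = {**{f"s|{k}": v for k, v in singletons.items()},
            **{f"o|{k}": v for k, v in outgroup_gpcrs.items()}}
    if len(seqs) < 4:
        return [], sorted(singletons)
    rows = star_alignment(seqs)
    tree, support = bootstrap_support(rows, replicates, seed)
    if outgroup_gpcrs:
        og = tree.find_node_with_taxon_label(sorted(f"o|{k}" for k in outgroup_gpcrs)[0])
        tree.reroot_at_edge(og.edge, update_bipartitions=False)
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    merged: list[list[str]] = []
    used: set[str] = set()

    def support_of(node) -> float:
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = min(side, all_taxa - side, key=lambda s: tuple(sorted(s)))
        return support.get(key, float("nan"))

    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if any(not l.startswith("s|") for l in leaves):
            continue
        if any(l[2:] in used for l in leaves):
            continue
        sup = support_of(node)
        if len(leaves) >= 2 and sup > support_floor:
            members = sorted(l[2:] for l in leaves)
            merged.append(members)
            used.update(members)
    rest = sorted(set(singletons) - used)
    return merged, rest


# ---------------------------------------------------------------------------
# non-intact assignment and naming
# ---------------------------------------------------------------------------

def assign_nonintact(nonintact: dict[str, str], intact_ogg: dict[str, tuple[str, str]],
                     min_norm_score: float = 0.2, top_k: int = 25
                     ) -> tuple[dict[str, str], list[str]]:
    """Assign each pseudogene/truncated fragment to the OGG of its single
    best-scoring intact gene.

    ``intact_ogg`` maps intact gene id -> (protein, ogg name).  Ties break
    by higher identity, then lexicographic gene id.  Returns (assignments,
    unassigned ids)."""
    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    if not intact_ogg:
        return {}, sorted(nonintact)
    intact_ids = sorted(intact_ogg)
    ik = {i: kmer_set(intact_ogg[i][0], 4) for i in intact_ids}
    self_scores = {i: local_score(intact_ogg[i][0], intact_ogg[i][0]) for i in intact_ids}
    for nid in sorted(nonintact):
        frag = nonintact[nid]
        if not frag:
            unassigned.append(nid)
            continue
        fk = kmer_set(frag, 4)
        ranked = sorted(intact_ids, key=lambda i: -kmer_jaccard(fk, ik[i]))[:top_k]
        best: tuple[float, float, str] | None = None  # (score, identity, gene id)
        frag_self = local_score(frag, frag)
        for i in ranked:
            score = local_score(frag, intact_ogg[i][0])
            norm = score / min(frag_self, self_scores[i])
            if norm < min_norm_score:
                continue
            ident = pair_identity(frag, intact_ogg[i][0]) if len(frag) == len(intact_ogg[i][0]) else 0.0
            cand = (score, ident, i)
            if best is None or (cand[0], cand[1], _revlex(cand[2])) > (best[0], best[1], _revlex(best[2])):
                best = cand
        if best is None:
            unassigned.append(nid)
        else:
            assignments[nid] = intact_ogg[best[2]][1]
    return assignments, unassigned


class _revlex(str):
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def name_oggs(oggs: list[OGG]) -> list[OGG]:
    """Rank OGGs within each class by intact size (desc), mean similarity
    (desc), then smallest member id; names follow OGG{1|2}-{rank}."""
    for ogg in oggs:
        if ogg.class_label not in ("I", "II"):
            raise ValueError(f"OGG without class label: {ogg}")
    out = []
    for cls, prefix in (("I", "OGG1"), ("II", "OGG2")):
        group = [o for o in oggs if o.class_label == cls]
        group.sort(key=lambda o: (-o.size,
                                  -(o.mean_similarity if o.mean_similarity == o.mean_similarity else -1.0),
                                  o.intact_ids[0] if o.intact_ids else ""))
        for rank, ogg in enumerate(group, start=1):
            ogg.name = f"{prefix}-{rank}"
            out.append(ogg)
    return out


def mean_ogg_size(oggs: list[OGG]) -> float:
    """Mean intact-member count over multi-member OGGs (the repertoire-wide
    average family size; singletons are excluded by definition)."""
    multi = [o.size for o in oggs if o.size >= 2]
    if not multi:
        return float("nan")
    return sum(multi) / len(multi)


def ogg_census(oggs: list[OGG]) -> tuple[int, int, int]:
    """(multi-member OGGs, singleton OGGs, total) — the partition identity
    n_multi + n_singleton = total."""
    n_multi = sum(1 for o in oggs if o.size >= 2)
    n_single = sum(1 for o in oggs if o.size == 1)
    return n_multi, n_single, n_multi + n_single


def ogg_table(oggs: list[OGG]) -> pd.DataFrame:
    rows = []
    for ogg in oggs:
        for species, ids in sorted(ogg.intact.items()):
            for gid in sorted(ids):
                rows.append({"ogg_name": ogg.name, "class": ogg.class_label,
                             "species": species, "gene_id": gid, "status": "intact"})
        for species, ids in sorted(ogg.nonintact.items()):
            for gid in sorted(ids):
                rows.append({"ogg_name": ogg.name, "class": ogg.class_label,
                             "species": species, "gene_id": gid, "status": "nonintact"})
    return pd.DataFrame(rows, columns=["ogg_name", "class", "species", "gene_id", "status"])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def classify_repertoire(intact: dict[str, str], species_of: dict[str, str],
                        anchors: dict[str, tuple[str, str]],
                        nonintact: dict[str, str] | None = None,
                        nonintact_status: dict[str, str] | None = None,
                        outgroup_gpcrs: dict[str, str] | None = None,
                        support_floor: float = 70, replicates: int = 100,
                        inflation: float | None = None, seed: int = 0
                        ) -> tuple[list[OGG], pd.DataFrame]:
    """Full classification stage: cluster, place singletons, label classes,
    attach non-intact genes, name OGGs.  Returns (OGGs, long table)."""
    nonintact = nonintact or {}
    outgroup_gpcrs = outgroup_gpcrs or {}
    clusters, singles = cluster_oggs(intact, inflation=inflation)
    merged, rest = place_singletons({s: intact[s] for s in singles}, outgroup_gpcrs,
                                    support_floor=support_floor, replicates=replicates,
                                    seed=seed)
    gene_class = assign_class(intact, anchors)
    oggs: list[OGG] = []
    for members in clusters + merged + [[s] for s in rest]:
        by_species: dict[str, list[str]] = {}
        for gid in members:
            by_species.setdefault(species_of.get(gid, "unknown"), []).append(gid)
        classes = [gene_class[g] for g in members]
        cls = max(("I", "II"), key=lambda c: (classes.count(c), c == "II"))
        oggs.append(OGG(class_label=cls, intact=by_species,
                        mean_similarity=ogg_mean_similarity([intact[g] for g in members])))
    oggs = name_oggs(oggs)
    intact_ogg = {}
    for ogg in oggs:
        for gid in ogg.intact_ids:
            intact_ogg[gid] = (intact[gid], ogg.name)
    assignments, unassigned = assign_nonintact(nonintact, intact_ogg)
    by_name = {o.name: o for o in oggs}
    for nid, ogg_name in assignments.items():
        sp = species_of.get(nid, "unknown")
        by_name[ogg_name].nonintact.setdefault(sp, []).append(nid)
    table = ogg_table(oggs)
    if nonintact_status:
        table["status"] = [
            nonintact_status.get(g, s) for g, s in zip(table["gene_id"], table["status"])
        ]
    if unassigned:
        logger.info("%d non-intact genes unassigned", len(unassigned))
    return oggs, table
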