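"""OR gene mining from genome assemblies.

Two-pass identification, mirroring the standard repertoire-mining recipe
for intronless OR genes:

pass 1 (intact genes)
    translated search of dereplicated reference OR proteins against the
    genome (E <= 1e-10) -> highest-scoring non-overlapping regions ->
    in-frame ORF extension to ATG..stop -> length >= 250 aa -> TM-segment
    transfer from the closest reference with a <= 5 aa gap tolerance per
    TM helix -> start-codon choice constrained to a 21-34 aa N-terminal
    segment -> phylogenetic confirmation against non-OR GPCR outgroups.

pass 2 (pseudogenes / truncated genes)
    the intact genes themselves become queries (E <= 1e-20); matched
    regions not overlapping intact calls are pseudogenes when disrupted
    (internal stop or frameshift) and truncated when disruption-free and
    ending within 30 bp of a contig end (a truncated gene may carry both
    flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import SearchHit, TranslatedSearch, global_alignment, global_identity, kmer_jaccard, kmer_set
from .sequences import frame_to_genomic, reverse_complement, six_frames, translate
from .trees import neighbor_joining, poisson_from_p

logger = logging.getLogger(__name__)

DEFAULTS = {
    "derep_identity": 0.50,
    "evalue1": 1e-10,
    "evalue2": 1e-20,
    "min_protein_length": 250,
    "tm_gap_max": 5,
    "nterm_min": 21,
    "nterm_max": 34,
    "contig_end_max_bp": 30,
    "region_join_bp": 60,
}


@dataclass
class ReferenceOR:
    """A query OR protein with its seven TM helix intervals (0-based,
    half-open, on the protein)."""

    id: str
    protein: str
    class_label: str  # "I" | "II"
    tm_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.tm_intervals) != 7:
            raise ValueError("exactly 7 TM intervals required")
        prev_end = 0
        for s, e in self.tm_intervals:
            if not (prev_end <= s < e <= len(self.protein)):
                raise ValueError("TM intervals must be ordered, disjoint and in bounds")
            prev_end = e

    @property
    def n_term_len(self) -> int:
        return self.tm_intervals[0][0]


@dataclass
class ORGeneCall:
    gene_id: str
    species: str
    contig: str
    strand: str
    start: int  # 0-based half-open CDS interval incl. stop codon (intact)
    end: int
    status: str  # intact | pseudogene | truncated
    protein: str = ""
    disruptions: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    class_label: str = ""
    ogg: str = ""

    def overlaps(self, contig: str, strand: str, start: int, end: int) -> bool:
        return (self.contig == contig and self.strand == strand
                and self.start < end and start < self.end)


# ---------------------------------------------------------------------------
# query dereplication
# ---------------------------------------------------------------------------

def dereplicate_queries(proteins: list[ReferenceOR], identity_ceiling: float = 0.50) -> list[ReferenceOR]:
    """Greedy longest-first selection keeping no pair at identity >=
    ``identity_ceiling`` (global-alignment identity)."""
    ranked = sorted(proteins, key=lambda r: (-len(r.protein), r.id))
    kept: list[ReferenceOR] = []
    for cand in ranked:
        if all(global_identity(cand.protein, k.protein) < identity_ceiling for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# pass 1: search, region selection, ORF extension
# ---------------------------------------------------------------------------

def translated_search(genome: dict[str, str], queries: list[ReferenceOR],
                      evalue_cutoff: float = 1e-10) -> list[SearchHit]:
    engine = TranslatedSearch({q.id: q.protein for q in queries}, max_evalue=evalue_cutoff)
    for name, seq in genome.items():
        if len(seq) < 3:
            logger.info("contig %s shorter than one codon, skipped", name)
    return engine.search_genome(genome)


def select_best_regions(hits: list[SearchHit]) -> list[SearchHit]:
    """Collapse overlapping same-strand hits to the single best one.

    Overlap is >= 1 bp shared on the same strand; ties broken by lower
    start coordinate, then query id.
    """
    out: list[SearchHit] = []
    by_key: dict[tuple[str, str], list[SearchHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig, h.strand), []).append(h)
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda h: h.start)
        cluster: list[SearchHit] = []
        cluster_end = -1
        for h in group + [None]:
            if h is not None and (not cluster or h.start < cluster_end):
                cluster.append(h)
                cluster_end = max(cluster_end, h.end)
                continue
            if cluster:
                best = max(cluster, key=lambda c: (c.score, -c.start, _neg_lex(c.query_id)))
                out.append(best)
            if h is not None:
                cluster = [h]
                cluster_end = h.end
    return sorted(out, key=lambda h: (h.contig, h.start, h.strand))


class _neg_lex(str):
    """Inverts lexicographic comparison so max() picks the smallest id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass
class OrfCandidate:
    contig: str
    strand: str
    frame: int
    aa_start: int  # on the frame translation, start at the farthest ATG
    aa_stop: int  # index of the terminating '*'
    protein: str
    hit: SearchHit

    def genomic_interval(self, contig_len: int) -> tuple[int, int]:
        # include the stop codon in the CDS interval
        return frame_to_genomic(self.aa_start, self.aa_stop + 1, self.strand,
                                self.frame, contig_len)


def extend_to_orf(hit: SearchHit, genome: dict[str, str],
                  min_protein_length: int = 250) -> OrfCandidate | str:
    """Extend a hit in frame to the longest ATG..stop ORF.

    Returns an :class:`OrfCandidate` or a rejection reason string
    ('off_end', 'no_start', 'too_short').
    """
    seq = genome[hit.contig]
    frame_seq = seq if hit.strand == "+" else reverse_complement(seq)
    prot = translate(frame_seq[hit.frame:])
    # downstream: first stop at or after the hit start
    stop_idx = None
    for i in range(hit.aa_start, len(prot)):
        if prot[i] == "*":
            stop_idx = i
            break
    if stop_idx is None:
        return "off_end"
    # upstream: farthest ATG not interrupted by a stop
    start_idx = None
    i = min(hit.aa_start, stop_idx - 1)
    while i >= 0 and prot[i] != "*":
        if prot[i] == "M":
            start_idx = i
        i -= 1
    if start_idx is None:
        # allow a start inside the hit, up to the stop
        for j in range(hit.aa_start, stop_idx):
            if prot[j] == "M":
                start_idx = j
                break
    if start_idx is None:
        return "no_start"
    protein = prot[start_idx:stop_idx]
    if len(protein) < min_protein_length:
        return "too_short"
    return OrfCandidate(hit.contig, hit.strand, hit.frame, start_idx, stop_idx, protein, hit)


# ---------------------------------------------------------------------------
# TM segmentation and start choice
# ---------------------------------------------------------------------------

@dataclass
class TMSegmentation:
    intervals: list[tuple[int, int]]  # on the candidate protein
    tm1_start: int
    reference_id: str


def closest_reference(protein: str, references: list[ReferenceOR]) -> ReferenceOR:
    kp = kmer_set(protein)
    return max(references, key=lambda r: (kmer_jaccard(kp, kmer_set(r.protein)), _neg_lex(r.id)))


def segment_tm(protein: str, reference: ReferenceOR, tm_gap_max: int = 5) -> TMSegmentation | str:
    """Transfer the reference's 7 TM intervals onto the candidate through a
    global alignment; reject when any TM carries an alignment gap longer
    than ``tm_gap_max`` residues or is not covered at all."""
    aln = global_alignment(reference.protein, protein)
    ref_blocks, cand_blocks = aln.aligned
    ref2cand = [-1] * len(reference.protein)
    for (rs, re_), (cs, ce) in zip(ref_blocks, cand_blocks):
        for k in range(re_ - rs):
            ref2cand[rs + k] = cs + k
    intervals = []
    for s, e in reference.tm_intervals:
        mapped = [ref2cand[i] for i in range(s, e)]
        aligned = [m for m in mapped if m >= 0]
        if not aligned:
            return "tm_uncovered"
        # deletion gap: longest run of unaligned reference positions
        run = best = 0
        for m in mapped:
            run = run + 1 if m < 0 else 0
            best = max(best, run)
        if best > tm_gap_max:
            return "tm_gap"
        # insertion gap: candidate residues inside the TM with no ref partner
        ins = (aligned[-1] - aligned[0] + 1) - len(aligned)
        if ins > tm_gap_max:
            return "tm_gap"
        intervals.append((aligned[0], aligned[-1] + 1))
    return TMSegmentation(intervals, intervals[0][0], reference.id)


def choose_start(candidate: OrfCandidate, tm1_start: int,
                 nterm_min: int = 21, nterm_max: int = 34) -> tuple[int, str] | None:
    """Pick the in-frame ATG whose N-terminal segment (start to TM1) is
    21-34 aa; among several, the longest N-terminus wins.  Returns the new
    (aa offset into the candidate, trimmed protein) or None."""
    protein = candidate.protein
    best = None
    for off in range(len(protein)):
        if protein[off] != "M":
            continue
        nterm = tm1_start - off
        if nterm_min <= nterm <= nterm_max:
            best = off  # smallest offset = longest qualifying N-terminus
            break
    if best is None:
        return None
    return best, protein[best:]


# ---------------------------------------------------------------------------
# OR identity confirmation
# ---------------------------------------------------------------------------

def _quick_p(a: str, b: str) -> float:
    if len(a) == len(b):
        diff = sum(x != y for x, y in zip(a, b))
        return diff / len(a)
    from .align import p_distance
    return p_distance(a, b)


def confirm_or_identity(candidates: dict[str, str], or_refs: dict[str, str],
                        outgroup_gpcrs: dict[str, str]) -> tuple[set[str], set[str]]:
    """Partition candidate ids into (kept OR, removed non-OR).

    A neighbor-joining tree over candidates + OR references + outgroups is
    rooted at an OR reference; candidates inside the smallest clade
    containing all outgroups are removed.  With < 4 sequences (or when the
    outgroup clade is not clean) the nearest-neighbor distance rule
    decides instead.
    """
    if not candidates:
        return set(), set()
    if not outgroup_gpcrs:
        return set(candidates), set()
    seqs = {**{f"c|{k}": v for k, v in candidates.items()},
            **{f"r|{k}": v for k, v in or_refs.items()},
            **{f"o|{k}": v for k, v in outgroup_gpcrs.items()}}
    if len(seqs) < 4 or not or_refs or len(outgroup_gpcrs) < 2:
        return _confirm_by_nn(candidates, or_refs, outgroup_gpcrs)
    labels = sorted(seqs)
    import numpy as np
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = poisson_from_p(min(1.0, _quick_p(seqs[labels[i]], seqs[labels[j]])))
    tree = neighbor_joining(labels, dm)
    ref_label = sorted(f"r|{k}" for k in or_refs)[0]
    ref_node = tree.find_node_with_taxon_label(ref_label)
    tree.reroot_at_edge(ref_node.edge, update_bipartitions=False)
    mrca = tree.mrca(taxon_labels=[f"o|{k}" for k in outgroup_gpcrs])
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    if any(lab.startswith("r|") for lab in clade):
        logger.info("outgroup clade not clean; falling back to nearest-neighbor rule")
        return _confirm_by_nn(candidates, or_refs, outgroup_gpcrs)
    removed = {lab[2:] for lab in clade if lab.startswith("c|")}
    kept = set(candidates) - removed
    return kept, removed


def _confirm_by_nn(candidates, or_refs, outgroups):
    kept, removed = set(), set()
    for cid, seq in candidates.items():
        d_ref = min((_quick_p(seq, r) for r in or_refs.values()), default=1.0)
        d_out = min((_quick_p(seq, o) for o in outgroups.values()), default=1.0)
        (kept if d_ref <= d_out else removed).add(cid)
    return kept, removed


# ---------------------------------------------------------------------------
# pass 2: pseudogenes and truncated genes
# ---------------------------------------------------------------------------

@dataclass
class _Region:
    contig: str
    strand: str
    start: int
    end: int
    hits: list[SearchHit]


def _merge_regions(hits: list[SearchHit], join_bp: int) -> list[_Region]:
    regions: list[_Region] = []
    by_key: dict[tuple[str, str], list[SearchHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig, h.strand), []).append(h)
    for (contig, strand) in sorted(by_key):
        group = sorted(by_key[(contig, strand)], key=lambda h: h.start)
        cur: _Region | None = None
        for h in group:
            if cur is not None and h.start <= cur.end + join_bp:
                cur.end = max(cur.end, h.end)
                cur.hits.append(h)
            else:
                cur = _Region(contig, strand, h.start, h.end, [h])
                regions.append(cur)
    return regions


def _region_disruptions(region: _Region, genome: dict[str, str]) -> list[str]:
    disruptions = []
    frames = {h.frame for h in region.hits}
    if len(frames) > 1:
        disruptions.append("frameshift")
    best = max(region.hits, key=lambda h: h.score)
    seq = genome[region.contig]
    frame_seq = seq if region.strand == "+" else reverse_complement(seq)
    prot = translate(frame_seq[best.frame:])
    aa_lo = min(h.aa_start for h in region.hits if h.frame == best.frame)
    aa_hi = max(h.aa_end for h in region.hits if h.frame == best.frame)
    for i in range(aa_lo, aa_hi):
        if prot[i] == "*":
            disruptions.append(f"stop@{i}")
    return disruptions


def _near_contig_end(region: _Region, genome: dict[str, str],
                     max_bp: int = 30, runoff_aa: int = 30) -> bool:
    """Contig-end rule with alignment-trim tolerance.

    True when either boundary of the matched region lies within ``max_bp``
    of a contig end, or when the reading frame continues stop-free from a
    region boundary all the way to the contig end within ``runoff_aa``
    codons (a local alignment may trim a diverged tail of a contig-cut
    fragment, but a genuine interior remnant ends at a stop codon long
    before the contig does).
    """
    best = max(region.hits, key=lambda h: h.score)
    seq = genome[region.contig]
    frame_seq = seq if region.strand == "+" else reverse_complement(seq)
    prot = translate(frame_seq[best.frame:])
    aa_lo = min(h.aa_start for h in region.hits if h.frame == best.frame)
    aa_hi = max(h.aa_end for h in region.hits if h.frame == best.frame)
    # downstream (3' in gene orientation)
    down_bp = len(frame_seq) - (best.frame + 3 * aa_hi)
    if down_bp < max_bp:
        return True
    if len(prot) - aa_hi <= runoff_aa and "*" not in prot[aa_hi:]:
        return True
    # upstream (5' in gene orientation)
    up_bp = best.frame + 3 * aa_lo
    if up_bp < max_bp:
        return True
    if aa_lo <= runoff_aa and "*" not in prot[:aa_lo]:
        return True
    return False


def _region_protein(region: _Region, genome: dict[str, str]) -> str:
    best = max(region.hits, key=lambda h: h.score)
    seq = genome[region.contig]
    frame_seq = seq if region.strand == "+" else reverse_complement(seq)
    prot = translate(frame_seq[best.frame:])
    return prot[best.aa_start : best.aa_end].replace("*", "X")


def second_pass_scan(genome: dict[str, str], intact_calls: list[ORGeneCall],
                     queries: list[ReferenceOR] | None = None,
                     evalue_cutoff: float = 1e-20, contig_end_max_bp: int = 30,
                     region_join_bp: int = 60, species: str = "",
                     exclude: list[ORGeneCall] | None = None,
                     outgroup_gpcrs: dict[str, str] | None = None) -> list[ORGeneCall]:
    """Find non-intact OR copies with the intact genes as queries.

    ``exclude`` lists loci already confirmed non-OR in pass 1; regions
    overlapping them are skipped.  When ``outgroup_gpcrs`` is given, each
    region's translation is additionally screened with the
    nearest-neighbor rule so non-OR GPCR remnants are not reported as OR
    pseudogenes.
    """
    if intact_calls:
        qmap = {c.gene_id: c.protein for c in intact_calls}
    elif queries:
        qmap = {q.id: q.protein for q in queries}
    else:
        return []
    engine = TranslatedSearch(qmap, max_evalue=evalue_cutoff)
    hits = engine.search_genome(genome)
    regions = _merge_regions(hits, region_join_bp)
    blocked = list(intact_calls) + list(exclude or [])
    calls: list[ORGeneCall] = []
    n = 0
    for reg in regions:
        if any(c.overlaps(reg.contig, reg.strand, reg.start, reg.end) for c in blocked):
            continue
        prot = _region_protein(reg, genome)
        if outgroup_gpcrs:
            kept, _removed = _confirm_by_nn({"region": prot}, qmap, outgroup_gpcrs)
            if "region" not in kept:
                continue
        disruptions = _region_disruptions(reg, genome)
        near_end = _near_contig_end(reg, genome, max_bp=contig_end_max_bp)
        truncated_flag = near_end
        pseudo_flag = bool(disruptions) or not near_end
        status = "truncated" if (near_end and not disruptions) else "pseudogene"
        calls.append(ORGeneCall(
            gene_id=f"{species or 'genome'}_nx{n:04d}", species=species,
            contig=reg.contig, strand=reg.strand, start=reg.start, end=reg.end,
            status=status, protein=prot, disruptions=disruptions,
            flags={"pseudogene": pseudo_flag, "truncated": truncated_flag},
        ))
        n += 1
    return calls


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def mine_genome(genome: dict[str, str], references: list[ReferenceOR],
                outgroup_gpcrs: dict[str, str] | None = None, species: str = "",
                config: dict | None = None) -> list[ORGeneCall]:
    """Run both identification passes on one genome assembly."""
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    queries = dereplicate_queries(references, cfg["derep_identity"])
    hits = translated_search(genome, queries, cfg["evalue1"])
    best = select_best_regions(hits)
    candidates: dict[tuple[str, str, int, int], OrfCandidate] = {}
    for hit in best:
        result = extend_to_orf(hit, genome, cfg["min_protein_length"])
        if isinstance(result, str):
            continue
        g0, g1 = result.genomic_interval(len(genome[result.contig]))
        key = (result.contig, result.strand, g0, g1)
        if key not in candidates or result.hit.score > candidates[key].hit.score:
            candidates[key] = result
    intact: list[ORGeneCall] = []
    n = 0
    for key in sorted(candidates):
        cand = candidates[key]
        ref = closest_reference(cand.protein, references)
        seg = segment_tm(cand.protein, ref, cfg["tm_gap_max"])
        if isinstance(seg, str):
            continue
        chosen = choose_start(cand, seg.tm1_start, cfg["nterm_min"], cfg["nterm_max"])
        if chosen is None:
            logger.info("candidate at %s:%d has no start with a 21-34 aa N-terminus", cand.contig, key[2])
            continue
        off, protein = chosen
        if len(protein) < cfg["min_protein_length"]:
            continue
        contig_len = len(genome[cand.contig])
        g0, g1 = frame_to_genomic(cand.aa_start + off, cand.aa_stop + 1, cand.strand,
                                  cand.frame, contig_len)
        intact.append(ORGeneCall(
            gene_id=f"{species or 'genome'}_or{n:04d}", species=species,
            contig=cand.contig, strand=cand.strand, start=g0, end=g1,
            status="intact", protein=protein, flags={"pseudogene": False, "truncated": False},
        ))
        n += 1
    non_or_calls: list[ORGeneCall] = []
    if outgroup_gpcrs:
        kept, removed = confirm_or_identity(
            {c.gene_id: c.protein for c in intact},
            {q.id: q.protein for q in queries}, outgroup_gpcrs)
        non_or_calls = [c for c in intact if c.gene_id in removed]
        intact = [c for c in intact if c.gene_id in kept]
    nonintact = second_pass_scan(
        genome, intact, queries=queries, evalue_cutoff=cfg["evalue2"],
        contig_end_max_bp=cfg["contig_end_max_bp"], region_join_bp=cfg["region_join_bp"],
        species=species, exclude=non_or_calls, outgroup_gpcrs=outgroup_gpcrs)
    return intact + nonintact
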