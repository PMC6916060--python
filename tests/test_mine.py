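"""Miner operations: dereplication, region selection, ORF extension, TM
segmentation, start choice, second-pass classification, OR confirmation."""

import itertools

import numpy as np
import pytest

from orevo.align import SearchHit, global_identity
from orevo.mine import (
    ORGeneCall,
    OrfCandidate,
    ReferenceOR,
    choose_start,
    confirm_or_identity,
    dereplicate_queries,
    extend_to_orf,
    second_pass_scan,
    segment_tm,
    select_best_regions,
    translated_search,
)
from orevo.sequences import reverse_complement
from orevo.simulate import TM_INTERVALS, back_translate, random_protein


AAS = "ACDEFGHIKLMNPQRSTVWY"


def _protein(rng, n=120):
    return "".join(AAS[i] for i in rng.integers(0, 20, n))


def _with_identity(base, frac, rng):
    """A sequence sharing ~frac identity with base (scattered changes)."""
    out = list(base)
    n_change = round(len(base) * (1 - frac))
    for pos in rng.choice(len(base), size=n_change, replace=False):
        out[pos] = AAS[(AAS.index(out[pos]) + 1 + int(rng.integers(18))) % 20]
    return "".join(out)


def _ref(rid, protein):
    return ReferenceOR(rid, protein, "II", list(TM_INTERVALS))


class TestDereplication:
    def test_identical_pair_keeps_one(self, rng):
        p = random_protein(rng)
        kept = dereplicate_queries([_ref("a", p), _ref("b", p)], 0.5)
        assert [r.id for r in kept] == ["a"]

    def test_49_percent_identity_keeps_both(self, rng):
        a = random_protein(rng)
        b = _with_identity(a, 0.44, rng)  # alignment identity lands just below 0.5
        ident = global_identity(a, b)
        assert ident < 0.5
        kept = dereplicate_queries([_ref("a", a), _ref("b", b)], 0.5)
        assert len(kept) == 2

    def test_chain_matches_greedy_oracle(self, rng):
        # A~B and B~C above the ceiling, A~C below; lengths A > B > C
        a = _protein(rng, 310)
        b = _with_identity(a, 0.62, rng)[:298]
        c = _with_identity(b, 0.62, rng)[:288]
        refs = [_ref("A", a), _ref("B", b), _ref("C", c)]
        idents = {(x.id, y.id): global_identity(x.protein, y.protein)
                  for x, y in itertools.combinations(refs, 2)}
        assert idents[("A", "B")] >= 0.5 and idents[("B", "C")] >= 0.5
        assert idents[("A", "C")] < 0.5

        # independent oracle: replay greedy longest-first over the identity table
        order = sorted(refs, key=lambda r: (-len(r.protein), r.id))
        expected = []
        for cand in order:
            if all(idents.get((cand.id, k.id), idents.get((k.id, cand.id), 0)) < 0.5
                   for k in expected):
                expected.append(cand)
        kept = dereplicate_queries(refs, 0.5)
        assert [r.id for r in kept] == [r.id for r in expected] == ["A", "C"]

    def test_empty_input(self):
        assert dereplicate_queries([], 0.5) == []


def _hit(score, start, end, query="q", contig="c", strand="+"):
    return SearchHit(query_id=query, contig=contig, strand=strand, frame=0,
                     start=start, end=end, aa_start=0, aa_end=(end - start) // 3,
                     query_start=0, query_end=10, score=score)


class TestRegionSelection:
    def test_highest_score_wins(self):
        kept = select_best_regions([_hit(500, 100, 400), _hit(300, 200, 500)])
        assert len(kept) == 1
        assert kept[0].score == 500

    def test_non_overlapping_both_kept(self):
        kept = select_best_regions([_hit(500, 100, 400), _hit(300, 600, 900)])
        assert len(kept) == 2

    def test_opposite_strands_not_collapsed(self):
        kept = select_best_regions([_hit(500, 100, 400, strand="+"),
                                    _hit(300, 100, 400, strand="-")])
        assert len(kept) == 2

    def test_equal_score_tie_break(self):
        # three mutually overlapping equal scores: lowest start, then query id
        hits = [_hit(400, 120, 420, query="qb"), _hit(400, 100, 400, query="qz"),
                _hit(400, 100, 400, query="qa")]
        kept = select_best_regions(hits)
        assert len(kept) == 1
        assert (kept[0].start, kept[0].query_id) == (100, "qa")


def _orf_contig(n_aa, rng, lead="", tail=""):
    """Contig with an ATG..stop ORF of n_aa residues (incl. Met)."""
    prot = "M" + "".join(AAS[i] for i in rng.integers(0, 20, n_aa - 1))
    prot = prot.replace("M", "L")  # keep a single unambiguous start
    prot = "M" + prot[1:]
    cds = back_translate(prot, rng)
    return lead + cds + tail, prot, len(lead)


class TestOrfExtension:
    @pytest.mark.parametrize("n_aa,expect", [(249, "too_short"), (250, "ok")])
    def test_length_boundary(self, n_aa, expect, rng):
        contig, prot, off = _orf_contig(n_aa, rng, lead="TAA" * 4, tail="G" * 30)
        genome = {"c": contig}
        hit = SearchHit("q", "c", "+", 0, off + 30, off + 120, (off + 30) // 3,
                        (off + 120) // 3, 0, 30, 200.0)
        res = extend_to_orf(hit, genome, min_protein_length=250)
        if expect == "too_short":
            assert res == "too_short"
        else:
            assert isinstance(res, OrfCandidate)
            assert res.protein == prot

    def test_runs_off_contig_end(self, rng):
        contig, _, off = _orf_contig(260, rng, lead="TAA" * 4)
        contig = contig[:-40]  # cut the stop codon away
        hit = SearchHit("q", "c", "+", 0, off + 30, off + 120, (off + 30) // 3,
                        (off + 120) // 3, 0, 30, 200.0)
        assert extend_to_orf(hit, {"c": contig}) == "off_end"

    def test_extension_stops_at_upstream_stop(self, rng):
        # the retained ORF must not reach past an in-frame upstream stop
        contig, prot, off = _orf_contig(260, rng, lead="TAA" * 5, tail="C" * 30)
        hit = SearchHit("q", "c", "+", 0, off + 60, off + 150, (off + 60) // 3,
                        (off + 150) // 3, 0, 30, 200.0)
        res = extend_to_orf(hit, {"c": contig})
        assert isinstance(res, OrfCandidate)
        g0, _ = res.genomic_interval(len(contig))
        assert g0 == off


class TestTMSegmentation:
    def test_gap_boundary_in_tm(self, rng):
        ref = _ref("r", random_protein(rng))
        s3, _e3 = ref.tm_intervals[2]
        for gap, ok in ((5, True), (6, False)):
            cand = ref.protein[: s3 + 3] + ref.protein[s3 + 3 + gap :]
            out = segment_tm(cand, ref, tm_gap_max=5)
            if ok:
                assert not isinstance(out, str)
            else:
                assert out == "tm_gap"

    def test_large_gap_in_loop_retained(self, rng):
        ref = _ref("r", random_protein(rng))
        _s1, e1 = ref.tm_intervals[0]
        s2, _ = ref.tm_intervals[1]
        mid = (e1 + s2) // 2  # inside the extramembrane loop
        cand = ref.protein[: mid - 5] + ref.protein[mid + 5 :]  # 10-aa deletion
        out = segment_tm(cand, ref, tm_gap_max=5)
        assert not isinstance(out, str)

    def test_identity_mapping(self, rng):
        ref = _ref("r", random_protein(rng))
        out = segment_tm(ref.protein, ref)
        assert out.intervals == ref.tm_intervals
        assert out.tm1_start == ref.n_term_len


class DummyCand:
    def __init__(self, protein):
        self.protein = protein


class TestChooseStart:
    def _candidate(self, m_offsets, tm1, length=320):
        prot = ["L"] * length
        for off in m_offsets:
            prot[off] = "M"
        return DummyCand("".join(prot)), tm1

    def test_picks_in_window(self):
        # N-termini of 40, 25, 18 from starts at offsets 0, 15, 22 (TM1 at 40)
        cand, tm1 = self._candidate([0, 15, 22], 40)
        off, prot = choose_start(cand, tm1)
        assert tm1 - off == 25

    def test_boundaries_inclusive_longest_wins(self):
        cand, tm1 = self._candidate([6, 19], 40)  # N-termini 34 and 21
        off, _ = choose_start(cand, tm1)
        assert tm1 - off == 34

    @pytest.mark.parametrize("nterm", [20, 35])
    def test_out_of_window_rejected(self, nterm):
        cand, tm1 = self._candidate([40 - nterm], 40)
        assert choose_start(cand, tm1) is None

    def test_exhaustive_window_scan(self):
        # every ATG placement: accepted iff its N-terminus is in [21, 34]
        for nterm in range(10, 45):
            cand, tm1 = self._candidate([45 - nterm], 45)
            got = choose_start(cand, tm1)
            assert (got is not None) == (21 <= nterm <= 34)


class TestSecondPassBoundaries:
    def _fragment_genome(self, rng, end_distance, lead=3000):
        """A disruption-free in-frame fragment of a query protein whose
        downstream end sits ``end_distance`` bp from the contig end; the
        flank opens with an in-frame stop, so the fragment's frame
        terminates at the region boundary."""
        query = random_protein(rng)
        cds = back_translate(query, rng)
        frag = cds[: 3 * 200]  # 200 codons, no stop
        flank = ("TAA" + "A" * (end_distance - 3)) if end_distance >= 3 else "A" * end_distance
        contig = ("G" * lead) + frag + flank
        genome = {"c": contig}
        return genome, _ref("q", query)

    @pytest.mark.parametrize("dist,expected", [(29, "truncated"), (30, "pseudogene")])
    def test_contig_end_rule_boundary(self, rng, dist, expected):
        genome, query = self._fragment_genome(rng, dist)
        calls = second_pass_scan(genome, [], queries=[query], evalue_cutoff=1e-20)
        assert len(calls) == 1
        assert calls[0].status == expected
        assert calls[0].flags["truncated"] == (dist == 29)

    def test_internal_stop_is_pseudogene(self, rng):
        query = random_protein(rng)
        cds = back_translate(query, rng)
        broken = cds[: 3 * 150] + "TAA" + cds[3 * 151 :]
        genome = {"c": "G" * 2000 + broken + "C" * 2000}
        calls = second_pass_scan(genome, [], queries=[_ref("q", query)])
        assert len(calls) == 1
        assert calls[0].status == "pseudogene"
        assert any(d.startswith("stop@") for d in calls[0].disruptions)

    def test_frameshift_detected(self, rng):
        query = random_protein(rng)
        cds = back_translate(query, rng)
        shifted = cds[: 3 * 150] + cds[3 * 150 + 1 :]  # 1-bp deletion
        genome = {"c": "G" * 2000 + shifted + "C" * 2000}
        calls = second_pass_scan(genome, [], queries=[_ref("q", query)])
        assert len(calls) == 1
        assert calls[0].status == "pseudogene"

    def test_regions_overlapping_intact_are_dropped(self, rng):
        query = random_protein(rng)
        cds = back_translate(query, rng)
        genome = {"c": "G" * 2000 + cds + "C" * 2000}
        intact = [ORGeneCall("g1", "", "c", "+", 2000, 2000 + len(cds), "intact",
                             protein=query)]
        calls = second_pass_scan(genome, intact)
        assert calls == []


class TestConfirmIdentity:
    def test_partition(self, rng):
        or_ref = random_protein(rng)
        gpcr_anc = _with_identity(or_ref, 0.45, rng)
        outgroups = {"out1": _with_identity(gpcr_anc, 0.8, rng),
                     "out2": _with_identity(gpcr_anc, 0.8, rng)}
        candidates = {
            "or1": _with_identity(or_ref, 0.92, rng),
            "or2": _with_identity(or_ref, 0.88, rng),
            "dec1": _with_identity(gpcr_anc, 0.93, rng),
        }
        kept, removed = confirm_or_identity(candidates, {"ref": or_ref}, outgroups)
        assert kept == {"or1", "or2"}
        assert removed == {"dec1"}

    def test_empty_candidates(self):
        kept, removed = confirm_or_identity({}, {"r": "MKL"}, {"o": "MNP"})
        assert kept == set() and removed == set()

    def test_no_outgroups_keeps_all(self):
        kept, removed = confirm_or_identity({"a": "MKL" * 50}, {"r": "MKL" * 50}, {})
        assert kept == {"a"}


class TestMinerRoundTrip:
    def test_full_miner_strand_symmetry(self, small_sim):
        """Mining an assembly and its full reverse complement yields the
        same call set with mirrored coordinates."""
        from orevo.mine import mine_genome

        genome = small_sim["genomes"]["A"]
        queries = small_sim["queries"]
        outg = small_sim["reference"].decoy_prototypes
        fwd = mine_genome(genome, queries, outg, species="A")
        rc = {k: reverse_complement(v) for k, v in genome.items()}
        rev = mine_genome(rc, queries, outg, species="A")
        lens = {k: len(v) for k, v in genome.items()}
        flip = {"+": "-", "-": "+"}
        fwd_keys = {(c.contig, c.strand, c.start, c.end, c.status) for c in fwd}
        rev_keys = {(c.contig, flip[c.strand], lens[c.contig] - c.end,
                     lens[c.contig] - c.start, c.status) for c in rev}
        assert fwd_keys == rev_keys

    def test_recovers_planted_truth(self, small_sim):
        """Round trip against the generator: every planted locus comes back
        with its planted status, intact CDS intervals exactly."""
        from orevo.mine import mine_genome

        truth = small_sim["truth"].genes
        truth = truth[truth["species"] == "B"]
        calls = mine_genome(small_sim["genomes"]["B"], small_sim["queries"],
                            small_sim["reference"].decoy_prototypes, species="B")
        ti = truth[truth["status"] == "intact"]
        mined = {(c.contig, c.start, c.end) for c in calls if c.status == "intact"}
        assert set(zip(ti["contig"], ti["start"], ti["end"])) == mined
        for row in truth[truth["status"].isin(["pseudogene", "truncated"])].itertuples():
            got = [c.status for c in calls if c.contig == row.contig
                   and c.start < row.end and row.start < c.end]
            assert got == [row.status]


class TestSearchProperties:
    def test_exact_copy_hit_full_coverage_and_strand_symmetry(self, rng):
        query = random_protein(rng)
        cds = back_translate(query, rng)
        fwd = {"c": "G" * 999 + cds + "C" * 999}
        rev = {"c": reverse_complement(fwd["c"])}
        h_fwd = translated_search(fwd, [_ref("q", query)], 1e-10)
        h_rev = translated_search(rev, [_ref("q", query)], 1e-10)
        assert len(h_fwd) == len(h_rev) == 1
        assert h_fwd[0].strand == "+" and h_rev[0].strand == "-"
        assert h_fwd[0].score == h_rev[0].score
        # mirrored coordinates
        L = len(fwd["c"])
        assert (h_rev[0].start, h_rev[0].end) == (L - h_fwd[0].end, L - h_fwd[0].start)
        # full ORF coverage (minus the stop codon)
        assert h_fwd[0].end - h_fwd[0].start >= len(cds) - 6

    def test_evalue_monotonicity(self, rng):
        query = random_protein(rng)
        planted = back_translate(_with_identity(query, 0.7, rng), rng)
        genome = {"c": "G" * 500 + planted + "T" * 500}
        strict = translated_search(genome, [_ref("q", query)], 1e-40)
        loose = translated_search(genome, [_ref("q", query)], 1e-5)
        keys = lambda hits: {(h.contig, h.strand, h.start, h.end) for h in hits}
        assert keys(strict) <= keys(loose)

    def test_divergent_planted_genes_all_hit(self, rng):
        query = random_protein(rng)
        genome = {}
        for i in range(20):
            planted = back_translate(_with_identity(query, 0.85, rng), rng)
            genome[f"c{i}"] = "A" * 300 + planted + "G" * 300
        hits = translated_search(genome, [_ref("q", query)], 1e-10)
        assert {h.contig for h in hits} == set(genome)
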