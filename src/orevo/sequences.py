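"""Low-level nucleotide/protein sequence helpers.

Olfactory-receptor genes are intronless, so every coding region is a single
ATG..stop ORF on one strand; all genomic work here reduces to six-frame
translation and in-frame scanning.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; '*' marks stops, 'X' unknowns."""
    get = CODON_TO_AA.get
    return "".join(get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3))


def six_frames(seq: str) -> list[tuple[str, int, str]]:
    """All six translation frames of a contig.

    Returns (strand, frame, protein) triples with strand in {'+', '-'} and
    frame in {0, 1, 2}.  Frame f on '-' is counted from the 5' end of the
    reverse complement.
    """
    rc = reverse_complement(seq)
    out = []
    for frame in range(3):
        out.append(("+", frame, translate(seq[frame:])))
        out.append(("-", frame, translate(rc[frame:])))
    return out


def frame_to_genomic(aa_start: int, aa_end: int, strand: str, frame: int, contig_len: int) -> tuple[int, int]:
    """Map a protein interval on a translation frame to 0-based half-open
    genomic coordinates on the forward strand."""
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return contig_len - nt_end, contig_len - nt_start


def genomic_to_frame(nt_start: int, strand: str, frame: int, contig_len: int) -> int:
    """Inverse of :func:`frame_to_genomic` for the start coordinate."""
    if strand == "+":
        return (nt_start - frame) // 3
    return (contig_len - nt_start - frame) // 3 - 0  # caller supplies interval end
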