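"""File formats at stage boundaries.

FASTA through Biopython; tables as TSV.  Coordinates are 0-based
half-open in memory and 1-based inclusive in every written report.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mine import ORGeneCall, ReferenceOR

CALL_COLUMNS = ["species", "gene_id", "contig", "start", "end", "strand", "status",
                "pseudogene_flag", "truncated_flag", "disruptions"]


def write_fasta(path, seqs: dict[str, str], descriptions: dict[str, str] | None = None) -> None:
    records = [SeqRecord(Seq(s), id=k, description=(descriptions or {}).get(k, ""))
               for k, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_calls(path, calls: list[ORGeneCall]) -> None:
    rows = []
    for c in sorted(calls, key=lambda c: (c.contig, c.start, c.gene_id)):
        rows.append({
            "species": c.species, "gene_id": c.gene_id, "contig": c.contig,
            "start": c.start + 1, "end": c.end, "strand": c.strand, "status": c.status,
            "pseudogene_flag": int(bool(c.flags.get("pseudogene"))),
            "truncated_flag": int(bool(c.flags.get("truncated"))),
            "disruptions": ";".join(c.disruptions),
        })
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"disruptions": str})
    df["disruptions"] = df["disruptions"].fillna("")
    return df


def write_bed(path, calls: list[ORGeneCall]) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.contig, c.start)):
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.gene_id}\t0\t{c.strand}\n")


def write_tm_intervals(path, references: list[ReferenceOR]) -> None:
    rows = []
    for ref in references:
        for i, (s, e) in enumerate(ref.tm_intervals, start=1):
            rows.append({"protein_id": ref.id, "tm_index": i, "start": s + 1, "end": e})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tm_intervals(path) -> dict[str, list[tuple[int, int]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[int, int]]] = {}
    for pid, grp in df.groupby("protein_id"):
        grp = grp.sort_values("tm_index")
        out[pid] = [(int(s) - 1, int(e)) for s, e in zip(grp["start"], grp["end"])]
    return out


def load_references(fasta_path, tm_path, classes: dict[str, str] | None = None) -> list[ReferenceOR]:
    """Reference OR queries: protein FASTA + TM interval TSV.  Class labels
    come from ``classes`` or from a 'class=I|II' token in the FASTA
    description (default II)."""
    seqs = {}
    desc_class = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq)
        for token in rec.description.split():
            if token.startswith("class="):
                desc_class[rec.id] = token.split("=", 1)[1]
    tm = read_tm_intervals(tm_path)
    refs = []
    for rid, seq in sorted(seqs.items()):
        if rid not in tm:
            raise ValueError(f"no TM intervals for reference {rid}")
        cls = (classes or {}).get(rid, desc_class.get(rid, "II"))
        refs.append(ReferenceOR(rid, seq, cls, tm[rid]))
    return refs


def load_labeled_proteins(fasta_path) -> dict[str, tuple[str, str]]:
    """FASTA with 'class=I|II' description tokens -> {id: (seq, class)}."""
    out = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        cls = "II"
        for token in rec.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
        out[rec.id] = (str(rec.seq), cls)
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
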