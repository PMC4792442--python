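"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; tabular formats (BED-like intervals,
BLAST outfmt-6-style hit tables, report TSVs) go through pandas.
"""

from __future__ import annotations

import gzip
import json
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .contamination import HitRecord, MatchInterval
from .mito import AlignmentRecord
from .readqc import ReadPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pair",
    "read_bed_intervals",
    "read_blast_hits",
    "read_alignment_table",
    "write_json",
]


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with _open(path, "wt") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Synchronised iteration over two mate FASTQ files (Phred+33)."""
    with _open(path1) as fh1, _open(path2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for r1 in it1:
            r2 = next(it2, None)
            if r2 is None:
                raise ValueError("mate files are desynchronised: file 2 is shorter")
            id1 = r1.id.removesuffix("/1")
            id2 = r2.id.removesuffix("/2")
            if id1 != id2:
                raise ValueError(f"mate id mismatch: {r1.id!r} vs {r2.id!r}")
            yield ReadPair(
                id=id1,
                seq1=str(r1.seq).upper(),
                seq2=str(r2.seq).upper(),
                qual1=np.asarray(r1.letter_annotations["phred_quality"]),
                qual2=np.asarray(r2.letter_annotations["phred_quality"]),
            )
        if next(it2, None) is not None:
            raise ValueError("mate files are desynchronised: file 1 is shorter")


def write_fastq_pair(pairs: Iterable[ReadPair], path1, path2) -> None:
    with _open(path1, "wt") as fh1, _open(path2, "wt") as fh2:
        for p in pairs:
            q1 = "".join(chr(int(q) + 33) for q in p.qual1)
            q2 = "".join(chr(int(q) + 33) for q in p.qual2)
            fh1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            fh2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")


def read_bed_intervals(path) -> pd.DataFrame:
    """BED-style TSV: chrom, start, end and optional extra columns.

    Extra columns, when present, are named ``family`` and
    ``repeat_class`` (the layout the repeat summariser consumes).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "family", "repeat_class"][: df.shape[1]]
    df.columns = names + [f"extra{i}" for i in range(df.shape[1] - len(names))]
    return df


def read_match_intervals(path) -> list[MatchInterval]:
    df = read_bed_intervals(path)
    source_col = "family" if "family" in df.columns else None
    return [
        MatchInterval(
            contig_id=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            source=str(getattr(r, source_col)) if source_col else "",
        )
        for r in df.itertuples()
    ]


def read_blast_hits(path) -> list[HitRecord]:
    """BLAST tabular hits with a trailing kingdom column.

    Expected columns (headerless TSV): qseqid, sseqid, evalue,
    bitscore, kingdom — where kingdom is 'bacterial' or anything else.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["qseqid", "sseqid", "evalue", "bitscore", "kingdom"]
    )
    return [
        HitRecord(
            contig_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            bacterial=str(r.kingdom).lower().startswith("bacter"),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


_ALN_COLS = [
    "query_id",
    "query_len",
    "ref_id",
    "ref_len",
    "q_start",
    "q_end",
    "r_start",
    "r_end",
    "identity",
    "evalue",
    "strand",
]


def read_alignment_table(path) -> list[AlignmentRecord]:
    """Contig-vs-reference alignments as a headerless TSV.

    Columns: query_id, query_len, ref_id, ref_len, q_start, q_end,
    r_start, r_end, identity (percent), evalue, strand (+/-).
    Coordinates are 0-based half-open on the forward reference strand.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_ALN_COLS)
    return [
        AlignmentRecord(
            query_id=str(r.query_id),
            query_len=int(r.query_len),
            ref_id=str(r.ref_id),
            ref_len=int(r.ref_len),
            q_start=int(r.q_start),
            q_end=int(r.q_end),
            r_start=int(r.r_start),
            r_end=int(r.r_end),
            identity=float(r.identity),
            evalue=float(r.evalue),
            reverse=str(r.strand) == "-",
        )
        for r in df.itertuples()
    ]


def write_alignment_table(records: Iterable[AlignmentRecord], path) -> None:
    rows = [
        [
            r.query_id,
            r.query_len,
            r.ref_id,
            r.ref_len,
            r.q_start,
            r.q_end,
            r.r_start,
            r.r_end,
            r.identity,
            r.evalue,
            "-" if r.reverse else "+",
        ]
        for r in records
    ]
    pd.DataFrame(rows, columns=_ALN_COLS).to_csv(path, sep="\t", header=False, index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
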