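"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tabular formats through pandas.  All
writers emit byte-stable output so that manifests can be checksummed, and
``read(write(x)) == x`` holds for every in-memory record type.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .intervals import BED_COLUMNS, IntervalSet


class FastqRecord(NamedTuple):
    name: str
    seq: str
    qual: str


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Name -> uppercase sequence (free line wrap accepted)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# FASTQ (Sanger Phred+33)
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[FastqRecord]:
    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            if len(seq) != len(qual):
                raise FormatError(f"sequence/quality length mismatch for {title!r}")
            out.append(FastqRecord(title, seq, qual))
    return out


def write_fastq(path, records: Iterable[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.name}\n{rec.seq}\n+\n{rec.qual}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED line needs >= 3 columns", line=lineno)
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", line=lineno) from None
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return IntervalSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def write_bed(path, intervals: IntervalSet) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """4-column bedGraph -> DataFrame(chrom, start, end, value).

    Rejects overlapping intervals within a chromosome: a track where the same
    base carries two values is ambiguous and always indicates an upstream bug.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError("bedGraph line needs exactly 4 columns", line=lineno)
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"bad bedGraph value: {exc}", line=lineno) from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if len(grp) > 1 and (starts[1:] < ends[:-1]).any():
            bad = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
            raise FormatError(
                f"overlapping bedGraph intervals on {chrom} near position {starts[bad + 1]}"
            )
    return df


def write_bedgraph(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")


# ---------------------------------------------------------------------------
# TSV / chrom.sizes / JSON
# ---------------------------------------------------------------------------

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    """UCSC chrom.sizes dialect: two tab-separated columns, name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("chrom.sizes line needs 2 columns", line=lineno)
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
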