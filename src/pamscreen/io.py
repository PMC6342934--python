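"""Reading and writing the flat-file formats the pipeline speaks.

FASTQ/FASTA go through Biopython; gzip-compressed FASTQ is handled
transparently by extension.  Tables are TSV via pandas, with a ``#``-prefixed
header block for bookkeeping metadata (sample id, read totals and similar)
so a count table round-trips without a side-car file.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pam_extract import ReadRecord

DEFAULT_QUAL_CHAR = "I"  # Phred+33 Q40, constant placeholder quality


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate reads from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield ReadRecord(id=rec.id, seq=str(rec.seq).upper(), qual=qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as 4-line FASTQ; constant quality if a read has none."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = read.qual or DEFAULT_QUAL_CHAR * len(read.seq)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-)FASTA into an ordered name -> sequence mapping."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict[str, object] | None = None
) -> None:
    """Write a TSV with an optional ``# key=value`` metadata header block."""
    with _open_text(path, "wt") as handle:
        for key, value in (meta or {}).items():
            handle.write(f"# {key}={value}\n")
        df.to_csv(handle, sep="\t", index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    meta: dict[str, str] = {}
    lines = []
    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
    return df, meta
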