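"""Plain/gzipped FASTQ reading and writing for simulated reads."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    n = 0
    with _open_text(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs, reporting the record number on parse errors."""
    with _open_text(path, "r") as fh:
        record_no = 0
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                record_no += 1
                yield rec.id, str(rec.seq).upper()
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record {record_no + 1} in {path}: {exc}"
            ) from exc
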