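"""Minimal FASTQ IO (4-line records, optional gzip).

Errors name the offending record index so a truncated or corrupt file can be
located. gzip output is written with ``mtime=0`` so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

Read = tuple[str, str, str]  # (id, sequence, quality)


class FastqFormatError(ValueError):
    pass


def _open_text(path: str | Path, mode: str) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # mtime=0 keeps gzip output reproducible byte-for-byte
            return gzip.GzipFile(path, "wb", mtime=0)  # type: ignore[return-value]
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield (id, sequence, quality) per record; raise on malformed records."""
    with _open_text(path, "r") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(f"truncated FASTQ record at index {idx}")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@"):
                raise FastqFormatError(f"record {idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise FastqFormatError(f"record {idx}: separator line does not start with '+'")
            if len(seq) != len(qual):
                raise FastqFormatError(f"record {idx}: sequence/quality length mismatch")
            yield header[1:].split()[0], seq, qual
            idx += 1


def write_fastq(path: str | Path, reads: Iterable[Read]) -> int:
    """Write records; returns the number written."""
    n = 0
    path = str(path)
    if path.endswith(".gz"):
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            for rid, seq, qual in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n".encode())
                n += 1
    else:
        with open(path, "w") as fh:
            for rid, seq, qual in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
                n += 1
    return n
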