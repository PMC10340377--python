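"""Adapter and random-base trimming with the 16-nt minimum-length filter.

Matching policy: the leftmost occurrence of an adapter prefix wins, with a
minimum overlap of 7 nt; overlaps shorter than 10 nt must match exactly and
overlaps of 10+ nt tolerate one substitution (a deterministic stand-in for a
10% error-rate policy).  After adapter removal the configured number of
random bases is stripped from each end, and inserts shorter than 16 nt are
classified "too short" and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from ._fastq import Read, read_fastq, write_fastq
from .adapters import AdapterPattern

MIN_INSERT_LEN = 16
MIN_OVERLAP = 7
MISMATCH_FREE_BELOW = 10  # overlaps below this length must match exactly


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    insert: str
    status: str  # "kept" | "too_short" | "no_adapter"
    quality: str = ""


@dataclass
class TrimStats:
    n_input: int = 0
    n_kept: int = 0
    n_too_short: int = 0
    n_no_adapter: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_too_short": self.n_too_short,
            "n_no_adapter": self.n_no_adapter,
        }


def locate_adapter(seq: str, adapter: str) -> int | None:
    """Start index of the leftmost adapter-prefix occurrence, or None."""
    n = len(seq)
    alen = len(adapter)
    for j in range(n - MIN_OVERLAP + 1):
        overlap = min(alen, n - j)
        allowed = 1 if overlap >= MISMATCH_FREE_BELOW else 0
        mm = 0
        for k in range(overlap):
            if seq[j + k] != adapter[k]:
                mm += 1
                if mm > allowed:
                    break
        else:
            return j
    return None


def trim_read(
    read: Read | tuple[str, str],
    pattern: AdapterPattern,
    min_insert: int = MIN_INSERT_LEN,
) -> TrimmedRead:
    """Trim one read; every read yields a classified TrimmedRead."""
    rid, seq = read[0], read[1]
    qual = read[2] if len(read) > 2 else ""
    j = locate_adapter(seq, pattern.adapter3)
    if j is None:
        # Adapter absent: the insert may simply fill the read.  The 5' random
        # bases are still present and removable; the 3' ones are not (the read
        # ended inside the insert), so only the 5' end is stripped.
        insert = seq[pattern.rand5_len :]
        return TrimmedRead(rid, insert, "no_adapter", qual[pattern.rand5_len :])
    core = seq[:j]
    start = min(pattern.rand5_len, len(core))
    end = max(start, len(core) - pattern.rand3_len)
    insert = core[start:end]
    status = "kept" if len(insert) >= min_insert else "too_short"
    return TrimmedRead(rid, insert, status, qual[start:end])


def trim_reads(
    reads: Iterable[Read],
    pattern: AdapterPattern | None,
    min_insert: int = MIN_INSERT_LEN,
    discard_untrimmed: bool = False,
) -> tuple[list[TrimmedRead], TrimStats]:
    """Trim a read stream; returns emitted reads and partitioning stats.

    With ``pattern=None`` (no adapter detected for the library) every read
    passes through untrimmed and is counted as no_adapter.  no_adapter reads
    of sufficient length are emitted unless ``discard_untrimmed``.
    """
    stats = TrimStats()
    emitted: list[TrimmedRead] = []
    for read in reads:
        stats.n_input += 1
        if pattern is None:
            tr = TrimmedRead(read[0], read[1], "no_adapter", read[2] if len(read) > 2 else "")
        else:
            tr = trim_read(read, pattern, min_insert=min_insert)
        if tr.status == "kept":
            stats.n_kept += 1
            emitted.append(tr)
        elif tr.status == "too_short":
            stats.n_too_short += 1
        else:
            stats.n_no_adapter += 1
            if not discard_untrimmed and len(tr.insert) >= min_insert:
                emitted.append(tr)
    return emitted, stats


def trim_sample(
    fastq_in: str | Path,
    pattern: AdapterPattern | None,
    fastq_out: str | Path | None = None,
    min_insert: int = MIN_INSERT_LEN,
    discard_untrimmed: bool = False,
) -> tuple[list[TrimmedRead], TrimStats]:
    """Trim a FASTQ file, optionally writing the emitted inserts."""
    emitted, stats = trim_reads(
        read_fastq(fastq_in), pattern, min_insert=min_insert, discard_untrimmed=discard_untrimmed
    )
    if fastq_out is not None:
        write_fastq(
            fastq_out,
            ((t.read_id, t.insert, t.quality or "I" * len(t.insert)) for t in emitted),
        )
    return emitted, stats


def write_trim_stats(path: str | Path, stats_by_sample: dict[str, TrimStats]) -> None:
    rows = [{"sample_id": sid, **st.as_dict()} for sid, st in sorted(stats_by_sample.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
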