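"""Reference-free inference of the 3' adapter pattern of a small RNA library.

Small RNA library kits append a 3' sequencing adapter directly after the
insert and some (e.g. 4N protocols) add degenerate random bases at the 5'
and/or 3' ends of the insert.  Because public datasets rarely document the
kit, the pattern must be recovered from the reads themselves.

The approach is anchor-consensus: abundant, well-characterized miRNA
sequences from the host catalog serve as anchors.  Reads containing a full
anchor locate an insert precisely, so the bases before the anchor measure the
5' random-base length and the suffix after the anchor is (3' random bases +
adapter).  A positional base consensus over thousands of anchored suffixes
then calls the 3' random-base length (the shift at which the consensus locks
in) and the adapter sequence itself.  Only the read stream and the miRNA
anchor catalog are consulted — never kit metadata.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import ReferenceCatalog
from .kits import annotate_adapter

ANCHOR_SEED_LEN = 16
MAX_RAND_LEN = 8
MAX_ADAPTER_CALL_LEN = 30

DEFAULT_MAX_READS = 50_000
DEFAULT_MIN_ANCHORED = 100
DEFAULT_CONSENSUS_THRESHOLD = 0.8


@dataclass(frozen=True)
class AdapterPattern:
    """Inferred (or ground-truth) 3' adapter pattern of a library."""

    adapter3: str
    rand5_len: int = 0
    rand3_len: int = 0
    support_fraction: float = 1.0
    n_anchored: int = 0

    def __post_init__(self):
        if len(self.adapter3) < 8:
            raise ValueError("adapter3 must be at least 8 nt")
        if not (0 <= self.rand5_len <= MAX_RAND_LEN and 0 <= self.rand3_len <= MAX_RAND_LEN):
            raise ValueError(f"random-base lengths must be in [0, {MAX_RAND_LEN}]")
        if not 0.0 <= self.support_fraction <= 1.0:
            raise ValueError("support_fraction must be in [0, 1]")

    @property
    def kit_annotation(self) -> str | None:
        return annotate_adapter(self.adapter3)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["kit_annotation"] = self.kit_annotation
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AdapterPattern":
        data = json.loads(Path(path).read_text())
        data.pop("kit_annotation", None)
        return cls(**data)


AnchorHit = tuple[int, str]  # (prefix_offset, suffix after the full anchor)


def collect_anchor_hits(
    reads: Iterable[str | tuple],
    anchors: ReferenceCatalog | Sequence[str],
    max_reads: int = DEFAULT_MAX_READS,
) -> list[AnchorHit]:
    """Scan up to ``max_reads`` reads for exact full-anchor occurrences.

    A read is anchored when the 16-nt seed of some anchor occurs exactly and
    the full anchor sequence matches at that position.  Emits, per anchored
    read, the anchor start offset (candidate 5' random-base length) and the
    suffix following the anchor (candidate 3' random bases + adapter).
    Returns an empty list when nothing anchors.
    """
    if max_reads < 1:
        raise ValueError("max_reads must be >= 1")
    if isinstance(anchors, ReferenceCatalog):
        anchor_seqs = [e.sequence for e in anchors.entries if e.biotype == "miRNA"]
    else:
        anchor_seqs = list(anchors)
    if not anchor_seqs:
        raise ValueError("anchor catalog contains no miRNA sequences")

    seed_map: dict[str, list[str]] = {}
    for seq in anchor_seqs:
        seed_map.setdefault(seq[:ANCHOR_SEED_LEN], []).append(seq)

    hits: list[AnchorHit] = []
    for n_scanned, read in enumerate(reads):
        if n_scanned >= max_reads:
            break
        seq = read if isinstance(read, str) else read[1]
        found = False
        for i in range(len(seq) - ANCHOR_SEED_LEN + 1):
            candidates = seed_map.get(seq[i : i + ANCHOR_SEED_LEN])
            if not candidates:
                continue
            for anchor in candidates:
                if seq.startswith(anchor, i):
                    hits.append((i, seq[i + len(anchor):]))
                    found = True
                    break
            if found:
                break
    return hits


def _majority(counter: Counter) -> tuple[str, int]:
    """Majority base with lexicographic tie-break."""
    best_base, best_n = "", -1
    for base in "ACGT":
        n = counter.get(base, 0)
        if n > best_n:
            best_base, best_n = base, n
    return best_base, best_n


def infer_adapter_pattern(
    hits: Sequence[AnchorHit],
    min_anchored: int = DEFAULT_MIN_ANCHORED,
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> AdapterPattern | None:
    """Call the adapter pattern from anchor hits, or None when undetectable.

    rand5_len is the modal anchor offset (ties -> smaller offset).  rand3_len
    is the smallest shift s in [0, 8] at which every one of the first 8
    suffix positions from s has a majority-base fraction of at least
    ``consensus_threshold`` — a random-base column never approaches the
    threshold (its majority fraction hovers near 1/4), so the consensus locks
    in exactly when the shift skips past the random bases.  The adapter is
    then the per-position majority base
    from s on, truncated at the first position covered by fewer than
    min_anchored/2 suffixes or at 30 nt.
    """
    if not (0.5 < consensus_threshold <= 1.0):
        raise ValueError("consensus_threshold must be in (0.5, 1]")
    n_anchored = len(hits)
    if n_anchored < min_anchored:
        return None

    offsets = Counter(off for off, _ in hits)
    rand5_len = min(off for off, n in offsets.items() if n == max(offsets.values()))

    suffixes = [suf for _, suf in hits]
    columns: list[Counter] = []
    max_len = max((len(s) for s in suffixes), default=0)
    for p in range(max_len):
        columns.append(Counter(s[p] for s in suffixes if len(s) > p))

    rand3_len = None
    for s in range(MAX_RAND_LEN + 1):
        fracs = []
        for p in range(s, s + 8):
            if p >= len(columns) or not columns[p]:
                fracs.append(0.0)
                continue
            total = sum(columns[p].values())
            _, best_n = _majority(columns[p])
            fracs.append(best_n / total)
        if min(fracs) >= consensus_threshold:
            rand3_len = s
            break
    if rand3_len is None:
        return None

    min_coverage = min_anchored / 2
    adapter_bases: list[str] = []
    for p in range(rand3_len, len(columns)):
        if len(adapter_bases) >= MAX_ADAPTER_CALL_LEN:
            break
        col = columns[p]
        if sum(col.values()) < min_coverage:
            break
        base, _ = _majority(col)
        adapter_bases.append(base)
    adapter3 = "".join(adapter_bases)
    if len(adapter3) < 8:
        return None

    check_len = min(10, len(adapter3))
    n_consistent = 0
    for off, suf in hits:
        if off != rand5_len:
            continue
        window = suf[rand3_len : rand3_len + check_len]
        if len(window) < min(7, check_len):
            continue
        mm = sum(a != b for a, b in zip(window, adapter3))
        if mm <= 1:
            n_consistent += 1
    return AdapterPattern(
        adapter3=adapter3,
        rand5_len=rand5_len,
        rand3_len=rand3_len,
        support_fraction=n_consistent / n_anchored,
        n_anchored=n_anchored,
    )


def find_adapter(
    reads: Iterable[str | tuple],
    anchors: ReferenceCatalog | Sequence[str],
    max_reads: int = DEFAULT_MAX_READS,
    min_anchored: int = DEFAULT_MIN_ANCHORED,
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> AdapterPattern | None:
    """Convenience wrapper: collect anchor hits, then call the pattern."""
    hits = collect_anchor_hits(reads, anchors, max_reads=max_reads)
    return infer_adapter_pattern(
        hits, min_anchored=min_anchored, consensus_threshold=consensus_threshold
    )
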