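"""Reference catalogs of small-RNA sequences labeled by biotype and origin.

A catalog stands in for the host genome + curated mature-transcript databases
(miRBase-style miRNAs, GtRNAdb-style tRNAs, ...) that a production small
RNA-seq pipeline aligns against, plus a miniature non-host (exogenous) decoy
set.  Sequences are random but mutually separated in Hamming distance so that
1-mismatch read assignment is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kits import KNOWN_ADAPTERS

ALPHABET = "ACGT"

#: Host small-RNA biotypes, ordered by assignment priority (miRNA first).
BIOTYPES = (
    "miRNA",
    "tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "YRNA",
    "mt_tRNA",
    "lincRNA",
    "misc",
    "host_other",
)

#: The eight composition classes; lincRNA and host_other are handled separately.
COMPOSITION_CLASSES = ("miRNA", "tRNA", "rRNA", "YRNA", "snRNA", "snoRNA", "mt_tRNA", "misc")

MIN_SEQ_LEN = 16

# Typical catalog sequence lengths per biotype (nt).  rRNA/tRNA (and anything
# longer than a read insert) are stored full length; reads sample fragments.
DEFAULT_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "miRNA": (20, 24),
    "tRNA": (70, 90),
    "rRNA": (90, 120),
    "snRNA": (24, 34),
    "snoRNA": (24, 34),
    "YRNA": (24, 34),
    "mt_tRNA": (20, 30),
    "lincRNA": (25, 35),
    "misc": (20, 30),
    "host_other": (60, 80),
}

DEFAULT_N_PER_BIOTYPE: dict[str, int] = {
    "miRNA": 30,
    "tRNA": 8,
    "rRNA": 6,
    "snRNA": 5,
    "snoRNA": 5,
    "YRNA": 5,
    "mt_tRNA": 4,
    "lincRNA": 4,
    "misc": 4,
    "host_other": 5,
}


@dataclass(frozen=True)
class CatalogEntry:
    feature_id: str
    sequence: str
    biotype: str
    origin: str  # "host" | "nonhost"


class CatalogError(ValueError):
    pass


class ReferenceCatalog:
    """Immutable collection of labeled small-RNA sequences."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self.entries: list[CatalogEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.feature_id in seen:
                raise CatalogError(f"duplicate feature_id {e.feature_id!r}")
            seen.add(e.feature_id)
            if len(e.sequence) < MIN_SEQ_LEN:
                raise CatalogError(f"{e.feature_id}: sequence shorter than {MIN_SEQ_LEN} nt")
            if set(e.sequence) - set(ALPHABET):
                raise CatalogError(f"{e.feature_id}: non-ACGT characters in sequence")
            if e.biotype not in BIOTYPES:
                raise CatalogError(f"{e.feature_id}: unknown biotype {e.biotype!r}")
            if e.origin not in ("host", "nonhost"):
                raise CatalogError(f"{e.feature_id}: origin must be host or nonhost")
        self._by_id = {e.feature_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, feature_id: str) -> CatalogEntry:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def subset(self, origin: str | None = None, biotype: str | None = None) -> "ReferenceCatalog":
        return ReferenceCatalog(
            e
            for e in self.entries
            if (origin is None or e.origin == origin)
            and (biotype is None or e.biotype == biotype)
        )

    @property
    def host_entries(self) -> list[CatalogEntry]:
        return [e for e in self.entries if e.origin == "host"]

    @property
    def nonhost_entries(self) -> list[CatalogEntry]:
        return [e for e in self.entries if e.origin == "nonhost"]

    def biotypes_present(self, origin: str | None = None) -> set[str]:
        return {e.biotype for e in self.entries if origin is None or e.origin == origin}

    # ------------------------------------------------------------------ IO
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(e.sequence),
                id=e.feature_id,
                description=f"biotype={e.biotype} origin={e.origin}",
            )
            for e in self.entries
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, default_origin: str = "host") -> "ReferenceCatalog":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            tags = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            entries.append(
                CatalogEntry(
                    feature_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    biotype=tags.get("biotype", "misc"),
                    origin=tags.get("origin", default_origin),
                )
            )
        return cls(entries)


# -------------------------------------------------------------- generation

def _min_cross_distance(seq: str, other: str) -> int:
    """Minimum Hamming distance over all full placements of the shorter
    sequence inside the longer (both orders handled by the caller's loop)."""
    short, long_ = (seq, other) if len(seq) <= len(other) else (other, seq)
    n = len(short)
    best = n
    for off in range(len(long_) - n + 1):
        d = sum(a != b for a, b in zip(short, long_[off : off + n]))
        if d < best:
            best = d
            if best == 0:
                return 0
    return best


_ADAPTER_SEEDS = [a[:8] for a in KNOWN_ADAPTERS]


def _contains_adapter_seed(seq: str) -> bool:
    return any(seed in seq for seed in _ADAPTER_SEEDS)


def generate_catalog(
    seed: int,
    n_per_biotype: Mapping[str, int] | None = None,
    length_range: tuple[int, int] | None = None,
    origin: str = "host",
    min_distance: int = 3,
    id_prefix: str | None = None,
) -> ReferenceCatalog:
    """Generate a random reference catalog.

    Sequences are drawn uniformly over ACGT, rejected if within Hamming
    distance ``min_distance`` of any accepted sequence (sliding the shorter
    over the longer) or if they contain the first 8 nt of a common library
    adapter — reads simulated from an adapter-free catalog trim unambiguously.
    Deterministic given ``seed``.
    """
    if n_per_biotype is None:
        n_per_biotype = DEFAULT_N_PER_BIOTYPE
    if length_range is not None and length_range[0] < MIN_SEQ_LEN:
        raise CatalogError(f"length_range minimum must be >= {MIN_SEQ_LEN}")
    for bt, n in n_per_biotype.items():
        if bt not in BIOTYPES:
            raise CatalogError(f"unknown biotype {bt!r}")
        if n < 0:
            raise CatalogError("counts must be >= 0")

    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else ("nh" if origin == "nonhost" else "")
    entries: list[CatalogEntry] = []
    accepted: list[str] = []
    for biotype in BIOTYPES:  # fixed order for determinism
        count = n_per_biotype.get(biotype, 0)
        lo, hi = length_range if length_range is not None else DEFAULT_LENGTH_RANGES[biotype]
        for i in range(count):
            for _attempt in range(200):
                length = int(rng.integers(lo, hi + 1))
                seq = "".join(ALPHABET[b] for b in rng.integers(0, 4, size=length))
                if _contains_adapter_seed(seq):
                    continue
                if all(_min_cross_distance(seq, s) >= min_distance for s in accepted):
                    break
            else:  # pragma: no cover - astronomically unlikely for random seqs
                raise CatalogError("could not generate a well-separated sequence")
            accepted.append(seq)
            entries.append(
                CatalogEntry(
                    feature_id=f"{prefix}{biotype}_{i + 1:03d}",
                    sequence=seq,
                    biotype=biotype,
                    origin=origin,
                )
            )
    return ReferenceCatalog(entries)


def default_catalog(seed: int, n_nonhost: int = 6) -> ReferenceCatalog:
    """Host catalog with every biotype plus a small non-host decoy set."""
    host = generate_catalog(seed, DEFAULT_N_PER_BIOTYPE)
    nonhost = generate_catalog(
        np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31),
        {"misc": n_nonhost},
        length_range=(60, 80),
        origin="nonhost",
    )
    return ReferenceCatalog(host.entries + nonhost.entries)
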