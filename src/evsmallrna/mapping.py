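"""Hierarchical assignment of trimmed inserts to small-RNA biotypes.

Two-tier mapping: inserts are first matched against the host catalog allowing
at most one substitution (no indels); host-unmapped inserts longer than 19 nt
are then matched exactly against the non-host catalog; the rest are unmapped.
Matching is substring search against catalog sequences — the deterministic,
desk-scale equivalent of a -v-style short-read aligner.

Reads hitting several features count once at biotype level (highest-priority
biotype wins: miRNA > tRNA > rRNA > snRNA > snoRNA > YRNA > mt-tRNA >
lincRNA > misc > host_other) and fractionally (1/k) at feature level, so
biotype counts stay a partition while feature-level mass is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import BIOTYPES, CatalogEntry, ReferenceCatalog
from .trimming import MIN_INSERT_LEN, TrimmedRead

#: Assignment priority (first = highest).  Configurable via ``priority=``.
DEFAULT_PRIORITY = tuple(bt for bt in BIOTYPES)

NONHOST_MIN_LEN = 20  # only inserts longer than 19 nt reach the non-host tier


@dataclass(frozen=True)
class AlignmentHit:
    feature_id: str
    biotype: str
    origin: str
    n_mismatches: int


def _best_substring_mismatches(insert: str, target: str, max_mm: int = 1) -> int | None:
    """Minimum substitutions over all full placements of ``insert`` in
    ``target`` (pigeonhole seed-and-verify; no indels), or None if > max_mm."""
    n, m = len(insert), len(target)
    if n > m:
        return None
    if insert in target:
        return 0
    if max_mm < 1:
        return None
    # Any 1-mismatch placement matches one half of the insert exactly.
    half = n // 2
    first, second = insert[:half], insert[half:]
    starts: set[int] = set()
    pos = target.find(first)
    while pos != -1:
        starts.add(pos)
        pos = target.find(first, pos + 1)
    pos = target.find(second)
    while pos != -1:
        if pos - half >= 0:
            starts.add(pos - half)
        pos = target.find(second, pos + 1)
    best: int | None = None
    for s in starts:
        if s + n > m:
            continue
        mm = 0
        window = target[s : s + n]
        for a, b in zip(insert, window):
            if a != b:
                mm += 1
                if mm > 1:
                    break
        else:
            if best is None or mm < best:
                best = mm
                if best == 0:
                    return 0
    return best


def align_host(
    insert: str, entries: Sequence[CatalogEntry] | ReferenceCatalog
) -> list[AlignmentHit]:
    """Best-stratum host hits (<=1 substitution; 0-mm hits suppress 1-mm)."""
    if len(insert) < MIN_INSERT_LEN:
        raise ValueError(
            f"insert shorter than {MIN_INSERT_LEN} nt reached mapping: {insert!r}"
        )
    if isinstance(entries, ReferenceCatalog):
        entries = entries.host_entries
    hits: list[AlignmentHit] = []
    for e in entries:
        mm = _best_substring_mismatches(insert, e.sequence, max_mm=1)
        if mm is not None:
            hits.append(AlignmentHit(e.feature_id, e.biotype, "host", mm))
    if any(h.n_mismatches == 0 for h in hits):
        hits = [h for h in hits if h.n_mismatches == 0]
    return hits


def align_nonhost(
    insert: str, entries: Sequence[CatalogEntry] | ReferenceCatalog
) -> list[AlignmentHit]:
    """Exact-substring non-host hits; inserts of <= 19 nt are not searched."""
    if isinstance(entries, ReferenceCatalog):
        entries = entries.nonhost_entries
    if len(insert) < NONHOST_MIN_LEN:
        return []
    return [
        AlignmentHit(e.feature_id, e.biotype, "nonhost", 0)
        for e in entries
        if insert in e.sequence
    ]


def assign_biotype(
    hits: Sequence[AlignmentHit], priority: Sequence[str] = DEFAULT_PRIORITY
) -> tuple[str, list[str]] | None:
    """Resolve one insert's best-stratum hits to (biotype, tied features).

    Returns None for an empty hit list (insert proceeds to the next tier or
    stays unmapped).  Deterministic under any permutation of ``hits``.
    """
    if not hits:
        return None
    present = {h.biotype for h in hits}
    rank = {bt: i for i, bt in enumerate(priority)}
    chosen = min(present, key=lambda bt: rank.get(bt, len(rank)))
    features = sorted({h.feature_id for h in hits if h.biotype == chosen})
    return chosen, features


@dataclass
class SampleProfile:
    """Per-sample read fates, biotype counts, and feature counts — the unit
    of all downstream statistics."""

    sample_id: str
    n_trimmed_kept: int = 0
    n_host: int = 0
    n_nonhost: int = 0
    n_unmapped: int = 0
    biotype_counts: dict[str, int] = field(default_factory=dict)
    feature_counts: dict[str, float] = field(default_factory=dict)
    zero_input_warning: bool = False

    def __post_init__(self):
        for bt in BIOTYPES:
            self.biotype_counts.setdefault(bt, 0)

    def check_invariants(self) -> None:
        assert self.n_trimmed_kept == self.n_host + self.n_nonhost + self.n_unmapped
        assert sum(self.biotype_counts.values()) == self.n_host

    @property
    def cpm(self) -> dict[str, float]:
        """Counts per million kept reads, per feature (0 when no reads)."""
        if self.n_trimmed_kept == 0:
            return {f: 0.0 for f in self.feature_counts}
        scale = 1e6 / self.n_trimmed_kept
        return {f: c * scale for f, c in self.feature_counts.items()}

    # --------------------------------------------------------------- IO
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        bio = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "biotype": list(BIOTYPES),
                "count": [self.biotype_counts[bt] for bt in BIOTYPES],
            }
        )
        cpm = self.cpm
        feat = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "feature_id": sorted(self.feature_counts),
                "count": [self.feature_counts[f] for f in sorted(self.feature_counts)],
                "cpm": [cpm[f] for f in sorted(self.feature_counts)],
            }
        )
        return bio, feat

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bio, feat = self.to_frames()
        header = pd.DataFrame(
            [
                {
                    "sample_id": self.sample_id,
                    "n_trimmed_kept": self.n_trimmed_kept,
                    "n_host": self.n_host,
                    "n_nonhost": self.n_nonhost,
                    "n_unmapped": self.n_unmapped,
                }
            ]
        )
        header.to_csv(out_dir / f"{self.sample_id}.summary.tsv", sep="\t", index=False)
        bio.to_csv(out_dir / f"{self.sample_id}.biotypes.tsv", sep="\t", index=False)
        feat.to_csv(
            out_dir / f"{self.sample_id}.features.tsv",
            sep="\t",
            index=False,
            float_format="%.6g",
        )

    @classmethod
    def read(cls, out_dir: str | Path, sample_id: str) -> "SampleProfile":
        out_dir = Path(out_dir)
        header = pd.read_csv(out_dir / f"{sample_id}.summary.tsv", sep="\t").iloc[0]
        bio = pd.read_csv(out_dir / f"{sample_id}.biotypes.tsv", sep="\t")
        feat = pd.read_csv(out_dir / f"{sample_id}.features.tsv", sep="\t")
        return cls(
            sample_id=sample_id,
            n_trimmed_kept=int(header["n_trimmed_kept"]),
            n_host=int(header["n_host"]),
            n_nonhost=int(header["n_nonhost"]),
            n_unmapped=int(header["n_unmapped"]),
            biotype_counts=dict(zip(bio["biotype"], bio["count"].astype(int))),
            feature_counts=dict(zip(feat["feature_id"], feat["count"].astype(float))),
        )


def quantify_sample(
    inserts: Iterable[TrimmedRead | str],
    host_catalog: ReferenceCatalog | Sequence[CatalogEntry],
    nonhost_catalog: ReferenceCatalog | Sequence[CatalogEntry] | None = None,
    sample_id: str = "S",
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> SampleProfile:
    """Map kept inserts through both tiers and tally the SampleProfile."""
    host_entries = (
        host_catalog.host_entries
        if isinstance(host_catalog, ReferenceCatalog)
        else list(host_catalog)
    )
    if nonhost_catalog is None and isinstance(host_catalog, ReferenceCatalog):
        nonhost_entries: Sequence[CatalogEntry] = host_catalog.nonhost_entries
    elif isinstance(nonhost_catalog, ReferenceCatalog):
        nonhost_entries = nonhost_catalog.nonhost_entries or nonhost_catalog.entries
    else:
        nonhost_entries = list(nonhost_catalog or [])

    profile = SampleProfile(sample_id=sample_id)
    for item in inserts:
        insert = item if isinstance(item, str) else item.insert
        profile.n_trimmed_kept += 1
        hits = align_host(insert, host_entries)
        assigned = assign_biotype(hits, priority=priority)
        if assigned is not None:
            biotype, features = assigned
            profile.n_host += 1
            profile.biotype_counts[biotype] += 1
            share = 1.0 / len(features)
            for f in features:
                profile.feature_counts[f] = profile.feature_counts.get(f, 0.0) + share
            continue
        nh = align_nonhost(insert, nonhost_entries)
        if nh:
            profile.n_nonhost += 1
        else:
            profile.n_unmapped += 1
    if profile.n_trimmed_kept == 0:
        profile.zero_input_warning = True
    profile.check_invariants()
    return profile
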