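"""Sample manifest: study design table for a multi-study EV corpus.

One row per sequencing sample: which study it belongs to, whether it profiles
vesicles (EV) or matched donor cells, the donor source, the EV isolation
method, the RNA kit, and an optional pair id linking a matched EV/cell pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

COMPARTMENTS = ("EV", "cell")
SOURCES = ("biofluid", "cell_line", "primary_culture")

#: The six EV isolation methods covered by the corpus.
ISOLATION_METHODS = (
    "ExoQuick",
    "ExoEasy",
    "ExoRNeasy",
    "qEV",
    "TotalExosomeIsolation",
    "Ultracentrifugation",
)

MANIFEST_COLUMNS = [
    "sample_id",
    "study_id",
    "compartment",
    "source",
    "biofluid_name",
    "isolation_method",
    "rna_kit",
    "pair_id",
]


class ManifestError(ValueError):
    pass


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ManifestError(f"duplicate sample_id {dup!r}")
    bad = set(df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ManifestError(f"unknown compartment values: {sorted(bad)}")
    bad = set(df["isolation_method"]) - set(ISOLATION_METHODS)
    if bad:
        raise ManifestError(f"unknown isolation_method values: {sorted(bad)}")
    paired = df[df["pair_id"].notna() & (df["pair_id"] != "")]
    for pid, grp in paired.groupby("pair_id"):
        comps = sorted(grp["compartment"])
        if comps != ["EV", "cell"]:
            raise ManifestError(
                f"pair_id {pid!r} must link exactly one EV and one cell sample"
            )
    return df


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace({"pair_id": {"": None}, "biofluid_name": {"": None}})
    return validate_manifest(df)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("pair_id", "biofluid_name"):
        out[col] = out[col].fillna("")
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ManifestSummary:
    n_samples: int
    n_studies: int
    n_ev_samples: int
    n_cell_samples: int
    n_ev_only_studies: int
    n_paired_studies: int


def summarize_manifest(df: pd.DataFrame) -> ManifestSummary:
    """Corpus-level counts: studies, samples, and the EV subset."""
    validate_manifest(df)
    per_study = df.groupby("study_id")["compartment"].agg(lambda c: set(c))
    n_paired = int(sum("cell" in s for s in per_study))
    return ManifestSummary(
        n_samples=len(df),
        n_studies=int(df["study_id"].nunique()),
        n_ev_samples=int((df["compartment"] == "EV").sum()),
        n_cell_samples=int((df["compartment"] == "cell").sum()),
        n_ev_only_studies=int(sum("cell" not in s for s in per_study)),
        n_paired_studies=n_paired,
    )
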