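"""Small-RNA composition: eight-class proportions and diagnostic log ratios.

Proportions are computed over total small-RNA reads (every host biotype
except host_other) across eight classes: miRNA, tRNA, rRNA, Y RNA, snRNA,
snoRNA, mt-tRNA, and misc; lincRNA and any other residual class are folded
into misc so the proportions form a true partition.  Two diagnostic ratios —
log2 miRNA/rRNA and log2 Y RNA/tRNA — use a +1 pseudocount on both counts so
they stay finite for all inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import COMPOSITION_CLASSES
from .mapping import SampleProfile


@dataclass
class CompositionProfile:
    sample_id: str
    proportions: dict[str, float]
    log2_mirna_rrna: float
    log2_yrna_trna: float
    no_smallrna_warning: bool = False


def biotype_proportions(profile: SampleProfile) -> CompositionProfile:
    """Eight-class composition of one sample's small-RNA reads."""
    counts = {bt: 0 for bt in COMPOSITION_CLASSES}
    for bt, c in profile.biotype_counts.items():
        if bt == "host_other":
            continue
        key = bt if bt in counts else "misc"  # lincRNA and residuals -> misc
        counts[key] += c
    total = sum(counts.values())
    if total == 0:
        props = {bt: 0.0 for bt in COMPOSITION_CLASSES}
        warn = True
    else:
        props = {bt: c / total for bt, c in counts.items()}
        warn = False
    return CompositionProfile(
        sample_id=profile.sample_id,
        proportions=props,
        log2_mirna_rrna=float(np.log2((counts["miRNA"] + 1) / (counts["rRNA"] + 1))),
        log2_yrna_trna=float(np.log2((counts["YRNA"] + 1) / (counts["tRNA"] + 1))),
        no_smallrna_warning=warn,
    )


def profiles_to_frame(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id}
        row.update({bt: p.proportions[bt] for bt in COMPOSITION_CLASSES})
        row["log2_mirna_rrna"] = p.log2_mirna_rrna
        row["log2_yrna_trna"] = p.log2_yrna_trna
        rows.append(row)
    return pd.DataFrame(rows)


def ratio_summary(
    profiles: Sequence[CompositionProfile],
    study_by_sample: Mapping[str, str],
    indicator_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-study median log2 ratios, with an indicator for median > 1.

    A study whose median log2(miRNA/rRNA) exceeds 1 has miRNA reads more
    than twice as abundant as rRNA fragments in a typical sample.
    """
    rows: dict[str, dict[str, list[float]]] = {}
    for p in profiles:
        study = study_by_sample[p.sample_id]
        d = rows.setdefault(study, {"mirna_rrna": [], "yrna_trna": []})
        d["mirna_rrna"].append(p.log2_mirna_rrna)
        d["yrna_trna"].append(p.log2_yrna_trna)
    out = []
    for study in sorted(rows):
        med_mr = float(np.median(rows[study]["mirna_rrna"]))
        med_yt = float(np.median(rows[study]["yrna_trna"]))
        out.append(
            {
                "study_id": study,
                "n_samples": len(rows[study]["mirna_rrna"]),
                "median_log2_mirna_rrna": med_mr,
                "median_log2_yrna_trna": med_yt,
                "mirna_rrna_above_1": med_mr > indicator_threshold,
                "yrna_trna_above_1": med_yt > indicator_threshold,
            }
        )
    return pd.DataFrame(out)


def compare_composition_groups(
    values_by_group: Mapping[str, Sequence[float]],
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Welch t-tests on per-study summary values between groups.

    With ``reference_group`` set, contrasts every other group against it;
    otherwise all pairwise contrasts.  Groups with fewer than 2 studies are
    skipped (recorded with NaN statistics).
    """
    names = sorted(values_by_group)
    if reference_group is not None:
        pairs = [(g, reference_group) for g in names if g != reference_group]
    else:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        va, vb = list(values_by_group[a]), list(values_by_group[b])
        if len(va) < 2 or len(vb) < 2:
            rows.append(
                {"group_a": a, "group_b": b, "n_a": len(va), "n_b": len(vb),
                 "t": np.nan, "p": np.nan, "skipped": True}
            )
            continue
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append(
            {"group_a": a, "group_b": b, "n_a": len(va), "n_b": len(vb),
             "t": float(t), "p": float(p), "skipped": False}
        )
    return pd.DataFrame(rows)
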