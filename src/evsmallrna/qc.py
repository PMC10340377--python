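"""Per-sample QC metrics, gate flags, and study-level variability summaries.

Metric definitions: overall mapping rate = (host + non-host reads) / trimmed
reads; host fraction = host reads / trimmed reads; small-RNA fraction = small
RNA reads / host reads (small RNA = every host biotype except host_other);
miRNA fraction = miRNA reads / host reads.  Zero denominators yield a
fraction of 0 plus the corresponding flag.

Default gates (each direction fixed and configurable):
  low_reads        trimmed reads <= 100,000   (fails "more than 100,000")
  low_overall_map  overall mapping rate < 0.20
  low_host_reads   host reads < 100,000
  low_host_frac    host fraction <= 0.50      (fails "greater than 50%")
  low_smallrna     small-RNA fraction < 0.75
  low_mirna        miRNA fraction < 0.10
A study is excluded when strictly more than half of its samples carry
low_smallrna or low_mirna.  Study variability is summarized by the median
and IQR of small-RNA proportions; a study is "high quality" when the median
exceeds 0.9 and the IQR is below 0.06.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import SampleProfile

ALL_FLAGS = (
    "low_reads",
    "low_overall_map",
    "low_host_reads",
    "low_host_frac",
    "low_smallrna",
    "low_mirna",
)


@dataclass(frozen=True)
class QCThresholds:
    min_reads: int = 100_000          # flag when n_trimmed <= min_reads
    min_overall_map: float = 0.20     # flag when rate < min_overall_map
    min_host_reads: int = 100_000     # flag when n_host < min_host_reads
    min_host_frac: float = 0.50       # flag when host_frac <= min_host_frac
    min_smallrna: float = 0.75        # flag when smallrna_frac < min_smallrna
    min_mirna: float = 0.10           # flag when mirna_frac < min_mirna

    def __post_init__(self):
        for name in ("min_reads", "min_overall_map", "min_host_reads",
                     "min_host_frac", "min_smallrna", "min_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    sample_id: str
    n_trimmed: int
    overall_map_rate: float
    n_host: int
    host_frac: float
    smallrna_frac_of_host: float
    mirna_frac_of_host: float
    flags: set[str] = field(default_factory=set)

    @property
    def failed_content(self) -> bool:
        """Fails the small-RNA / miRNA content rules (drives study exclusion)."""
        return bool({"low_smallrna", "low_mirna"} & self.flags)


def compute_qc(profile: SampleProfile) -> QCReport:
    """QC metrics for one sample profile (flags not yet applied)."""
    n_trimmed = profile.n_trimmed_kept
    n_host = profile.n_host
    smallrna = n_host - profile.biotype_counts.get("host_other", 0)
    mirna = profile.biotype_counts.get("miRNA", 0)
    return QCReport(
        sample_id=profile.sample_id,
        n_trimmed=n_trimmed,
        overall_map_rate=(n_host + profile.n_nonhost) / n_trimmed if n_trimmed else 0.0,
        n_host=n_host,
        host_frac=n_host / n_trimmed if n_trimmed else 0.0,
        smallrna_frac_of_host=smallrna / n_host if n_host else 0.0,
        mirna_frac_of_host=mirna / n_host if n_host else 0.0,
    )


def flag_sample(report: QCReport, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Apply the QC gates; each flag is present iff its gate fails."""
    flags = set()
    if report.n_trimmed <= thresholds.min_reads:
        flags.add("low_reads")
    if report.overall_map_rate < thresholds.min_overall_map:
        flags.add("low_overall_map")
    if report.n_host < thresholds.min_host_reads:
        flags.add("low_host_reads")
    if report.host_frac <= thresholds.min_host_frac:
        flags.add("low_host_frac")
    if report.smallrna_frac_of_host < thresholds.min_smallrna:
        flags.add("low_smallrna")
    if report.mirna_frac_of_host < thresholds.min_mirna:
        flags.add("low_mirna")
    report.flags = flags
    return report


def qc_report(profile: SampleProfile, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    return flag_sample(compute_qc(profile), thresholds)


def flag_study(reports: Sequence[QCReport]) -> bool:
    """True iff strictly more than half of the samples fail the content rules."""
    if not reports:
        raise ValueError("study has no samples")
    n_fail = sum(r.failed_content for r in reports)
    return n_fail > len(reports) / 2


@dataclass
class StudySummary:
    study_id: str
    n_samples: int
    median_smallrna_prop: float
    iqr_smallrna_prop: float
    excluded: bool
    label: str  # high_quality | variable | excluded
    single_sample_warning: bool = False


def study_variability(
    props_by_study: Mapping[str, Sequence[float]],
    excluded: Mapping[str, bool] | None = None,
    median_threshold: float = 0.9,
    iqr_threshold: float = 0.06,
) -> list[StudySummary]:
    """Median and IQR (linear-interpolation quantiles) of small-RNA
    proportions per study, labeled high_quality / variable / excluded."""
    summaries = []
    for study_id in sorted(props_by_study):
        props = np.asarray(list(props_by_study[study_id]), dtype=float)
        if props.size == 0:
            raise ValueError(f"study {study_id!r} has no samples")
        if ((props < 0) | (props > 1)).any():
            raise ValueError(f"study {study_id!r}: proportions outside [0, 1]")
        median = float(np.median(props))
        q1, q3 = np.percentile(props, [25, 75])  # linear interpolation
        iqr = float(q3 - q1)
        is_excluded = bool(excluded.get(study_id, False)) if excluded else False
        if is_excluded:
            label = "excluded"
        elif median > median_threshold and iqr < iqr_threshold:
            label = "high_quality"
        else:
            label = "variable"
        summaries.append(
            StudySummary(
                study_id=study_id,
                n_samples=int(props.size),
                median_smallrna_prop=median,
                iqr_smallrna_prop=iqr,
                excluded=is_excluded,
                label=label,
                single_sample_warning=props.size == 1,
            )
        )
    return summaries


def compare_study_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test on per-study summary values -> (t, p)."""
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least 2 studies")
    t, p = stats.ttest_ind(values_a, values_b, equal_var=False)
    return float(t), float(p)


# ----------------------------------------------------------------- IO

def reports_to_frame(reports: Iterable[QCReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "sample_id": r.sample_id,
            "n_trimmed": r.n_trimmed,
            "overall_map_rate": r.overall_map_rate,
            "n_host": r.n_host,
            "host_frac": r.host_frac,
            "smallrna_frac_of_host": r.smallrna_frac_of_host,
            "mirna_frac_of_host": r.mirna_frac_of_host,
        }
        for f in ALL_FLAGS:
            row[f] = f in r.flags
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Iterable[StudySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": s.study_id,
                "n_samples": s.n_samples,
                "median_smallrna_prop": s.median_smallrna_prop,
                "iqr_smallrna_prop": s.iqr_smallrna_prop,
                "excluded": s.excluded,
                "label": s.label,
            }
            for s in summaries
        ]
    )
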