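"""EV-versus-donor-cell enrichment: which small RNAs are preferentially
loaded into vesicles?

Three layers of analysis:

* **Biotype level** — for each biotype, a three-factor least-squares ANOVA of
  per-sample proportions on compartment (EV vs cell), EV isolation method
  (the technical confounder), and study, with a type-II F-test on the
  compartment term.  Main effects only, untransformed proportions.
* **miRNA level, within study** — a per-feature negative-binomial log-linear
  model of raw counts on compartment + isolation method with a log
  library-size offset (method-of-moments dispersion floored at 0.01, Wald
  test on the compartment coefficient, Benjamini-Hochberg FDR).  A feature is
  significantly differential when FDR < 0.05 and |fold change| > 1.5.
* **Across studies** — export classification: a miRNA that is EV-enriched in
  every study where it is testable is a context-independent EV cargo;
  symmetric for cell retention; anything significant somewhere but not
  everywhere is study-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

LOG2_FC_THRESHOLD = np.log2(1.5)
FDR_THRESHOLD = 0.05
DISPERSION_FLOOR = 0.01
DISPERSION_CEILING = 10.0


# --------------------------------------------------------- biotype ANOVA

@dataclass
class BiotypeEnrichmentResult:
    biotype: str
    direction: str  # enriched_in_EV | depleted_in_EV | none
    p_compartment: float
    effect: float  # mean EV proportion - mean cell proportion
    dropped_terms: list[str] = field(default_factory=list)


def _anova_compartment(
    data: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, float, list[str]]:
    """Type-II F-test p-value for the compartment term of
    proportion ~ compartment + isolation_method + study.

    Terms with a single level, or terms that make the design rank-deficient
    (e.g. compartment confounded with study), are dropped and reported.
    """
    if set(data["compartment"]) != {"EV", "cell"}:
        raise ValueError("design must contain both EV and cell samples")
    terms = ["C(compartment)"]
    dropped: list[str] = []
    for term, col in (("C(isolation_method)", "isolation_method"), ("C(study_id)", "study_id")):
        if data[col].nunique() >= 2:
            terms.append(term)
        else:
            dropped.append(col)

    while True:
        formula = "proportion ~ " + " + ".join(terms)
        model = smf.ols(formula, data=data)
        rank = np.linalg.matrix_rank(model.exog)
        if rank == model.exog.shape[1] or len(terms) == 1:
            break
        # Rank-deficient: drop the last confounder still in the model.
        removed = terms.pop()
        dropped.append(removed.replace("C(", "").replace(")", ""))
    res = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(res, typ=2)
    p = float(table.loc["C(compartment)", "PR(>F)"])
    effect = float(
        data.loc[data["compartment"] == "EV", "proportion"].mean()
        - data.loc[data["compartment"] == "cell", "proportion"].mean()
    )
    return p, effect, dropped


def anova_biotype(
    proportions: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
) -> list[BiotypeEnrichmentResult]:
    """Confounder-adjusted enrichment test per biotype.

    ``proportions``: long table (sample_id, biotype, proportion).
    ``manifest``: sample table with compartment, isolation_method, study_id.
    """
    merged = proportions.merge(
        manifest[["sample_id", "compartment", "isolation_method", "study_id"]],
        on="sample_id",
        how="inner",
    )
    results = []
    for biotype in sorted(merged["biotype"].unique()):
        sub = merged[merged["biotype"] == biotype]
        p, effect, dropped = _anova_compartment(sub, alpha=alpha)
        if p < alpha:
            direction = "enriched_in_EV" if effect > 0 else "depleted_in_EV"
        else:
            direction = "none"
        results.append(
            BiotypeEnrichmentResult(
                biotype=biotype,
                direction=direction,
                p_compartment=p,
                effect=effect,
                dropped_terms=dropped,
            )
        )
    return results


# ----------------------------------------------------- median normalization

def median_normalize(expression: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Divide each feature (row) by its median across samples.

    Highlights highly expressed features on a common scale.  Features with a
    zero median are set to 0 and returned in the flagged list.
    """
    if expression.shape[1] < 3:
        raise ValueError("median normalization needs at least 3 samples")
    med = expression.median(axis=1)
    zero = med == 0
    safe = med.where(~zero, 1.0)
    normalized = expression.div(safe, axis=0)
    normalized.loc[zero] = 0.0
    return normalized, list(expression.index[zero])


# ------------------------------------------------- per-study differential

def median_of_ratios_size_factors(values: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors (features x samples counts).

    Each sample's factor is the median, over features detected in every
    sample, of its count divided by the feature's geometric mean.  Robust to
    a minority of genuinely differential features, which inflate plain total
    counts and would bias every null feature's fold change.  Falls back to
    total counts (scaled to geometric mean 1) when too few features are
    detected everywhere.
    """
    with np.errstate(divide="ignore"):
        logv = np.log(values.astype(float))
    all_positive = np.isfinite(logv).all(axis=1)
    if all_positive.sum() >= 5:
        log_geomean = logv[all_positive].mean(axis=1)
        log_sf = np.median(logv[all_positive] - log_geomean[:, None], axis=0)
    else:
        totals = values.sum(axis=0).astype(float)
        log_sf = np.log(totals)
        log_sf -= log_sf.mean()
    return np.exp(log_sf)


@dataclass
class MirnaDEResult:
    feature_id: str
    log2fc: float
    p: float
    fdr: float
    significant: bool
    base_mean: float = 0.0


def _pearson_dispersion(y: np.ndarray, mu: np.ndarray, resid_df: int) -> float:
    """Moment estimate of the NB2 dispersion alpha: solve
    sum (y-mu)^2 / (mu + alpha mu^2) = residual df by bisection.

    Matching the Pearson chi-square to its degrees of freedom absorbs the
    variance already explained by the fitted mean, which a naive residual
    moment estimator ignores (it underestimates alpha and inflates Wald
    significance at small n).
    """
    resid2 = (y - mu) ** 2

    def g(alpha: float) -> float:
        return float((resid2 / (mu + alpha * mu**2)).sum()) - resid_df

    if g(DISPERSION_FLOOR) <= 0:
        return DISPERSION_FLOOR
    if g(DISPERSION_CEILING) >= 0:
        return DISPERSION_CEILING
    lo, hi = DISPERSION_FLOOR, DISPERSION_CEILING
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _nb_wald_fit(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> tuple[float, float]:
    """Per-feature NB GLM: Poisson pilot fit for the mean, Pearson-moment
    dispersion, NB refit, then a Wald test on the compartment coefficient
    (column 1 of X) against a t reference with residual df.  Returns
    (log2fc, p)."""
    n, k = X.shape
    resid_df = max(n - k, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pilot = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = np.clip(pilot.fittedvalues, 1e-8, None)
        alpha = _pearson_dispersion(y, mu, resid_df)
        res = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
        # one dispersion re-estimate at the NB mean, then a final refit
        mu = np.clip(res.fittedvalues, 1e-8, None)
        alpha = _pearson_dispersion(y, mu, resid_df)
        res = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
    log2fc = float(res.params[1] / np.log(2))
    se = float(res.bse[1])
    if not np.isfinite(se) or se <= 0:
        return log2fc, 1.0
    tval = res.params[1] / se
    p = float(2.0 * stats.t.sf(abs(tval), resid_df))
    if not np.isfinite(p):
        p = 1.0
    return log2fc, p


def differential_mirnas(
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    study_id: str | None = None,
) -> list[MirnaDEResult]:
    """Negative-binomial EV-vs-cell differential test within one study.

    ``counts``: features x samples raw integer counts.  ``manifest`` rows are
    matched to the count columns by sample_id and must carry compartment and
    isolation_method.  All-zero features are excluded before testing; the
    library-size offset is log total counts per sample.
    """
    label = study_id or "study"
    meta = manifest.set_index("sample_id").loc[list(counts.columns)]
    n_ev = int((meta["compartment"] == "EV").sum())
    n_cell = int((meta["compartment"] == "cell").sum())
    if n_ev < 2 or n_cell < 2:
        raise ValueError(
            f"{label}: needs >= 2 EV and >= 2 cell samples (got {n_ev} EV, {n_cell} cell)"
        )
    values = counts.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{label}: counts must be integers")
    values = np.round(values).astype(np.int64)

    if (values.sum(axis=0) == 0).any():
        raise ValueError(f"{label}: sample with zero total counts")
    offset = np.log(median_of_ratios_size_factors(values))

    is_ev = (meta["compartment"] == "EV").to_numpy().astype(float)
    X_cols = [np.ones(len(meta)), is_ev]
    methods = meta["isolation_method"]
    if methods.nunique() >= 2:
        levels = sorted(methods.unique())[1:]  # first level is baseline
        for lv in levels:
            X_cols.append((methods == lv).to_numpy().astype(float))
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = X[:, :2]  # method confounded with compartment: drop it

    keep = values.sum(axis=1) > 0
    results: list[MirnaDEResult] = []
    pvals = []
    for fid, y in zip(counts.index[keep], values[keep]):
        try:
            log2fc, p = _nb_wald_fit(y, X, offset)
        except Exception:
            log2fc, p = 0.0, 1.0
        results.append(
            MirnaDEResult(
                feature_id=str(fid),
                log2fc=log2fc,
                p=p,
                fdr=np.nan,
                significant=False,
                base_mean=float(y.mean()),
            )
        )
        pvals.append(p)
    if results:
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
            r.significant = bool(q < FDR_THRESHOLD and abs(r.log2fc) > LOG2_FC_THRESHOLD)
    return results


def de_results_to_frame(results: Sequence[MirnaDEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "base_mean": r.base_mean,
                "log2fc": r.log2fc,
                "p": r.p,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ]
    )


# ------------------------------------------------------ export classes

@dataclass
class ExportClassification:
    feature_id: str
    export_class: str
    per_study_calls: dict[str, str] = field(default_factory=dict)


def classify_export(
    per_study: Mapping[str, Sequence[MirnaDEResult]],
    min_testable: int = 2,
    mostly_tolerance: int = 3,
) -> list[ExportClassification]:
    """Cross-study consistency of each miRNA's EV/cell preference.

    Per study a feature is called EV-enriched (significant, log2fc > 0),
    cell-enriched (significant, log2fc < 0), ns (tested, not significant) or
    untestable (filtered out before testing).  Classes:

    * context_independent_EV — EV-enriched in all testable studies
      (at least ``min_testable`` of them); symmetric for _cell.
    * mostly_EV — EV-enriched in all but at most ``mostly_tolerance``
      testable studies and never cell-enriched.
    * study_specific — significant somewhere but inconsistent.
    * unclassified — everything else.
    """
    if len(per_study) < 2:
        raise ValueError("classification needs >= 2 studies")
    features: set[str] = set()
    for results in per_study.values():
        features.update(r.feature_id for r in results)

    indexed = {
        study: {r.feature_id: r for r in results} for study, results in per_study.items()
    }
    out: list[ExportClassification] = []
    for fid in sorted(features):
        calls: dict[str, str] = {}
        for study in sorted(per_study):
            r = indexed[study].get(fid)
            if r is None:
                calls[study] = "untestable"
            elif r.significant and r.log2fc > 0:
                calls[study] = "EV-enriched"
            elif r.significant and r.log2fc < 0:
                calls[study] = "cell-enriched"
            else:
                calls[study] = "ns"
        n_testable = sum(c != "untestable" for c in calls.values())
        n_ev = sum(c == "EV-enriched" for c in calls.values())
        n_cell = sum(c == "cell-enriched" for c in calls.values())
        if n_testable < min_testable:
            cls = "unclassified"
        elif n_ev == n_testable:
            cls = "context_independent_EV"
        elif n_cell == n_testable:
            cls = "context_independent_cell"
        elif n_cell == 0 and n_ev >= 1 and n_testable - n_ev <= mostly_tolerance:
            cls = "mostly_EV"
        elif n_ev + n_cell >= 1:
            cls = "study_specific"
        else:
            cls = "unclassified"
        out.append(ExportClassification(feature_id=fid, export_class=cls, per_study_calls=calls))
    return out


def classifications_to_frame(classifications: Sequence[ExportClassification]) -> pd.DataFrame:
    studies = sorted(
        {s for c in classifications for s in c.per_study_calls}
    )
    rows = []
    for c in classifications:
        row = {"feature_id": c.feature_id, "export_class": c.export_class}
        for s in studies:
            row[f"call_{s}"] = c.per_study_calls.get(s, "untestable")
        rows.append(row)
    return pd.DataFrame(rows)
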