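"""Confounder-adjusted ANOVA, median normalization, NB differential tests,
and export classification."""

import numpy as np
import pandas as pd
import pytest

from evsmallrna.enrichment import (
    MirnaDEResult,
    _anova_compartment,
    anova_biotype,
    classify_export,
    differential_mirnas,
    median_of_ratios_size_factors,
    median_normalize,
)
from evsmallrna.simulate import simulate_nb_counts, simulate_proportion_design


class TestAnova:
    def test_exact_null_pairs(self):
        # identical EV and cell values per pair -> zero effect, p ~ 1
        df = simulate_proportion_design(1, n_studies=2, n_pairs=5)
        cells = df[df.compartment == "cell"].copy()
        evs = cells.copy()
        evs["compartment"] = "EV"
        evs["sample_id"] = evs["sample_id"] + "_ev"
        both = pd.concat([cells, evs], ignore_index=True)
        p, effect, _ = _anova_compartment(both)
        assert effect == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_planted_shift_detected_with_direction(self):
        prop = simulate_proportion_design(7, ev_shift=0.15)
        prop["biotype"] = "rRNA"
        manifest = prop[["sample_id", "compartment", "isolation_method", "study_id"]]
        (res,) = anova_biotype(prop[["sample_id", "biotype", "proportion"]], manifest)
        assert res.p_compartment < 0.01
        assert res.direction == "enriched_in_EV"
        assert res.effect == pytest.approx(0.15, abs=0.05)

    def test_requires_both_compartments(self):
        df = simulate_proportion_design(1)
        with pytest.raises(ValueError):
            _anova_compartment(df[df.compartment == "EV"])

    def test_single_study_drops_term_and_annotates(self):
        df = simulate_proportion_design(3, n_studies=1)
        p, _, dropped = _anova_compartment(df)
        assert np.isfinite(p)
        assert "isolation_method" in dropped and "study_id" in dropped

    def test_method_effect_does_not_inflate_type1(self):
        """Isolation-method main effect with no compartment effect keeps the
        compartment test near nominal."""
        rej = 0
        n = 200
        for i in range(n):
            df = simulate_proportion_design(
                40_000 + i,
                ev_shift=0.0,
                method_effects={"ExoQuick": 0.1, "ExoEasy": -0.1},
            )
            p, _, _ = _anova_compartment(df)
            rej += p < 0.05
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert abs(rej / n - 0.05) < half_width + 0.01


class TestMedianNormalize:
    def test_arithmetic(self):
        df = pd.DataFrame({"a": [2.0], "b": [4.0], "c": [8.0]}, index=["f"])
        norm, flagged = median_normalize(df)
        assert list(norm.loc["f"]) == [0.5, 1.0, 2.0]
        assert flagged == []

    def test_constant_feature_all_ones(self):
        df = pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}, index=["f"])
        norm, _ = median_normalize(df)
        assert (norm.loc["f"] == 1.0).all()

    def test_zero_median_flagged(self):
        df = pd.DataFrame({"a": [0.0], "b": [0.0], "c": [3.0]}, index=["f"])
        norm, flagged = median_normalize(df)
        assert (norm.loc["f"] == 0.0).all() and flagged == ["f"]

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            median_normalize(pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["f"]))


class TestSizeFactors:
    def test_robust_to_asymmetric_de(self):
        counts, meta, _ = simulate_nb_counts(3, libsize_range=(1.0, 1.0))
        sf = median_of_ratios_size_factors(counts.to_numpy())
        ev = meta["compartment"].to_numpy() == "EV"
        # DE features inflate EV totals ~1.3x but not median-of-ratios factors
        assert abs(np.log(sf[ev].mean() / sf[~ev].mean())) < 0.1


class TestDifferentialMirnas:
    def test_significance_needs_both_fdr_and_fc(self):
        r1 = MirnaDEResult("a", log2fc=np.log2(1.6), p=0.01, fdr=0.04, significant=False)
        r2 = MirnaDEResult("b", log2fc=np.log2(1.4), p=0.01, fdr=0.04, significant=False)
        thresh = np.log2(1.5)
        assert abs(r1.log2fc) > thresh and r1.fdr < 0.05
        assert abs(r2.log2fc) < thresh
        # the pipeline applies exactly this conjunction
        counts, meta, _ = simulate_nb_counts(11, n_features=40, n_de=5, log2fc=3.0)
        for r in differential_mirnas(counts, meta, "sim"):
            assert r.significant == (r.fdr < 0.05 and abs(r.log2fc) > thresh)

    def test_non_integer_counts_rejected(self):
        counts, meta, _ = simulate_nb_counts(1, n_features=10)
        bad = counts.astype(float) + 0.5
        with pytest.raises(ValueError, match="integer"):
            differential_mirnas(bad, meta, "studyX")

    def test_single_compartment_errors_with_study_name(self):
        counts, meta, _ = simulate_nb_counts(1, n_features=10)
        ev_only = meta[meta.compartment == "EV"]
        with pytest.raises(ValueError, match="studyZ"):
            differential_mirnas(counts[ev_only.sample_id], ev_only, "studyZ")

    def test_fdr_monotone_in_p(self):
        counts, meta, _ = simulate_nb_counts(2, n_features=60, n_de=10)
        res = differential_mirnas(counts, meta, "sim")
        res = sorted(res, key=lambda r: r.p)
        fdrs = [r.fdr for r in res]
        assert fdrs == sorted(fdrs)

    def test_sign_coherence_with_mean_difference(self):
        counts, meta, de = simulate_nb_counts(4, n_de=10, log2fc=2.0, dispersion=0.05)
        res = {r.feature_id: r for r in differential_mirnas(counts, meta, "sim")}
        sf = median_of_ratios_size_factors(counts.to_numpy())
        norm = counts / sf
        ev = meta.loc[meta.compartment == "EV", "sample_id"]
        cell = meta.loc[meta.compartment == "cell", "sample_id"]
        for fid in de:
            diff = norm.loc[fid, ev].mean() - norm.loc[fid, cell].mean()
            assert np.sign(res[fid].log2fc) == np.sign(diff)

    def test_recovery_quick(self):
        counts, meta, de = simulate_nb_counts(0)
        res = differential_mirnas(counts, meta, "sim")
        sig = {r.feature_id for r in res if r.significant}
        assert len(sig & set(de)) / len(de) >= 0.8


class TestAgainstDeseq2Reference:
    def test_log2fc_and_calls_concordant_with_pydeseq2(self):
        """The in-package NB GLM route agrees with an independent
        implementation of the same model family (pydeseq2) on fold-change
        estimates and on which features pass the FDR/fold-change filter."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats

            counts, meta, de = simulate_nb_counts(42, n_features=120, n_de=12, log2fc=2.0)
            dds = DeseqDataSet(
                counts=counts.T,
                metadata=meta.set_index("sample_id"),
                design="~compartment",
                quiet=True,
            )
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["compartment", "EV", "cell"], quiet=True)
            ds.summary()
            ref = ds.results_df
        ours = {r.feature_id: r for r in differential_mirnas(counts, meta, "sim")}
        common = [f for f in ref.index if f in ours]
        lfc_ref = np.array([ref.loc[f, "log2FoldChange"] for f in common])
        lfc_ours = np.array([ours[f].log2fc for f in common])
        assert np.corrcoef(lfc_ref, lfc_ours)[0, 1] > 0.98
        thresh = np.log2(1.5)
        sig_ref = {
            f for f in common
            if ref.loc[f, "padj"] < 0.05 and abs(ref.loc[f, "log2FoldChange"]) > thresh
        }
        sig_ours = {f for f in common if ours[f].significant}
        jaccard = len(sig_ref & sig_ours) / max(len(sig_ref | sig_ours), 1)
        assert jaccard >= 0.8
        assert set(de) <= sig_ours


class TestClassifyExport:
    def _result(self, fid, lfc, sig):
        return MirnaDEResult(fid, log2fc=lfc, p=0.001, fdr=0.001 if sig else 0.9,
                             significant=sig)

    def test_all_testable_ev_enriched(self):
        per_study = {
            f"st{i}": [self._result("mirX", 2.0, True)] for i in range(5)
        }
        (c,) = classify_export(per_study)
        assert c.export_class == "context_independent_EV"
        assert all(v == "EV-enriched" for v in c.per_study_calls.values())

    def test_mixed_directions_study_specific(self):
        per_study = {
            "st1": [self._result("m", 2.0, True)],
            "st2": [self._result("m", 2.0, True)],
            "st3": [self._result("m", 2.0, True)],
            "st4": [self._result("m", -2.0, True)],
            "st5": [self._result("m", 0.1, False)],
        }
        (c,) = classify_export(per_study)
        assert c.export_class == "study_specific"

    def test_untestable_studies_do_not_count(self):
        per_study = {
            "st1": [self._result("m", 2.0, True)],
            "st2": [self._result("m", 2.0, True)],
            "st3": [],  # feature filtered out here
        }
        (c,) = classify_export(per_study)
        assert c.per_study_calls["st3"] == "untestable"
        assert c.export_class == "context_independent_EV"

    def test_min_testable_gate(self):
        per_study = {"st1": [self._result("m", 2.0, True)], "st2": []}
        (c,) = classify_export(per_study, min_testable=2)
        assert c.export_class == "unclassified"

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            classify_export({"st1": [self._result("m", 1.0, True)]})

    def test_simulated_universal_exporters_recovered(self):
        """Planted universal-export features are the exact context-independent
        set across simulated studies."""
        universal = None
        per_study = {}
        for s in range(3):
            counts, meta, de = simulate_nb_counts(
                800 + s, n_features=60, n_de=6, log2fc=3.0, mean_log=5.0
            )
            universal = set(de)
            per_study[f"st{s}"] = differential_mirnas(counts, meta, f"st{s}")
        classes = classify_export(per_study)
        called = {c.feature_id for c in classes if c.export_class == "context_independent_EV"}
        assert called == universal
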