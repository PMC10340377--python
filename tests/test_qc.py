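"""QC metric arithmetic, gate boundary semantics, and study-level rules."""

import pytest
from hypothesis import given, settings, strategies as st

from evsmallrna.mapping import SampleProfile
from evsmallrna.qc import (
    ALL_FLAGS,
    QCReport,
    QCThresholds,
    compare_study_groups,
    compute_qc,
    flag_sample,
    flag_study,
    qc_report,
    study_variability,
)


def make_profile(n_trimmed, n_host, n_nonhost, mirna=0, host_other=0):
    smallrna_other = n_host - mirna - host_other
    return SampleProfile(
        sample_id="s",
        n_trimmed_kept=n_trimmed,
        n_host=n_host,
        n_nonhost=n_nonhost,
        n_unmapped=n_trimmed - n_host - n_nonhost,
        biotype_counts={"miRNA": mirna, "YRNA": smallrna_other, "host_other": host_other},
    )


def make_report(**kw):
    base = dict(
        sample_id="s",
        n_trimmed=200_000,
        overall_map_rate=0.9,
        n_host=150_000,
        host_frac=0.8,
        smallrna_frac_of_host=0.95,
        mirna_frac_of_host=0.5,
    )
    base.update(kw)
    return QCReport(**base)


def test_metric_arithmetic():
    rep = compute_qc(make_profile(200_000, 120_000, 10_000, mirna=60_000, host_other=6_000))
    assert rep.overall_map_rate == pytest.approx(0.65)
    assert rep.host_frac == pytest.approx(0.6)
    assert rep.smallrna_frac_of_host == pytest.approx(114_000 / 120_000)
    assert rep.mirna_frac_of_host == pytest.approx(0.5)


def test_zero_reads_all_flags():
    rep = qc_report(make_profile(0, 0, 0))
    assert rep.overall_map_rate == 0.0 and rep.host_frac == 0.0
    assert rep.flags == set(ALL_FLAGS)


class TestGateBoundaries:
    def test_read_and_mapping_gate_pass_just_above(self):
        rep = flag_sample(make_report(n_trimmed=100_001, overall_map_rate=0.205))
        assert "low_reads" not in rep.flags and "low_overall_map" not in rep.flags

    def test_read_gate_fails_at_exactly_100k(self):
        assert "low_reads" in flag_sample(make_report(n_trimmed=100_000)).flags

    def test_host_reads_minimum(self):
        assert "low_host_reads" in flag_sample(make_report(n_host=99_999)).flags
        assert "low_host_reads" not in flag_sample(make_report(n_host=100_000)).flags

    def test_host_frac_strictly_greater(self):
        assert "low_host_frac" in flag_sample(make_report(host_frac=0.50)).flags
        assert "low_host_frac" not in flag_sample(make_report(host_frac=0.501)).flags

    def test_mirna_boundary_10_percent(self):
        assert "low_mirna" not in flag_sample(make_report(mirna_frac_of_host=0.10)).flags
        assert "low_mirna" in flag_sample(make_report(mirna_frac_of_host=0.099)).flags

    def test_smallrna_boundary(self):
        assert "low_smallrna" in flag_sample(make_report(smallrna_frac_of_host=0.749)).flags
        assert "low_smallrna" not in flag_sample(make_report(smallrna_frac_of_host=0.75)).flags


@given(
    scale=st.floats(min_value=1.0, max_value=3.0),
    n_trimmed=st.integers(min_value=0, max_value=400_000),
    map_rate=st.floats(min_value=0, max_value=1),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_gate_monotonicity(scale, n_trimmed, map_rate):
    """Raising thresholds can only add flags, never remove them."""
    rep = make_report(n_trimmed=n_trimmed, overall_map_rate=map_rate)
    loose = flag_sample(make_report(n_trimmed=n_trimmed, overall_map_rate=map_rate),
                        QCThresholds())
    tight = flag_sample(rep, QCThresholds(
        min_reads=int(100_000 * scale),
        min_overall_map=min(1.0, 0.20 * scale),
        min_host_reads=int(100_000 * scale),
        min_host_frac=min(1.0, 0.50 * scale),
        min_smallrna=min(1.0, 0.75 * scale),
        min_mirna=min(1.0, 0.10 * scale),
    ))
    assert loose.flags <= tight.flags


class TestStudyRules:
    def _reports(self, n_fail, n_total):
        reps = []
        for i in range(n_total):
            frac = 0.05 if i < n_fail else 0.5
            reps.append(flag_sample(make_report(mirna_frac_of_host=frac)))
        return reps

    def test_majority_exclusion_3_of_5(self):
        assert flag_study(self._reports(3, 5)) is True

    def test_half_is_not_excluded_2_of_4(self):
        assert flag_study(self._reports(2, 4)) is False

    def test_single_failing_sample_excludes(self):
        assert flag_study(self._reports(1, 1)) is True

    def test_exclusion_uses_only_content_flags(self):
        # low_reads alone never triggers exclusion
        reps = [flag_sample(make_report(n_trimmed=10)) for _ in range(4)]
        assert flag_study(reps) is False


class TestStudyVariability:
    def test_median_iqr_high_quality(self):
        (s,) = study_variability({"st1": (0.92, 0.93, 0.94)})
        assert s.median_smallrna_prop == pytest.approx(0.93)
        assert s.iqr_smallrna_prop == pytest.approx(0.01)
        assert s.label == "high_quality"

    def test_two_sample_interpolated_iqr(self):
        import numpy as np

        (s,) = study_variability({"st1": (0.5, 0.95)})
        q1, q3 = np.percentile([0.5, 0.95], [25, 75])
        assert s.iqr_smallrna_prop == pytest.approx(q3 - q1)
        assert s.label == "variable"

    def test_constant_props_zero_iqr(self):
        (s,) = study_variability({"st1": (0.8, 0.8, 0.8)})
        assert s.iqr_smallrna_prop == 0.0

    def test_single_sample_warns(self):
        (s,) = study_variability({"st1": (0.95,)})
        assert s.single_sample_warning and s.iqr_smallrna_prop == 0.0

    def test_excluded_label_wins(self):
        (s,) = study_variability({"st1": (0.95, 0.96)}, excluded={"st1": True})
        assert s.label == "excluded"


def test_welch_needs_two_per_group():
    with pytest.raises(ValueError):
        compare_study_groups([0.9], [0.5, 0.6])
    t, p = compare_study_groups([0.9, 0.91, 0.92], [0.5, 0.52, 0.51])
    assert p < 0.01
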