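"""Two-tier insert mapping against an exhaustive Hamming-search oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evsmallrna.catalog import CatalogEntry, generate_catalog
from evsmallrna.mapping import (
    AlignmentHit,
    align_host,
    align_nonhost,
    assign_biotype,
    quantify_sample,
)
from evsmallrna.simulate import SimulationTruth, simulate_sample
from evsmallrna.adapters import AdapterPattern
from evsmallrna.simulate import DEFAULT_ADAPTER3


def brute_force_hits(insert: str, entries, max_mm: int):
    """Independent oracle: scan every window of every catalog sequence with
    a vectorized Hamming count."""
    q = np.frombuffer(insert.encode(), dtype=np.uint8)
    hits = []
    for e in entries:
        t = np.frombuffer(e.sequence.encode(), dtype=np.uint8)
        if len(q) > len(t):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
        mm = (windows != q).sum(axis=1)
        best = int(mm.min())
        if best <= max_mm:
            hits.append((e.feature_id, best))
    return hits


def _mutate(seq: str, pos: int) -> str:
    repl = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return seq[:pos] + repl + seq[pos + 1 :]


class TestAlignHost:
    def test_identity_hit(self, catalog):
        e = next(e for e in catalog.host_entries if e.biotype == "miRNA")
        hits = align_host(e.sequence, catalog)
        assert AlignmentHit(e.feature_id, "miRNA", "host", 0) in hits
        assert all(h.n_mismatches == 0 for h in hits)

    def test_one_substitution_hit(self, catalog):
        e = next(e for e in catalog.host_entries if e.biotype == "tRNA")
        window = e.sequence[10:34]
        hits = align_host(_mutate(window, 5), catalog)
        assert any(h.feature_id == e.feature_id and h.n_mismatches == 1 for h in hits)

    def test_two_substitutions_miss(self, catalog):
        e = catalog.host_entries[0]
        bad = _mutate(_mutate(e.sequence, 2), 9)
        assert all(h.feature_id != e.feature_id for h in align_host(bad, catalog))

    def test_oracle_equivalence_random_inserts(self, catalog):
        """Pigeonhole matcher agrees with exhaustive Hamming search."""
        rng = np.random.default_rng(17)
        host = catalog.host_entries
        inserts = []
        for _ in range(100):  # catalog-derived, with 0/1/2 planted errors
            e = host[rng.integers(len(host))]
            L = int(rng.integers(16, min(30, len(e.sequence)) + 1))
            start = int(rng.integers(0, len(e.sequence) - L + 1))
            ins = e.sequence[start : start + L]
            for _ in range(rng.integers(0, 3)):
                ins = _mutate(ins, int(rng.integers(0, L)))
            inserts.append(ins)
        inserts += [
            "".join("ACGT"[b] for b in rng.integers(0, 4, 22)) for _ in range(100)
        ]
        for ins in inserts:
            expected = brute_force_hits(ins, host, max_mm=1)
            if any(mm == 0 for _, mm in expected):
                expected = [(f, mm) for f, mm in expected if mm == 0]
            got = sorted((h.feature_id, h.n_mismatches) for h in align_host(ins, host))
            assert got == sorted(expected), ins


class TestAlignNonhost:
    def test_length_19_not_searched(self, catalog):
        e = catalog.nonhost_entries[0]
        assert align_nonhost(e.sequence[:19], catalog) == []

    def test_length_20_exact_hit(self, catalog):
        e = catalog.nonhost_entries[0]
        hits = align_nonhost(e.sequence[:20], catalog)
        assert [h.feature_id for h in hits] == [e.feature_id]

    def test_one_mismatch_rejected(self, catalog):
        e = catalog.nonhost_entries[0]
        assert align_nonhost(_mutate(e.sequence[:22], 4), catalog) == []


class TestAssignBiotype:
    def test_priority_mirna_over_rrna(self):
        hits = [
            AlignmentHit("rrnB", "rRNA", "host", 0),
            AlignmentHit("mirA", "miRNA", "host", 0),
        ]
        assert assign_biotype(hits) == ("miRNA", ["mirA"])

    def test_fractional_split_on_ties(self):
        hits = [
            AlignmentHit("mirA", "miRNA", "host", 0),
            AlignmentHit("mirB", "miRNA", "host", 0),
        ]
        biotype, features = assign_biotype(hits)
        assert biotype == "miRNA" and features == ["mirA", "mirB"]

    def test_empty_hits_is_none(self):
        assert assign_biotype([]) is None

    @given(st.permutations(list(range(5))))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariance(self, order):
        base = [
            AlignmentHit("a", "rRNA", "host", 0),
            AlignmentHit("b", "tRNA", "host", 0),
            AlignmentHit("c", "tRNA", "host", 0),
            AlignmentHit("d", "YRNA", "host", 0),
            AlignmentHit("e", "misc", "host", 0),
        ]
        shuffled = [base[i] for i in order]
        assert assign_biotype(shuffled) == assign_biotype(base)


class TestQuantifySample:
    def test_cpm_arithmetic(self):
        entries = [
            CatalogEntry("m1", "ACGTACGTACGTACGTACGTAC", "miRNA", "host"),
            CatalogEntry("m2", "TTGGCCAATTGGCCAATTGGCA", "miRNA", "host"),
            CatalogEntry("m3", "CAGTCAGTCAGTCAGTCAGTCA", "miRNA", "host"),
        ]
        inserts = [entries[0].sequence, entries[1].sequence,
                   entries[2].sequence, entries[2].sequence]
        profile = quantify_sample(inserts, entries, [])
        assert profile.cpm == {"m1": 250_000.0, "m2": 250_000.0, "m3": 500_000.0}

    def test_all_junk_unmapped(self, catalog):
        rng = np.random.default_rng(3)
        inserts = ["".join("ACGT"[b] for b in rng.integers(0, 4, 25)) for _ in range(50)]
        profile = quantify_sample(inserts, catalog)
        assert profile.n_host == 0
        assert sum(profile.biotype_counts.values()) == 0
        assert profile.n_unmapped + profile.n_nonhost == 50

    def test_empty_input_warns(self, catalog):
        profile = quantify_sample([], catalog)
        assert profile.zero_input_warning and profile.cpm == {}

    def test_partition_and_truth_recount(self, catalog, truseq_pattern):
        """Profile equals a brute-force recount of the ground-truth table."""
        truth = SimulationTruth(
            adapter=truseq_pattern,
            composition={"miRNA": 0.4, "rRNA": 0.2, "tRNA": 0.2, "snoRNA": 0.2},
            n_reads=600,
            seed=5,
        )
        _, table = simulate_sample(truth, catalog)
        profile = quantify_sample(list(table["insert_seq"]), catalog, sample_id="s")
        assert profile.n_trimmed_kept == profile.n_host + profile.n_nonhost + profile.n_unmapped
        expected = table["biotype"].value_counts().to_dict()
        for bt in ("miRNA", "rRNA", "tRNA", "snoRNA"):
            assert profile.biotype_counts[bt] == expected.get(bt, 0)
        mirna_feature_mass = sum(
            c for f, c in profile.feature_counts.items() if catalog[f].biotype == "miRNA"
        )
        assert mirna_feature_mass == pytest.approx(profile.biotype_counts["miRNA"])

    def test_profile_io_round_trip(self, tmp_path, catalog):
        e = catalog.host_entries[0]
        profile = quantify_sample([e.sequence] * 3, catalog, sample_id="x")
        profile.write(tmp_path)
        from evsmallrna.mapping import SampleProfile

        back = SampleProfile.read(tmp_path, "x")
        assert back.biotype_counts == profile.biotype_counts
        assert back.feature_counts == profile.feature_counts
        assert back.n_trimmed_kept == profile.n_trimmed_kept
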