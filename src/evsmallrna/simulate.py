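"""Synthetic small RNA-seq data with known ground truth.

Every downstream stage of the pipeline (adapter inference, trimming, biotype
assignment, QC, composition, enrichment) is testable against data generated
here: reads are catalog-drawn small-RNA inserts wrapped in kit-style random
bases and a 3' adapter, with configurable per-sample biotype composition and
planted EV-versus-cell effects.  A fixed seed yields byte-identical output.

The read model
--------------
``read = [rand5 bases] + insert + [rand3 bases] + adapter + [random padding]``
truncated to the read length (default 51 nt).  Inserts are full catalog
sequences for compact biotypes (miRNA and similar); entries longer than the
maximum insert size (rRNA, tRNA, and other long precursors) contribute a
random 18-35 nt window, emulating the fragment nature of those biotypes.
Substitution errors are applied per base at ``error_rate``.  The remainder of
the composition (1 - sum) is uniform random "junk" sequence expected to map
nowhere, which exercises the mapping-rate QC gates.  Quality strings are a
constant 'I' (Phred 40); the pipeline checks but never filters on quality.

Each simulated read is checked against the trimmer's own matching rule so
that the first adapter occurrence is the planted one; flanks are redrawn in
the vanishingly rare case a chance prefix match lands earlier.  This keeps
the error-free simulation an exact oracle for trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._fastq import write_fastq
from .adapters import AdapterPattern
from .catalog import ALPHABET, ReferenceCatalog
from .manifest import ISOLATION_METHODS, MANIFEST_COLUMNS, write_manifest
from .trimming import MIN_OVERLAP, locate_adapter

#: Illumina TruSeq Small RNA 3' adapter — the default simulated kit.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_READ_LENGTH = 51
FRAGMENT_LEN_RANGE = (18, 35)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Ground-truth generating parameters for one simulated sample."""

    adapter: AdapterPattern
    composition: Mapping[str, float]  # biotype (or "nonhost") -> read fraction
    n_reads: int
    seed: int
    per_feature_abundance: Mapping[str, float] | None = None
    planted_log2fc: Mapping[str, float] = field(default_factory=dict)
    error_rate: float = 0.0
    read_length: int = DEFAULT_READ_LENGTH
    lognormal_sigma: float = 1.0

    def __post_init__(self):
        if len(self.adapter.adapter3) < 8:
            raise SimulationError("adapter must be at least 8 nt")
        if self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise SimulationError("error_rate must be in [0, 0.05]")
        total = 0.0
        for bt, p in self.composition.items():
            if p < 0:
                raise SimulationError(f"negative composition for {bt}")
            total += p
        if total > 1.0 + 1e-9:
            raise SimulationError("composition fractions must sum to <= 1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[b] for b in rng.integers(0, 4, size=length))


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    flags = rng.random(len(seq)) < error_rate
    if not flags.any():
        return seq
    out = list(seq)
    for pos in np.flatnonzero(flags):
        choices = [b for b in ALPHABET if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_sample(
    truth: SimulationTruth,
    catalog: ReferenceCatalog,
    sample_id: str = "S",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one sample's reads plus a per-read ground-truth table.

    Returns ``(reads, truth_table)`` where reads are (id, sequence, quality)
    tuples and the table records each read's source feature, biotype, and
    insert boundaries (junk reads carry feature_id '*').
    """
    rng = np.random.default_rng(truth.seed)
    frag_min, frag_max = FRAGMENT_LEN_RANGE

    # Resolve composition categories to catalog entries and feature weights.
    categories = sorted(truth.composition)
    cat_entries: dict[str, list] = {}
    cat_weights: dict[str, np.ndarray] = {}
    for cat in categories:
        if cat == "nonhost":
            entries = sorted(catalog.nonhost_entries, key=lambda e: e.feature_id)
        else:
            entries = sorted(
                (e for e in catalog.host_entries if e.biotype == cat),
                key=lambda e: e.feature_id,
            )
        if not entries and truth.composition[cat] > 0:
            raise SimulationError(f"composition references biotype {cat!r} absent from catalog")
        if truth.per_feature_abundance is not None:
            w = np.array(
                [truth.per_feature_abundance.get(e.feature_id, 1.0) for e in entries]
            )
        elif entries:
            w = rng.lognormal(0.0, truth.lognormal_sigma, size=len(entries))
        else:
            w = np.array([])
        for i, e in enumerate(entries):
            lfc = truth.planted_log2fc.get(e.feature_id)
            if lfc:
                w[i] *= 2.0**lfc
        cat_entries[cat] = entries
        cat_weights[cat] = w / w.sum() if len(w) and w.sum() > 0 else w

    probs = np.array([truth.composition[c] for c in categories])
    junk = 1.0 - probs.sum()
    all_cats = categories + ["junk"]
    all_probs = np.append(probs, max(junk, 0.0))
    all_probs = all_probs / all_probs.sum()
    cat_draw = rng.choice(len(all_cats), size=truth.n_reads, p=all_probs)

    adapter = truth.adapter.adapter3
    r5, r3 = truth.adapter.rand5_len, truth.adapter.rand3_len
    L = truth.read_length

    reads: list[tuple[str, str, str]] = []
    rows: list[dict] = []
    for i in range(truth.n_reads):
        rid = f"{sample_id}_r{i:06d}"
        cat = all_cats[cat_draw[i]]
        if cat == "junk":
            seq = _apply_errors(rng, _random_seq(rng, L), truth.error_rate)
            reads.append((rid, seq, "I" * len(seq)))
            rows.append(
                {
                    "read_id": rid,
                    "feature_id": "*",
                    "biotype": "junk",
                    "insert_start": -1,
                    "insert_end": -1,
                    "insert_seq": "",
                }
            )
            continue
        entries = cat_entries[cat]
        fidx = int(rng.choice(len(entries), p=cat_weights[cat])) if len(entries) > 1 else 0
        entry = entries[fidx]
        if len(entry.sequence) > frag_max:
            flen = int(rng.integers(frag_min, frag_max + 1))
            start = int(rng.integers(0, len(entry.sequence) - flen + 1))
            insert = entry.sequence[start : start + flen]
        else:
            insert = entry.sequence
        j_true = r5 + len(insert) + r3
        expected = j_true if L - j_true >= MIN_OVERLAP else None
        for _attempt in range(25):
            pre = _random_seq(rng, r5)
            post = _random_seq(rng, r3)
            full = pre + insert + post + adapter
            if len(full) < L:
                full += _random_seq(rng, L - len(full))
            full = full[:L]
            if locate_adapter(full, adapter) == expected:
                break
        seq = _apply_errors(rng, full, truth.error_rate)
        reads.append((rid, seq, "I" * len(seq)))
        rows.append(
            {
                "read_id": rid,
                "feature_id": entry.feature_id,
                "biotype": entry.biotype if entry.origin == "host" else "nonhost",
                "insert_start": r5,
                "insert_end": r5 + len(insert),
                "insert_seq": insert,
            }
        )
    return reads, pd.DataFrame(rows)


# ------------------------------------------------------------- study sets

#: Baseline read-fraction compositions.  EV libraries carry relatively more
#: rRNA/tRNA/Y RNA fragments; donor cells more miRNA and snoRNA.  The
#: remainder to 1 is unmappable junk.
BASE_COMPOSITION = {
    "EV": {
        "miRNA": 0.36,
        "YRNA": 0.14,
        "rRNA": 0.10,
        "tRNA": 0.045,
        "snRNA": 0.02,
        "snoRNA": 0.015,
        "mt_tRNA": 0.01,
        "misc": 0.02,
        "lincRNA": 0.01,
        "host_other": 0.06,
        "nonhost": 0.02,
    },
    "cell": {
        "miRNA": 0.46,
        "YRNA": 0.10,
        "rRNA": 0.06,
        "tRNA": 0.02,
        "snRNA": 0.03,
        "snoRNA": 0.05,
        "mt_tRNA": 0.01,
        "misc": 0.02,
        "lincRNA": 0.01,
        "host_other": 0.06,
        "nonhost": 0.01,
    },
}


def default_composition(compartment: str = "EV") -> dict[str, float]:
    return dict(BASE_COMPOSITION[compartment])


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _jitter_composition(
    rng: np.random.Generator, comp: Mapping[str, float], concentration: float
) -> dict[str, float]:
    """Dirichlet jitter over composition + junk, preserving zero classes."""
    keys = [k for k in sorted(comp) if comp[k] > 0]
    junk = 1.0 - sum(comp.values())
    alpha = np.array([comp[k] for k in keys] + [max(junk, 1e-6)]) * concentration
    draw = rng.dirichlet(alpha)
    return {k: float(draw[i]) for i, k in enumerate(keys)}


def build_paired_design(
    seed: int,
    catalog: ReferenceCatalog,
    n_studies: int = 2,
    n_pairs: int = 4,
    n_reads: int = 2000,
    adapter: AdapterPattern | None = None,
    error_rate: float = 0.0,
    planted_biotype_shift: Mapping[str, float] | None = None,
    planted_log2fc: Mapping[str, float] | None = None,
    dirichlet_concentration: float = 300.0,
    read_length: int = DEFAULT_READ_LENGTH,
) -> tuple[pd.DataFrame, dict[str, SimulationTruth]]:
    """Design a paired EV/cell multi-study simulation.

    Feature abundances are log-normal, shared by all samples of a study;
    ``planted_log2fc`` multiplies EV-sample abundances (feature-level export
    effects) and ``planted_biotype_shift`` adds to EV biotype fractions
    (composition-level enrichment), drawing the difference from the junk
    margin.  Returns the manifest and per-sample generating truths.
    """
    if adapter is None:
        adapter = AdapterPattern(DEFAULT_ADAPTER3, rand5_len=4, rand3_len=4)
    ss = np.random.SeedSequence(seed)
    study_ss = ss.spawn(n_studies)
    host_features = sorted(e.feature_id for e in catalog.host_entries)

    rows: list[dict] = []
    truths: dict[str, SimulationTruth] = {}
    for s in range(n_studies):
        study_id = f"study{s + 1:02d}"
        srng = np.random.default_rng(_child_seed(study_ss[s]))
        weights = {
            fid: float(w)
            for fid, w in zip(host_features, srng.lognormal(0.0, 1.0, len(host_features)))
        }
        method = ISOLATION_METHODS[s % len(ISOLATION_METHODS)]
        sample_ss = study_ss[s].spawn(2 * n_pairs)
        for p in range(n_pairs):
            pair_id = f"{study_id}_p{p + 1}"
            for k, compartment in enumerate(("EV", "cell")):
                sample_id = f"{study_id}_{compartment}{p + 1}"
                comp = default_composition(compartment)
                if compartment == "EV" and planted_biotype_shift:
                    for bt, delta in planted_biotype_shift.items():
                        comp[bt] = max(0.0, comp.get(bt, 0.0) + delta)
                child = sample_ss[2 * p + k]
                jrng = np.random.default_rng(_child_seed(child))
                comp = _jitter_composition(jrng, comp, dirichlet_concentration)
                truths[sample_id] = SimulationTruth(
                    adapter=adapter,
                    composition=comp,
                    n_reads=n_reads,
                    seed=_child_seed(child.spawn(1)[0]),
                    per_feature_abundance=weights,
                    planted_log2fc=dict(planted_log2fc or {})
                    if compartment == "EV"
                    else {},
                    error_rate=error_rate,
                    read_length=read_length,
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "study_id": study_id,
                        "compartment": compartment,
                        "source": "cell_line",
                        "biofluid_name": None,
                        "isolation_method": method,
                        "rna_kit": "miRNeasy",
                        "pair_id": pair_id,
                    }
                )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS), truths


def simulate_study_set(
    design: Sequence[tuple[Mapping, SimulationTruth]] | tuple[pd.DataFrame, Mapping[str, SimulationTruth]],
    catalog: ReferenceCatalog,
    out_dir: str | Path,
) -> dict:
    """Write one FASTQ + truth table per sample, plus the manifest.

    ``design`` is either (manifest DataFrame, {sample_id: truth}) as produced
    by :func:`build_paired_design`, or a list of (manifest-row dict, truth)
    pairs.  Returns a bundle of paths sufficient to score every downstream
    stage.
    """
    if isinstance(design, tuple) and isinstance(design[0], pd.DataFrame):
        manifest, truth_map = design
    else:
        rows = [dict(row) for row, _ in design]
        manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        truth_map = {row["sample_id"]: t for row, t in design}
    if manifest["sample_id"].duplicated().any():
        dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SimulationError(f"duplicate sample_id {dup!r}")

    out_dir = Path(out_dir)
    fastq_dir = out_dir / "fastq"
    truth_dir = out_dir / "truth"
    fastq_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    fastq_paths: dict[str, Path] = {}
    truth_paths: dict[str, Path] = {}
    for sample_id in manifest["sample_id"]:
        truth = truth_map[sample_id]
        reads, table = simulate_sample(truth, catalog, sample_id=sample_id)
        fq = fastq_dir / f"{sample_id}.fastq"
        write_fastq(fq, reads)
        tp = truth_dir / f"{sample_id}.truth.tsv"
        table.to_csv(tp, sep="\t", index=False)
        fastq_paths[sample_id] = fq
        truth_paths[sample_id] = tp

    manifest_path = out_dir / "manifest.tsv"
    write_manifest(manifest, manifest_path)
    return {
        "manifest": manifest_path,
        "fastq": fastq_paths,
        "truth": truth_paths,
        "truths": truth_map,
    }


# ----------------------------------------------------- corpus-scale manifest

def make_corpus_manifest(
    n_ev_only_studies: int = 55,
    n_paired_studies: int = 28,
    n_samples: int = 2756,
    n_cell_samples: int = 513,
) -> pd.DataFrame:
    """Deterministic manifest emulating the scale of the public EV corpus:
    EV-only and paired EV+cell studies, with donor-cell samples confined to
    the paired studies.  Metadata-only (no reads); used for manifest
    arithmetic and design checks."""
    n_studies = n_ev_only_studies + n_paired_studies
    n_ev = n_samples - n_cell_samples
    if n_paired_studies < 1 or n_ev < n_studies:
        raise ValueError("infeasible corpus dimensions")

    # Spread cells over paired studies, EVs over all studies, remainder-first.
    cells = [n_cell_samples // n_paired_studies] * n_paired_studies
    for i in range(n_cell_samples % n_paired_studies):
        cells[i] += 1
    evs = [n_ev // n_studies] * n_studies
    for i in range(n_ev % n_studies):
        evs[i] += 1

    rows: list[dict] = []
    for s in range(n_studies):
        paired = s < n_paired_studies
        study_id = f"GSE{900000 + s}"
        method = ISOLATION_METHODS[s % len(ISOLATION_METHODS)]
        source = "cell_line" if paired else ("biofluid" if s % 2 else "primary_culture")
        n_cell = cells[s] if paired else 0
        n_pairs = min(evs[s], n_cell)
        for j in range(evs[s]):
            rows.append(
                {
                    "sample_id": f"{study_id}_EV{j + 1:03d}",
                    "study_id": study_id,
                    "compartment": "EV",
                    "source": source,
                    "biofluid_name": "plasma" if source == "biofluid" else None,
                    "isolation_method": method,
                    "rna_kit": "miRNeasy",
                    "pair_id": f"{study_id}_p{j + 1}" if j < n_pairs else None,
                }
            )
        for j in range(n_cell):
            rows.append(
                {
                    "sample_id": f"{study_id}_cell{j + 1:03d}",
                    "study_id": study_id,
                    "compartment": "cell",
                    "source": source,
                    "biofluid_name": None,
                    "isolation_method": method,
                    "rna_kit": "miRNeasy",
                    "pair_id": f"{study_id}_p{j + 1}" if j < n_pairs else None,
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


# ------------------------------------------------ statistical-design helpers

def simulate_proportion_design(
    seed: int,
    n_studies: int = 3,
    n_pairs: int = 10,
    ev_shift: float = 0.0,
    base: float = 0.3,
    noise_sd: float = 0.05,
    study_sd: float = 0.03,
    method_effects: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample biotype proportions under a paired multi-study design.

    Gaussian model: base + study effect + isolation-method effect +
    ``ev_shift`` (EV samples only) + noise, clipped to [0, 1].  Used for
    calibration and power checks of the confounder-adjusted ANOVA.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_studies):
        study_id = f"study{s + 1:02d}"
        method = ISOLATION_METHODS[s % len(ISOLATION_METHODS)]
        study_eff = rng.normal(0.0, study_sd)
        method_eff = (method_effects or {}).get(method, 0.0)
        for p in range(n_pairs):
            for compartment in ("EV", "cell"):
                value = (
                    base
                    + study_eff
                    + method_eff
                    + (ev_shift if compartment == "EV" else 0.0)
                    + rng.normal(0.0, noise_sd)
                )
                rows.append(
                    {
                        "sample_id": f"{study_id}_{compartment}{p + 1}",
                        "study_id": study_id,
                        "compartment": compartment,
                        "isolation_method": method,
                        "pair_id": f"{study_id}_p{p + 1}",
                        "proportion": float(np.clip(value, 0.0, 1.0)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_nb_counts(
    seed: int,
    n_features: int = 200,
    n_ev: int = 8,
    n_cell: int = 8,
    n_de: int = 20,
    log2fc: float = 2.0,
    dispersion: float = 0.1,
    mean_log: float = 4.5,
    mean_log_sd: float = 1.0,
    libsize_range: tuple[float, float] = (0.7, 1.3),
    n_methods: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Negative-binomial miRNA count matrix with planted EV/cell effects.

    The first ``n_de`` features carry the planted log2 fold change in EV
    samples; the rest are null.  Per-sample library-size factors are uniform
    on ``libsize_range``.  Returns (counts features x samples, sample table,
    planted feature ids).
    """
    rng = np.random.default_rng(seed)
    features = [f"mir{i + 1:04d}" for i in range(n_features)]
    de_features = features[:n_de]
    base = np.exp(rng.normal(mean_log, mean_log_sd, size=n_features))

    samples, compartments, methods = [], [], []
    for i in range(n_ev):
        samples.append(f"EV{i + 1}")
        compartments.append("EV")
        methods.append(ISOLATION_METHODS[i % n_methods])
    for i in range(n_cell):
        samples.append(f"cell{i + 1}")
        compartments.append("cell")
        methods.append(ISOLATION_METHODS[i % n_methods])
    sf = rng.uniform(*libsize_range, size=len(samples))

    lfc = np.zeros(n_features)
    lfc[:n_de] = log2fc
    counts = np.empty((n_features, len(samples)), dtype=np.int64)
    for j, comp in enumerate(compartments):
        mu = base * sf[j] * (2.0**lfc if comp == "EV" else 1.0)
        if dispersion > 0:
            n_param = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(n_param, n_param / (n_param + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=features, columns=samples)
    sample_df = pd.DataFrame(
        {
            "sample_id": samples,
            "compartment": compartments,
            "isolation_method": methods,
        }
    )
    return counts_df, sample_df, de_features
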