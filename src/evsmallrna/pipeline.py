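"""End-to-end orchestration: simulate -> infer adapter -> trim -> quantify ->
QC -> composition -> enrichment, with every intermediate written to disk.

All randomness flows from the single config seed through per-stage derived
seeds, so a rerun with the same config reproduces byte-identical tabular
outputs.  Each stage consumes only files produced by earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._fastq import read_fastq
from .adapters import AdapterPattern, find_adapter
from .catalog import ReferenceCatalog, default_catalog
from .composition import biotype_proportions, profiles_to_frame, ratio_summary
from .enrichment import (
    anova_biotype,
    classifications_to_frame,
    classify_export,
    de_results_to_frame,
    differential_mirnas,
)
from .manifest import load_manifest
from .mapping import quantify_sample
from .qc import (
    QCThresholds,
    flag_study,
    qc_report,
    reports_to_frame,
    study_variability,
    summaries_to_frame,
)
from .simulate import DEFAULT_ADAPTER3, build_paired_design, simulate_study_set
from .trimming import trim_sample, write_trim_stats

logger = logging.getLogger("evsmallrna")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "evqc_run"
    # simulation
    n_studies: int = 2
    n_pairs: int = 4
    n_reads: int = 2000
    error_rate: float = 0.0
    read_length: int = 51
    adapter3: str = DEFAULT_ADAPTER3
    rand5_len: int = 4
    rand3_len: int = 4
    planted_biotype_shift: dict = field(default_factory=dict)
    planted_log2fc: dict = field(default_factory=dict)
    # adapter inference
    max_reads: int = 50_000
    min_anchored: int = 100
    consensus_threshold: float = 0.8
    # QC gates
    qc_min_reads: int = 100_000
    qc_min_overall_map: float = 0.20
    qc_min_host_reads: int = 100_000
    qc_min_host_frac: float = 0.50
    qc_min_smallrna: float = 0.75
    qc_min_mirna: float = 0.10
    # enrichment
    min_testable: int = 2
    mostly_tolerance: int = 3

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_reads=self.qc_min_reads,
            min_overall_map=self.qc_min_overall_map,
            min_host_reads=self.qc_min_host_reads,
            min_host_frac=self.qc_min_host_frac,
            min_smallrna=self.qc_min_smallrna,
            min_mirna=self.qc_min_mirna,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis-relevant config (the output path is
        location, not analysis, so two runs of one config hash alike)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


TSV_FLOAT = "%.10g"


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run summary (also written
    as ``run_summary.json``).  Any stage failure raises PipelineError naming
    the stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"version": __version__, "config_hash": config.digest()}

    # ---------------------------------------------------------- simulate
    stage = "simulate"
    try:
        catalog = default_catalog(_stage_seed(config.seed, 0))
        ReferenceCatalog(catalog.host_entries).to_fasta(out / "catalog_host.fa")
        ReferenceCatalog(catalog.nonhost_entries).to_fasta(out / "catalog_nonhost.fa")
        adapter = AdapterPattern(
            config.adapter3, rand5_len=config.rand5_len, rand3_len=config.rand3_len
        )
        design = build_paired_design(
            _stage_seed(config.seed, 1),
            catalog,
            n_studies=config.n_studies,
            n_pairs=config.n_pairs,
            n_reads=config.n_reads,
            adapter=adapter,
            error_rate=config.error_rate,
            planted_biotype_shift=config.planted_biotype_shift,
            planted_log2fc=config.planted_log2fc,
            read_length=config.read_length,
        )
        bundle = simulate_study_set(design, catalog, out)
        manifest = load_manifest(bundle["manifest"])
        logger.info("simulated %d samples", len(manifest))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --------------------------------------------------- adapter inference
    stage = "adapter_inference"
    adapter_dir = out / "adapters"
    adapter_dir.mkdir(exist_ok=True)
    patterns: dict[str, AdapterPattern | None] = {}
    anchors = catalog.subset(origin="host", biotype="miRNA")
    for sample_id, fq in sorted(bundle["fastq"].items()):
        try:
            pattern = find_adapter(
                read_fastq(fq),
                anchors,
                max_reads=config.max_reads,
                min_anchored=config.min_anchored,
                consensus_threshold=config.consensus_threshold,
            )
            if pattern is None:
                raise ValueError("no adapter pattern detectable")
            pattern.to_json(adapter_dir / f"{sample_id}.json")
            patterns[sample_id] = pattern
        except Exception as exc:
            raise PipelineError(stage, f"sample {sample_id}: {exc}") from exc

    # -------------------------------------------------------------- trim
    stage = "trim"
    trimmed_dir = out / "trimmed"
    trimmed_dir.mkdir(exist_ok=True)
    trimmed: dict[str, list] = {}
    trim_stats: dict[str, object] = {}
    for sample_id, fq in sorted(bundle["fastq"].items()):
        try:
            emitted, stats = trim_sample(
                fq, patterns[sample_id], trimmed_dir / f"{sample_id}.fastq"
            )
            trimmed[sample_id] = emitted
            trim_stats[sample_id] = stats
        except Exception as exc:
            raise PipelineError(stage, f"sample {sample_id}: {exc}") from exc
    write_trim_stats(out / "trim_stats.tsv", trim_stats)

    # ---------------------------------------------------------- quantify
    stage = "quantify"
    profile_dir = out / "profiles"
    profiles = {}
    for sample_id in sorted(trimmed):
        try:
            profile = quantify_sample(trimmed[sample_id], catalog, sample_id=sample_id)
            profile.write(profile_dir)
            profiles[sample_id] = profile
        except Exception as exc:
            raise PipelineError(stage, f"sample {sample_id}: {exc}") from exc

    # ---------------------------------------------------------------- QC
    stage = "qc"
    try:
        thresholds = config.qc_thresholds()
        reports = {sid: qc_report(profiles[sid], thresholds) for sid in sorted(profiles)}
        qc_frame = reports_to_frame(reports.values())
        qc_frame.to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format=TSV_FLOAT)
        study_of = dict(zip(manifest["sample_id"], manifest["study_id"]))
        by_study: dict[str, list] = {}
        for sid, rep in reports.items():
            by_study.setdefault(study_of[sid], []).append(rep)
        excluded = {study: flag_study(reps) for study, reps in by_study.items()}
        props_by_study = {
            study: [r.smallrna_frac_of_host for r in reps]
            for study, reps in by_study.items()
        }
        summaries = study_variability(props_by_study, excluded)
        summaries_to_frame(summaries).to_csv(
            out / "study_summary.tsv", sep="\t", index=False, float_format=TSV_FLOAT
        )
        summary["qc"] = {
            "n_samples": len(reports),
            "n_flagged": int(sum(bool(r.flags) for r in reports.values())),
            "excluded_studies": sorted(s for s, e in excluded.items() if e),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -------------------------------------------------------- composition
    stage = "composition"
    try:
        comps = [biotype_proportions(profiles[sid]) for sid in sorted(profiles)]
        comp_frame = profiles_to_frame(comps)
        comp_frame.to_csv(
            out / "composition.tsv", sep="\t", index=False, float_format=TSV_FLOAT
        )
        ratios = ratio_summary(comps, study_of)
        ratios.to_csv(out / "ratio_summary.tsv", sep="\t", index=False, float_format=TSV_FLOAT)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --------------------------------------------------------- enrichment
    stage = "enrichment"
    try:
        enrich_dir = out / "enrichment"
        enrich_dir.mkdir(exist_ok=True)
        long_rows = []
        for c in comps:
            for bt, p in c.proportions.items():
                long_rows.append({"sample_id": c.sample_id, "biotype": bt, "proportion": p})
        prop_long = pd.DataFrame(long_rows)
        meta = manifest.rename(columns={})[
            ["sample_id", "compartment", "isolation_method", "study_id"]
        ]
        anova_results = anova_biotype(prop_long, meta)
        pd.DataFrame(
            [
                {
                    "biotype": r.biotype,
                    "direction": r.direction,
                    "p_compartment": r.p_compartment,
                    "effect": r.effect,
                    "dropped_terms": ",".join(r.dropped_terms),
                }
                for r in anova_results
            ]
        ).to_csv(enrich_dir / "biotype_anova.tsv", sep="\t", index=False, float_format=TSV_FLOAT)

        mirna_ids = sorted(
            e.feature_id for e in catalog.host_entries if e.biotype == "miRNA"
        )
        per_study_de = {}
        for study, group in manifest.groupby("study_id"):
            sample_ids = sorted(group["sample_id"])
            counts = pd.DataFrame(
                {
                    sid: [
                        int(round(profiles[sid].feature_counts.get(f, 0.0)))
                        for f in mirna_ids
                    ]
                    for sid in sample_ids
                },
                index=mirna_ids,
            )
            results = differential_mirnas(counts, meta, study_id=study)
            de_results_to_frame(results).to_csv(
                enrich_dir / f"de_{study}.tsv", sep="\t", index=False, float_format=TSV_FLOAT
            )
            per_study_de[study] = results
        classification_summary = {}
        if len(per_study_de) >= 2:
            classes = classify_export(
                per_study_de,
                min_testable=config.min_testable,
                mostly_tolerance=config.mostly_tolerance,
            )
            classifications_to_frame(classes).to_csv(
                enrich_dir / "export_classification.tsv", sep="\t", index=False
            )
            for c in classes:
                classification_summary.setdefault(c.export_class, 0)
                classification_summary[c.export_class] += 1
        summary["enrichment"] = {
            "biotype_directions": {r.biotype: r.direction for r in anova_results},
            "n_significant_per_study": {
                s: int(sum(r.significant for r in res)) for s, res in per_study_de.items()
            },
            "export_classes": classification_summary,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    summary["studies"] = sorted(manifest["study_id"].unique())
    summary["n_samples"] = int(len(manifest))
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
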