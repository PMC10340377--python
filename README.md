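# evsmallrna

Quality assessment and cargo-enrichment analysis for **extracellular-vesicle
(EV) small RNA sequencing**, packaged with a ground-truth simulator so every
stage is testable without downloading a single public dataset.

EVs — exosomes, microvesicles and related particles — carry small non-coding
RNAs between cells: miRNAs, Y RNAs, and fragments of tRNA, rRNA, snRNA,
snoRNA and mt-tRNA. Profiling that cargo by small RNA-seq is plagued by
heterogeneous library kits (undocumented 3′ adapters, degenerate "4N" random
bases), uneven data quality across studies, isolation-method batch effects,
and the central biological question of which RNAs are *selectively loaded*
into vesicles versus retained in the donor cell. This package implements the
full assessment chain a reanalysis of such a corpus needs:

1. **Reference-free adapter inference** (`evsmallrna.adapters`) — anchors
   reads on known miRNA sequences and calls, by positional base consensus,
   the 3′ adapter sequence and the number of random bases at each end of the
   insert. No kit metadata is ever consulted.
2. **Trimming** (`evsmallrna.trimming`) — removes the adapter (minimum
   overlap 7, one substitution tolerated from overlap 10) and the random
   bases; inserts under 16 nt are "too short" and discarded.
3. **Hierarchical biotype assignment** (`evsmallrna.mapping`) — host catalog
   first (≤ 1 substitution), then non-host catalog (exact, inserts > 19 nt
   only), else unmapped; multi-mapped reads count once per biotype (priority
   miRNA > tRNA > rRNA > …) and fractionally per feature. Reports raw counts
   and CPM (counts per million kept reads).
4. **QC gating** (`evsmallrna.qc`) — per-sample read-depth and mapping-rate
   gates (> 100,000 trimmed reads, ≥ 20 % overall mapping, ≥ 100,000 host
   reads, > 50 % host fraction, ≥ 75 % small RNA of host, ≥ 10 % miRNA of
   host), study-level exclusion when a strict majority of samples fails the
   content rules, and per-study median/IQR variability summaries.
5. **Composition statistics** (`evsmallrna.composition`) — eight-class
   biotype proportions (miRNA, tRNA, rRNA, Y RNA, snRNA, snoRNA, mt-tRNA,
   misc) over total small-RNA reads, plus pseudocounted log₂ miRNA/rRNA and
   log₂ YRNA/tRNA diagnostic ratios and Welch *t* group comparisons.
6. **EV-vs-cell enrichment** (`evsmallrna.enrichment`) — for each biotype, a
   three-factor ANOVA (compartment + isolation method + study, type-II
   F-test on compartment); for each miRNA within a study, a
   negative-binomial GLM
   `count ~ compartment + isolation_method + offset(log s_j)` with
   median-of-ratios size factors, moment-estimated dispersion and a Wald
   test, BH-corrected (significant when FDR < 0.05 and |FC| > 1.5); and a
   cross-study export classification (context-independent EV cargo,
   mostly-EV, context-independent cell, study-specific).
7. **Simulation** (`evsmallrna.simulate`) — reads built as
   `rand5 + insert + rand3 + adapter`, with catalog-drawn inserts, fragment
   windows for long biotypes, per-sample composition, log-normal feature
   abundances, planted EV/cell effects, and byte-identical output per seed.

## Worked example

Simulate one EV library (5000 reads, TruSeq-style adapter with 4N random
bases, 1 % sequencing error), then recover everything from the reads alone:

```python
from evsmallrna import (AdapterPattern, QCThresholds, SimulationTruth,
                        biotype_proportions, default_catalog, find_adapter,
                        qc_report, quantify_sample)
from evsmallrna.simulate import DEFAULT_ADAPTER3, default_composition, simulate_sample
from evsmallrna.trimming import trim_reads

catalog = default_catalog(seed=1)
truth = SimulationTruth(
    adapter=AdapterPattern(DEFAULT_ADAPTER3, rand5_len=4, rand3_len=4),
    composition=default_composition("EV"), n_reads=5000, seed=11, error_rate=0.01)
reads, _ = simulate_sample(truth, catalog, sample_id="demo")

pattern = find_adapter((seq for _, seq, _ in reads), catalog)
emitted, stats = trim_reads(reads, pattern)
profile = quantify_sample(emitted, catalog, sample_id="demo")
report = qc_report(profile, QCThresholds(min_reads=1000, min_host_reads=500))
comp = biotype_proportions(profile)
```

which prints (via the obvious f-strings):

```
adapter=TGGAATTCTCGGGTGCCAAGG rand5=4 rand3=4 support=1.00 kit=Illumina TruSeq Small RNA
kept=3517 too_short=0 no_adapter=1483
overall_map_rate=0.675 host_frac=0.663 smallRNA/host=0.926 miRNA/host=0.440 flags=[]
top biotypes: miRNA=0.475, YRNA=0.209, rRNA=0.146, tRNA=0.066
log2(miRNA/rRNA)=1.70  log2(YRNA/tRNA)=1.66
```

The planted adapter pattern is recovered exactly from the reads; the ~30 %
of reads with no adapter hit are the simulated unmappable background, which
correctly drags the overall mapping rate to 0.675 while the host reads stay
> 92 % small RNA — so the sample passes every QC gate. The composition
reproduces the generating mixture: miRNA-dominated with substantial Y RNA
and rRNA-fragment mass.

The same stages are available from the shell: `evsim catalog|sample|study`
to generate data, and `evqc find-adapter|trim|quantify|report|composition|
enrich|run` to analyze it (`evqc run --config run.yaml` executes the whole
chain deterministically).

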