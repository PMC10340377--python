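# Methods

This note documents the models and procedures implemented in `evsmallrna`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## The read model and the simulator

A small RNA-seq read is modeled as

```
read = [rand5 bases] + insert + [rand3 bases] + 3' adapter + padding,
```

truncated to the read length (default 51 nt, a common single-end small-RNA
configuration; instrument characteristics are a free parameter). `rand5`/
`rand3` are the degenerate bases some library kits (e.g. 4N protocols) place
between insert and adapter; both are ≤ 8 nt. Inserts are drawn from a
labeled reference catalog. Catalog entries at most 35 nt long (miRNAs and
other compact species) are sequenced full length; longer entries (tRNA,
rRNA, and any other long precursor) contribute a uniformly placed random
window of 18–35 nt, emulating the fragment nature of those biotypes without
modeling their biogenesis. Substitution errors are applied per base at a
configurable rate (≤ 5 %); indels and ligation bias are not simulated.
Quality strings are constant Phred 40 — the pipeline inspects but never
filters on quality. The un-allocated remainder of a sample's composition is
uniform random sequence ("junk") that is expected to map nowhere and
exercises the mapping-rate QC gates.

Per-sample biotype mixtures default to EV- and cell-characteristic
compositions (EV: relatively more rRNA/tRNA/Y RNA fragment mass; cells:
more miRNA and snoRNA), jittered by a Dirichlet draw (concentration 300) to
create between-sample variability. Feature abundances within a biotype are
log-normal (σ = 1), shared by all samples of a study; planted EV effects
multiply EV-sample abundances by `2^log2fc`. A fixed seed makes all output
byte-identical; every down-stream seed derives from one root seed.

Two consistency choices make error-free simulations exact oracles rather
than merely approximate ones: catalog sequences are rejected if they contain
the first 8 nt of a common library adapter, and each simulated read is
checked against the trimmer's own matching rule so that the leftmost adapter
occurrence is the planted one (flanks are redrawn in the rare chance-match
case). Without these, roughly one read in ten thousand would trim at a
spurious prefix match and break byte-level comparisons.

**What the simulator does not capture:** ligation/sequence bias of real
kits, indels, isomiR heterogeneity, genuine exogenous (microbial) content
beyond a small decoy catalog, and the long-tailed library-size and quality
variation of public data. Passing the synthetic benchmarks therefore
demonstrates the *correctness of the implemented contracts* (trimming
arithmetic, assignment rules, gate boundaries, statistical calibration on
the assumed generative families), not performance on any real corpus.

## Adapter-pattern inference

Inference is anchor-consensus and uses only the read stream plus the miRNA
catalog — never kit metadata. Reads containing the exact 16-nt seed of a
catalog miRNA, extended to a full exact anchor match, yield (offset, suffix)
pairs. The 5′ random-base length is the modal offset (ties broken toward the
smaller offset). The 3′ random-base length is the smallest shift
`s ∈ [0, 8]` at which **every** one of the first 8 suffix positions from `s`
has a majority-base fraction ≥ the consensus threshold (default 0.8); the
adapter call is the per-position majority base from `s` onward, truncated at
30 nt or when coverage drops below half of `min_anchored` (default 100).
Base ties break lexicographically. The support fraction is the share of
anchored reads consistent with the called pattern (modal offset, adapter
prefix within one mismatch).

The per-position **minimum** criterion, rather than an average over the 8
positions, is essential: a uniform random column has a majority fraction
near 0.25–0.3, so an average over 8 positions crosses 0.8 while two random
columns are still inside the window, systematically undercalling the random
bases. With the minimum criterion a random column can never pass, and the
called shift is exact. This also preserves monotonicity: raising the
threshold never decreases the called 3′ length. Defaults (subsample cap
50,000 reads; `min_anchored` 100; threshold 0.8) favor robustness at desk
scale and are all configurable. A table of common kit adapters is used only
to *annotate* a call with a likely kit name, never to infer.

## Trimming

The leftmost occurrence of an adapter prefix wins, with minimum overlap
7 nt; overlaps below 10 nt must match exactly and overlaps of ≥ 10 nt
tolerate one substitution — a deterministic stand-in for a 10 % error-rate
matching policy. After adapter removal the configured number of random bases
is stripped from both ends. Inserts shorter than 16 nt are classified
`too_short` and discarded; inserts of ≥ 16 nt are `kept`. Reads with no
adapter occurrence are classified `no_adapter`: the 5′ random bases are
still stripped (they are present regardless), the 3′ ones are not (the read
ended inside the insert), and the read is passed through by default (a
`--discard-untrimmed` switch inverts this) — the conservative choice, since
an insert may simply fill the read. The three statuses partition the input
exactly. Random bases are removed, not used for deduplication.

## Biotype assignment

Mapping is substring matching against catalog sequences — the deterministic
equivalent of a `-v`-style short-read aligner at desk scale. Host tier: at
most one substitution, no indels, with 0-mismatch hits suppressing
1-mismatch hits. The matcher uses pigeonhole seed-and-verify (any 1-mismatch
placement matches one half of the insert exactly) and is verified in the
tests against an exhaustive vectorized Hamming search. Non-host tier: exact
matches only, and only for host-unmapped inserts longer than 19 nt. A read
hitting several features counts once toward the highest-priority biotype
present (miRNA > tRNA > rRNA > snRNA > snoRNA > YRNA > mt-tRNA > lincRNA >
misc > host_other; configurable) and `1/k` toward each of the `k` tied
features of that biotype, so biotype counts partition host reads while
feature-level mass is conserved. `host_other` models genome-mapped reads
outside small-RNA annotation. CPM is `count × 10⁶ / kept reads`.

Generated catalogs keep all sequences at pairwise Hamming distance ≥ 3
(sliding the shorter over the longer), so 1-mismatch assignment of
full-length inserts is unambiguous and error-free round trips recover
ground-truth counts exactly.

## QC metrics and gates

With `T` trimmed (kept) reads, `H` host-mapped, `N` non-host-mapped, `S`
small-RNA (host minus `host_other`) and `M` miRNA reads:
overall mapping rate `(H+N)/T`, host fraction `H/T`, small-RNA fraction
`S/H`, miRNA fraction `M/H`; zero denominators yield 0 plus the
corresponding flag. Default gates: `low_reads` at `T ≤ 100,000`;
`low_overall_map` at rate `< 0.20`; `low_host_reads` at `H < 100,000`;
`low_host_frac` at `H/T ≤ 0.50`; `low_smallrna` at `S/H < 0.75`;
`low_mirna` at `M/H < 0.10`. The strict/non-strict direction at each
boundary follows the rule each gate paraphrases ("more than 100,000",
"greater than 50 %", "minimum of …"); where a source rule is ambiguous at
the exact boundary the chosen convention is fixed here and configurable. A
study is excluded when strictly more than half of its samples carry
`low_smallrna` or `low_mirna`; exclusion depends only on those content
flags, never on raw counts. Study variability is the median and IQR
(linear-interpolation quantiles, the common default) of small-RNA
proportions; a study is `high_quality` when median > 0.9 and IQR < 0.06.
Group comparisons of study summaries use Welch's t-test (no equal-variance
assumption — the safer default for unbalanced study groups).

## Composition

Proportions are computed over total small-RNA reads across exactly eight
classes; lincRNA and any residual class fold into `misc` so the vector sums
to 1 (to 1e-9) whenever at least one small-RNA read exists. The diagnostic
ratios `log2((miRNA+1)/(rRNA+1))` and `log2((YRNA+1)/(tRNA+1))` use a +1
pseudocount on both counts so they are finite for all inputs, including
zeros. Per-study medians of the ratios are reported with an indicator for
median > 1 (numerator class more than twice the denominator class in a
typical sample).

## Enrichment statistics

**Biotype ANOVA.** `proportion ~ compartment + isolation_method + study`,
main effects only, on untransformed proportions, with a type-II F-test on
the compartment term — type-II because multi-study EV designs are
unbalanced, and interactions are deliberately omitted (none of the planted
designs generate them, and the compartment main effect is the quantity of
interest). Study is the third factor: it is the only remaining design
variable in a multi-study paired design, and it absorbs between-study
baseline differences. Single-level terms are dropped; a rank-deficient
design (e.g. compartment confounded with study) drops the offending
confounder and annotates the result. The reported effect is the raw mean
EV − cell proportion difference.

**Per-miRNA differential test.** For each feature with any counts, a
negative-binomial (NB2) log-linear model
`count ~ compartment + isolation_method + offset(log s_j)` is fit, where
`s_j` are median-of-ratios size factors: each sample's factor is the median,
over features detected in every sample, of its count divided by the
feature's geometric mean. Median-of-ratios rather than total counts is
deliberate: a minority of genuinely exported features inflates EV totals
and would shift every null feature's apparent fold change (in the planted
benchmark, 20 of 200 features at 4× bias null log₂FC by ≈ −0.3 and push the
false-discovery proportion toward 50 %); the median is robust to such
asymmetric signal. Dispersion is estimated per feature by matching the
Pearson χ² statistic to its residual degrees of freedom (bisection on
`Σ (y−μ)²/(μ+αμ²) = n−p`, floored at 0.01, capped at 10, with one
re-estimate at the NB fit's mean) — a moment estimator that, unlike the
naive residual-variance version, accounts for variance already absorbed by
the fitted mean. The compartment Wald statistic is referred to a *t*
distribution with residual df rather than the normal, the standard
small-sample correction; with these two choices permutation-null p-values
are uniform (KS test), where the naive estimator + normal reference is
visibly anticonservative at n = 16. No information is shared across
features (no shrinkage); the tests verify the route against pydeseq2 as an
independent reference implementation. Benjamini–Hochberg correction is
applied across tested features, and a feature is significantly differential
when FDR < 0.05 and |fold change| > 1.5. Counts must be integers (tied
fractional feature counts are rounded before testing in the pipeline — ties
are essentially impossible under the separated catalog).

**Export classification.** Per study a feature is EV-enriched
(significant, log₂FC > 0), cell-enriched, `ns`, or `untestable` (absent
from that study's tested set). With at least `min_testable` (default 2)
testable studies: `context_independent_EV` when EV-enriched in *every*
testable study (symmetric for cells); `mostly_EV` when never cell-enriched
and EV-enriched in all but at most `k` (default 3) testable studies;
`study_specific` when significant somewhere but inconsistent; otherwise
`unclassified`.

**Expression screening.** `median_normalize` divides each feature by its
median across samples (≥ 3 samples required; zero-median features are set
to 0 and flagged) to put highly expressed features on a common scale. The
"highly abundant" cutoff on that scale is exposed as a parameter with no
fixed default.

## Problem sizes in the benchmarks

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen to keep each check sharp while the whole suite stays
fast: libraries of 800–5000 reads; catalogs of ~80 entries (500 for the
matcher-vs-oracle comparison); 100 seeded libraries for adapter recovery;
500 null and 200 shifted simulations for ANOVA calibration and power; 50
seeds × 200 features × 8 vs 8 samples for differential-test recovery;
2 studies × 2–4 pairs for end-to-end runs. QC-gate scenarios scale the two
read-count thresholds to the simulated depths (e.g. 1000/500) — the gate
logic is identical at any threshold, and the boundary semantics of the
full-scale defaults are tested exactly in the unit suite.

## Known limitations

* Substring matching cannot represent spliced or indel alignments, genome
  coordinates, or isomiR variation; there is no SAM/BAM output.
* The NB dispersion is estimated per feature without cross-feature
  shrinkage, which costs power at very small n relative to
  empirical-Bayes methods; calibration, not maximal power, was the goal.
* The ANOVA treats proportions as unbounded responses; with proportions
  near 0 or 1 a variance-stabilizing transform would be preferable.
* Adapter inference requires the library to contain full-length miRNA
  inserts matching the anchor catalog exactly; heavily degraded or
  miRNA-poor libraries return "none detected" rather than a guess.
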