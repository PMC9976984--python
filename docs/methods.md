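# Methods

## The benchmark design

`taxbench` evaluates taxonomic classifiers against synthetic data whose
ground truth is known by construction. The central device is the
*exclusion database*: for a registry of n microbial species and one host,
each replicate consists of one host-only file (Dataset-1, the negative
control) and n mixture files (Dataset-2), the i-th of which contains reads
from every microbial species except species i. Because the left-out species
contributed no reads, any count a tool assigns to it in that file is a
false positive of bacterial origin (cross-species mis-hits); any microbial
count in the host-only file is a false positive of host origin. True
positives for a species present in a file are its reported count minus its
count in the negative control, clamped at zero. This subtraction puts
binners (per-read counts) and profilers (relative abundances, first
converted to pseudo-counts) on one comparable metric.

## Read simulation model

Reads are paired-end. For each fragment the simulator draws, from a single
`numpy.random.Generator`:

1. an inter-mate gap, uniform on [`gap_min`, min(`gap_max`, G − 2L)]
   (defaults 0–300 nt) — the insert-size law of real libraries is platform
   dependent and a uniform gap is the least-informative bounded choice;
2. a fragment start, uniform over all placements that fit both mates and
   the gap on the linear genome (fragments never wrap);
3. a strand with probability 1/2. Mate 1 reads the fragment strand; mate 2
   is the reverse complement of the fragment's other end, as a sequencer
   reports it. Coordinates recorded in the truth manifest are forward-genome
   offsets of each mate's slice.

### Quality model

Per-base qualities are integers on the Phred scale. A non-tail base at
scenario mean μ takes the value μ − f + Binomial(2f, 1/2), i.e. a symmetric
discrete distribution with mean μ whose support is exactly the *variance
frame* [μ − f, μ + f]; f defaults to 4. This makes the frame a hard bound,
not a dispersion summary: no sampled non-tail quality can leave it. The
last `tail_length` = 10 positions model phasing/signal decay: tail position
k (k = 1…10) loses k·`tail_step` Phred units (default 1/position, a linear
schedule — the simplest monotone "progressive" penalty) before flooring at
`floor_phred` = 2, the conventional minimum meaningful base quality. Scenario
means are 23 ("bad", per-base error 10^(−2.3) ≈ 0.005) and 35 ("good",
≈ 0.00032).

### Error injection

Each base is substituted independently with probability 10^(−q/10) for its
sampled quality q, choosing uniformly among the three alternative bases;
N bases are never substituted. This makes the emitted quality strings
operationally meaningful and is switchable off (`inject_errors=False`) for
quality-string-only emulation. Indels, PCR duplicates, adapters and
platform-specific error profiles are out of scope.

### Composition arithmetic

Given `reads_per_species` R fragments per microbe and per-species
prevalence p, a file holds `total = round(R/p)` fragments, of which
`host = total − n·R` are host and the overall microbial prevalence is n·p.
With the preset regimes and 20 mixed species: R = 10 000, p = 3.9% gives
256 410 fragments (56 410 host, 78% microbial); R = 1 000, p = 1.5% gives
66 667 fragments (46 667 host, 30% microbial). Rounding makes emitted
prevalences exact to within one read. Dataset-1 is sized to the Dataset-2
total so false-positive counts from the two datasets are directly
comparable.

### Determinism

Every file's seed is the SHA-256 of (base_seed, scenario, left-out species,
replicate) folded to 31 bits, so files are mutually independent and the
whole database is reproducible file-by-file. Records are shuffled with the
file's generator and given neutral sequential ids (truth lives only in the
manifest). Gzip streams are written with a pinned header (mtime 0, no
filename), so identical configuration and seed yield byte-identical FASTQ.

## Scoring

Per species and replicate: Se = TP/(TP+FN), PPV = TP/(TP+FP),
F1 = 2·Se·PPV/(Se+PPV). Degenerate corners: PPV := 1 when TP = FP = 0 (no
false claim was made; flagged `vacuous_ppv`), Se := 0 when the ground truth
is empty (flagged `degenerate_truth`), F1 := 0 when Se + PPV = 0. Because a
species appears in n − 1 mixture files per replicate, the harness takes its
TP as the mean of the clamped subtraction over those files, rounded to the
nearest read and capped at the ground truth; the per-file primitive
(`subtract_negative`) is exposed unchanged for other aggregation choices.
Bacterial-origin and host-origin false positives are summed for PPV;
both primitives are available separately. Replicate aggregation reports the
arithmetic mean and sample SD (n − 1 denominator; SD 0 with a flag for
single-replicate groups).

### Coverage evidence

For a species credited with n reads of length L on a genome of length G,
the observed coverage breadth (fraction of the genome under the union of
the assigned intervals) is compared with the expectation under independent
uniform placement, 1 − (1 − L/G)^n. The ratio observed/expected (0 when
n = 0) is scale-free in (L, G) at fixed n; assignments scoring below a
configurable threshold (default 0.5) are flagged for discard, on the logic
that reads piling onto one locus are weak evidence that the genome is
present. This closed-form placement model is this package's own stand-in
for coverage-scoring binners whose internal formulas are not public; it
shares their contract (expected vs observed breadth), not their exact
score.

## Statistical battery

Group location comparisons are routed by a normality gate: Shapiro–Wilk for
samples below 30 observations, the Lilliefors variant of the
Kolmogorov–Smirnov test from 30 up (`statsmodels`). If both samples pass at
α = 0.05 a two-sample t-test is used (one-way ANOVA beyond two groups),
otherwise the Wilcoxon rank-sum test with the tie-corrected normal
approximation. Pairs of constant samples are flagged and not tested.
Variance ranges are compared with Fligner–Killeen (rank-based, robust to
non-normality; the choice of variance test is this package's own).
Cross-tool agreement uses Spearman's rank correlation on per-species
sensitivity profiles with pairwise-complete observations (≥ 3 shared
species per pair). No multiple-testing correction is applied; all p-values
are reported.

## What the synthetic data does and does not emulate

The generator reproduces controlled prevalence, bounded quality with a
decaying tail, paired-end geometry and quality-consistent substitution
errors on arbitrary (including toy) genomes. It does not reproduce real
genomic repeat structure, strain-level variation, low-complexity regions,
host transcriptome structure (host reads are simulated from a host FASTA,
a synthetic stand-in for real unmapped-host decoy reads), indels, adapter
or contaminant content. Passing benchmarks here therefore demonstrate that
a classifier's accounting, thresholds and abundance reporting behave
correctly under known truth — not how it handles the sequence-similarity
ambiguities of real communities.

## Problem sizes

The test suite and the acceptance script run at deliberately small scale:
toy genomes of 10–100 kb, 3-species registries with 20–50 fragments per
microbe for structural checks, 10 000 quality strings for the quality-model
measurements, and one full-size mixture file (21 species × 10 000
fragments, 256 410 pairs at 48 nt) for the end-to-end composition check.
These sizes were chosen so the whole suite completes in a few minutes while
every estimate they produce (prevalence fractions, quality means, error
rates) is already well inside its Monte-Carlo tolerance.
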