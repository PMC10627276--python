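# Methods

This note documents the models and procedures `modpore` implements, the
parameters that matter, what the simulator does and does not emulate,
and the numerical conventions that make results reproducible.

## Error model and definitions

All coordinates are 0-based, half-open; the internal alphabet is RNA
(A, C, G, U), with T accepted on input and normalized to U. Reads are
compared against the known template transcript (the "DNA sense strand"
view of a direct-RNA read).

Per reference position the pileup records base-call counts, deletion
counts, and insertion events:

* **mismatch rate** = mismatched calls / (matched + mismatched calls).
  Deletions are *excluded* from this denominator.
* **deletion rate** = deleted / (aligned + deleted) reference calls.
* **insertion rate** = insertion events / aligned base calls. A
  multi-base insertion is one event, attributed to the reference
  position immediately preceding the inserted bases. Whether the
  denominator should be aligned bases or reads is a genuinely open
  convention; we default to aligned bases and expose
  `denominator="reads"`.
* **A-to-X … U-to-X** = per-reference-base substitution percentages,
  with the finer per-alternative split (U→A vs U→C vs U→G) available.
  A base class with zero coverage reports a missing rate, never 0.

An indel "follows" a homopolymer run if its attributed position lies
within a maximal run of ≥ 3 identical bases or at the single position
immediately 3′ of one. Homopolymer runs are maximal and non-overlapping;
a length-5 run counts once. For base fractions of runs we support two
weightings — one-per-run (default) and length-3 sliding windows — which
can disagree at integer-percent precision (on the bundled transcript the
C fraction is 40.9% per-run, 39.9% window-weighted); published figures
rarely state which convention they used.

**Control normalization.** The per-position modification score is the
*difference* between sample and control mismatch rates. A difference is
preferred over a ratio because control rates near zero make ratios
explode. Positions with control coverage below 20 reads are masked and
excluded from both the top-N and bottom-N of any ranking (otherwise the
bottom-N fills with uncovered, trivially error-free sites).

## Dwell analysis

Event tables carry one row per (read, reference position) keyed by the
*center* of the 5-mer in the pore reader-head (converters are provided
for start-anchored dialects and for dwell given in raw samples). Dwell
comparisons pool every occurrence of the central base across the
transcript and use a two-sided two-sample t-test — Student's
equal-variance by default, Welch by flag. With counts in the 10⁴–10⁶
range the flavor rarely changes any conclusion; both are exposed
because published tables often omit which was used.

Under a:b modified:canonical mixing, only p = a/(a+b) of target-base
molecules carry the mark, so a per-molecule dwell multiplier m appears
as a pooled mean shift of (1−p) + p·m. Measured percent changes in
mixed samples are therefore attenuated underestimates; the package's
tests verify this mixture arithmetic against simulation.

## Multivariate analyses

All PCA inputs are z-scored per feature (sample SD, n−1); constant
features are dropped with a warning. PCA uses the full SVD with a
deterministic sign convention (the largest-|loading| entry of each
component is made positive). Variance explained is reported in percent
and sums to 100 at full rank; an eigen-decomposition oracle in the test
suite pins the implementation to 1e-9.

* **Sample level.** One observation per sample with 7 variables: the
  four per-base error percentages, insertion rate, deletion rate, and
  mean dwell (the mean, not median, of all event dwells; the choice is
  documented because pooled dwell distributions are heavily skewed and
  a median variant would produce smaller numbers). Canonical replicates
  are pooled by summing pileup counts *before* computing rates, which
  is exactly equivalent to concatenating their reads.
* **Read level.** Features are per-read mean current and dwell for the
  5-mers whose signals are most variable across samples relative to
  within (one-way ANOVA per 5-mer; top 5% per channel, current and
  dwell selected independently and their union used — the joint-vs-
  separate choice is ambiguous in the field and the union is the more
  inclusive reading). Reads are subsampled to ≤ 5,000 per sample with a
  seed; reads missing > 50% of features are dropped and remaining gaps
  are feature-mean imputed with a recorded missingness fraction.
* **Nucleotide level.** One observation per reference position.
  *Without a control* the 7 variables use a base-slot encoding (the
  slot matching the reference base carries the position's mismatch
  percentage, the other three are 0), which reproduces the
  characteristic clustering of positions by base identity in PC space.
  *With a control* the features are instead four base-agnostic
  differences (Δerror, Δinsertion, Δdeletion percentages, Δmean dwell).
  This is a deliberate design choice: base identity is a known
  covariate of every position, not evidence of modification. Keeping
  the base-slot encoding in the control-normalized analysis makes the
  Euclidean outlier rule respond to cluster geometry — under a
  canonical-vs-canonical comparison the outlier set then tracks
  whichever base clusters happen to project onto PC1/PC2 (4–6σ
  composition distortions in our calibration runs) — whereas the
  difference encoding leaves all positions exchangeable under the null,
  and the outlier composition matches the transcript composition.

**Outlier sites.** Distance is Euclidean over (PC1, PC2) from the
score centroid, and the centroid is the component-wise **median** by
default. With the mean, a sizable modified minority (a third of target
positions at 1:2 mixing) drags the center toward the modified cluster
and awards spurious distance to the unmodified bulk; the median stays
anchored on the bulk. In our planted-modification benchmarks the median
centroid recovers 93/100 truth sites where the mean recovers 83/100
(`centroid="mean"` restores the plain mean). The default is top-k with
k = 100; a quantile rule is exposed, as is restriction to the declared
target base for experiments that know which nucleotide was doped.

**Read annotation.** At each outlier site, each covering read is called
*modified* if it mismatches, is deleted, or has an insertion there, or
if its dwell exceeds 1.5× the canonical sample's median dwell at that
site; *unmodified* otherwise; *no-data* without coverage. The 1.5×
factor is a package default (no published value exists); because dwell
is log-normal with SD exceeding the mean, single-event dwell is a weak
classifier and the error criterion carries most of the signal.

## The simulator

The generator emulates the IVT benchmarking design: T7 polymerase
transcribes a known ~2 kb template with one modified NTP doped in at a
molar ratio against its canonical counterpart. Since T7 incorporation
is sequence-agnostic, modification status is drawn independently per
read × target-base position with probability a/(a+b) — the ground-truth
table records every modified (read, position).

Study-condition defaults (canonical baseline): substitution 11.2%,
insertion 2.5%, deletion 5.5% — the transcript-wide error rates of
deeply sequenced canonical-only direct-RNA samples. Dwell is log-normal
per base, parameterized by target mean and SD in ms (A 17.1/26.7,
C 15.0/23.4, U 15.4/25.6 from pooled canonical event tables; G 16.0/25.0
chosen between A and C, as no canonical G figure is published);
log-normality matches the positive, right-skewed, SD > mean character
of real event dwell. Currents are Gaussian per reference 5-mer around a
deterministic synthetic pore model (means spread over ~80–130 pA, SDs
2–4 pA, fixed functions of k-mer identity shared by every simulation).

Homopolymer-enhanced indels: the indel probability at the single
position immediately 3′ of a maximal run ≥ 3 is multiplied by a
configurable factor (default 3), and the profile is then renormalized
so the configured baselines remain the expected *transcript-wide*
rates — the multiplier redistributes indels without changing totals,
which keeps parameter-recovery contracts exact. Terminal positions are
never deleted so alignments cannot start or end with a deletion.
Insertions are single-base (a multi-base insertion would count as one
event anyway). Deleted positions get no event row and inserted bases
get no event row, mirroring what resquiggling can assign.

Per-modification effect sizes are free parameters — no published source
quantifies miscall inflation per modification — and the presets fix
them once: pseudouridine-like (substitution 0.312 at modified U, i.e.
baseline + 0.2, biased toward A/C miscalls; dwell ×1.5), biotin-C-like
(substitution 0.5 — a bulky adduct, the strongest signature; dwell
×2.62, the per-molecule value consistent with a 54% pooled increase at
1:2 mixing), m6A-like (substitution 0.35 *gated on a neighboring A*,
emulating reader-head context effects, dwell ×1.09), and Am-like
(substitution 0.25, dwell ×1.07). The m6A context gate is what produces
flanking-A motif enrichment at top-error sites, versus central-base-only
enrichment for the context-free pseudouridine preset.

Reproducibility: one root seed spawns an independent child stream per
read, so output is byte-identical across runs and independent of read
order or parallelism.

### What the simulator does not emulate

Raw current squiggles, basecaller internals, PHRED qualities, poly(A)
tails, truncated or chimeric reads, coverage decay along the template,
carrier/contaminant species, and modification-specific current *shapes*
(only mean shifts). Reads span the full template, so coverage is
uniform. Consequently, passing tests demonstrate that the analysis
correctly recovers planted signals under a faithful rendering of the
experimental design's statistics — not that real basecaller error
biases are captured. Real-data summary figures (e.g. transcript-wide
PCA variance splits) depend on basecaller behavior and are not
reproducible from simulation; their published values serve here only as
simulation defaults and report formats.

## Numerical conventions and scale choices

* Ranking ties break by higher coverage, then lower position index.
* Motif significance: per-cell two-sided binomial test against the
  transcript background, Bonferroni-corrected across the 20 cells,
  flagged at |log2 enrichment| > 1 and adjusted p < 0.01. These
  thresholds are this package's own; motif calls in the literature this
  mirrors are qualitative.
* Zero-coverage or all-masked inputs raise errors rather than emitting
  zeros; undefined fractions (no indels) are reported as missing.
* Test and acceptance runs use desk-scale problem sizes chosen to make
  3-binomial-SE recovery checks decisive: 2,000 reads for rate
  recovery, 1,000× coverage for planted-site ranking, 600× for PCA
  outlier analyses, 200 replicate pairs for null calibration.

## Known limitations

* The per-read annotation's dwell criterion uses a single event per
  (read, site); with log-normal dwell (SD ≈ 1.7× mean) its
  discrimination is intrinsically weak, and annotation accuracy is
  dominated by the error criterion.
* The Euclidean outlier rule is a heuristic; it has no calibrated false
  discovery rate. The chi-square/binomial calibration tests bound its
  behavior under the null but not its FDR under alternatives.
* Event validation drops rows whose 5-mer disagrees with the reference;
  event tables from tools that report basecalled (rather than
  reference) k-mers must be converted first.
* Single unspliced reference only — by design: the IVT benchmarking
  setting sequences one known template. Genome-scale, spliced, or
  multi-isoform references are out of scope.
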