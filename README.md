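# modpore

Detection of modified ribonucleotides in Oxford Nanopore **direct RNA
sequencing** from systematic basecalling-error signatures and pore dwell
times — together with a ground-truthed simulator of the in vitro
transcription (IVT) experimental design used to benchmark such methods.

## The problem

Direct RNA nanopore sequencing reads native RNA molecules, so chemical
modifications (m6A, pseudouridine Ψ, 5-methylcytidine, 2′-*O*-methyl
sugars, bulky adducts such as biotinylated C, …) leave traces in the
data: the basecaller, trained on canonical nucleotides, systematically
miscalls modified positions, and modified nucleotides transit the pore
constriction (which holds ~5 nt at a time) at a different speed. Neither
signal is clean — even canonical-only transcripts basecall with >10%
substitution error — so modification detection is a statistics problem:
compare a sample against a canonical-only control sequenced from the
same template and find the positions whose error and dwell behavior
deviates.

`modpore` implements that comparative analysis as a tested, reusable
library for researchers benchmarking direct-RNA modification callers:

* **`refseq`** — reference transcript handling: k-mer inventory,
  maximal homopolymer runs (indels concentrate next to them), ±2-base
  context windows. A 1908-nt IVT template transcript
  (chr19:45406985–45408892, hg19) ships with the package.
* **`simdata`** — a simulator of the IVT design: per-read Bernoulli
  incorporation of one modified species at molar ratios (1:100 … 1:2,
  100%), baseline substitution/insertion/deletion errors, homopolymer-
  enhanced indels, modification-conditioned mismatch inflation,
  log-normal dwell with multiplicative shifts, per-5-mer Gaussian
  currents with additive shifts — plus a ground-truth table of every
  modified (read, position).
* **`errprof`** — per-position pileup statistics from SAM/BAM. The
  mismatch rate at a position is mismatches / (matched + mismatched);
  deletions are excluded from that denominator and rated separately;
  insertions count as events attributed to the preceding position.
  Includes the A-to-X/C-to-X/G-to-X/U-to-X substitution breakdown,
  homopolymer-adjacent indel fractions, and control normalization
  (sample − control mismatch rate).
* **`dwell`** — resquiggle-style event tables (read, position, 5-mer,
  current, dwell); per-base dwell pooling and Student/Welch t-test
  comparisons with percent change 100·(μ_mod/μ_canonical − 1).
* **`sitedetect`** — top-N / bottom-N site ranking by normalized error,
  base composition of the selections, and ±2-base motif matrices with
  log2 enrichment against the transcript background.
* **`multivar`** — three PCA views (z-score + PCA): per **sample**
  (7 variables: four per-base error rates, insertion rate, deletion
  rate, mean dwell), per **read** (ANOVA-selected top-5% most
  discriminating 5-mer current/dwell signals), and per **nucleotide**
  (outlier sites = positions farthest by Euclidean distance from the
  PC1/PC2 score centroid, then per-read modified/unmodified annotation
  from errors and long dwell at those sites).
* **`cli`** — `modpore simulate | profile | dwell | detect | pca |
  annotate | run-all`, manifest-driven.

## Worked example

Simulate a pseudouridine-like sample (1:2 modified:canonical, so ~1/3 of
uridine molecules carry the mark) plus a canonical control, then rank
sites by control-normalized error and compare uridine dwell:

```python
from modpore import refseq, simdata, errprof, sitedetect, dwell

transcript = refseq.bundled_reference()
control, _ = simdata.simulate_sample(
    simdata.preset_config("canonical", n_reads=300, seed=0), transcript)
psi, truth = simdata.simulate_sample(
    simdata.preset_config("pseudoU", mix_ratio=(1, 2), n_reads=300, seed=1),
    transcript)

psi_profile = errprof.pileup_sample(psi, transcript)
scores = errprof.normalize_to_control(
    psi_profile, errprof.pileup_sample(control, transcript))
ranking = sitedetect.rank_sites(scores, transcript, n=100,
                                coverage=psi_profile.coverage)
comp = sitedetect.site_base_composition(ranking, transcript)
print("top-100 base composition:   ", comp["top"])
print("bottom-100 base composition:", comp["bottom"])
hits = sum(1 for p in ranking.top if p in truth.positions())
print(f"truth-table sites in top-100: {hits}")

cmp_ = dwell.compare_dwell(simdata.events_frame(psi, transcript),
                           simdata.events_frame(control, transcript),
                           transcript, "U")
print(f"U dwell: {cmp_.mean_mod_ms:.1f} vs {cmp_.mean_canonical_ms:.1f} ms "
      f"({cmp_.percent_change:+.1f}%), p = {cmp_.p_value:.2e}")
```

Output (exact numbers for these seeds):

```
top-100 base composition:    {'A': 0, 'C': 0, 'G': 1, 'U': 99}
bottom-100 base composition: {'A': 29, 'C': 39, 'G': 32, 'U': 0}
truth-table sites in top-100: 99
U dwell: 17.9 vs 15.5 ms (+15.8%), p = 7.43e-99
```

Read: 99 of the 100 highest-error sites are uridines that the truth
table confirms as modified positions, while the 100 lowest-error sites
contain no uridine at all. The per-molecule 1.5× dwell multiplier shows
up as ~+16% because only a third of the U molecules are modified at 1:2
mixing — measured dwell shifts in mixed samples are always attenuated
underestimates of the per-molecule effect.

The same analysis from the shell:

```bash
modpore simulate --preset canonical --n-reads 300 --seed 0 --out-dir ctrl
modpore simulate --preset pseudoU --ratio 1:2 --n-reads 300 --seed 1 --out-dir psi
modpore detect --alignments psi/reads.sam --control-alignments ctrl/reads.sam \
    --out-dir detect_out
```

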