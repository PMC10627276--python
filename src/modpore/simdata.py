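"""Ground-truthed synthetic direct-RNA nanopore alignments and event tables.

The generator emulates an IVT (in vitro transcription) experimental design:
a T7 polymerase transcribes a known ~2 kb template either with canonical
NTPs only, or with one modified nucleotide species doped in at a molar
ratio against its canonical counterpart (1:100, 1:10, 1:5, 1:2, or 100%).
Because T7 incorporation is sequence-agnostic, each target-base position in
each transcript molecule independently carries the modification with
probability a/(a+b) for ratio a:b.

Per read, the simulator draws

* substitutions at a baseline per-base rate (canonical positions) or an
  inflated rate (modified positions, with a configurable mismatch-identity
  bias, optionally gated on a neighboring base to emulate reader-head
  context effects);
* single-base insertions and deletions at baseline rates, multiplied at
  the position immediately 3' of a homopolymer run of >= ``min_len``
  identical bases, where nanopore indels concentrate;
* per-position dwell times from a log-normal (positive, right-skewed,
  SD > mean as in real direct-RNA event tables), multiplied at modified
  positions;
* per-position mean currents from a Gaussian around a deterministic
  synthetic pore model (one mean/SD per reference 5-mer), with an additive
  shift at modified positions.

Reads span the whole template (poly(A)-anchored full-length cDNA-free
reads dominate short-template direct-RNA runs). Deletions get no event
row and inserted bases get no event row, mirroring what signal
resquiggling can assign. One root seed spawns an independent child
stream per read, so output is reproducible regardless of read order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .refseq import (
    BASE_TO_CODE,
    CODE_TO_BASE,
    ReferenceTranscript,
    following_positions,
    homopolymer_runs,
)

DELETION_CODE = 4
NO_INSERTION = -1

#: canonical per-base dwell means/SDs in ms (A, C, U from deep direct-RNA
#: event tables of canonical-only transcripts; G chosen between A and C).
DEFAULT_DWELL_MEAN_MS = {"A": 17.1, "C": 15.0, "G": 16.0, "U": 15.4}
DEFAULT_DWELL_SD_MS = {"A": 26.7, "C": 23.4, "G": 25.0, "U": 25.6}


@dataclass
class SimulationConfig:
    """Everything that parameterizes one simulated sample.

    ``mix_ratio`` is (modified, canonical) molar parts; incorporation
    probability is a/(a+b), and (1, 0) means 100% modified.
    """

    modification_name: str = "canonical"
    target_base: Optional[str] = None
    mix_ratio: tuple[int, int] = (0, 1)
    n_reads: int = 100
    sub_rate_baseline: float = 0.112
    ins_rate_baseline: float = 0.025
    del_rate_baseline: float = 0.055
    homopolymer_indel_multiplier: float = 3.0
    homopolymer_min_len: int = 3
    sub_rate_modified: float = 0.112
    sub_bias_modified: Optional[dict[str, float]] = None
    context_base: Optional[str] = None  # gate modified-position error inflation
    dwell_mean_canonical_ms: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_MEAN_MS)
    )
    dwell_sd_canonical_ms: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_SD_MS)
    )
    dwell_multiplier_modified: float = 1.0
    current_shift_modified_pA: float = 0.0
    seed: int = 0

    @property
    def incorporation_probability(self) -> float:
        a, b = self.mix_ratio
        return a / (a + b) if (a + b) > 0 else 0.0

    def validate(self) -> None:
        for name in ("sub_rate_baseline", "ins_rate_baseline", "del_rate_baseline",
                     "sub_rate_modified"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.homopolymer_indel_multiplier <= 0 or self.dwell_multiplier_modified <= 0:
            raise ValueError("multipliers must be > 0")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        a, b = self.mix_ratio
        if a < 0 or b < 0 or (a + b) == 0:
            raise ValueError(f"invalid mix_ratio {self.mix_ratio}")
        if a > 0 and self.target_base not in BASE_TO_CODE:
            raise ValueError("a modified mixture needs target_base in {A,C,G,U}")
        for d in (self.dwell_mean_canonical_ms, self.dwell_sd_canonical_ms):
            missing = set("ACGU") - set(d)
            if missing:
                raise ValueError(f"dwell parameters missing for bases {sorted(missing)}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mix_ratio"] = list(self.mix_ratio)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mix_ratio" in d:
            d["mix_ratio"] = tuple(d["mix_ratio"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def preset_config(
    modification: str,
    mix_ratio: tuple[int, int] = (1, 2),
    n_reads: int = 500,
    seed: int = 0,
) -> SimulationConfig:
    """Study-condition presets for the modifications with the clearest
    signatures. Effect sizes are free parameters of the generator (real
    per-modification miscall inflation is not quantified anywhere); they
    are fixed here and documented in the methods note.

    * ``canonical`` — baseline errors only.
    * ``pseudoU`` — U-targeted mismatch inflation +0.2 biased toward A/C
      calls, mildly longer dwell.
    * ``biotinC`` — bulky C adduct: strong miscalls and ~2.6x dwell
      (consistent with a 54% pooled dwell increase at 1:2 mixing).
    * ``m6A`` — subtle; miscall inflation gated on a neighboring A
      (reader-head context), near-baseline dwell.
    * ``Am`` — 2'-O-methyl sugar on A: modest inflation, slight dwell.
    """
    base = dict(n_reads=n_reads, seed=seed, mix_ratio=mix_ratio)
    if modification == "canonical":
        return SimulationConfig(modification_name="canonical", mix_ratio=(0, 1),
                                n_reads=n_reads, seed=seed)
    if modification == "pseudoU":
        return SimulationConfig(
            modification_name="pseudoU", target_base="U",
            sub_rate_modified=0.312,
            sub_bias_modified={"A": 0.45, "C": 0.45, "G": 0.10},
            dwell_multiplier_modified=1.5, current_shift_modified_pA=2.0,
            **base,
        )
    if modification == "biotinC":
        return SimulationConfig(
            modification_name="biotinC", target_base="C",
            sub_rate_modified=0.5,
            dwell_multiplier_modified=2.62, current_shift_modified_pA=4.0,
            **base,
        )
    if modification == "m6A":
        return SimulationConfig(
            modification_name="m6A", target_base="A",
            sub_rate_modified=0.35, context_base="A",
            dwell_multiplier_modified=1.09, current_shift_modified_pA=1.5,
            **base,
        )
    if modification == "Am":
        return SimulationConfig(
            modification_name="Am", target_base="A",
            sub_rate_modified=0.25,
            dwell_multiplier_modified=1.07, current_shift_modified_pA=1.0,
            **base,
        )
    raise ValueError(f"unknown preset {modification!r}")


@dataclass(frozen=True)
class SimulatedRead:
    """One read as per-reference-position arrays.

    ``calls[i]`` is 0..3 (called base code) or 4 (deleted); ``ins_base[i]``
    is the code of a single base inserted immediately after position i, or
    -1; ``dwell_ms``/``current_pA`` are NaN at deleted positions.
    """

    read_id: str
    calls: np.ndarray
    ins_base: np.ndarray
    dwell_ms: np.ndarray
    current_pA: np.ndarray
    modified: np.ndarray


@dataclass
class SimulatedSample:
    """Matrix view of all reads of one simulated sample (reads x positions)."""

    label: str
    read_ids: list[str]
    calls: np.ndarray       # int8, (n, L); 4 = deletion
    ins_base: np.ndarray    # int8, (n, L); -1 = none
    dwell_ms: np.ndarray    # float32, NaN at deletions
    current_pA: np.ndarray  # float32, NaN at deletions / missing context
    modified: np.ndarray    # bool

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def reads(self) -> list[SimulatedRead]:
        return [
            SimulatedRead(
                read_id=rid,
                calls=self.calls[i],
                ins_base=self.ins_base[i],
                dwell_ms=self.dwell_ms[i],
                current_pA=self.current_pA[i],
                modified=self.modified[i],
            )
            for i, rid in enumerate(self.read_ids)
        ]


@dataclass
class TruthTable:
    """Simulator ground truth: which (read, position) carries a modification."""

    entries: set[tuple[str, int]]
    target_base: Optional[str] = None

    def positions(self) -> set[int]:
        return {pos for _, pos in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tposition\tbase\n")
            for rid, pos in sorted(self.entries):
                fh.write(f"{rid}\t{pos}\t{self.target_base or ''}\n")

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        base = None
        if "base" in df.columns and len(df):
            vals = df["base"].dropna().unique()
            base = str(vals[0]) if len(vals) else None
        return cls(entries=set(zip(df["read_id"], df["position"].astype(int))),
                   target_base=base)


_PORE_MODEL_SALT = 7919  # fixed: the synthetic pore model is seed-independent


def kmer_current_params(kmer: str) -> tuple[float, float]:
    """Deterministic synthetic pore model: mean (pA) and SD for a 5-mer.

    Means are spread over ~80-130 pA and SDs over 2-4 pA, fixed functions
    of the k-mer identity so that every simulation shares one pore model.
    """
    code = 0
    for c in kmer:
        code = code * 4 + BASE_TO_CODE[c]
    rng = np.random.default_rng(code + _PORE_MODEL_SALT)
    return 80.0 + 50.0 * rng.random(), 2.0 + 2.0 * rng.random()


def _transcript_current_model(transcript: ReferenceTranscript) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (mean, sd) current arrays; NaN where the +/-2 5-mer
    context is incomplete."""
    L = transcript.length
    mean = np.full(L, np.nan)
    sd = np.full(L, np.nan)
    cache: dict[str, tuple[float, float]] = {}
    for pos in range(2, L - 2):
        km = transcript.sequence[pos - 2 : pos + 3]
        if km not in cache:
            cache[km] = kmer_current_params(km)
        mean[pos], sd[pos] = cache[km]
    return mean, sd


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_sample(
    config: SimulationConfig, transcript: ReferenceTranscript
) -> tuple[SimulatedSample, TruthTable]:
    """Simulate one sample; returns the reads and the ground-truth table."""
    config.validate()
    ref = transcript.codes()
    L = transcript.length
    n = config.n_reads
    p_mod = config.incorporation_probability

    if p_mod > 0:
        target_code = BASE_TO_CODE[config.target_base]
        target_mask = ref == target_code
        if not target_mask.any():
            raise ValueError(
                f"target base {config.target_base} absent from transcript "
                f"{transcript.name}"
            )
    else:
        target_mask = np.zeros(L, dtype=bool)

    # context gating of modified-position miscall inflation (+/-1 neighbor)
    if config.context_base is not None:
        ctx_code = BASE_TO_CODE[config.context_base]
        ctx = np.zeros(L, dtype=bool)
        ctx[1:] |= ref[:-1] == ctx_code
        ctx[:-1] |= ref[1:] == ctx_code
    else:
        ctx = np.ones(L, dtype=bool)

    # The indel multiplier applies at the position immediately 3' of a run,
    # but is normalized so the configured baseline rates stay the expected
    # *transcript-wide* rates: the multiplier redistributes indels toward
    # post-run positions without changing the totals. Terminal positions are
    # never deleted (alignments must not start or end with a deletion).
    runs = homopolymer_runs(transcript, min_len=config.homopolymer_min_len)
    indel_factor = np.ones(L)
    indel_factor[following_positions(runs, L)] = config.homopolymer_indel_multiplier
    del_factor = indel_factor.copy()
    del_factor[0] = 0.0
    del_factor[-1] = 0.0
    del_p = np.clip(
        config.del_rate_baseline * L * del_factor / del_factor.sum(), 0.0, 1.0
    )
    # insertion events per aligned call: account for calls lost to deletions
    aligned_w = 1.0 - del_p
    ins_p = np.clip(
        config.ins_rate_baseline
        * indel_factor
        * aligned_w.sum()
        / (indel_factor * aligned_w).sum(),
        0.0,
        1.0,
    )

    # mismatch identity tables: for each reference base, its 3 alternatives
    # and cumulative draw probabilities for canonical / modified positions
    alts = {b: np.array([c for c in range(4) if c != b], dtype=np.int8) for b in range(4)}
    cum_canon = {b: np.array([1 / 3, 2 / 3, 1.0]) for b in range(4)}
    if config.sub_bias_modified is not None:
        cum_mod = {}
        for b in range(4):
            w = np.array(
                [config.sub_bias_modified.get(str(CODE_TO_BASE[c]), 0.0) for c in alts[b]]
            )
            if w.sum() <= 0:
                w = np.ones(3)
            cum_mod[b] = np.cumsum(w / w.sum())
    else:
        cum_mod = cum_canon

    # per-base dwell log-normal parameters
    dwell_mu = np.empty(4)
    dwell_sigma = np.empty(4)
    for base, code in BASE_TO_CODE.items():
        dwell_mu[code], dwell_sigma[code] = _lognormal_params(
            config.dwell_mean_canonical_ms[base], config.dwell_sd_canonical_ms[base]
        )

    cur_mean, cur_sd = _transcript_current_model(transcript)

    calls = np.empty((n, L), dtype=np.int8)
    ins_base = np.full((n, L), NO_INSERTION, dtype=np.int8)
    dwell = np.empty((n, L), dtype=np.float32)
    current = np.empty((n, L), dtype=np.float32)
    modified = np.zeros((n, L), dtype=bool)

    label = f"{config.modification_name}_{config.mix_ratio[0]}to{config.mix_ratio[1]}"
    read_ids = [f"{label}_r{i:05d}" for i in range(n)]
    truth: set[tuple[str, int]] = set()

    children = np.random.SeedSequence(config.seed).spawn(n)
    for i in range(n):
        rng = np.random.default_rng(children[i])

        mod = target_mask & (rng.random(L) < p_mod) if p_mod > 0 else np.zeros(L, bool)
        modified[i] = mod
        if mod.any():
            truth.update((read_ids[i], int(p)) for p in np.flatnonzero(mod))

        deleted = rng.random(L) < del_p
        sub_p = np.where(mod & ctx, config.sub_rate_modified, config.sub_rate_baseline)
        mism = ~deleted & (rng.random(L) < sub_p)

        row = ref.copy()
        if mism.any():
            u = rng.random(L)  # one uniform per position; used where mismatching
            for b in range(4):
                sel = mism & (ref == b)
                if not sel.any():
                    continue
                sel_mod = sel & mod & ctx
                for cum, mask in ((cum_mod[b], sel_mod), (cum_canon[b], sel & ~sel_mod)):
                    if mask.any():
                        idx = np.searchsorted(cum, u[mask], side="right")
                        row[mask] = alts[b][np.minimum(idx, 2)]
        row[deleted] = DELETION_CODE
        calls[i] = row

        ins = (rng.random(L) < ins_p) & ~deleted
        if ins.any():
            ins_base[i, ins] = rng.integers(0, 4, size=int(ins.sum()), dtype=np.int8)

        d = rng.lognormal(mean=dwell_mu[ref], sigma=dwell_sigma[ref])
        d[mod] *= config.dwell_multiplier_modified
        d[deleted] = np.nan
        dwell[i] = d

        c = cur_mean + cur_sd * rng.standard_normal(L)
        c[mod] += config.current_shift_modified_pA
        c[deleted] = np.nan
        current[i] = c

    sample = SimulatedSample(
        label=label, read_ids=read_ids, calls=calls, ins_base=ins_base,
        dwell_ms=dwell, current_pA=current, modified=modified,
    )
    return sample, TruthTable(entries=truth, target_base=config.target_base)


# ---------------------------------------------------------------------------
# writers

_RNA_TO_DNA = str.maketrans("ACGU", "ACGT")


def _read_to_sam_fields(
    read_calls: np.ndarray, read_ins: np.ndarray, ref_seq_dna: str
) -> tuple[str, str, str, int]:
    """CIGAR, SEQ (DNA alphabet), MD and NM for one simulated read."""
    cigar: list[str] = []
    seq_parts: list[str] = []
    md_parts: list[str] = []
    md_match = 0
    nm = 0
    op, op_len = "", 0
    bases = "ACGT"

    def flush() -> None:
        nonlocal op, op_len
        if op_len:
            cigar.append(f"{op_len}{op}")
        op, op_len = "", 0

    def extend(o: str) -> None:
        nonlocal op, op_len
        if o != op:
            flush()
            op = o
        op_len += 1

    in_del = False
    for i, call in enumerate(read_calls):
        if call == DELETION_CODE:
            extend("D")
            if not in_del:
                md_parts.append(f"{md_match}^")
                md_match = 0
                in_del = True
            md_parts.append(ref_seq_dna[i])
            nm += 1
        else:
            if in_del:
                in_del = False
            extend("M")
            called = bases[call]
            seq_parts.append(called)
            if called == ref_seq_dna[i]:
                md_match += 1
            else:
                md_parts.append(f"{md_match}{ref_seq_dna[i]}")
                md_match = 0
                nm += 1
        ib = read_ins[i]
        if ib >= 0:
            extend("I")
            seq_parts.append(bases[ib])
            nm += 1
    flush()
    md_parts.append(str(md_match))
    # MD requires a match count between a deletion and a following mismatch;
    # normalize "^C0A"-style by keeping the explicit zeros (already emitted).
    return "".join(cigar), "".join(seq_parts), "".join(md_parts), nm


def write_sam(sample: SimulatedSample, transcript: ReferenceTranscript, path) -> None:
    """Write the sample as a coordinate-sorted SAM against the transcript.

    SEQ and MD use the DNA alphabet (U -> T), matching basecaller output;
    all reads are forward-strand, full template span, MAPQ 60.
    """
    ref_dna = transcript.sequence.translate(_RNA_TO_DNA)
    header = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:{transcript.name}\tLN:{transcript.length}\n"
        "@PG\tID:modpore\tPN:modpore\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, rid in enumerate(sample.read_ids):
            cigar, seq, md, nm = _read_to_sam_fields(
                sample.calls[i], sample.ins_base[i], ref_dna
            )
            fh.write(
                f"{rid}\t0\t{transcript.name}\t1\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*\tNM:i:{nm}\tMD:Z:{md}\n"
            )
    # validate through htslib so malformed records never propagate
    with pysam.AlignmentFile(str(path), "r") as af:
        assert af.nreferences == 1


def events_frame(sample: SimulatedSample, transcript: ReferenceTranscript) -> pd.DataFrame:
    """Event table as a DataFrame: one row per (read, position) with full
    +/-2 5-mer context; deleted positions are omitted."""
    L = transcript.length
    kmers = np.array(
        ["" if (p < 2 or p >= L - 2) else transcript.sequence[p - 2 : p + 3] for p in range(L)]
    )
    ctx_ok = np.zeros(L, dtype=bool)
    ctx_ok[2 : L - 2] = True
    valid = ~np.isnan(sample.dwell_ms) & ctx_ok[None, :]
    ridx, pos = np.nonzero(valid)
    rid_arr = np.array(sample.read_ids)
    return pd.DataFrame(
        {
            "read_id": rid_arr[ridx],
            "position": pos.astype(int),
            "reference_kmer": kmers[pos],
            "event_mean_pA": sample.current_pA[ridx, pos].astype(float),
            "dwell_ms": sample.dwell_ms[ridx, pos].astype(float),
        }
    )


def write_events(sample: SimulatedSample, transcript: ReferenceTranscript, path) -> None:
    """Write the resquiggle-style event TSV (tab-separated, header row;
    ``position`` is the 0-based reference coordinate of the 5-mer center)."""
    events_frame(sample, transcript).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )
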