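"""Per-position error statistics from alignments.

The central quantity is the per-position mismatch rate: mismatched calls
divided by (matched + mismatched) calls — deletions are excluded from the
denominator and tallied separately with deleted positions included in
their own denominator. Insertions are counted as *events* (a multi-base
insertion is one event) attributed to the reference position immediately
preceding the inserted bases.

On top of the pileup this module derives the transcript-wide substitution
breakdown by reference base (A-to-X, ..., U-to-X, with the finer
per-alternative split), insertion/deletion rates, homopolymer-adjacent
indel fractions, and control normalization (sample minus canonical
control mismatch rate, the basis for site ranking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam

from .refseq import (
    CODE_TO_BASE,
    HomopolymerRun,
    ReferenceTranscript,
    RNA_ALPHABET,
)
from .simdata import DELETION_CODE, NO_INSERTION, SimulatedSample

_DNA_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": -1}


@dataclass
class PileupProfile:
    """Per-reference-position call counts and rates.

    ``base_calls[p, c]`` is the number of reads calling base code ``c``
    (A,C,G,U -> 0..3) at position ``p``; ``deletions[p]`` the number of
    reads with ``p`` deleted; ``insertions[p]`` the number of insertion
    events opening immediately after ``p``.
    """

    reference_name: str
    ref_codes: np.ndarray      # int8 (L,)
    base_calls: np.ndarray     # int64 (L, 4)
    deletions: np.ndarray      # int64 (L,)
    insertions: np.ndarray     # int64 (L,)
    n_reads: int

    @property
    def length(self) -> int:
        return len(self.ref_codes)

    @property
    def coverage(self) -> np.ndarray:
        """Matched + mismatched calls per position (deletions excluded)."""
        return self.base_calls.sum(axis=1)

    @property
    def matches(self) -> np.ndarray:
        return self.base_calls[np.arange(self.length), self.ref_codes]

    @property
    def mismatch_rate(self) -> np.ndarray:
        """Mismatch rate per position; NaN where coverage is zero."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, (cov - self.matches) / cov, np.nan)

    @property
    def insertion_rate(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.insertions / cov, np.nan)

    @property
    def deletion_rate(self) -> np.ndarray:
        denom = self.coverage + self.deletions
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.deletions / denom, np.nan)

    def __add__(self, other: "PileupProfile") -> "PileupProfile":
        """Pool counts of two profiles over the same reference (used to
        merge canonical replicates before rate computation)."""
        if self.reference_name != other.reference_name or self.length != other.length:
            raise ValueError("profiles are over different references")
        return PileupProfile(
            reference_name=self.reference_name,
            ref_codes=self.ref_codes,
            base_calls=self.base_calls + other.base_calls,
            deletions=self.deletions + other.deletions,
            insertions=self.insertions + other.insertions,
            n_reads=self.n_reads + other.n_reads,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(self.length),
                "ref_base": CODE_TO_BASE[self.ref_codes],
                "A": self.base_calls[:, 0],
                "C": self.base_calls[:, 1],
                "G": self.base_calls[:, 2],
                "U": self.base_calls[:, 3],
                "del": self.deletions,
                "ins": self.insertions,
                "coverage": self.coverage,
                "mismatch_rate": self.mismatch_rate,
                "insertion_rate": self.insertion_rate,
                "deletion_rate": self.deletion_rate,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def pileup(
    alignments: Union[str, "pysam.AlignmentFile"],
    transcript: ReferenceTranscript,
    use_md: bool = False,
) -> PileupProfile:
    """Pile up a SAM/BAM file against the reference transcript.

    Unmapped, secondary and supplementary records are skipped; soft-clips
    ignored; MAPQ-0 reads retained (single-reference mapping). With
    ``use_md=True`` the reference is reconstructed per read from the MD
    tag instead of the transcript (both paths must agree; the transcript
    is still required for the reference-name check and base identities).
    """
    own = isinstance(alignments, (str,)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments), "r") if own else alignments

    L = transcript.length
    ref_codes = transcript.codes()
    base_calls = np.zeros((L, 4), dtype=np.int64)
    deletions = np.zeros(L, dtype=np.int64)
    insertions = np.zeros(L, dtype=np.int64)
    n_reads = 0

    try:
        names = set(af.references)
        if transcript.name not in names:
            raise ValueError(
                f"transcript {transcript.name!r} not among alignment references {sorted(names)}"
            )
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != transcript.name:
                raise ValueError(
                    f"read {read.query_name} aligned to {read.reference_name!r}, "
                    f"expected {transcript.name!r}"
                )
            n_reads += 1
            if use_md:
                # reconstruct the reference over the aligned span from the MD
                # tag and require it to agree with the transcript
                rseq = read.get_reference_sequence().upper()
                rcodes = np.array([_DNA_TO_CODE[c] for c in rseq], dtype=np.int8)
                span = ref_codes[read.reference_start : read.reference_end]
                if not np.array_equal(rcodes, span):
                    raise ValueError(
                        f"MD-declared reference of read {read.query_name} "
                        "disagrees with the transcript"
                    )
            qseq = read.query_sequence
            q = np.array([_DNA_TO_CODE[c] for c in qseq], dtype=np.int8)
            rpos = read.reference_start
            qpos = 0
            for op, ln in read.cigartuples:
                if op in (0, 7, 8):  # M, =, X consume both
                    calls = q[qpos : qpos + ln]
                    ok = calls >= 0  # skip N calls
                    np.add.at(
                        base_calls,
                        (np.arange(rpos, rpos + ln)[ok], calls[ok]),
                        1,
                    )
                    rpos += ln
                    qpos += ln
                elif op == 1:  # I: one event at the preceding position
                    if rpos > 0:
                        insertions[rpos - 1] += 1
                    qpos += ln
                elif op == 2:  # D
                    deletions[rpos : rpos + ln] += 1
                    rpos += ln
                elif op == 3:  # N
                    rpos += ln
                elif op == 4:  # S
                    qpos += ln
                # H, P consume nothing we track
    finally:
        if own:
            af.close()

    if n_reads == 0:
        raise ValueError("no usable alignments (empty file or all filtered)")
    return PileupProfile(
        reference_name=transcript.name,
        ref_codes=ref_codes,
        base_calls=base_calls,
        deletions=deletions,
        insertions=insertions,
        n_reads=n_reads,
    )


def pileup_sample(sample: SimulatedSample, transcript: ReferenceTranscript) -> PileupProfile:
    """Pile up an in-memory simulated sample (no SAM round trip).

    Exactly equivalent to ``write_sam`` followed by :func:`pileup`; the
    equivalence is covered by the round-trip tests.
    """
    L = transcript.length
    base_calls = np.zeros((L, 4), dtype=np.int64)
    for c in range(4):
        base_calls[:, c] = (sample.calls == c).sum(axis=0)
    return PileupProfile(
        reference_name=transcript.name,
        ref_codes=transcript.codes(),
        base_calls=base_calls,
        deletions=(sample.calls == DELETION_CODE).sum(axis=0).astype(np.int64),
        insertions=(sample.ins_base != NO_INSERTION).sum(axis=0).astype(np.int64),
        n_reads=sample.n_reads,
    )


@dataclass
class SubstitutionSummary:
    """Transcript-wide 4x4 reference-base x called-base count matrix and
    the derived A-to-X ... U-to-X percentages (None where a reference
    base has zero coverage, never 0)."""

    matrix: np.ndarray  # (4, 4) counts, rows = reference base

    def row_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_x_rates(self) -> dict[str, Optional[float]]:
        """A-to-X, C-to-X, G-to-X, U-to-X as percentages."""
        out: dict[str, Optional[float]] = {}
        totals = self.row_totals()
        for b, base in enumerate(RNA_ALPHABET):
            if totals[b] == 0:
                out[f"{base}_to_X"] = None
            else:
                off = totals[b] - self.matrix[b, b]
                out[f"{base}_to_X"] = 100.0 * off / totals[b]
        return out

    def fine_rates(self) -> dict[str, Optional[float]]:
        """Per-alternative split, e.g. U_to_A, U_to_C, U_to_G (percent of
        that reference base's calls)."""
        out: dict[str, Optional[float]] = {}
        totals = self.row_totals()
        for b, base in enumerate(RNA_ALPHABET):
            for c, called in enumerate(RNA_ALPHABET):
                if b == c:
                    continue
                key = f"{base}_to_{called}"
                out[key] = (
                    None if totals[b] == 0 else 100.0 * self.matrix[b, c] / totals[b]
                )
        return out

    def overall_rate(self) -> float:
        """Transcript-wide substitution rate (percent)."""
        total = self.matrix.sum()
        return 100.0 * (total - np.trace(self.matrix)) / total


def substitution_breakdown(profile: PileupProfile) -> SubstitutionSummary:
    matrix = np.zeros((4, 4), dtype=np.int64)
    for b in range(4):
        rows = profile.ref_codes == b
        matrix[b] = profile.base_calls[rows].sum(axis=0)
    return SubstitutionSummary(matrix=matrix)


def indel_rates(
    profile: PileupProfile, denominator: str = "aligned_bases"
) -> tuple[float, float]:
    """Transcript-wide (insertion %, deletion %).

    Insertions: events / aligned base calls (or events / read with
    ``denominator="reads"``). Deletions: deleted reference positions /
    (aligned + deleted).
    """
    total_calls = int(profile.coverage.sum())
    if total_calls == 0:
        raise ValueError("empty profile")
    ins_events = int(profile.insertions.sum())
    dels = int(profile.deletions.sum())
    if denominator == "aligned_bases":
        ins_rate = 100.0 * ins_events / total_calls
    elif denominator == "reads":
        ins_rate = 100.0 * ins_events / profile.n_reads
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    del_rate = 100.0 * dels / (total_calls + dels)
    return ins_rate, del_rate


@dataclass
class HomopolymerIndelSummary:
    insertion_fraction: Optional[float]  # fraction of insertion events in/after runs
    deletion_fraction: Optional[float]
    insertion_run_bases: dict[str, int]  # implicated-run base tallies (event-weighted)
    deletion_run_bases: dict[str, int]


def homopolymer_indel_fraction(
    profile: PileupProfile, runs: Iterable[HomopolymerRun]
) -> HomopolymerIndelSummary:
    """Fraction of insertions / deletions whose attributed position lies
    within a homopolymer run or at the single position immediately 3' of
    one, plus the base composition of the implicated runs.

    Fractions are None (undefined) when the sample has no indels of that
    kind.
    """
    runs = list(runs)
    L = profile.length
    run_of = np.full(L, -1, dtype=int)
    for k, r in enumerate(runs):
        run_of[r.start : r.end] = k
        # a position immediately 3' of run A may be the start of run B; the
        # containing run wins, so only unassigned following positions map back
        if r.end < L and run_of[r.end] == -1:
            run_of[r.end] = k

    def tally(counts: np.ndarray) -> tuple[Optional[float], dict[str, int]]:
        total = int(counts.sum())
        if total == 0:
            return None, {b: 0 for b in RNA_ALPHABET}
        near = run_of >= 0
        frac = float(counts[near].sum() / total)
        per_base = {b: 0 for b in RNA_ALPHABET}
        for k in np.unique(run_of[near]):
            per_base[runs[k].base] += int(counts[(run_of == k)].sum())
        return frac, per_base

    ins_frac, ins_bases = tally(profile.insertions)
    del_frac, del_bases = tally(profile.deletions)
    return HomopolymerIndelSummary(
        insertion_fraction=ins_frac,
        deletion_fraction=del_frac,
        insertion_run_bases=ins_bases,
        deletion_run_bases=del_bases,
    )


def normalize_to_control(
    sample_profile: PileupProfile,
    control_profile: PileupProfile,
    min_control_coverage: int = 20,
) -> np.ma.MaskedArray:
    """Per-position normalized error score: sample mismatch rate minus
    control (canonical-only) mismatch rate.

    A difference is used rather than a ratio so the score stays finite
    when the control rate is near zero. Positions where either profile
    lacks coverage, or control coverage is below ``min_control_coverage``,
    are masked.
    """
    if sample_profile.length != control_profile.length:
        raise ValueError("profiles have different lengths")
    s = sample_profile.mismatch_rate
    c = control_profile.mismatch_rate
    mask = (
        np.isnan(s)
        | np.isnan(c)
        | (control_profile.coverage < min_control_coverage)
    )
    score = np.where(mask, 0.0, s - np.where(np.isnan(c), 0.0, c))
    return np.ma.MaskedArray(score, mask=mask)
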