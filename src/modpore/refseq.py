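"""Reference transcript loading and sequence annotation.

Direct RNA nanopore reads are sequenced off a single known template
(here an in vitro transcribed ~2 kb transcript), so the reference model
is deliberately minimal: one unspliced, forward-strand RNA sequence.
This module provides k-mer inventories (the pore reader-head holds ~5 nt,
so 5-mer diversity bounds how much signal space a template explores),
maximal homopolymer runs (indels concentrate next to them), and local
sequence context windows for motif analysis.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "ACGU"
GAP = "-"

#: base -> integer code used by the numeric modules
BASE_TO_CODE = {b: i for i, b in enumerate(RNA_ALPHABET)}
CODE_TO_BASE = np.array(list(RNA_ALPHABET))


@dataclass(frozen=True)
class ReferenceTranscript:
    """A single unspliced forward-strand RNA reference sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference transcript sequence is empty")
        bad = [i for i, c in enumerate(self.sequence) if c not in BASE_TO_CODE]
        if bad:
            raise ValueError(
                f"non-ACGU characters in reference at offsets {bad[:10]}"
                + (" ..." if len(bad) > 10 else "")
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        """Sequence as an int8 array with A,C,G,U -> 0,1,2,3."""
        return np.frombuffer(
            self.sequence.translate(str.maketrans(RNA_ALPHABET, "\x00\x01\x02\x03")).encode("latin1"),
            dtype=np.int8,
        ).copy()

    def base_composition(self) -> dict[str, int]:
        c = Counter(self.sequence)
        return {b: c.get(b, 0) for b in RNA_ALPHABET}

    def kmer_at(self, pos: int, k: int = 5) -> str:
        """k-mer centered at ``pos`` (k odd); raises near the ends."""
        flank = k // 2
        if pos - flank < 0 or pos + flank >= self.length:
            raise IndexError(f"position {pos} lacks full +/-{flank} context")
        return self.sequence[pos - flank : pos + flank + 1]


class HomopolymerRun(NamedTuple):
    """Maximal run of identical bases, [start, end) on the reference."""

    base: str
    start: int
    end: int

    @property
    def run_length(self) -> int:
        return self.end - self.start


class KmerInventory(NamedTuple):
    count: int
    fraction: float  # count / 4**k


def from_string(sequence: str, name: str = "ref") -> ReferenceTranscript:
    """Build a transcript from a raw string (T accepted, normalized to U)."""
    return ReferenceTranscript(name=name, sequence=sequence.upper().replace("T", "U"))


def load_reference(path) -> ReferenceTranscript:
    """Load the first FASTA record as the reference transcript.

    T is normalized to U and the sequence uppercased; any other non-ACGU
    character is fatal, with offsets reported.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    return from_string(str(rec.seq), name=rec.id)


def bundled_reference() -> ReferenceTranscript:
    """The 1908-nt IVT template transcript (chr19:45406985-45408892, hg19)
    that ships with the package."""
    path = resources.files("modpore").joinpath("data/ivt_transcript.fasta")
    with resources.as_file(path) as p:
        return load_reference(p)


def distinct_kmer_stats(transcript: ReferenceTranscript, k: int) -> KmerInventory:
    """Number of distinct k-mers in the transcript and the fraction of all
    4**k possible k-mers that they cover."""
    if not 1 <= k <= transcript.length:
        raise ValueError(f"k={k} out of range for length {transcript.length}")
    seq = transcript.sequence
    count = len({seq[i : i + k] for i in range(transcript.length - k + 1)})
    return KmerInventory(count=count, fraction=count / 4**k)


def distinct_kmer_count(transcript: ReferenceTranscript, k: int) -> int:
    return distinct_kmer_stats(transcript, k).count


def homopolymer_runs(
    transcript: ReferenceTranscript, min_len: int = 3
) -> list[HomopolymerRun]:
    """All maximal runs of identical bases with length >= ``min_len``,
    sorted by start. A length-5 run is one run, never multiple windows."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = transcript.sequence
    runs: list[HomopolymerRun] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append(HomopolymerRun(base=seq[i], start=i, end=j))
        i = j
    return runs


def homopolymer_base_fraction(
    runs: Iterable[HomopolymerRun], weight: str = "runs"
) -> dict[str, float]:
    """Fraction of homopolymer runs contributed by each base.

    ``weight="runs"`` counts each maximal run once (default).
    ``weight="windows"`` weights a run of length L by its L-2 sliding
    length-3 windows; counting conventions differ in the literature and
    the two can disagree at integer-percent precision, so both are exposed.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("empty run list")
    if weight == "runs":
        weights = {r: 1 for r in runs}
    elif weight == "windows":
        weights = {r: r.run_length - 2 for r in runs}
    else:
        raise ValueError(f"unknown weight mode {weight!r}")
    total = sum(weights.values())
    per_base: Counter[str] = Counter()
    for r, w in weights.items():
        per_base[r.base] += w
    return {b: per_base.get(b, 0) / total for b in RNA_ALPHABET}


def run_adjacency_mask(
    runs: Iterable[HomopolymerRun], length: int, include_following: bool = True
) -> np.ndarray:
    """Boolean mask over reference positions that lie within a run or (if
    ``include_following``) at the single position immediately 3' of one."""
    mask = np.zeros(length, dtype=bool)
    for r in runs:
        mask[r.start : r.end] = True
        if include_following and r.end < length:
            mask[r.end] = True
    return mask


def following_positions(runs: Iterable[HomopolymerRun], length: int) -> np.ndarray:
    """Positions immediately 3' of a maximal run (used by the simulator's
    homopolymer-enhanced indel model)."""
    pos = [r.end for r in runs if r.end < length]
    return np.asarray(sorted(set(pos)), dtype=int)


def context_window(
    transcript: ReferenceTranscript, pos: int, flank: int = 2, pad: str = GAP
) -> str:
    """Sequence window of length 2*flank+1 centered at ``pos``; positions
    beyond the sequence ends are padded with ``pad``."""
    if not 0 <= pos < transcript.length:
        raise IndexError(f"position {pos} out of range [0, {transcript.length})")
    out = []
    for i in range(pos - flank, pos + flank + 1):
        out.append(transcript.sequence[i] if 0 <= i < transcript.length else pad)
    return "".join(out)


def write_runs_tsv(runs: Iterable[HomopolymerRun], path) -> None:
    """Dump the homopolymer run table (base, start, end, length)."""
    with open(path, "w") as fh:
        fh.write("base\tstart\tend\tlength\n")
        for r in runs:
            fh.write(f"{r.base}\t{r.start}\t{r.end}\t{r.run_length}\n")
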