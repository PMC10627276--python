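"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written from scratch against the file
formats / definitions, without importing the package's own parsing or
numeric code paths (numpy is used only for array containers and basic
linear algebra).
"""

from __future__ import annotations

import re
from collections import Counter

import numpy as np

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def brute_force_distinct_kmers(seq: str, k: int) -> int:
    return len({seq[i : i + k] for i in range(len(seq) - k + 1)})


def brute_force_runs(seq: str, min_len: int) -> list[tuple[str, int, int]]:
    """Maximal homopolymer runs by a neighbor-comparing linear scan."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                runs.append((seq[start], start, i))
            start = i
    return runs


def brute_force_run_base_fractions(seq: str, min_len: int) -> dict[str, float]:
    runs = brute_force_runs(seq, min_len)
    tally = Counter(base for base, _, _ in runs)
    return {b: tally.get(b, 0) / len(runs) for b in "ACGU"}


def sam_text_pileup(sam_text: str, ref_rna: str):
    """Reference pileup by directly parsing SAM text (no pysam).

    Returns (base_calls[L,4], deletions[L], insertion_events[L]) under the
    same conventions as the package: deletions out of the mismatch
    denominator, one insertion event attributed to the preceding
    reference position, soft clips ignored.
    """
    L = len(ref_rna)
    base_calls = np.zeros((L, 4), dtype=int)
    deletions = np.zeros(L, dtype=int)
    insertions = np.zeros(L, dtype=int)
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        flag = int(f[1])
        if flag & 0x4 or flag & 0x100 or flag & 0x800:
            continue
        pos = int(f[3]) - 1
        cigar = f[5]
        seq = f[9]
        rpos, qpos = pos, 0
        for ln, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            ln = int(ln)
            if op in "M=X":
                for j in range(ln):
                    base_calls[rpos + j, _BASE[seq[qpos + j]]] += 1
                rpos += ln
                qpos += ln
            elif op == "I":
                if rpos > 0:
                    insertions[rpos - 1] += 1
                qpos += ln
            elif op == "D":
                for j in range(ln):
                    deletions[rpos + j] += 1
                rpos += ln
            elif op == "N":
                rpos += ln
            elif op == "S":
                qpos += ln
    return base_calls, deletions, insertions


def eigen_pca(standardized: np.ndarray):
    """PCA via eigen-decomposition of the sample covariance matrix.

    Returns (scores, components, variance_explained_pct), components in
    rows, sorted by decreasing eigenvalue. Signs are arbitrary.
    """
    X = np.asarray(standardized, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0, None)
    scores = Xc @ vecs
    return scores, vecs.T, 100.0 * vals / vals.sum()


def two_sample_t_equal_var(x, y):
    """Textbook pooled-variance two-sample t statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
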