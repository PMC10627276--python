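"""Ranking of candidate modified sites and motif analysis.

Sites are ranked by the control-normalized error score. The top-N sites
(default N=100) should be enriched for the base carrying the doped-in
modification; the bottom-N act as a negative control whose base
composition should match the transcript. A +/-2-base position frequency
matrix over the top sites, compared against the transcript background,
reveals whether neighboring bases contribute to the error signature
(reader-head context) or the central base acts alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .refseq import GAP, RNA_ALPHABET, ReferenceTranscript, context_window


@dataclass
class SiteRanking:
    """Positions ordered by descending normalized score.

    Ties break by higher coverage, then by lower position index, so the
    ranking is deterministic. Masked (e.g. low-control-coverage) positions
    are excluded entirely — also from the bottom-N, which would otherwise
    fill up with trivially error-free uncovered sites.
    """

    order: np.ndarray   # positions, best first
    scores: np.ndarray  # aligned with order
    n: int

    @property
    def top(self) -> np.ndarray:
        return self.order[: self.n]

    @property
    def bottom(self) -> np.ndarray:
        return self.order[-self.n :]

    def to_frame(self, transcript: ReferenceTranscript,
                 coverage: Optional[np.ndarray] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "position": self.order,
                "base": [transcript.sequence[p] for p in self.order],
                "score": self.scores,
            }
        )
        if coverage is not None:
            df["coverage"] = coverage[self.order]
        return df


def rank_sites(
    normalized_scores: np.ma.MaskedArray,
    transcript: ReferenceTranscript,
    n: int = 100,
    coverage: Optional[np.ndarray] = None,
) -> SiteRanking:
    """Rank unmasked positions by descending normalized error score."""
    scores = np.ma.asarray(normalized_scores)
    valid = np.flatnonzero(~np.ma.getmaskarray(scores))
    if len(valid) == 0:
        raise ValueError("all positions are masked")
    if n > len(valid):
        raise ValueError(f"n={n} exceeds {len(valid)} unmasked positions")
    vals = scores.data[valid]
    cov = coverage[valid] if coverage is not None else np.zeros(len(valid))
    # descending score, then descending coverage, then ascending position
    order = np.lexsort((valid, -cov, -vals))
    return SiteRanking(order=valid[order], scores=vals[order], n=n)


def site_base_composition(
    ranking: SiteRanking, transcript: ReferenceTranscript
) -> dict[str, dict[str, int]]:
    """Counts of A/C/G/U among the top-n and bottom-n sites; each of the
    two 4-vectors sums to n."""
    def tally(positions: np.ndarray) -> dict[str, int]:
        out = {b: 0 for b in RNA_ALPHABET}
        for p in positions:
            out[transcript.sequence[p]] += 1
        return out

    return {"top": tally(ranking.top), "bottom": tally(ranking.bottom)}


@dataclass
class MotifMatrix:
    """Position frequency matrix over selected sites, columns -flank..+flank.

    ``frequencies[j, b]`` is the frequency of base b at offset j among
    non-gap entries (each column sums to 1); ``enrichment`` is
    log2(freq / background); ``significant`` flags cells with
    |log2| > 1 and a Bonferroni-adjusted binomial p < 0.01. Thresholds are
    this package's own convention — motif calls in the literature this
    mirrors are qualitative.
    """

    offsets: np.ndarray       # (2*flank+1,)
    frequencies: np.ndarray   # (2*flank+1, 4)
    background: np.ndarray    # (4,)
    enrichment: np.ndarray    # log2(freq/background), -inf where freq 0
    p_values: np.ndarray      # per-cell binomial p (Bonferroni-adjusted)
    significant: np.ndarray   # bool
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, off in enumerate(self.offsets):
            for b, base in enumerate(RNA_ALPHABET):
                rows.append(
                    {"offset": int(off), "base": base,
                     "frequency": self.frequencies[j, b],
                     "background": self.background[b],
                     "log2_enrichment": self.enrichment[j, b],
                     "p_adjusted": self.p_values[j, b],
                     "significant": bool(self.significant[j, b])}
                )
        return pd.DataFrame(rows)


def motif_matrix(
    ranking_or_positions,
    transcript: ReferenceTranscript,
    flank: int = 2,
    alpha: float = 0.01,
    min_abs_log2: float = 1.0,
) -> MotifMatrix:
    """Build the +/-flank motif matrix over the top sites and test each
    cell against the transcript background composition."""
    positions: Sequence[int]
    if isinstance(ranking_or_positions, SiteRanking):
        positions = ranking_or_positions.top
    else:
        positions = ranking_or_positions
    if len(positions) == 0:
        raise ValueError("no sites selected")

    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=int)
    for p in positions:
        win = context_window(transcript, int(p), flank=flank)
        for j, c in enumerate(win):
            if c != GAP:
                counts[j, RNA_ALPHABET.index(c)] += 1

    col_totals = counts.sum(axis=1)  # < n_sites only at sequence edges
    freq = counts / np.maximum(col_totals, 1)[:, None]

    comp = transcript.base_composition()
    total = sum(comp.values())
    background = np.array([comp[b] / total for b in RNA_ALPHABET])

    with np.errstate(divide="ignore"):
        enrich = np.log2(np.where(freq > 0, freq, np.nan) / background)
    enrich = np.where(np.isnan(enrich), -np.inf, enrich)

    n_cells = width * 4
    pvals = np.ones((width, 4))
    for j in range(width):
        if col_totals[j] == 0:
            continue
        for b in range(4):
            p = stats.binomtest(
                counts[j, b], col_totals[j], background[b], alternative="two-sided"
            ).pvalue
            pvals[j, b] = min(1.0, p * n_cells)  # Bonferroni over all cells

    significant = (np.abs(enrich) > min_abs_log2) & (pvals < alpha)
    return MotifMatrix(
        offsets=np.arange(-flank, flank + 1),
        frequencies=freq,
        background=background,
        enrichment=enrich,
        p_values=pvals,
        significant=significant,
        n_sites=len(positions),
    )
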