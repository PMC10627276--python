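"""Dwell-time extraction and modified-vs-canonical comparison.

Event tables are tab-separated files with one row per (read, reference
position) as produced by signal-alignment (resquiggling) tools, keyed by
the *center* position of the reference 5-mer occupying the pore
reader-head. Dwell analyses pool every occurrence of the central base
across the transcript and compare a modified sample against its
canonical counterpart with a two-sample t-test (Student's equal-variance
by default, Welch by flag), reporting counts, means, SDs and the percent
dwell change.

Under 1:r modified:canonical mixing only a fraction a/(a+b) of the
target-base molecules are modified, so the measured percent change is an
attenuated version of the per-molecule effect (mixture mean
(1-p) + p*multiplier); comparisons should be read as underestimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .refseq import ReferenceTranscript

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["read_id", "position", "reference_kmer", "event_mean_pA", "dwell_ms"]


def load_events(path, transcript: ReferenceTranscript) -> pd.DataFrame:
    """Read an event TSV and validate it against the transcript.

    Rows whose ``reference_kmer`` does not match the transcript 5-mer at
    ``position +/- 2`` are dropped (count logged); extra columns are kept.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} missing columns {missing}")
    L = transcript.length
    expected = np.array(
        ["" if (p < 2 or p >= L - 2) else transcript.sequence[p - 2 : p + 3] for p in range(L)]
    )
    pos = df["position"].to_numpy()
    in_range = (pos >= 2) & (pos < L - 2)
    ok = in_range.copy()
    ok[in_range] = df["reference_kmer"].to_numpy()[in_range] == expected[pos[in_range]]
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d/%d event rows with mismatched reference k-mers",
                       dropped, len(df))
    return df.loc[ok].reset_index(drop=True)


def start_anchored_to_center(df: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Convert a start-anchored event dialect (``position`` = 5' end of the
    k-mer) to the center-anchored convention used here."""
    out = df.copy()
    out["position"] = out["position"] + k // 2
    return out


def samples_to_ms(df: pd.DataFrame, sampling_rate_hz: float,
                  column: str = "dwell_samples") -> pd.DataFrame:
    """Convert a dialect reporting dwell in raw signal samples to ms."""
    out = df.copy()
    out["dwell_ms"] = out[column] / sampling_rate_hz * 1000.0
    return out


def dwell_by_base(
    events: pd.DataFrame, transcript: ReferenceTranscript, base: str
) -> np.ndarray:
    """All dwell values (ms) at positions whose central base is ``base``."""
    codes = np.frombuffer(transcript.sequence.encode(), dtype="S1")
    sel = codes[events["position"].to_numpy()] == base.encode()
    return events.loc[sel, "dwell_ms"].to_numpy(dtype=float)


@dataclass
class DwellComparison:
    """Two-sample dwell comparison in the layout of a per-modification
    dwell report (sample labels, counts, means, SDs, t, p, % change)."""

    label_mod: str
    label_canonical: str
    base: str
    n_mod: int
    n_canonical: int
    mean_mod_ms: float
    mean_canonical_ms: float
    sd_mod_ms: float
    sd_canonical_ms: float
    t_statistic: float
    p_value: float

    @property
    def percent_change(self) -> float:
        return dwell_percent_change(self.mean_mod_ms, self.mean_canonical_ms)


def dwell_percent_change(mean_mod: float, mean_canonical: float) -> float:
    """Percent dwell change, 100 * (mean_mod / mean_canonical - 1)."""
    if mean_canonical <= 0:
        raise ValueError("canonical mean must be positive")
    return 100.0 * (mean_mod / mean_canonical - 1.0)


def compare_dwell(
    mod_events: pd.DataFrame,
    canon_events: pd.DataFrame,
    transcript: ReferenceTranscript,
    base: str,
    equal_var: bool = True,
    label_mod: str = "modified",
    label_canonical: str = "canonical",
) -> DwellComparison:
    """Compare dwell at the given central base between a modified and a
    canonical sample (two-sided Student's t-test; Welch with
    ``equal_var=False``)."""
    x = dwell_by_base(mod_events, transcript, base)
    y = dwell_by_base(canon_events, transcript, base)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"need >= 2 dwell observations per group for base {base}")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return DwellComparison(
        label_mod=label_mod,
        label_canonical=label_canonical,
        base=base,
        n_mod=len(x),
        n_canonical=len(y),
        mean_mod_ms=float(np.mean(x)),
        mean_canonical_ms=float(np.mean(y)),
        sd_mod_ms=float(np.std(x, ddof=1)),
        sd_canonical_ms=float(np.std(y, ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
    )


def comparison_table(comparisons: list[DwellComparison]) -> pd.DataFrame:
    """Report table with one modified and one canonical row per comparison
    (columns Sample, Conc., Count, Mean (ms), SD, P-value)."""
    rows = []
    for c in comparisons:
        rows.append(
            {"Sample": c.label_mod, "Conc.": "", "Count": c.n_mod,
             "Mean (ms)": round(c.mean_mod_ms, 1), "SD": round(c.sd_mod_ms, 1),
             "P-value (t-test)": c.p_value}
        )
        rows.append(
            {"Sample": c.label_canonical, "Conc.": "", "Count": c.n_canonical,
             "Mean (ms)": round(c.mean_canonical_ms, 1), "SD": round(c.sd_canonical_ms, 1),
             "P-value (t-test)": ""}
        )
    return pd.DataFrame(rows)
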