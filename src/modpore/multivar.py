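"""Multivariate analyses: PCA at sample, read, and nucleotide level.

Three complementary views of the same signal space:

* **sample level** — one observation per sample, 7 variables (A-to-X,
  C-to-X, G-to-X, U-to-X error percentages, insertion rate, deletion
  rate, mean dwell), z-scored then PCA; samples carrying detectable
  modifications separate from the canonical pool.
* **read level** — one observation per read; variables are per-5-mer mean
  current and dwell for the 5-mers whose signals differ most among the
  samples (one-way ANOVA F statistic, top 5% per channel).
* **nucleotide level** — one observation per reference position, same 7
  variables (the base-rate slot matching the reference base carries the
  position's mismatch rate, the other three are 0). Outlier sites are
  the positions whose (PC1, PC2) scores lie farthest by Euclidean
  distance from the score centroid; individual reads are then annotated
  at those sites as modified/unmodified from their errors and dwell.

When a canonical control is supplied for the nucleotide-level analysis,
rate and dwell features are sample-minus-control differences: this
removes the base-identity cluster structure from the score space, so the
Euclidean outlier rule responds to modification signal rather than to
which base a position happens to be, and canonical-vs-canonical runs
yield outlier sets with the transcript's own base composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .errprof import PileupProfile, indel_rates, substitution_breakdown
from .refseq import BASE_TO_CODE, CODE_TO_BASE, RNA_ALPHABET, ReferenceTranscript
from .simdata import DELETION_CODE, NO_INSERTION, SimulatedSample

logger = logging.getLogger(__name__)

SAMPLE_FEATURES = ["A_to_X", "C_to_X", "G_to_X", "U_to_X",
                   "insertion_pct", "deletion_pct", "dwell_ms"]


# ---------------------------------------------------------------------------
# standardization and PCA core

@dataclass
class ZscoreResult:
    matrix: np.ndarray        # standardized, constant columns dropped
    mean: np.ndarray          # per retained column
    sd: np.ndarray            # sample SD (ddof=1) per retained column
    kept_columns: np.ndarray  # indices into the input columns

    def inverse(self) -> np.ndarray:
        """Undo the standardization (retained columns only)."""
        return self.matrix * self.sd + self.mean


def zscore(matrix: np.ndarray) -> ZscoreResult:
    """Standardize columns to mean 0, sample SD 1; constant columns are
    dropped with a warning (they carry no variance to analyze)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant feature column(s)", int((~keep).sum()))
    if not keep.any():
        raise ValueError("all feature columns are constant")
    return ZscoreResult(
        matrix=(X[:, keep] - mean[keep]) / sd[keep],
        mean=mean[keep],
        sd=sd[keep],
        kept_columns=np.flatnonzero(keep),
    )


@dataclass
class PCAResult:
    scores: np.ndarray                 # (n_obs, n_components), zero mean
    loadings: np.ndarray               # (n_components, n_features)
    variance_explained_pct: np.ndarray  # (n_components,)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(standardized: np.ndarray, n_components: Optional[int] = None) -> PCAResult:
    """PCA of a standardized matrix with a deterministic sign convention:
    each component is flipped so its largest-|loading| entry is positive.

    ``n_components`` beyond the matrix rank is truncated with a warning.
    """
    X = np.asarray(standardized, dtype=float)
    max_comp = min(X.shape)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        logger.warning("n_components=%d truncated to rank bound %d",
                       n_components, max_comp)
        n_components = max_comp
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained_pct=pca.explained_variance_ratio_ * 100.0,
    )


# ---------------------------------------------------------------------------
# sample-level analysis

def sample_feature_vector(profile: PileupProfile, events: pd.DataFrame) -> dict[str, float]:
    """The 7 analysis variables for one sample."""
    rates = substitution_breakdown(profile).to_x_rates()
    ins_pct, del_pct = indel_rates(profile)
    return {
        "A_to_X": rates["A_to_X"],
        "C_to_X": rates["C_to_X"],
        "G_to_X": rates["G_to_X"],
        "U_to_X": rates["U_to_X"],
        "insertion_pct": ins_pct,
        "deletion_pct": del_pct,
        "dwell_ms": float(events["dwell_ms"].mean()),
    }


def sample_feature_table(
    samples: dict[str, tuple[PileupProfile, pd.DataFrame]]
) -> pd.DataFrame:
    """One 7-variable row per sample. Canonical replicates should be pooled
    (profiles summed, event tables concatenated) before calling this, so
    rates are computed from pooled counts. Samples missing dwell data are
    dropped with a warning."""
    rows = {}
    for label, (profile, events) in samples.items():
        if events is None or len(events) == 0:
            logger.warning("sample %s has no dwell data; dropped", label)
            continue
        rows[label] = sample_feature_vector(profile, events)
    if not rows:
        raise ValueError("no samples with complete features")
    return pd.DataFrame.from_dict(rows, orient="index")[SAMPLE_FEATURES]


def sample_level_pca(table: pd.DataFrame, n_components: int = 2) -> PCAResult:
    return run_pca(zscore(table.to_numpy()).matrix, n_components)


# ---------------------------------------------------------------------------
# read-level analysis

_CHANNEL_COLUMNS = {"current": "event_mean_pA", "dwell": "dwell_ms"}


def anova_select(
    events_by_sample: dict[str, pd.DataFrame],
    channel: str,
    top_frac: float = 0.05,
    min_per_sample: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA per reference 5-mer on a signal channel across
    samples; returns F statistics with the top ``top_frac`` flagged.

    K-mers observed fewer than ``min_per_sample`` times in any sample are
    excluded (logged).
    """
    if channel not in _CHANNEL_COLUMNS:
        raise ValueError(f"channel must be one of {sorted(_CHANNEL_COLUMNS)}")
    if len(events_by_sample) < 2:
        raise ValueError("ANOVA needs at least 2 samples")
    col = _CHANNEL_COLUMNS[channel]

    grouped = {
        label: dict(iter(df.groupby("reference_kmer")[col]))
        for label, df in events_by_sample.items()
    }
    common = set.intersection(*(set(g) for g in grouped.values()))
    rows = []
    excluded = 0
    for kmer in sorted(common):
        groups = [g[kmer].to_numpy(dtype=float) for g in grouped.values()]
        if any(len(x) < min_per_sample for x in groups):
            excluded += 1
            continue
        f, _ = stats.f_oneway(*groups)
        rows.append({"kmer": kmer, "channel": channel, "F": float(f)})
    if excluded:
        logger.info("excluded %d k-mers below the %d-observation minimum",
                    excluded, min_per_sample)
    if not rows:
        raise ValueError("no k-mers passed the minimum-count filter")
    df = pd.DataFrame(rows)
    cutoff = df["F"].quantile(1.0 - top_frac)
    df["selected"] = df["F"] >= cutoff
    return df.sort_values("F", ascending=False).reset_index(drop=True)


def read_level_pca(
    events_by_sample: dict[str, pd.DataFrame],
    selected: pd.DataFrame,
    max_reads_per_sample: int = 5000,
    seed: int = 0,
    min_feature_cover: float = 0.5,
    n_components: int = 2,
) -> tuple[PCAResult, pd.DataFrame]:
    """PCA over reads using the ANOVA-selected (k-mer, channel) signals.

    Per read, each feature is the mean of that read's events at the k-mer.
    Reads are subsampled to ``max_reads_per_sample`` with the given seed;
    reads with under ``min_feature_cover`` of features observed are
    dropped (logged) and remaining gaps are feature-mean imputed.

    Returns the PCA result and a per-read metadata frame (read_id, sample,
    missing-feature fraction) aligned with the score rows.
    """
    rng = np.random.default_rng(seed)
    features = list(selected.loc[selected["selected"], ["kmer", "channel"]]
                    .itertuples(index=False, name=None))
    if not features:
        raise ValueError("no selected features")

    blocks = []
    for label in sorted(events_by_sample):
        df = events_by_sample[label]
        reads = df["read_id"].unique()
        if len(reads) > max_reads_per_sample:
            reads = rng.choice(reads, size=max_reads_per_sample, replace=False)
        sub = df[df["read_id"].isin(reads)].copy()
        sub["sample"] = label
        blocks.append(sub)
    pooled = pd.concat(blocks, ignore_index=True)

    cols = []
    for kmer, channel in features:
        sel = pooled[pooled["reference_kmer"] == kmer]
        series = sel.groupby("read_id")[_CHANNEL_COLUMNS[channel]].mean()
        series.name = f"{kmer}:{channel}"
        cols.append(series)
    table = pd.concat(cols, axis=1)

    meta = pooled[["read_id", "sample"]].drop_duplicates().set_index("read_id")
    table = table.reindex(meta.index)

    missing_frac = table.isna().mean(axis=1)
    keep = missing_frac <= (1.0 - min_feature_cover)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d reads with <%.0f%% feature coverage",
                       dropped, 100 * min_feature_cover)
    table = table[keep]
    meta = meta[keep].copy()
    meta["missing_feature_fraction"] = missing_frac[keep]

    table = table.fillna(table.mean())
    z = zscore(table.to_numpy())
    pca = run_pca(z.matrix, n_components)
    return pca, meta.reset_index()


# ---------------------------------------------------------------------------
# nucleotide-level analysis

@dataclass
class PerNucleotidePCA:
    pca: PCAResult
    positions: np.ndarray  # reference positions of the score rows
    bases: np.ndarray      # reference base per score row
    features: pd.DataFrame


CONTROL_POSITION_FEATURES = ["normalized_error_pct", "d_insertion_pct",
                             "d_deletion_pct", "d_dwell_ms"]


def position_feature_table(
    profile: PileupProfile,
    events: pd.DataFrame,
    control_profile: Optional[PileupProfile] = None,
    control_events: Optional[pd.DataFrame] = None,
    min_coverage: int = 20,
) -> pd.DataFrame:
    """Per-position feature table (index = reference position).

    Without a control: the 7 analysis variables, where the base-rate slot
    matching the reference base holds that position's mismatch percentage
    and the other three slots are 0 — this encoding reproduces the
    base-wise clustering of positions in score space.

    With a control: four base-agnostic difference variables
    (sample-minus-control error, insertion, deletion percentages and mean
    dwell). Base identity is a known covariate of a reference position,
    not evidence of modification, so it is deliberately removed from the
    features; this keeps all positions exchangeable under the null, and
    outlier calls then respond to modification signal only.
    """
    mism = profile.mismatch_rate * 100.0
    ins = profile.insertion_rate * 100.0
    dele = profile.deletion_rate * 100.0
    dwell_pos = events.groupby("position")["dwell_ms"].mean()

    if control_profile is not None:
        mism = mism - control_profile.mismatch_rate * 100.0
        ins = ins - control_profile.insertion_rate * 100.0
        dele = dele - control_profile.deletion_rate * 100.0
        if control_events is not None:
            dwell_pos = dwell_pos - control_events.groupby("position")["dwell_ms"].mean()

    ok = (profile.coverage >= min_coverage) & ~np.isnan(mism)
    if control_profile is not None:
        ok &= control_profile.coverage >= min_coverage
    positions = np.flatnonzero(ok)
    positions = positions[np.isin(positions, dwell_pos.index)]
    dwell_vals = dwell_pos.loc[positions].to_numpy(dtype=float)
    keep = ~np.isnan(dwell_vals)
    positions, dwell_vals = positions[keep], dwell_vals[keep]

    if control_profile is not None:
        table = pd.DataFrame(index=positions, columns=CONTROL_POSITION_FEATURES,
                             dtype=float)
        table["normalized_error_pct"] = mism[positions]
        table["d_insertion_pct"] = ins[positions]
        table["d_deletion_pct"] = dele[positions]
        table["d_dwell_ms"] = dwell_vals
        return table

    table = pd.DataFrame(0.0, index=positions, columns=SAMPLE_FEATURES)
    for b, base in enumerate(RNA_ALPHABET):
        rows = positions[profile.ref_codes[positions] == b]
        table.loc[rows, f"{base}_to_X"] = mism[rows]
    table["insertion_pct"] = ins[positions]
    table["deletion_pct"] = dele[positions]
    table["dwell_ms"] = dwell_vals
    return table


def per_nucleotide_pca(
    profile: PileupProfile,
    events: pd.DataFrame,
    control_profile: Optional[PileupProfile] = None,
    control_events: Optional[pd.DataFrame] = None,
    min_coverage: int = 20,
    n_components: int = 2,
) -> PerNucleotidePCA:
    """PCA over reference positions (one observation per position)."""
    table = position_feature_table(
        profile, events, control_profile, control_events, min_coverage
    )
    positions = table.index.to_numpy()
    pca = run_pca(zscore(table.to_numpy()).matrix, n_components)
    return PerNucleotidePCA(
        pca=pca,
        positions=positions,
        bases=CODE_TO_BASE[profile.ref_codes[positions]],
        features=table,
    )


def outlier_sites(
    result: PerNucleotidePCA,
    k: Optional[int] = 100,
    quantile: Optional[float] = None,
    restrict_base: Optional[str] = None,
    centroid: str = "median",
) -> np.ndarray:
    """Positions with (PC1, PC2) scores farthest (Euclidean) from the
    score centroid; top-k (default 100) or top-quantile.

    The centroid is the component-wise *median* by default: when a
    sizable minority of positions carries modification signal, the mean
    is dragged toward that cluster and the unmodified bulk acquires
    spurious distance; the median stays anchored on the unmodified bulk
    (``centroid="mean"`` restores the plain mean).

    ``restrict_base`` limits the candidate pool to positions of one
    reference base, for experiments that declare the doped-in nucleotide.
    """
    scores = result.pca.scores[:, :2]
    if centroid == "median":
        center = np.median(scores, axis=0)
    elif centroid == "mean":
        center = scores.mean(axis=0)
    else:
        raise ValueError(f"unknown centroid {centroid!r}")
    dist = np.linalg.norm(scores - center, axis=1)
    pool = np.arange(len(result.positions))
    if restrict_base is not None:
        if restrict_base not in BASE_TO_CODE:
            raise ValueError(f"unknown base {restrict_base!r}")
        pool = pool[result.bases == restrict_base]
    if quantile is not None:
        cut = np.quantile(dist[pool], quantile)
        chosen = pool[dist[pool] >= cut]
        return result.positions[chosen[np.argsort(-dist[chosen])]]
    if k is None:
        raise ValueError("either k or quantile must be given")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds {len(pool)} candidate positions")
    order = pool[np.argsort(-dist[pool], kind="stable")]
    return result.positions[order[:k]]


# ---------------------------------------------------------------------------
# per-read annotation at outlier sites

def _site_calls_from_sam(
    alignments, transcript: ReferenceTranscript, sites: np.ndarray
) -> dict[str, dict[int, tuple[int, bool]]]:
    """Per read, per site: (call code with 4 = deletion, insertion-after?)."""
    site_set = {int(s) for s in sites}
    out: dict[str, dict[int, tuple[int, bool]]] = {}
    with pysam.AlignmentFile(str(alignments), "r") as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            calls: dict[int, tuple[int, bool]] = {}
            q = read.query_sequence
            rpos = read.reference_start
            qpos = 0
            for op, ln in read.cigartuples:
                if op in (0, 7, 8):
                    for s in site_set:
                        if rpos <= s < rpos + ln:
                            code = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}.get(
                                q[qpos + (s - rpos)], -1
                            )
                            calls[s] = (code, False)
                    rpos += ln
                    qpos += ln
                elif op == 1:
                    if rpos - 1 in site_set:
                        code, _ = calls.get(rpos - 1, (-1, False))
                        calls[rpos - 1] = (code, True)
                    qpos += ln
                elif op == 2:
                    for s in site_set:
                        if rpos <= s < rpos + ln:
                            calls[s] = (DELETION_CODE, False)
                    rpos += ln
                elif op == 3:
                    rpos += ln
                elif op == 4:
                    qpos += ln
            out[read.query_name] = calls
    return out


def _site_calls_from_sample(
    sample: SimulatedSample, sites: np.ndarray
) -> dict[str, dict[int, tuple[int, bool]]]:
    out: dict[str, dict[int, tuple[int, bool]]] = {}
    for i, rid in enumerate(sample.read_ids):
        out[rid] = {
            int(s): (int(sample.calls[i, s]), sample.ins_base[i, s] != NO_INSERTION)
            for s in sites
        }
    return out


def annotate_reads(
    alignments: Union[str, SimulatedSample],
    transcript: ReferenceTranscript,
    events: pd.DataFrame,
    sites: np.ndarray,
    canonical_events: Optional[pd.DataFrame] = None,
    dwell_factor: float = 1.5,
) -> pd.DataFrame:
    """Annotate each read at each outlier site.

    A read is called ``modified`` at a site if it mismatches, is deleted,
    or has an insertion there, OR if its dwell exceeds ``dwell_factor``
    times the canonical sample's median dwell at that site; ``unmodified``
    otherwise; ``no-data`` if the read does not cover the site. Without
    canonical events the dwell criterion is skipped (flagged in the
    ``dwell_criterion_used`` column).
    """
    sites = np.asarray(sites, dtype=int)
    if isinstance(alignments, SimulatedSample):
        calls = _site_calls_from_sample(alignments, sites)
    else:
        calls = _site_calls_from_sam(alignments, transcript, sites)

    if canonical_events is not None:
        med = canonical_events[canonical_events["position"].isin(sites)] \
            .groupby("position")["dwell_ms"].median()
        site_median = {int(p): float(v) for p, v in med.items()}
    else:
        site_median = {}

    ev = events[events["position"].isin(sites)]
    dwell_lookup = {
        (rid, int(pos)): d
        for rid, pos, d in zip(ev["read_id"], ev["position"], ev["dwell_ms"])
    }

    ref = transcript.codes()
    rows = []
    for rid, site_calls in calls.items():
        for s in sites:
            s = int(s)
            if s not in site_calls or site_calls[s][0] < 0 and not site_calls[s][1]:
                rows.append({"read_id": rid, "position": s, "call": "no-data",
                             "error_evidence": False, "dwell_evidence": False,
                             "dwell_criterion_used": s in site_median})
                continue
            code, has_ins = site_calls[s]
            error = has_ins or code == DELETION_CODE or code != ref[s]
            d = dwell_lookup.get((rid, s))
            used = s in site_median
            long_dwell = bool(
                used and d is not None and d > dwell_factor * site_median[s]
            )
            rows.append({
                "read_id": rid, "position": s,
                "call": "modified" if (error or long_dwell) else "unmodified",
                "error_evidence": bool(error),
                "dwell_evidence": long_dwell,
                "dwell_criterion_used": used,
            })
    return pd.DataFrame(rows)


def write_sites_bed(sites: Sequence[int], transcript: ReferenceTranscript, path) -> None:
    """Outlier sites as a BED file (0-based half-open) on the transcript."""
    with open(path, "w") as fh:
        for s in sorted(int(x) for x in sites):
            fh.write(f"{transcript.name}\t{s}\t{s + 1}\toutlier\n")
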