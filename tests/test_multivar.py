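import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import matthews_corrcoef, silhouette_score

from modpore import errprof, multivar, simdata

import oracles


# ---------------------------------------------------------------------------
# standardization and PCA core

def test_zscore_examples_and_round_trip():
    z = multivar.zscore(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
    assert np.allclose(z.matrix[:, 0], [-1, 0, 1])  # sample SD (n-1)
    assert list(z.kept_columns) == [0]  # constant column dropped
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 5)) * [1, 2, 3, 4, 5]
    z2 = multivar.zscore(X)
    assert np.allclose(z2.inverse(), X, atol=1e-12)
    with pytest.raises(ValueError):
        multivar.zscore(X[:1])
    with pytest.raises(ValueError):
        multivar.zscore(np.ones((5, 2)))


def test_pca_rank_one_and_variance_conservation():
    rng = np.random.default_rng(0)
    direction = rng.normal(size=4)
    X = np.outer(rng.normal(size=30), direction)
    res = multivar.run_pca(X, n_components=1)
    assert res.variance_explained_pct[0] == pytest.approx(100.0)
    X2 = rng.normal(size=(30, 4))
    full = multivar.run_pca(X2)
    assert full.variance_explained_pct.sum() == pytest.approx(100.0)
    assert np.allclose(full.scores.mean(axis=0), 0.0, atol=1e-10)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(7)
    X = multivar.zscore(rng.normal(size=(10, 7))).matrix
    res = multivar.run_pca(X)
    scores_o, comps_o, var_o = oracles.eigen_pca(X)
    assert np.allclose(res.variance_explained_pct, var_o, atol=1e-9)
    for j in range(res.n_components):
        # signs are conventions; compare up to sign
        assert (
            np.allclose(res.scores[:, j], scores_o[:, j], atol=1e-9)
            or np.allclose(res.scores[:, j], -scores_o[:, j], atol=1e-9)
        )
    # deterministic sign convention: the largest-|loading| entry is positive
    for row in res.loadings:
        assert row[np.argmax(np.abs(row))] > 0


def test_pca_truncates_beyond_rank(caplog):
    X = np.random.default_rng(1).normal(size=(4, 7))
    res = multivar.run_pca(multivar.zscore(X).matrix, n_components=7)
    assert res.n_components <= 4


# ---------------------------------------------------------------------------
# feature tables

def test_identical_samples_have_identical_feature_vectors(clone, canonical_600):
    _, prof, events = canonical_600
    table = multivar.sample_feature_table(
        {"s1": (prof, events), "s2": (prof, events)}
    )
    assert np.allclose(table.loc["s1"], table.loc["s2"])
    assert list(table.columns) == multivar.SAMPLE_FEATURES


def test_pooling_order_invariance(clone):
    samples = [
        simdata.simulate_sample(simdata.SimulationConfig(n_reads=25, seed=s), clone)[0]
        for s in (5, 6)
    ]
    profs = [errprof.pileup_sample(s, clone) for s in samples]
    evs = [simdata.events_frame(s, clone) for s in samples]
    pooled_prof = profs[0] + profs[1]
    pooled_ev = pd.concat(evs, ignore_index=True)
    v_pooled = multivar.sample_feature_vector(pooled_prof, pooled_ev)
    # recompute by concatenating the raw reads first
    both = simdata.SimulatedSample(
        label="both",
        read_ids=samples[0].read_ids + samples[1].read_ids,
        calls=np.vstack([samples[0].calls, samples[1].calls]),
        ins_base=np.vstack([samples[0].ins_base, samples[1].ins_base]),
        dwell_ms=np.vstack([samples[0].dwell_ms, samples[1].dwell_ms]),
        current_pA=np.vstack([samples[0].current_pA, samples[1].current_pA]),
        modified=np.vstack([samples[0].modified, samples[1].modified]),
    )
    v_joint = multivar.sample_feature_vector(
        errprof.pileup_sample(both, clone), simdata.events_frame(both, clone)
    )
    for key in v_pooled:
        assert v_pooled[key] == pytest.approx(v_joint[key], rel=1e-12)


def test_sample_without_events_is_dropped(clone, canonical_600):
    _, prof, events = canonical_600
    table = multivar.sample_feature_table(
        {"ok": (prof, events), "noev": (prof, events.iloc[0:0])}
    )
    assert list(table.index) == ["ok"]


# ---------------------------------------------------------------------------
# ANOVA feature selection

def test_anova_f_equals_t_squared_for_two_groups(clone):
    sims = {
        lab: simdata.simulate_sample(
            simdata.SimulationConfig(n_reads=15, seed=s), clone
        )[0]
        for lab, s in [("a", 1), ("b", 2)]
    }
    ev = {lab: simdata.events_frame(s, clone) for lab, s in sims.items()}
    sel = multivar.anova_select(ev, "dwell")
    kmer = sel["kmer"].iloc[0]
    groups = [
        e.loc[e["reference_kmer"] == kmer, "dwell_ms"].to_numpy() for e in ev.values()
    ]
    t, _ = stats.ttest_ind(*groups)
    f = sel.loc[sel["kmer"] == kmer, "F"].iloc[0]
    assert f == pytest.approx(t**2, abs=1e-9 * max(1, abs(f)))
    # quantile rule keeps ~5%
    assert sel["selected"].sum() == pytest.approx(0.05 * len(sel), abs=2)


def test_planted_current_shift_has_max_f(clone):
    sims = {}
    for lab, s in [("a", 3), ("b", 4)]:
        sample, _ = simdata.simulate_sample(
            simdata.SimulationConfig(n_reads=15, seed=s), clone
        )
        sims[lab] = sample
    ev = {lab: simdata.events_frame(s, clone) for lab, s in sims.items()}
    target = ev["a"]["reference_kmer"].iloc[500]
    ev["a"].loc[ev["a"]["reference_kmer"] == target, "event_mean_pA"] += 10.0
    sel = multivar.anova_select(ev, "current")
    assert sel["kmer"].iloc[0] == target


def test_anova_needs_two_samples(canonical_600, clone):
    _, _, events = canonical_600
    with pytest.raises(ValueError):
        multivar.anova_select({"only": events}, "dwell")
    with pytest.raises(ValueError):
        multivar.anova_select({"a": events, "b": events}, "quality")


# ---------------------------------------------------------------------------
# read-level PCA

def test_read_level_pca_reproducible_and_separates_strong_modification(clone):
    ev = {}
    for name, seed in [("canonical", 1), ("biotinC", 3)]:
        cfg = simdata.preset_config(name, (1, 2), n_reads=40, seed=seed)
        sample, _ = simdata.simulate_sample(cfg, clone)
        ev[name] = simdata.events_frame(sample, clone)
    sel = pd.concat(
        [multivar.anova_select(ev, "current"), multivar.anova_select(ev, "dwell")],
        ignore_index=True,
    )
    pca1, meta1 = multivar.read_level_pca(ev, sel, max_reads_per_sample=30, seed=5)
    pca2, meta2 = multivar.read_level_pca(ev, sel, max_reads_per_sample=30, seed=5)
    assert np.allclose(pca1.scores, pca2.scores)
    assert meta1["read_id"].tolist() == meta2["read_id"].tolist()
    # strongly modified reads sit outside the canonical score radius
    r = np.linalg.norm(pca1.scores[:, :2] - np.median(pca1.scores[:, :2], 0), axis=1)
    thr = np.quantile(r[(meta1["sample"] == "canonical").to_numpy()], 0.99)
    outliers = (r > thr) & (meta1["sample"] == "biotinC").to_numpy()
    assert outliers.sum() > 0


# ---------------------------------------------------------------------------
# per-nucleotide PCA and outliers

def test_raw_mode_positions_cluster_by_base(clone, canonical_600):
    _, prof, events = canonical_600
    res = multivar.per_nucleotide_pca(prof, events)
    sil = silhouette_score(res.pca.scores[:, :2], res.bases)
    assert sil > 0


def test_per_nucleotide_pca_agrees_with_eigen_oracle(clone, canonical_600):
    _, prof, events = canonical_600
    table = multivar.position_feature_table(prof, events)
    z = multivar.zscore(table.to_numpy()).matrix
    res = multivar.run_pca(z, 2)
    _, _, var_o = oracles.eigen_pca(z)
    assert np.allclose(res.variance_explained_pct, var_o[:2], atol=1e-9)


def test_outlier_distance_invariances(clone, canonical_600):
    _, prof, events = canonical_600
    res = multivar.per_nucleotide_pca(prof, events)
    sites = multivar.outlier_sites(res, k=50)
    flipped = multivar.PerNucleotidePCA(
        pca=multivar.PCAResult(
            scores=-res.pca.scores,
            loadings=-res.pca.loadings,
            variance_explained_pct=res.pca.variance_explained_pct,
        ),
        positions=res.positions,
        bases=res.bases,
        features=res.features,
    )
    assert np.array_equal(sites, multivar.outlier_sites(flipped, k=50))
    only_u = multivar.outlier_sites(res, k=30, restrict_base="U")
    assert all(clone.sequence[p] == "U" for p in only_u)
    with pytest.raises(ValueError):
        multivar.outlier_sites(res, k=10**6)


def test_planted_site_is_farthest_outlier(clone, canonical_600):
    _, ctrl_prof, ctrl_ev = canonical_600
    cfg = simdata.SimulationConfig(n_reads=300, seed=61)
    sample, _ = simdata.simulate_sample(cfg, clone)
    prof = errprof.pileup_sample(sample, clone)
    # plant one site with gross extra mismatches
    pos = 700
    ref_code = prof.ref_codes[pos]
    alt = (ref_code + 1) % 4
    prof.base_calls[pos, alt] += 250
    prof.base_calls[pos, ref_code] = max(prof.base_calls[pos, ref_code] - 250, 0)
    ev = simdata.events_frame(sample, clone)
    res = multivar.per_nucleotide_pca(prof, ev, ctrl_prof, ctrl_ev)
    sites = multivar.outlier_sites(res, k=1)
    assert sites[0] == pos


# ---------------------------------------------------------------------------
# read annotation

def test_annotation_calls_and_no_data(clone, canonical_600):
    _, _, ctrl_ev = canonical_600
    cfg = simdata.SimulationConfig(
        n_reads=3, sub_rate_baseline=0.0, ins_rate_baseline=0.0, del_rate_baseline=0.0
    )
    sample, _ = simdata.simulate_sample(cfg, clone)
    sample.dwell_ms[:, :] = 10.0  # typical, below any 1.5x median threshold
    ev = simdata.events_frame(sample, clone)
    sites = np.array([100, 200])
    ann = multivar.annotate_reads(sample, clone, ev, sites, ctrl_ev)
    assert set(ann["call"]) == {"unmodified"}
    # a read with a mismatch at the site is called modified
    sample.calls[0, 100] = (sample.calls[0, 100] + 1) % 4
    ann2 = multivar.annotate_reads(sample, clone, simdata.events_frame(sample, clone),
                                   sites, ctrl_ev)
    row = ann2[(ann2["read_id"] == sample.read_ids[0]) & (ann2["position"] == 100)]
    assert row["call"].iloc[0] == "modified"
    assert row["error_evidence"].iloc[0]
    # deletion at the site -> no event row -> still called from the error
    sample.calls[1, 200] = simdata.DELETION_CODE
    ann3 = multivar.annotate_reads(sample, clone, simdata.events_frame(sample, clone),
                                   sites, ctrl_ev)
    row = ann3[(ann3["read_id"] == sample.read_ids[1]) & (ann3["position"] == 200)]
    assert row["call"].iloc[0] == "modified"


def test_annotation_against_truth_exceeds_chance(clone, canonical_600):
    """Per-read calls at outlier sites recover the simulated ground truth
    well beyond chance for the strong modification preset."""
    _, ctrl_prof, ctrl_ev = canonical_600
    cfg = simdata.preset_config("biotinC", (1, 2), n_reads=300, seed=9)
    sample, truth = simdata.simulate_sample(cfg, clone)
    prof = errprof.pileup_sample(sample, clone)
    ev = simdata.events_frame(sample, clone)
    res = multivar.per_nucleotide_pca(prof, ev, ctrl_prof, ctrl_ev)
    sites = multivar.outlier_sites(res, k=100, restrict_base="C")
    ann = multivar.annotate_reads(sample, clone, ev, sites, ctrl_ev)
    called = ann[ann["call"] != "no-data"]
    y_true = [
        (r, p) in truth.entries for r, p in zip(called["read_id"], called["position"])
    ]
    y_pred = (called["call"] == "modified").to_numpy()
    assert matthews_corrcoef(y_true, y_pred) > 0.3
    # modified-call fraction at truth sites = true positive capture, well
    # above the 1/3 incorporation floor
    tp = y_pred[np.asarray(y_true)]
    assert tp.mean() > 0.5


def test_sites_bed_output(tmp_path, clone):
    multivar.write_sites_bed([5, 2], clone, tmp_path / "s.bed")
    lines = (tmp_path / "s.bed").read_text().splitlines()
    assert lines[0].split("\t")[:3] == [clone.name, "2", "3"]
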