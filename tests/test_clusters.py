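"""Correlation curves, exponential-decay fits, sliding-window coactivation,
nonnegative-ICA cluster extraction, shuffle control, and cluster activity."""

import numpy as np
import pytest
from scipy import optimize

from dendroglu.clusters import (
    FunctionalClusterICA,
    cluster_activity,
    cluster_shuffle_control,
    extract_functional_clusters,
    find_nonanatomical_clusters,
    fit_correlation_decay,
    nearest_nonnegative,
    pairwise_correlation_vs_distance,
    pooled_shuffle_control,
    sliding_window_coactivation,
)


# ---------------------------------------------------------------------------
# correlations vs distance
# ---------------------------------------------------------------------------

def test_identical_maps_correlate_at_one():
    m = np.sin(np.linspace(0, 3, 50))
    S = np.vstack([m, m, m])
    curve = pairwise_correlation_vs_distance(S, positions_um=np.array([0., 3., 6.]))
    assert curve.n_pairs == 3
    assert curve.overall_mean == pytest.approx(1.0)


def test_negated_map_correlates_at_minus_one():
    m = np.sin(np.linspace(0, 3, 50))
    S = np.vstack([m, 2 * m.mean() - m])
    curve = pairwise_correlation_vs_distance(S, positions_um=np.array([0., 5.]))
    assert curve.overall_mean == pytest.approx(-1.0)


def test_pairs_at_one_micron_excluded():
    rng = np.random.default_rng(0)
    S = rng.random((3, 40))
    curve = pairwise_correlation_vs_distance(
        S, positions_um=np.array([0.0, 1.0, 3.0]))
    assert curve.n_pairs == 2  # (0,3) and (1,3); the 1-um pair is dropped


def test_constant_signal_pairs_skipped():
    S = np.vstack([np.ones(30), np.random.default_rng(1).random(30)])
    curve = pairwise_correlation_vs_distance(S, positions_um=np.array([0., 5.]))
    assert curve.n_pairs == 0 and curve.n_skipped == 1


def test_independent_rois_give_flat_curve():
    """No falloff for independent signals: regression slope CI includes 0."""
    rng = np.random.default_rng(2)
    S = rng.normal(0, 1, (40, 400))
    curve = pairwise_correlation_vs_distance(
        S, positions_um=np.arange(40, dtype=float))
    ok = curve.count > 5
    d, r = curve.distance_um[ok], curve.mean_r[ok]
    slope, intercept = np.polyfit(d, r, 1)
    resid = r - (slope * d + intercept)
    se = np.sqrt(resid @ resid / (d.size - 2) / np.sum((d - d.mean()) ** 2))
    assert abs(slope) < 2.5 * se


# ---------------------------------------------------------------------------
# exponential decay + LR
# ---------------------------------------------------------------------------

def test_noiseless_tau_recovery_within_one_percent():
    d = np.arange(2, 31, 1.0)
    for tau in (2.55, 1.43):
        y = 0.3 * np.exp(-d / tau) + 0.02
        res = fit_correlation_decay({"g": (d, y)})
        assert res["fits"]["g"]["tau"] == pytest.approx(tau, rel=0.01)


def test_flat_curve_flagged_and_excluded():
    d = np.arange(2, 31, 1.0)
    curves = {
        "flat": (d, np.full(d.size, 0.02)),
        "a": (d, 0.3 * np.exp(-d / 2.0) + 0.01),
        "b": (d, 0.2 * np.exp(-d / 3.0) + 0.02),
    }
    res = fit_correlation_decay(curves)
    assert res["fits"]["flat"]["flat"]
    assert "flat" not in res["groups_compared"]
    assert np.isfinite(res["lr_p"])


def test_lr_test_calibrated_under_shared_tau():
    d = np.arange(2, 31, 1.0)
    rej = 0
    n_sim = 200
    for s in range(n_sim):
        rng = np.random.default_rng(5000 + s)
        curves = {}
        for g, (A, c) in {"place": (0.3, 0.02), "nonplace": (0.25, 0.01),
                          "inter": (0.2, 0.03)}.items():
            curves[g] = (d, A * np.exp(-d / 2.0) + c + rng.normal(0, 0.01, d.size))
        rej += fit_correlation_decay(curves)["lr_p"] < 0.05
    assert 0.01 <= rej / n_sim <= 0.10


def test_lr_test_rejects_distinct_taus():
    d = np.arange(2, 31, 1.0)
    rng = np.random.default_rng(6)
    curves = {
        "place": (d, 0.3 * np.exp(-d / 2.55) + 0.02 + rng.normal(0, 0.005, d.size)),
        "nonplace": (d, 0.3 * np.exp(-d / 1.43) + 0.02 + rng.normal(0, 0.005, d.size)),
    }
    assert fit_correlation_decay(curves)["lr_p"] < 0.01


# ---------------------------------------------------------------------------
# sliding-window coactivation
# ---------------------------------------------------------------------------

def test_sliding_window_all_zero():
    hist = sliding_window_coactivation(np.zeros((15, 100)))
    assert hist[0] == hist.sum()


def test_sliding_window_counts_block():
    A = np.zeros((12, 50))
    A[3:6, 20] = 1.0   # ROIs 3-5 active in one bin
    hist = sliding_window_coactivation(A, window_rows=10)
    assert hist[3] > 0
    assert hist[4:].sum() == 0


def test_sliding_window_sees_planted_cluster():
    A = np.zeros((14, 200))
    acts = [20, 60, 120]
    A[4:10, acts] = 1.0   # 6-ROI synchronous cluster
    hist = sliding_window_coactivation(A, window_rows=10)
    assert hist[6] >= len(acts)


def test_sliding_window_short_branch_errors():
    with pytest.raises(ValueError):
        sliding_window_coactivation(np.zeros((10, 50)), window_rows=10)


# ---------------------------------------------------------------------------
# nonnegative projection
# ---------------------------------------------------------------------------

def test_clamp_example():
    np.testing.assert_array_equal(
        nearest_nonnegative([[1.0, -2.0], [3.0, 0.0]]),
        [[1.0, 0.0], [3.0, 0.0]])


def test_clamp_equals_qp_projection_on_random_matrices():
    """Element-wise max(0, .) minimizes the Frobenius distance over
    nonnegative matrices (QP oracle on 5x5)."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        W = rng.normal(0, 1, (5, 5))
        res = optimize.minimize(
            lambda x: np.sum((x.reshape(5, 5) - W) ** 2),
            x0=np.abs(W).ravel(),
            jac=lambda x: (2 * (x.reshape(5, 5) - W)).ravel(),
            bounds=[(0, None)] * 25, method="L-BFGS-B")
        np.testing.assert_allclose(res.x.reshape(5, 5),
                                   nearest_nonnegative(W), atol=1e-8)


# ---------------------------------------------------------------------------
# ICA cluster extraction
# ---------------------------------------------------------------------------

def _branch(rng, n_rois=20, n_bins=2500, members=(), rate=0.01,
            participation=0.85, indep_rate=0.005):
    A = np.zeros((n_rois, n_bins))
    for j in range(n_rois):
        t = np.flatnonzero(rng.random(n_bins) < indep_rate)
        A[j, t] = rng.lognormal(0, 0.5, t.size)
    acts = np.flatnonzero(rng.random(n_bins) < rate)
    for t in acts:
        for m in members:
            if rng.random() < participation:
                A[m, t] = rng.lognormal(0.3, 0.5)
    return A


def test_planted_five_roi_cluster_recovered():
    hits = 0
    n_seeds = 10
    planted = {3, 4, 5, 6, 7}
    for s in range(n_seeds):
        A = _branch(np.random.default_rng(100 + s), members=sorted(planted))
        clusters = extract_functional_clusters(A, seed=s)
        hits += any(set(c.member_index) == planted for c in clusters)
    assert hits >= 0.9 * n_seeds


def test_three_roi_group_is_not_a_cluster():
    rng = np.random.default_rng(8)
    A = _branch(rng, members=(5, 6, 7), rate=0.012)
    clusters = extract_functional_clusters(A, seed=0)
    assert not any(set(c.member_index) == {5, 6, 7} for c in clusters)
    assert not any({5, 6, 7} >= set(c.member_index) for c in clusters)


def test_extraction_scale_invariant():
    rng = np.random.default_rng(9)
    A = _branch(rng, members=(2, 3, 4, 5, 6))
    c1 = extract_functional_clusters(A, seed=3)
    c2 = extract_functional_clusters(A * 11.0, seed=3)
    assert [c.member_index for c in c1] == [c.member_index for c in c2]


def test_threshold_robustness_of_recovery():
    """Planted-cluster recovery persists when the 20%/70% thresholds move
    by +/- 5 points."""
    planted = {4, 5, 6, 7, 8}
    for wt, cf in [(0.15, 0.70), (0.25, 0.70), (0.20, 0.65), (0.20, 0.75)]:
        hits = 0
        for s in range(5):
            A = _branch(np.random.default_rng(300 + s), members=sorted(planted))
            clusters = extract_functional_clusters(
                A, seed=s, weight_threshold=wt, contributing_fraction=cf)
            hits += any(len(set(c.member_index) & planted) >= 4 for c in clusters)
        assert hits >= 4


def test_branch_with_too_few_active_rois_errors():
    A = np.zeros((8, 500))
    A[:, 10] = 1.0
    with pytest.raises(ValueError, match="active ROIs"):
        FunctionalClusterICA().fit(A)


def test_shuffle_control_preserves_rows_and_planted_significance():
    rng = np.random.default_rng(10)
    ests = []
    for s in range(3):
        A = _branch(np.random.default_rng(200 + s),
                    members=(3, 4, 5, 6, 7), rate=0.012)
        ests.append(FunctionalClusterICA(random_state=s).fit(A))
    ctrl = pooled_shuffle_control(ests, n_shuffles=1000, seed=11)
    assert ctrl["original_count"] > np.percentile(ctrl["null_counts"], 95)
    assert ctrl["p_empirical"] < 0.05


def test_shuffle_control_calibrated_on_independent_rois():
    ok = 0
    n_runs = 8
    for s in range(n_runs):
        A = _branch(np.random.default_rng(400 + s), members=(),
                    indep_rate=0.01)
        est = FunctionalClusterICA(random_state=s).fit(A)
        ctrl = cluster_shuffle_control(est, n_shuffles=300, seed=s)
        ok += (ctrl["original_count"] == 0) or (ctrl["p_empirical"] > 0.05)
    assert ok >= 0.9 * n_runs


# ---------------------------------------------------------------------------
# cluster activity
# ---------------------------------------------------------------------------

def _simple_cluster(members, weights=None):
    from dendroglu.clusters import FunctionalCluster

    w = np.asarray(weights if weights is not None else np.ones(len(members)),
                   dtype=float)
    return FunctionalCluster(branch_id="b0", member_index=list(members),
                             member_rois=[f"r{m}" for m in members],
                             weights=w, peak_normalized=w / w.max(),
                             component=0, n_components=2)


def test_single_member_activation_fraction():
    fps = 30.0
    sig = np.zeros((300, 10))
    sig[60:66, 2] = 0.5   # only member ROI 2 active
    clu = _simple_cluster([2, 3, 4, 5])
    act = cluster_activity(clu, sig, fps)
    assert act["activation_bins"].size > 0
    f = act["coactivation_fraction"][act["activation_bins"]]
    np.testing.assert_allclose(f, 0.25)
    assert act["pct_high_coactivation"] == 0.0


def test_all_members_active_is_full_coactivation():
    fps = 30.0
    sig = np.zeros((300, 10))
    sig[60:66, [2, 3, 4, 5]] = 0.5
    clu = _simple_cluster([2, 3, 4, 5])
    act = cluster_activity(clu, sig, fps)
    f = act["coactivation_fraction"][act["activation_bins"]]
    np.testing.assert_allclose(f, 1.0)
    assert act["pct_high_coactivation"] == pytest.approx(100.0)


def test_infield_synchronized_cluster_coactivation_profile():
    """A cluster synchronized only inside the somatic field shows higher
    in-field than out-of-field coactivation."""
    from dendroglu.clusters import coactivation_vs_field_distance

    rng = np.random.default_rng(12)
    fps, n_frames = 30.0, 30000
    pos = np.tile(np.linspace(0, 300, 1500, endpoint=False), 20)[:n_frames]
    sig = np.zeros((n_frames, 6))
    clu = _simple_cluster([0, 1, 2, 3])
    infield = np.abs(pos - 150.0) <= 30.0
    for t in np.flatnonzero((rng.random(n_frames) < 0.01) & infield):
        sig[t:t + 4, [0, 1, 2, 3]] = 0.5           # full coactivation in-field
    for t in np.flatnonzero((rng.random(n_frames) < 0.01) & ~infield):
        sig[t:t + 4, rng.integers(0, 4)] = 0.5     # lone activations outside
    act = cluster_activity(clu, sig, fps)
    pos_per_bin = pos[: sig.shape[0] // 3 * 3].reshape(-1, 3).mean(axis=1)
    prof = coactivation_vs_field_distance(act, pos_per_bin, 150.0, 60.0,
                                          n_bins=8)
    inb = np.abs(prof.centers) <= 0.5
    assert np.nanmean(prof.mean[inb]) > np.nanmean(prof.mean[~inb])


# ---------------------------------------------------------------------------
# nonanatomical components
# ---------------------------------------------------------------------------

def test_dispersed_singletons_reported():
    w = np.zeros(16)
    w[[1, 5, 9, 13]] = 1.0
    out = find_nonanatomical_clusters({2: w[:, None]})
    assert len(out) == 1
    assert [g for g in out[0]["groups"]] == [[1], [5], [9], [13]]


def test_single_block_not_reported():
    w = np.zeros(16)
    w[4:10] = 1.0
    assert find_nonanatomical_clusters({2: w[:, None]}) == []


def test_planted_dispersed_quartet_detected():
    hits = 0
    n_seeds = 10
    members = (1, 6, 11, 16)
    for s in range(n_seeds):
        A = _branch(np.random.default_rng(500 + s), n_rois=20,
                    members=members, rate=0.015, participation=0.95)
        est = FunctionalClusterICA(random_state=s).fit(A)
        found = find_nonanatomical_clusters(est.weights_by_k_)
        hits += any(set(sum(f["groups"], [])) >= set(members) for f in found)
    assert hits >= 0.8 * n_seeds
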