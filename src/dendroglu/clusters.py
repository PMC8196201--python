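"""Functional dendritic organization.

Four analyses on significant transient-only activity ordered along each
branch: (1) pairwise ROI correlations (spatial maps or 100-ms binned
traces) versus dendritic distance, (2) nested exponential-decay fits to
the correlation falloff with a likelihood-ratio comparison, (3)
sliding-window coactivation counts, and (4) ICA-based functional cluster
detection — the activity matrix is decomposed with FastICA (PCA
initialization), the mixing weights are projected to the Frobenius-nearest
nonnegative matrix (element-wise clamp at zero), and groups of >= 4
nearby high-weight ROIs (single-ROI gaps allowed, >= 70% of the span
contributing) form clusters, validated against a 1000-fold ROI-order
shuffle.  Because PCA/ICA is invariant to the row order, the shuffle
permutes the fitted weight matrices and re-runs only the spatial grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA

from .detection import bin_activity_matrix, find_runs

__all__ = [
    "CorrelationCurve",
    "FunctionalCluster",
    "pairwise_correlation_vs_distance",
    "fit_correlation_decay",
    "sliding_window_coactivation",
    "nearest_nonnegative",
    "FunctionalClusterICA",
    "extract_functional_clusters",
    "cluster_shuffle_control",
    "cluster_activity",
    "find_nonanatomical_clusters",
]


# ---------------------------------------------------------------------------
# correlation vs distance
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCurve:
    """Mean Pearson r per distance bin for one pair group."""

    distance_um: np.ndarray
    mean_r: np.ndarray
    se_r: np.ndarray
    count: np.ndarray
    group: str = ""
    overall_mean: float = float("nan")
    n_pairs: int = 0
    n_skipped: int = 0


def pairwise_correlation_vs_distance(
    signals: np.ndarray,
    positions_um: np.ndarray,
    branch_ids: np.ndarray | None = None,
    group: str = "",
    min_distance_um: float = 1.0,
    bin_edges: np.ndarray | None = None,
    inter_dendrite: bool = False,
    positions_xy: np.ndarray | None = None,
) -> CorrelationCurve:
    """Pearson r between all qualifying ROI pairs versus distance.

    ``signals``: ROIs x features (a mean dF/F map per ROI for spatial
    mode, a significant-only binned trace for temporal mode); silent ROIs
    should already be excluded.  Intra-dendrite pairs must lie on one
    branch strictly more than ``min_distance_um`` apart; inter-dendrite
    mode pairs ROIs across different branches at Euclidean distance
    (``positions_xy``).  Constant signals cannot be correlated — those
    pairs are skipped and counted.
    """
    S = np.asarray(signals, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 active ROIs")
    if bin_edges is None:
        bin_edges = np.arange(1.5, 30.5 + 1e-9, 1.0)  # 1-um bins, 2..30 um
    sd = S.std(axis=1)
    center = S - S.mean(axis=1, keepdims=True)

    dists, rs = [], []
    n_skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if inter_dendrite:
                if branch_ids is None or branch_ids[i] == branch_ids[j]:
                    continue
                d = float(np.linalg.norm(positions_xy[i] - positions_xy[j]))
            else:
                if branch_ids is not None and branch_ids[i] != branch_ids[j]:
                    continue
                d = abs(float(positions_um[i] - positions_um[j]))
            if d <= min_distance_um:
                continue
            if sd[i] == 0 or sd[j] == 0:
                n_skipped += 1
                continue
            r = float(center[i] @ center[j] / (S.shape[1] * sd[i] * sd[j]))
            dists.append(d)
            rs.append(r)
    dists = np.asarray(dists)
    rs = np.asarray(rs)
    nb = bin_edges.size - 1
    mean_r = np.full(nb, np.nan)
    se_r = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    idx = np.digitize(dists, bin_edges) - 1
    for b in range(nb):
        v = rs[idx == b]
        count[b] = v.size
        if v.size:
            mean_r[b] = v.mean()
            se_r[b] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return CorrelationCurve(
        distance_um=0.5 * (bin_edges[:-1] + bin_edges[1:]),
        mean_r=mean_r, se_r=se_r, count=count, group=group,
        overall_mean=float(rs.mean()) if rs.size else float("nan"),
        n_pairs=int(rs.size), n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# exponential-decay fits with LR test
# ---------------------------------------------------------------------------

def _exp_model(d, A, tau, c):
    return A * np.exp(-d / tau) + c


def _fit_exp(d, y, tau0_list=(1.0, 3.0, 10.0)):
    best = None
    for tau0 in tau0_list:
        A0 = max(y[0] - y[-1], 1e-3)
        try:
            popt, _ = optimize.curve_fit(
                _exp_model, d, y, p0=[A0, tau0, y[-1]],
                bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e3, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _exp_model(d, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("exponential fit failed from all starts")
    return best


def fit_correlation_decay(curves: dict[str, tuple[np.ndarray, np.ndarray]]):
    """Per-group exponential fits A exp(-d/tau) + c, a nested fit sharing
    tau across groups, and a likelihood-ratio test (stationary Gaussian
    noise, chi-square with #groups - 1 df).

    ``curves`` maps group name -> (distance_um, mean_r).  Groups whose
    amplitude is indistinguishable from flat (A ~ 0, tau unidentifiable)
    are flagged and excluded from the LR comparison.
    """
    fits = {}
    usable = {}
    for g, (d, y) in curves.items():
        d = np.asarray(d, float)
        y = np.asarray(y, float)
        ok = np.isfinite(y)
        d, y = d[ok], y[ok]
        if d.size < 5:
            raise ValueError(f"group {g}: need >= 5 distance bins")
        (A, tau, c), rss = _fit_exp(d, y)
        spread = float(y.max() - y.min())
        flat = abs(A) < 0.05 * max(spread, 1e-12) or spread == 0.0
        fits[g] = {"A": float(A), "tau": float(tau), "c": float(c),
                   "rss": rss, "n": int(d.size), "flat": bool(flat)}
        if not flat:
            usable[g] = (d, y)

    result = {"fits": fits, "lr_stat": float("nan"), "lr_p": float("nan"),
              "shared_tau": float("nan"), "groups_compared": sorted(usable)}
    if len(usable) < 2:
        return result

    names = sorted(usable)
    ds = [usable[g][0] for g in names]
    ys = [usable[g][1] for g in names]

    def nested_rss(log_tau):
        tau = float(np.exp(log_tau))
        total = 0.0
        per_group = []
        for d, y in zip(ds, ys):
            X = np.column_stack([np.exp(-d / tau), np.ones_like(d)])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = float(np.sum((y - X @ beta) ** 2))
            total += r
            per_group.append(r)
        return total, per_group

    taus = np.log(np.clip([fits[g]["tau"] for g in names], 1e-2, 1e2))
    opt = optimize.minimize_scalar(
        lambda lt: nested_rss(lt)[0],
        bounds=(min(taus.min(), np.log(0.1)) - 2, max(taus.max(), np.log(30)) + 2),
        method="bounded",
    )
    shared_tau = float(np.exp(opt.x))
    _, nested_per_group = nested_rss(opt.x)

    # stationary Gaussian noise = one shared sigma across groups; profiling
    # it gives LR = N ln(RSS_nested/RSS_full).  The (N - p_full)/N Bartlett
    # factor keeps the chi-square reference honest at these bin counts.
    N = sum(d.size for d in ds)
    p_full = 3 * len(names)
    rss_full = sum(fits[g]["rss"] for g in names)
    rss_nested = sum(nested_per_group)
    lr = max((N - p_full) * np.log(rss_nested / rss_full), 0.0)
    df = len(names) - 1
    result.update(
        lr_stat=float(lr),
        lr_p=float(stats.chi2.sf(lr, df)),
        shared_tau=shared_tau,
        df=df,
    )
    return result


# ---------------------------------------------------------------------------
# sliding-window coactivation
# ---------------------------------------------------------------------------

def sliding_window_coactivation(
    activity: np.ndarray,
    window_rows: int = 10,
    roi_mask: np.ndarray | None = None,
    time_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Histogram of co-active (nonzero) ROI counts in a
    ``window_rows`` x 1-bin window over all positions of the ROI x
    time-bin activity matrix.

    ``roi_mask`` restricts to windows containing at least one ROI of the
    type of interest; ``time_mask`` restricts the time bins (e.g. in- vs
    out-of-somatic-field).  Branches with <= ``window_rows`` ROIs are a
    caller-side skip.
    """
    A = np.asarray(activity)
    n_rois, n_bins = A.shape
    if n_rois <= window_rows:
        raise ValueError(
            f"branch has {n_rois} ROIs; needs more than {window_rows}"
        )
    active = (A > 0).astype(np.int32)
    # column-wise rolling sum over window_rows rows
    cs = np.cumsum(np.vstack([np.zeros((1, n_bins), np.int32), active]), axis=0)
    counts = cs[window_rows:] - cs[:-window_rows]   # (n_rois-window+1) x n_bins
    keep = np.ones_like(counts, dtype=bool)
    if roi_mask is not None:
        m = np.asarray(roi_mask, dtype=np.int32)
        mc = np.cumsum(np.concatenate(([0], m)))
        present = (mc[window_rows:] - mc[:-window_rows]) > 0
        keep &= present[:, None]
    if time_mask is not None:
        keep &= np.asarray(time_mask, dtype=bool)[None, :]
    vals = counts[keep]
    return np.bincount(vals, minlength=window_rows + 1)


# ---------------------------------------------------------------------------
# nonnegative ICA clusters
# ---------------------------------------------------------------------------

def nearest_nonnegative(W: np.ndarray) -> np.ndarray:
    """Frobenius-nearest nonnegative matrix: element-wise max(0, .)."""
    return np.maximum(np.asarray(W, dtype=float), 0.0)


@dataclass
class FunctionalCluster:
    """A group of >= 4 nearby ROIs dominating one nonnegative IC."""

    branch_id: object
    member_index: list                 # row indices on the branch
    member_rois: list
    weights: np.ndarray                # component weights of the members
    peak_normalized: np.ndarray
    component: int
    n_components: int
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_index)

    @property
    def span(self) -> int:
        return self.member_index[-1] - self.member_index[0] + 1


def _contributing_groups(norm_w: np.ndarray, weight_threshold: float):
    """Split contributing ROIs (> threshold of peak) into groups allowing
    single-ROI gaps."""
    contrib = np.flatnonzero(norm_w > weight_threshold)
    groups = []
    for k in contrib:
        if groups and k - groups[-1][-1] <= 2:
            groups[-1].append(int(k))
        else:
            groups.append([int(k)])
    return groups


def _groups_to_clusters(norm_w, weight_threshold, min_size, contributing_fraction):
    """Apply the >=4-member / <=1-gap / >=70%-of-span-contributing rules."""
    out = []
    for g in _contributing_groups(norm_w, weight_threshold):
        if len(g) < min_size:
            continue
        span = g[-1] - g[0] + 1
        if len(g) / span < contributing_fraction:
            continue
        out.append(g)
    return out


class FunctionalClusterICA(BaseEstimator):
    """ICA-based functional cluster extraction on one branch.

    Fits FastICA with PCA initialization for component counts
    k = 2 .. n_active/2, scanned while the detected-cluster count is
    nondecreasing; each component's mixing weights are sign-aligned
    (largest-magnitude weight positive), projected to the nearest
    nonnegative matrix, peak-normalized, and grouped spatially.
    Duplicate member sets across k keep the smallest-k weights.

    Fitted attributes: ``clusters_`` (list of
    :class:`FunctionalCluster`), ``weights_by_k_`` (dict k -> ROI x k
    nonnegative weight matrix), ``k_used_``.
    """

    def __init__(
        self,
        weight_threshold: float = 0.20,
        contributing_fraction: float = 0.70,
        min_cluster_size: int = 4,
        min_active_rois: int = 9,
        random_state: int = 0,
        max_iter: int = 500,
        stop_on_decrease: bool = True,
    ):
        self.weight_threshold = weight_threshold
        self.contributing_fraction = contributing_fraction
        self.min_cluster_size = min_cluster_size
        self.min_active_rois = min_active_rois
        self.random_state = random_state
        self.max_iter = max_iter
        self.stop_on_decrease = stop_on_decrease

    def _ica_weights(self, A: np.ndarray, k: int, seed: int) -> np.ndarray:
        """ROI x k nonnegative, sign-aligned, peak-normalized weights."""
        rng = np.random.default_rng(seed)
        ica = FastICA(
            n_components=k,
            whiten="unit-variance",
            w_init=np.eye(k),          # identity on whitened PCs = PCA initial guess
            max_iter=self.max_iter,
            tol=1e-4,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(A.T)               # samples = time bins, features = ROIs
        W = ica.mixing_                # ROIs x k
        flip = np.sign(W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])])
        flip[flip == 0] = 1.0
        W = nearest_nonnegative(W * flip[None, :])
        peaks = W.max(axis=0)
        peaks[peaks == 0] = 1.0
        return W / peaks[None, :]

    def fit(self, A: np.ndarray, y=None, branch_id=None, roi_ids=None,
            active_rois: np.ndarray | None = None):
        """A: ROI x time-bin activity matrix in branch order."""
        A = np.asarray(A, dtype=float)
        n_rois = A.shape[0]
        if active_rois is None:
            active_rois = (A > 0).any(axis=1)
        n_active = int(np.asarray(active_rois).sum())
        if n_active <= self.min_active_rois - 1:
            raise ValueError(
                f"branch has {n_active} active ROIs; needs > {self.min_active_rois - 1}"
            )
        roi_ids = list(roi_ids) if roi_ids is not None else list(range(n_rois))
        k_max = max(n_active // 2, 2)

        self.weights_by_k_ = {}
        groups_by_k = {}
        prev_count = -1
        for k in range(2, k_max + 1):
            seed = (self.random_state * 100003 + k) % (2**31)
            try:
                W = self._ica_weights(A, k, seed)
            except Exception:      # ICA failure at this k: skip, keep scanning
                continue
            self.weights_by_k_[k] = W
            groups = []
            for comp in range(k):
                for g in _groups_to_clusters(
                    W[:, comp], self.weight_threshold,
                    self.min_cluster_size, self.contributing_fraction,
                ):
                    groups.append((comp, g))
            groups_by_k[k] = groups
            if self.stop_on_decrease and len(groups) < prev_count:
                del groups_by_k[k]
                break
            prev_count = len(groups)

        clusters = []
        seen = set()
        for k in sorted(groups_by_k):
            for comp, g in groups_by_k[k]:
                key = tuple(g)
                if key in seen:
                    continue
                seen.add(key)
                W = self.weights_by_k_[k]
                clusters.append(FunctionalCluster(
                    branch_id=branch_id,
                    member_index=list(g),
                    member_rois=[roi_ids[i] for i in g],
                    weights=W[g, comp].copy(),
                    peak_normalized=W[g, comp] / max(W[g, comp].max(), 1e-12),
                    component=comp,
                    n_components=k,
                ))
        self.clusters_ = clusters
        self.k_used_ = sorted(groups_by_k)
        self.n_active_ = n_active
        return self

    def count_clusters_for_order(self, order: np.ndarray) -> tuple[int, int]:
        """Cluster count and #ROIs in clusters after permuting the branch
        (row) order — PCA/ICA weights are row-permutation invariant, so
        only the spatial grouping and the k-scan are re-run."""
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        prev = -1
        seen = set()
        roi_in = set()
        for k in sorted(self.weights_by_k_):
            W = self.weights_by_k_[k][order]
            groups = []
            for comp in range(k):
                groups.extend(_groups_to_clusters(
                    W[:, comp], self.weight_threshold,
                    self.min_cluster_size, self.contributing_fraction,
                ))
            if self.stop_on_decrease and len(groups) < prev:
                break
            prev = len(groups)
            for g in groups:
                key = tuple(g)
                if key not in seen:
                    seen.add(key)
                    roi_in.update(g)
        return len(seen), len(roi_in)


def extract_functional_clusters(
    activity: np.ndarray,
    seed: int = 0,
    branch_id=None,
    roi_ids=None,
    **kwargs,
) -> list[FunctionalCluster]:
    """Functional wrapper over :class:`FunctionalClusterICA`."""
    est = FunctionalClusterICA(random_state=seed, **kwargs)
    est.fit(activity, branch_id=branch_id, roi_ids=roi_ids)
    return est.clusters_


def cluster_shuffle_control(
    est: FunctionalClusterICA,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """ROI-order shuffle null for the cluster count.

    Returns the null count distribution, the empirical p-value of the
    original count, and a likelihood-ratio chi-square on the fraction of
    ROIs in clusters (original vs pooled shuffles).
    """
    rng = np.random.default_rng(seed)
    if not est.weights_by_k_:   # ICA failed at every k: nothing to control
        return {"null_counts": np.zeros(n_shuffles, dtype=int),
                "null_roi_counts": np.zeros(n_shuffles, dtype=int),
                "original_count": 0, "original_rois_in_clusters": 0,
                "p_empirical": 1.0, "chi2": float("nan"),
                "lr_p": float("nan"), "exceeds_all_shuffles": False}
    n_rois = next(iter(est.weights_by_k_.values())).shape[0]
    null_counts = np.zeros(n_shuffles, dtype=int)
    null_rois = np.zeros(n_shuffles, dtype=int)
    for s in range(n_shuffles):
        order = rng.permutation(n_rois)
        null_counts[s], null_rois[s] = est.count_clusters_for_order(order)
    orig_count = len(est.clusters_)
    orig_rois = len({i for c in est.clusters_ for i in c.member_index})
    p_emp = float((null_counts >= orig_count).mean())

    # LR chi-square on P(ROI in a cluster), original vs shuffle-pooled
    k1, n1 = orig_rois, n_rois
    k0, n0 = int(null_rois.sum()), n_rois * n_shuffles
    chi2 = lr_p = float("nan")
    if n0 > 0:
        def _ll(k, n, p):
            p = min(max(p, 1e-12), 1 - 1e-12)
            return k * np.log(p) + (n - k) * np.log(1 - p)
        p_pool = (k0 + k1) / (n0 + n1)
        ll_alt = _ll(k1, n1, k1 / n1 if n1 else 0) + _ll(k0, n0, k0 / n0)
        ll_null = _ll(k1, n1, p_pool) + _ll(k0, n0, p_pool)
        chi2 = float(2 * (ll_alt - ll_null))
        lr_p = float(stats.chi2.sf(chi2, 1))
    return {
        "null_counts": null_counts,
        "null_roi_counts": null_rois,
        "original_count": orig_count,
        "original_rois_in_clusters": orig_rois,
        "p_empirical": p_emp,
        "chi2": chi2,
        "lr_p": lr_p,
        "exceeds_all_shuffles": bool(orig_count > null_counts.max())
        if n_shuffles else False,
    }


def pooled_shuffle_control(
    estimators: list[FunctionalClusterICA],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Shuffle control pooled across branches: per shuffle the cluster
    counts of all branches (each under its own ROI-order permutation) are
    summed, and the pooled original count is compared with the null."""
    rng = np.random.default_rng(seed)
    null_total = np.zeros(n_shuffles, dtype=int)
    null_rois = np.zeros(n_shuffles, dtype=int)
    orig_total = 0
    orig_rois = 0
    n_total_rois = 0
    for est in estimators:
        n_rois = next(iter(est.weights_by_k_.values())).shape[0]
        n_total_rois += n_rois
        orig_total += len(est.clusters_)
        orig_rois += len({i for c in est.clusters_ for i in c.member_index})
        for s in range(n_shuffles):
            c, r = est.count_clusters_for_order(rng.permutation(n_rois))
            null_total[s] += c
            null_rois[s] += r
    return {
        "null_counts": null_total,
        "null_roi_counts": null_rois,
        "original_count": orig_total,
        "original_rois_in_clusters": orig_rois,
        "n_rois": n_total_rois,
        "p_empirical": float((null_total >= orig_total).mean()),
        "exceeds_all_shuffles": bool(orig_total > null_total.max()),
    }


def cluster_activity(
    cluster: FunctionalCluster,
    sig: np.ndarray,
    frame_rate: float,
    bin_s: float = 0.1,
    coactivation_threshold: float = 0.70,
) -> dict:
    """Cluster trace (weight-summed member significant-only traces),
    activation bins (trace > 0), and per-activation member-coactivation
    fractions.

    ``sig``: frames x branch-ROIs in branch order; the cluster's
    ``member_index`` indexes its columns.
    """
    members = cluster.member_index
    w = cluster.weights
    trace = sig[:, members] @ w
    binned = bin_activity_matrix(trace[:, None], frame_rate, bin_s)[0]
    member_binned = bin_activity_matrix(sig[:, members], frame_rate, bin_s)
    activation = binned > 0
    frac = np.zeros(binned.size)
    if activation.any():
        frac[activation] = (member_binned[:, activation] > 0).mean(axis=0)
    high = activation & (frac > coactivation_threshold)
    return {
        "trace": trace,
        "binned_trace": binned,
        "activation_bins": np.flatnonzero(activation),
        "coactivation_fraction": frac,
        "high_coactivation_bins": np.flatnonzero(high),
        "pct_high_coactivation": float(100.0 * high.sum() / max(activation.sum(), 1)),
    }


def coactivation_vs_field_distance(
    activity_result: dict,
    position_per_bin: np.ndarray,
    soma_peak_cm: float,
    soma_width_cm: float,
    n_bins: int = 10,
    coactivation_threshold: float = 0.70,
) -> "al.AlignedProfile":
    """Percentage of cluster-activation time with > 70% member
    coactivation, binned by the animal's distance from the somatic field
    peak in field-width units (adaptive equal-count bins).

    ``position_per_bin``: track position (cm) of each 100-ms bin of the
    activity matrix (e.g. the per-bin mean of ``behavior.position``).
    """
    from . import alignment as al

    act = activity_result["binned_trace"] > 0
    if not act.any():
        raise ValueError("cluster never activates")
    frac = activity_result["coactivation_fraction"]
    u = (np.asarray(position_per_bin)[: act.size] - soma_peak_cm) / soma_width_cm
    u_act = u[act]
    high = (frac[act] > coactivation_threshold).astype(float) * 100.0
    edges = al.adaptive_bins(u_act, n_bins)
    return al._bin_profile(u_act, high, edges)


def find_nonanatomical_clusters(
    weights_by_k: dict[int, np.ndarray],
    weight_threshold: float = 0.20,
    min_isolated_groups: int = 4,
) -> list[dict]:
    """Spatially disperse, temporally clustered components: components
    whose contributing ROIs form >= 4 isolated groups of 1-3 ROIs
    (single-ROI gaps allowed within a group, >= 2 ROIs between groups)."""
    out = []
    for k, W in weights_by_k.items():
        for comp in range(W.shape[1]):
            groups = _contributing_groups(W[:, comp], weight_threshold)
            isolated = [g for g in groups if 1 <= len(g) <= 3]
            if len(groups) == len(isolated) and len(isolated) >= min_isolated_groups:
                out.append({
                    "n_components": k,
                    "component": comp,
                    "groups": isolated,
                })
    return out
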