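"""Significant-transient detection from raw fluorescence.

Pipeline: background-subtracted raw counts -> sliding-percentile dF/F ->
QC exclusions (dim ROIs, branch-end ROIs, out-of-plane frames) -> run-period
restriction -> noise-model fitting -> significance by the ratio of
positive- to negative-going transients of various amplitude/duration
classes (accepted classes have a false-positive ratio < 1%) -> the 0.40
dF/F amplitude gate -> significant transient-only traces (dF/F inside
significant transients, zero elsewhere).

The noise sd of each dF/F trace is estimated from the positive-going
deviations about the trace mean (keeping the original mean in the
calculation), which avoids the floor-effect underestimate that taking the
full two-sided std of a baseline-corrected trace would give.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .session import AnalysisConfig, BehaviorSession, RoiTraceSet

__all__ = [
    "DffTrace",
    "ExclusionReport",
    "TransientDetector",
    "compute_dff",
    "run_period_mask",
    "exclude_rois_and_frames",
    "fit_detection_model",
    "detect_significant_transients",
    "event_spatial_extent",
    "input_rate_summary",
    "find_runs",
]


def find_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and (exclusive) ends of contiguous True runs."""
    m = np.asarray(mask, dtype=bool)
    d = np.diff(np.concatenate(([False], m, [False])).astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


# ---------------------------------------------------------------------------
# dF/F and masks
# ---------------------------------------------------------------------------

@dataclass
class DffTrace:
    """dF/F matrix with the baseline used and validity bookkeeping.

    Excluded frames are marked, never dropped, so the time base is
    preserved everywhere downstream.
    """

    dff: np.ndarray                    # frames x ROIs
    baseline: np.ndarray               # F0, frames x ROIs
    frame_rate: float
    roi_ids: list
    f0_invalid: np.ndarray             # per ROI: baseline <= 0 somewhere

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def n_rois(self) -> int:
        return self.dff.shape[1]


def compute_dff(
    traces: RoiTraceSet | np.ndarray,
    window_s: float = 1.5,
    percentile: float = 8.0,
    frame_rate: float | None = None,
) -> DffTrace:
    """Sliding-percentile dF/F: F0 is the given percentile of F in a
    centered +/-``window_s`` window (truncated at trace edges, no padding).

    dF/F(t) = (F(t) - F0(t)) / F0(t).  ROIs where F0 <= 0 anywhere are
    flagged via ``f0_invalid`` and must be excluded downstream.  The
    background trace is expected to already be subtracted (see
    :meth:`RoiTraceSet.subtract_background`).
    """
    if isinstance(traces, RoiTraceSet):
        raw = traces.traces
        fps = traces.frame_rate
        roi_ids = list(traces.roi_table["roi_id"])
    else:
        raw = np.asarray(traces, dtype=float)
        if raw.ndim == 1:
            raw = raw[:, None]
        if frame_rate is None:
            raise ValueError("frame_rate required when passing a bare array")
        fps = frame_rate
        roi_ids = list(range(raw.shape[1]))

    half = int(round(window_s * fps))
    window = 2 * half + 1
    f0 = (
        pd.DataFrame(raw)
        .rolling(window=window, center=True, min_periods=1)
        .quantile(percentile / 100.0)
        .to_numpy()
    )
    f0_invalid = (f0 <= 0).any(axis=0)
    safe = np.where(f0 > 0, f0, 1.0)
    dff = (raw - f0) / safe
    return DffTrace(dff=dff, baseline=f0, frame_rate=fps, roi_ids=roi_ids,
                    f0_invalid=f0_invalid)


def run_period_mask(
    behavior: BehaviorSession,
    velocity_threshold: float = 4.0,
    min_distance: float = 40.0,
) -> np.ndarray:
    """True exactly on frames of qualifying run periods: velocity above
    ``velocity_threshold`` cm/s over a stretch covering more than
    ``min_distance`` cm of track."""
    fast = behavior.velocity > velocity_threshold
    dt = np.gradient(behavior.time)
    mask = np.zeros(behavior.n_frames, dtype=bool)
    for s, e in zip(*find_runs(fast)):
        distance = float(np.sum(behavior.velocity[s:e] * dt[s:e]))
        if distance > min_distance:
            mask[s:e] = True
    return mask


@dataclass
class ExclusionReport:
    """QC exclusions: which ROIs and frames are dropped from statistics."""

    roi_excluded: np.ndarray           # bool per ROI
    roi_reason: dict = field(default_factory=dict)
    frame_excluded: np.ndarray = None  # bool per frame

    def valid_rois(self) -> np.ndarray:
        return ~self.roi_excluded


def exclude_rois_and_frames(
    traces: RoiTraceSet,
    dff: DffTrace | None = None,
    dim_threshold: float = 1.5,
    pos_std: float = 2.0,
    neg_std: float = 1.0,
    exclude_branch_ends: bool = True,
    detrend_window_frames: int = 600,
) -> ExclusionReport:
    """Apply the three QC rules on background-subtracted raw counts.

    (1) branch-end ROIs (most prone to out-of-plane movement) are
    excluded; (2) ROIs with mean fluorescence below ``dim_threshold``
    counts are too dim for an accurate dF/F; (3) frames where the
    field-mean fluorescence deviates more than ``pos_std`` STD positively
    or ``neg_std`` STD negatively from its mean are excluded (large
    out-of-plane movements across many ROIs).
    """
    raw = traces.traces
    n_rois = traces.n_rois
    roi_excluded = np.zeros(n_rois, dtype=bool)
    reasons: dict = {}

    mean_counts = raw.mean(axis=0)
    dim = mean_counts < dim_threshold
    roi_excluded |= dim
    for j in np.flatnonzero(dim):
        reasons[traces.roi_table.at[j, "roi_id"]] = "dim (<%.1f counts)" % dim_threshold

    if exclude_branch_ends:
        for _, grp in traces.roi_table[traces.roi_table["channel"] != "soma"].groupby(
            "branch_id"
        ):
            if len(grp) < 3:
                continue
            order = grp["position_um"].to_numpy(dtype=float).argsort()
            ends = [grp.index[order[0]], grp.index[order[-1]]]
            for j in ends:
                roi_excluded[j] = True
                reasons.setdefault(traces.roi_table.at[j, "roi_id"], "branch end")

    if dff is not None:
        roi_excluded |= dff.f0_invalid
        for j in np.flatnonzero(dff.f0_invalid):
            reasons.setdefault(traces.roi_table.at[j, "roi_id"], "nonpositive baseline")

    # The frame rule targets fast out-of-plane movements; a slow bleaching
    # trend would otherwise dominate the STD and flag ordinary late frames,
    # so the field mean is detrended with a wide rolling median first.
    field_mean = raw.mean(axis=1)
    if detrend_window_frames and field_mean.size > detrend_window_frames:
        trend = (
            pd.Series(field_mean)
            .rolling(detrend_window_frames, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        resid = field_mean - trend
    else:
        resid = field_mean - field_mean.mean()
    mu, sd = resid.mean(), resid.std()
    frame_excluded = (resid > mu + pos_std * sd) | (resid < mu - neg_std * sd)
    return ExclusionReport(roi_excluded=roi_excluded, roi_reason=reasons,
                           frame_excluded=frame_excluded)


# ---------------------------------------------------------------------------
# the positive/negative transient-ratio detector
# ---------------------------------------------------------------------------

def _candidate_events(z: np.ndarray, valid: np.ndarray, onset_min: float,
                      offset_sigma: float) -> list[tuple[int, int, float]]:
    """Excursions above ``offset_sigma`` (in sigma units, within valid
    frames) that reach at least ``onset_min`` sigma; returns
    (start, end_exclusive, peak_sigma) triples.  Invalid frames terminate
    excursions, so no event ever overlaps an excluded frame."""
    above = (z > offset_sigma) & valid
    out = []
    for s, e in zip(*find_runs(above)):
        peak = float(z[s:e].max())
        if peak >= onset_min:
            out.append((int(s), int(e), peak))
    return out


class TransientDetector(BaseEstimator, TransformerMixin):
    """Significant dF/F transient detector (positive/negative event-ratio
    criterion plus amplitude gate).

    ``fit`` estimates a per-ROI noise sigma and tabulates candidate
    positive- and negative-going events on an (amplitude-class x
    duration-class) grid, pooled over ROIs; classes whose
    negative/positive count ratio is below ``fp_ratio_max`` are accepted
    (events in them have a < 1% chance of arising from noise).
    ``transform`` zeroes the trace outside significant transients.

    Parameters
    ----------
    onset_sigma_grid : sequence of float
        Lower edges of the amplitude classes in noise-sigma units; events
        must reach the smallest to count as candidates.
    offset_sigma : float
        Excursion termination threshold (re-crossing), sigma units.
    fp_ratio_max : float
        Maximum accepted negative/positive event-count ratio per class.
    amplitude_gate : float
        Minimum peak dF/F of a significant transient (inclusive).
    max_duration_s : float
        Durations pooled above this in the class grid.
    min_fit_frames : int
        Minimum valid frames per ROI required to estimate sigma.
    """

    def __init__(
        self,
        onset_sigma_grid=(2.0, 2.5, 3.0, 3.5, 4.0, 4.5),
        offset_sigma: float = 0.5,
        fp_ratio_max: float = 0.01,
        amplitude_gate: float = 0.40,
        max_duration_s: float = 1.0,
        min_fit_frames: int = 1000,
    ):
        self.onset_sigma_grid = onset_sigma_grid
        self.offset_sigma = offset_sigma
        self.fp_ratio_max = fp_ratio_max
        self.amplitude_gate = amplitude_gate
        self.max_duration_s = max_duration_s
        self.min_fit_frames = min_fit_frames

    # -- internals ---------------------------------------------------------

    @staticmethod
    def noise_sigma(x: np.ndarray) -> float:
        """Noise sd from positive-going deviations about the mean."""
        m = float(np.mean(x))
        dev = x[x > m] - m
        if dev.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(dev**2)))

    def _amp_class(self, peaks_sigma: np.ndarray) -> np.ndarray:
        grid = np.asarray(self.onset_sigma_grid, dtype=float)
        return np.clip(np.searchsorted(grid, peaks_sigma, side="right") - 1,
                       0, grid.size - 1)

    def _dur_class(self, n_frames_event: np.ndarray) -> np.ndarray:
        return np.clip(n_frames_event, 1, self._max_dur_frames_ + 1) - 1

    def _scan(self, x, sigma, valid, polarity):
        """Candidate events of one polarity; returns arrays of
        (start, end, peak_sigma, peak_dff, n_frames)."""
        m = float(np.mean(x[valid])) if valid.any() else 0.0
        z = (x - m) / sigma * polarity
        evs = _candidate_events(z, valid, min(self.onset_sigma_grid),
                                self.offset_sigma)
        if not evs:
            return (np.empty(0, int),) * 2 + (np.empty(0),) * 2 + (np.empty(0, int),)
        s, e, pk = map(np.asarray, zip(*evs))
        peak_dff = np.array([x[a:b].max() if polarity > 0 else x[a:b].min()
                             for a, b in zip(s, e)])
        return s, e, pk, peak_dff, (e - s)

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y=None, frame_rate: float = 30.0, valid: np.ndarray | None = None):
        """Fit the noise model and the accepted-class grid.

        X : dF/F matrix (frames x ROIs); ``valid`` marks frames usable for
        statistics (run periods minus excluded frames), default all.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, n_rois = X.shape
        if valid is None:
            valid = np.ones(n, dtype=bool)
        if valid.sum() < self.min_fit_frames:
            raise ValueError(
                f"only {int(valid.sum())} valid frames; "
                f"need >= {self.min_fit_frames} to fit the noise model"
            )
        self.frame_rate_ = float(frame_rate)
        self._max_dur_frames_ = max(int(round(self.max_duration_s * frame_rate)), 1)
        grid = np.asarray(self.onset_sigma_grid, dtype=float)
        n_amp, n_dur = grid.size, self._max_dur_frames_ + 1

        self.sigma_ = np.array([self.noise_sigma(X[valid, j]) for j in range(n_rois)])
        pos = np.zeros((n_amp, n_dur), dtype=np.int64)
        neg = np.zeros((n_amp, n_dur), dtype=np.int64)
        for j in range(n_rois):
            if self.sigma_[j] <= 0:
                continue
            for polarity, grid_counts in ((1, pos), (-1, neg)):
                s, e, pk, _, nf = self._scan(X[:, j], self.sigma_[j], valid, polarity)
                if s.size:
                    np.add.at(grid_counts,
                              (self._amp_class(pk), self._dur_class(nf)), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pos > 0, neg / np.maximum(pos, 1), np.inf)
        self.positive_counts_ = pos
        self.negative_counts_ = neg
        self.fp_ratio_ = ratio
        self.accepted_ = (pos > 0) & (ratio < self.fp_ratio_max)
        self.valid_ = valid
        return self

    def detect(self, X, valid: np.ndarray | None = None) -> tuple[pd.DataFrame, np.ndarray]:
        """All positive candidate events plus the significant-only trace.

        An event is significant iff its (amplitude, duration) class is
        accepted and its peak dF/F is at or above the amplitude gate (a
        peak of exactly the gate is kept).
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "accepted_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, n_rois = X.shape
        if valid is None:
            valid = self.valid_ if self.valid_.shape[0] == n else np.ones(n, bool)
        sig = np.zeros_like(X)
        rows = []
        for j in range(n_rois):
            if self.sigma_[j] <= 0:
                continue
            s, e, pk, peak_dff, nf = self._scan(X[:, j], self.sigma_[j], valid, 1)
            if not s.size:
                continue
            ok_class = self.accepted_[self._amp_class(pk), self._dur_class(nf)]
            significant = ok_class & (peak_dff >= self.amplitude_gate)
            for i in range(s.size):
                rows.append((j, int(s[i]), int(e[i]),
                             float(nf[i] / self.frame_rate_),
                             float(peak_dff[i]), float(pk[i]),
                             bool(significant[i])))
                if significant[i]:
                    sig[s[i]:e[i], j] = X[s[i]:e[i], j]
        events = pd.DataFrame(
            rows, columns=["roi", "onset_frame", "offset_frame", "duration_s",
                           "peak_dff", "peak_sigma", "significant"],
        )
        return events, sig

    def transform(self, X, valid: np.ndarray | None = None) -> np.ndarray:
        """Significant transient-only traces (dF/F inside significant
        events, zero elsewhere)."""
        return self.detect(X, valid=valid)[1]


def fit_detection_model(
    dff: DffTrace | np.ndarray,
    valid: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
    frame_rate: float | None = None,
) -> TransientDetector:
    """Thin functional wrapper over :class:`TransientDetector`."""
    cfg = config or AnalysisConfig()
    X = dff.dff if isinstance(dff, DffTrace) else np.asarray(dff)
    fps = dff.frame_rate if isinstance(dff, DffTrace) else frame_rate
    det = TransientDetector(
        onset_sigma_grid=tuple(cfg.onset_sigma_grid),
        offset_sigma=cfg.offset_sigma,
        fp_ratio_max=cfg.fp_ratio_max,
        amplitude_gate=cfg.amplitude_gate,
        max_duration_s=cfg.max_duration_s,
    )
    return det.fit(X, frame_rate=fps, valid=valid)


def detect_significant_transients(
    dff: DffTrace | np.ndarray,
    model: TransientDetector,
    amplitude_gate: float | None = None,
    valid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Events table plus significant transient-only trace matrix."""
    if amplitude_gate is not None:
        model.amplitude_gate = amplitude_gate
    X = dff.dff if isinstance(dff, DffTrace) else np.asarray(dff)
    return model.detect(X, valid=valid)


# ---------------------------------------------------------------------------
# event spatial extent and input rate
# ---------------------------------------------------------------------------

def bin_activity_matrix(sig: np.ndarray, frame_rate: float, bin_s: float = 0.1):
    """Mean significant-only dF/F per time bin; (frames x ROIs) ->
    (ROIs x bins)."""
    per_bin = max(int(round(bin_s * frame_rate)), 1)
    n = sig.shape[0] // per_bin * per_bin
    binned = sig[:n].reshape(-1, per_bin, sig.shape[1]).mean(axis=1)
    return binned.T


def event_spatial_extent(
    sig: np.ndarray,
    roi_table: pd.DataFrame,
    frame_rate: float,
    bin_s: float = 0.1,
    min_branch_rois: int = 8,
) -> pd.DataFrame:
    """Per-event dendritic length (um) and peak dF/F on each branch.

    Traces are binned at ``bin_s``; events are connected components of
    co-active (nonzero) cells in the ROI x time-bin grid (ROIs adjacent on
    the branch, bins adjacent in time).  Event length is the largest
    number of contiguous co-active ROIs at any time point of the event;
    event peak is the maximum dF/F among the co-active ROIs at those time
    points.  Branches shorter than ``min_branch_rois`` are skipped.
    """
    rows = []
    for branch, grp in roi_table.groupby("branch_id", sort=False):
        if len(grp) < min_branch_rois:
            continue
        order = grp.index[np.argsort(grp["position_um"].to_numpy(dtype=float))]
        mat = bin_activity_matrix(sig[:, order], frame_rate, bin_s)
        active = mat > 0
        labels, n_lab = ndimage.label(
            active, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]]
        )
        for lab in range(1, n_lab + 1):
            cells = labels == lab
            bins = np.flatnonzero(cells.any(axis=0))
            best_len, best_bins = 0, []
            for b in bins:
                col = cells[:, b]
                starts, ends = find_runs(col)
                run_len = int((ends - starts).max())
                if run_len > best_len:
                    best_len, best_bins = run_len, [b]
                elif run_len == best_len:
                    best_bins.append(b)
            peak = float(max(mat[cells[:, b], b].max() for b in best_bins))
            rows.append((branch, best_len, peak, int(bins[0]), int(bins[-1])))
    return pd.DataFrame(
        rows, columns=["branch_id", "length_um", "peak_dff", "start_bin", "end_bin"]
    )


def input_rate_summary(
    sig: np.ndarray,
    valid: np.ndarray,
    frame_rate: float,
) -> np.ndarray:
    """Per-ROI mean excitatory input: trapezoidal integral of the
    significant-only trace over valid time, divided by valid seconds
    (dF/F per second).  NaN where there is no valid time."""
    sig = np.asarray(sig, dtype=float)
    if sig.ndim == 1:
        sig = sig[:, None]
    total_s = valid.sum() / frame_rate
    if total_s == 0:
        return np.full(sig.shape[1], np.nan)
    out = np.zeros(sig.shape[1])
    for s, e in zip(*find_runs(valid)):
        seg = sig[s:e]
        if e - s >= 2:
            out += np.trapezoid(seg, dx=1.0 / frame_rate, axis=0)
    return out / total_s
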