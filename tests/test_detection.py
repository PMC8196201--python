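"""dF/F baseline, run filter, QC exclusions, the transient-ratio detector,
event extents, and input rates."""

import numpy as np
import pandas as pd
import pytest

from dendroglu.detection import (
    TransientDetector,
    compute_dff,
    event_spatial_extent,
    exclude_rois_and_frames,
    input_rate_summary,
    run_period_mask,
)
from dendroglu.session import BehaviorSession, RoiTraceSet


def _behavior_from_velocity(vel, fps=30.0, track_length=300.0):
    vel = np.asarray(vel, dtype=float)
    n = vel.size
    pos = np.clip(np.cumsum(vel) / fps, 0, track_length)
    return BehaviorSession(
        time=np.arange(n) / fps, position=pos, velocity=vel,
        traversal_id=np.zeros(n, dtype=int),
        run_mask=np.zeros(n, dtype=bool), track_length=track_length,
    )


# ---------------------------------------------------------------------------
# dF/F
# ---------------------------------------------------------------------------

def test_dff_constant_trace_is_zero():
    out = compute_dff(np.full(2000, 100.0), frame_rate=30.0)
    np.testing.assert_allclose(out.dff, 0.0, atol=1e-12)
    np.testing.assert_allclose(out.baseline, 100.0)


def test_dff_removes_bleaching_trend():
    fps = 30.0
    t5 = np.arange(9000) / fps / 300.0
    trace = 100.0 * np.exp(np.log1p(-0.159) * t5)  # 15.9% per 5 min
    out = compute_dff(trace, window_s=1.5, frame_rate=fps)
    assert abs(out.dff.mean()) < 0.02


def test_dff_short_pulse_peak_recovered():
    fps = 30.0
    trace = np.ones(3000)
    trace[1500:1503] = 2.0  # +1.0 pulse, far shorter than the 8% window tail
    out = compute_dff(trace, window_s=1.5, frame_rate=fps)
    assert abs(out.dff.max() - 1.0) < 1e-9


def test_dff_flags_nonpositive_baseline():
    trace = np.full(2000, -1.0)
    out = compute_dff(trace, frame_rate=30.0)
    assert out.f0_invalid[0]


# ---------------------------------------------------------------------------
# run-period mask
# ---------------------------------------------------------------------------

def test_run_mask_slow_run_rejected():
    beh = _behavior_from_velocity(np.full(3000, 3.0))
    assert not run_period_mask(beh).any()


def test_run_mask_short_run_rejected():
    vel = np.zeros(3000)
    vel[100:205] = 10.0  # 10 cm/s x 3.5 s = 35 cm < 40 cm
    beh = _behavior_from_velocity(vel)
    assert not run_period_mask(beh).any()


def test_run_mask_long_run_accepted():
    vel = np.zeros(3000)
    vel[100:400] = 10.0  # 10 cm/s x 10 s = 100 cm
    beh = _behavior_from_velocity(vel)
    mask = run_period_mask(beh)
    assert mask[100:400].all() and mask.sum() == 300


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def _trace_set(arr, positions=None):
    n_rois = arr.shape[1]
    tbl = pd.DataFrame({
        "roi_id": [f"r{j}" for j in range(n_rois)],
        "branch_id": "b0",
        "position_um": positions if positions is not None
        else np.arange(n_rois, dtype=float),
        "cell_id": "c0",
        "channel": "glu",
    })
    return RoiTraceSet(traces=arr, frame_rate=30.0, roi_table=tbl)


def test_dim_roi_excluded():
    rng = np.random.default_rng(0)
    arr = rng.normal(100, 1, (2000, 5))
    arr[:, 2] = rng.normal(1.4, 0.1, 2000)
    rep = exclude_rois_and_frames(_trace_set(arr), exclude_branch_ends=False)
    assert rep.roi_excluded[2]
    assert not rep.roi_excluded[[1, 3]].any()


def test_branch_end_rois_excluded():
    rng = np.random.default_rng(0)
    arr = rng.normal(100, 1, (2000, 6))
    rep = exclude_rois_and_frames(_trace_set(arr))
    assert rep.roi_excluded[0] and rep.roi_excluded[5]
    assert not rep.roi_excluded[1:5].any()


def test_frame_exclusion_thresholds():
    rng = np.random.default_rng(1)
    arr = rng.normal(100, 1, (3000, 20))
    fm = arr.mean(axis=1)
    resid = fm - fm.mean()
    sd = resid.std()
    mu = fm.mean()
    arr[500] = mu + 2.5 * sd   # field mean +2.5 STD -> excluded
    arr[900] = mu - 1.5 * sd   # field mean -1.5 STD -> excluded
    arr[1300] = mu + 1.5 * sd  # +1.5 STD (< +2 STD) -> kept
    rep = exclude_rois_and_frames(_trace_set(arr), detrend_window_frames=0)
    assert rep.frame_excluded[500]
    assert rep.frame_excluded[900]
    assert not rep.frame_excluded[1300]


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------

def test_sigma_estimator_on_unit_normal():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(100_000)
    assert abs(TransientDetector.noise_sigma(x) - 1.0) < 0.1


def test_symmetric_noise_yields_near_unit_ratios_and_low_retention():
    rng = np.random.default_rng(3)
    X = rng.normal(0, 0.19, (9000, 50))
    det = TransientDetector().fit(X, frame_rate=30.0)
    events, _ = det.detect(X)
    # most-populated class has a ratio near 1
    k = np.unravel_index(det.positive_counts_.argmax(),
                         det.positive_counts_.shape)
    assert 0.5 < det.fp_ratio_[k] < 2.0
    assert events["significant"].mean() <= 0.01


def test_single_clear_event_accepted():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 0.1, 6000)
    x[3000:3015] += 0.9  # ~9 sigma, 0.5 s
    det = TransientDetector().fit(x, frame_rate=30.0)
    events, sig = det.detect(x)
    hits = events[(events.onset_frame <= 3000) & (events.offset_frame >= 3010)]
    assert len(hits) == 1 and bool(hits.significant.iloc[0])
    assert sig[3005, 0] > 0


def test_amplitude_gate_inclusive_boundary():
    # two clean accepted-class events differing only in peak dF/F
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.02, 6000)
    x[1000:1012] = 0.39
    x[4000:4012] = 0.41
    det = TransientDetector().fit(x, frame_rate=30.0)
    events, _ = det.detect(x)
    ev_a = events[(events.onset_frame <= 1000) & (events.offset_frame >= 1011)]
    ev_b = events[(events.onset_frame <= 4000) & (events.offset_frame >= 4011)]
    assert not ev_a.significant.iloc[0]
    assert ev_b.significant.iloc[0]
    det.amplitude_gate = 0.40
    ev2, _ = det.detect(x)
    # a peak of exactly 0.40 is kept (inclusive gate)
    x2 = x.copy()
    x2[1000:1012] = 0.40
    ev3, _ = det.detect(x2)
    assert ev3[(ev3.onset_frame <= 1000)
               & (ev3.offset_frame >= 1011)].significant.iloc[0]


def test_raising_gate_never_adds_events():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 0.19, 9000)
    for t in range(500, 8500, 400):
        x[t:t + 10] += rng.uniform(0.2, 1.5)
    det = TransientDetector().fit(x, frame_rate=30.0)
    kept = []
    for gate in (0.2, 0.4, 0.6, 0.8):
        det.amplitude_gate = gate
        ev, _ = det.detect(x)
        kept.append(set(map(tuple, ev[ev.significant][["onset_frame",
                                                       "offset_frame"]].values)))
    for a, b in zip(kept[1:], kept[:-1]):
        assert a <= b


def test_no_event_overlaps_masked_out_frames():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 0.19, 9000)
    x[4000:4020] += 2.0
    valid = np.ones(9000, dtype=bool)
    valid[4005:4010] = False
    det = TransientDetector().fit(x, frame_rate=30.0, valid=valid)
    ev, sig = det.detect(x, valid=valid)
    assert (sig[~valid] == 0).all()
    for _, e in ev.iterrows():
        assert valid[int(e.onset_frame):int(e.offset_frame)].all()


def test_planted_event_recovery_rate():
    """>= 90% of planted events with peak >= 0.6 dF/F and duration >= 0.2 s
    are detected on synthetic noise."""
    from dendroglu.simulate import GeneratorParams, _render_events

    rng = np.random.default_rng(8)
    p = GeneratorParams()
    fps, n = 30.0, 9000
    n_rois, found, total = 30, 0, 0
    X = rng.normal(0, p.noise_sigma, (n, n_rois))
    planted = []
    for j in range(n_rois):
        onsets = np.sort(rng.choice(np.arange(200, n - 200), size=12,
                                    replace=False))
        onsets = onsets[np.diff(np.concatenate(([0], onsets))) > 90]
        amps = rng.uniform(0.6, 1.5, onsets.size)
        durs = rng.uniform(0.2, 0.6, onsets.size)
        _render_events(X[:, j], onsets, amps, durs, fps, p.noise_sigma)
        planted.extend((j, int(t)) for t in onsets)
    det = TransientDetector().fit(X, frame_rate=fps)
    _, sig = det.detect(X)
    for j, t in planted:
        total += 1
        found += bool((sig[t:t + 5, j] > 0).any())
    assert total > 200
    assert found / total >= 0.90


# ---------------------------------------------------------------------------
# event spatial extent
# ---------------------------------------------------------------------------

def _extent_setup(active: list, n_rois=10, n_frames=600, fps=30.0):
    """active: [(roi, frame_slice, value), ...]"""
    sig = np.zeros((n_frames, n_rois))
    for j, sl, v in active:
        sig[sl, j] = v
    tbl = pd.DataFrame({"roi_id": [f"r{j}" for j in range(n_rois)],
                        "branch_id": "b0",
                        "position_um": np.arange(n_rois, dtype=float),
                        "cell_id": "c0", "channel": "glu"})
    return sig, tbl, fps


def test_single_roi_event_length_one():
    sig, tbl, fps = _extent_setup([(7, slice(90, 96), 0.8)])
    ev = event_spatial_extent(sig, tbl, fps)
    assert len(ev) == 1
    assert ev.length_um.iloc[0] == 1


def test_three_contiguous_rois_length_and_peak():
    sig, tbl, fps = _extent_setup([
        (5, slice(90, 93), 0.5), (6, slice(90, 93), 1.2),
        (7, slice(90, 93), 0.8),
    ])
    ev = event_spatial_extent(sig, tbl, fps)
    assert len(ev) == 1
    assert ev.length_um.iloc[0] == 3
    assert ev.peak_dff.iloc[0] == pytest.approx(1.2)


def test_noncontiguous_rois_are_two_events():
    sig, tbl, fps = _extent_setup([
        (5, slice(90, 93), 0.5), (9, slice(90, 93), 0.7),
    ])
    ev = event_spatial_extent(sig, tbl, fps)
    assert len(ev) == 2
    assert sorted(ev.length_um) == [1, 1]


def test_short_branch_skipped():
    sig, tbl, fps = _extent_setup([(2, slice(90, 93), 0.5)], n_rois=5)
    ev = event_spatial_extent(sig, tbl, fps, min_branch_rois=8)
    assert len(ev) == 0


# ---------------------------------------------------------------------------
# input rate
# ---------------------------------------------------------------------------

def test_input_rate_silent_roi_is_zero():
    valid = np.ones(3000, dtype=bool)
    out = input_rate_summary(np.zeros((3000, 1)), valid, 30.0)
    assert out[0] == 0.0


def test_input_rate_rectangular_event():
    fps = 30.0
    n = int(100 * fps)
    sig = np.zeros((n, 1))
    sig[1500:1500 + int(2 * fps), 0] = 0.5  # 0.5 dF/F x 2 s in 100 s
    out = input_rate_summary(sig, np.ones(n, dtype=bool), fps)
    assert out[0] == pytest.approx(0.01, rel=1e-6)


def test_input_rate_matches_kernel_integral():
    """Generator schedule: measured rate matches the analytic sum of
    exponential-kernel integrals within 2%."""
    from dendroglu.simulate import _render_events

    fps, n = 30.0, 30000
    trace = np.zeros(n)
    rng = np.random.default_rng(9)
    onsets = np.arange(200, n - 600, 450)
    amps = rng.uniform(0.5, 1.5, onsets.size)
    durs = rng.uniform(0.3, 0.8, onsets.size)
    sigma = 0.19
    _render_events(trace, onsets, amps, durs, fps, sigma)
    valid = np.ones(n, dtype=bool)
    measured = input_rate_summary(trace, valid, fps)[0]
    # closed form per event: exponential-decay integral to the truncation
    # point plus the half-frame rise edge of the trapezoid
    dt = 1.0 / fps
    taus = durs / np.log(np.maximum(amps / sigma, 1.5))
    n_k = np.maximum(np.ceil(5 * taus * fps), 2)
    analytic = float(np.sum(
        amps * (taus * (1 - np.exp(-(n_k - 1) * dt / taus)) + dt / 2)
    )) / (n / fps)
    assert measured == pytest.approx(analytic, rel=0.02)


def test_input_rate_no_valid_time_is_missing():
    out = input_rate_summary(np.zeros((100, 2)), np.zeros(100, dtype=bool), 30.0)
    assert np.isnan(out).all()
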