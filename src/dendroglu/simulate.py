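"""Synthetic session generator with full ground truth.

Emulates the statistical structure of dendritic glutamate-sensor imaging
during linear-track running: teleporting track traversals; somatic traces
of place / silent / active-nonplace cells; 1-um dendritic ROI traces whose
transients have in-vivo-like amplitude (1.11 +/- 0.65 dF/F) and duration
(0.35 +/- 0.21 s) statistics; spatially tuned place-ROIs with ~59.5 +/-
14.5 cm fields; anatomically clustered co-activating ROI groups; rare
large-spatial-extent events spanning adjacent ROIs; additive Gaussian
noise (sigma ~ 0.19 dF/F) and multiplicative photobleaching (~15.9% per
5 min); and a GFP-control pure-noise mode.

Everything downstream is tested against the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .session import BehaviorSession, RoiTraceSet, write_session

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_behavior",
    "plan_ground_truth",
    "plant_clusters",
    "generate_dendrite_traces",
    "generate_soma_traces",
    "generate_gfp_control",
    "generate_session",
]

ROI_CLASSES = ("place", "active_nonplace", "silent")


@dataclass
class GeneratorParams:
    """Study-condition parameters of the synthetic session generator.

    Class mixes, transient moments, field widths, noise, bleaching, the
    event-extent mixture, and cluster geometry default to the in-vivo
    summary statistics; rates and behavior parameters are chosen to give
    ~20 track traversals and tens of transients per active ROI in a 5-min
    session.
    """

    # --- behavior ---
    duration_s: float = 300.0
    frame_rate: float = 30.0
    track_length: float = 300.0
    speed_mean: float = 25.0          # cm/s while running
    speed_sd: float = 3.0
    pause_rate: float = 0.02          # 1/s, run -> pause hazard
    pause_mean_s: float = 2.0
    reward_delay_s: float = 1.0       # stop at track end before teleport
    min_traversals: int = 2

    # --- cohort layout ---
    n_cells: int = 8
    fraction_place_cells: float = 0.5
    branches_per_cell: int = 2
    rois_per_branch: int = 16

    # --- ROI class mixes (place, active_nonplace, silent) ---
    roi_mix_place_cell: tuple = (0.19, 0.41, 0.40)
    roi_mix_nonplace_cell: tuple = (0.11, 0.56, 0.34)

    # --- spatial tuning ---
    field_width_mean: float = 59.5    # cm
    field_width_sd: float = 14.5
    field_width_min: float = 20.0
    field_width_max: float = 120.0
    infield_enrichment: float = 1.6   # place-ROI center density in/out of somatic field
    stratified_tuning: bool = False   # per-branch stratified (not iid) centers

    # --- transient statistics ---
    amp_mean: float = 1.11            # dF/F
    amp_sd: float = 0.65
    amp_min: float = 0.10
    dur_mean: float = 0.35            # s
    dur_sd: float = 0.21
    dur_min: float = 0.10

    # --- rates (events/s during running) ---
    place_roi_peak_rate: float = 0.8
    place_roi_base_rate: float = 0.01
    nonplace_roi_rate: float = 0.2
    soma_peak_rate: float = 1.2
    soma_base_rate: float = 0.05
    soma_nonplace_rate: float = 0.3

    # --- noise and trend ---
    noise_sigma: float = 0.19         # dF/F
    bleach_per_5min: float = 0.159
    baseline_counts: float = 100.0
    background_counts: float = 10.0

    # --- clusters ---
    clusters_per_branch: int = 1
    cluster_size_min: int = 4
    cluster_size_max: int = 9
    cluster_gap_prob: float = 0.25    # chance of a single-ROI gap per step
    cluster_rate: float = 0.15        # activations/s at tuning peak
    cluster_base_rate: float = 0.02
    cluster_participation: float = 0.3
    cluster_cotuning: bool = True     # cluster tuning follows the somatic field

    # --- large-spatial-extent events: P(extent = 1, 2, 3, >=4 ROIs) ---
    extent_mixture: tuple = (0.76, 0.15, 0.06, 0.03)
    extent_max: int = 6

    def validate(self) -> None:
        for mix, name in (
            (self.roi_mix_place_cell, "roi_mix_place_cell"),
            (self.roi_mix_nonplace_cell, "roi_mix_nonplace_cell"),
        ):
            # reported class percentages can sum to ~101% from independent
            # rounding; tolerate that and renormalize at sampling time
            if any(p < 0 or p > 1 for p in mix) or abs(sum(mix) - 1.0) > 0.02:
                raise ValueError(f"{name} must be probabilities summing to ~1")
        if abs(sum(self.extent_mixture) - 1.0) > 1e-9:
            raise ValueError("extent_mixture must sum to 1")
        for name in ("duration_s", "frame_rate", "track_length", "speed_mean",
                     "noise_sigma", "amp_mean", "dur_mean", "field_width_mean",
                     "baseline_counts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_s * self.speed_mean < self.track_length:
            raise ValueError("duration_s too short for one track traversal")


@dataclass
class GroundTruth:
    """Everything the generator decided, for parameter-recovery tests.

    ``cells``: cell_id, cell_class, field_center_cm, field_width_cm.
    ``rois``: roi_id, branch_id, cell_id, roi_class, tuning_center_cm,
    field_width_cm.  ``events``: roi_id, onset_frame, amplitude_dff,
    duration_s, extent_rois, source.  ``clusters``: list of dicts with
    branch_id, member roi_ids, tuning center, and activation frames.
    """

    cells: pd.DataFrame
    rois: pd.DataFrame
    events: pd.DataFrame
    clusters: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "rois": self.rois.to_dict(orient="list"),
            "events": self.events.to_dict(orient="list"),
            "clusters": self.clusters,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cells=pd.DataFrame(d["cells"]),
            rois=pd.DataFrame(d["rois"]),
            events=pd.DataFrame(d["events"]),
            clusters=d["clusters"],
        )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def generate_behavior(params: GeneratorParams, seed: int) -> BehaviorSession:
    """Simulate linear-track running with pauses, rewards, and teleports.

    The animal runs at an Ornstein-Uhlenbeck-smoothed speed around
    ``speed_mean``, occasionally pausing; reaching the track end delivers a
    reward, holds position through ``reward_delay_s``, then teleports to
    the start (``traversal_id`` increments; position is never
    interpolated across the teleport).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    fps = params.frame_rate
    dt = 1.0 / fps
    n = int(round(params.duration_s * fps))

    time = np.arange(n) * dt
    position = np.zeros(n)
    velocity = np.zeros(n)
    traversal = np.zeros(n, dtype=np.int64)
    reward = np.zeros(n, dtype=bool)

    pos = 0.0
    trav = 0
    v = params.speed_mean
    state = "run"                       # run | pause | delay
    state_left = 0.0                    # s remaining in pause/delay
    tau_v = 0.5                         # s, speed relaxation

    for i in range(n):
        if state == "run":
            v += (params.speed_mean - v) * dt / tau_v
            v += params.speed_sd * np.sqrt(2 * dt / tau_v) * rng.standard_normal()
            v = max(v, 0.0)
            if params.pause_rate > 0 and rng.random() < params.pause_rate * dt:
                state = "pause"
                state_left = rng.exponential(params.pause_mean_s)
        else:
            v = 0.0
            state_left -= dt
            if state_left <= 0:
                if state == "delay":
                    pos = 0.0
                    trav += 1
                state = "run"
                v = params.speed_mean

        pos_new = pos + v * dt
        if state == "run" and pos_new >= params.track_length:
            pos_new = params.track_length
            reward[i] = True
            state = "delay"
            state_left = params.reward_delay_s
        pos = pos_new
        position[i] = pos
        velocity[i] = v
        traversal[i] = trav

    from .detection import run_period_mask  # local import avoids a cycle at module load

    behavior = BehaviorSession(
        time=time,
        position=position,
        velocity=velocity,
        traversal_id=traversal,
        run_mask=np.zeros(n, dtype=bool),
        track_length=params.track_length,
        reward_flag=reward,
    )
    behavior.run_mask = run_period_mask(behavior)
    if behavior.n_traversals - 1 < params.min_traversals:
        raise ValueError(
            f"behavior produced {behavior.n_traversals - 1} full traversals, "
            f"fewer than min_traversals={params.min_traversals}"
        )
    return behavior


# ---------------------------------------------------------------------------
# ground-truth planning
# ---------------------------------------------------------------------------

def _sample_width(params: GeneratorParams, rng, size=None):
    w = rng.normal(params.field_width_mean, params.field_width_sd, size=size)
    return np.clip(w, params.field_width_min, params.field_width_max)


def _sample_enriched_center(params: GeneratorParams, soma_center, soma_width,
                            rng, margin: float = 0.0):
    """Tuning-center density proportional to ``infield_enrichment`` inside
    the somatic field (|x - center| < width/2) and 1 outside.

    Centers may fall up to ``margin`` cm off-track (fields truncated at
    the track edges), which keeps the marginal input rate uniform along
    the track instead of depressed at the edges.
    """
    L = params.track_length
    lo = max(-margin, soma_center - soma_width / 2)
    hi = min(L + margin, soma_center + soma_width / 2)
    w_in = (hi - lo) * params.infield_enrichment
    w_out = (L + 2 * margin) - (hi - lo)
    if rng.random() < w_in / (w_in + w_out):
        return rng.uniform(lo, hi)
    # rejection-sample the outside region
    while True:
        x = rng.uniform(-margin, L + margin)
        if x < lo or x > hi:
            return x


def plan_ground_truth(params: GeneratorParams, seed: int) -> GroundTruth:
    """Assign cell classes, somatic fields, ROI classes/tuning and clusters."""
    params.validate()
    rng = np.random.default_rng(seed)
    L = params.track_length

    n_place = int(round(params.n_cells * params.fraction_place_cells))
    cell_rows = []
    for c in range(params.n_cells):
        cid = f"c{c:02d}"
        if c < n_place:
            cls = "place"
            center = rng.uniform(0.1 * L, 0.9 * L)
            width = float(_sample_width(params, rng))
        else:
            cls = "active_nonplace" if rng.random() < 0.7 else "silent"
            center, width = np.nan, np.nan
        cell_rows.append((cid, cls, center, width))
    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "cell_class", "field_center_cm", "field_width_cm"]
    )

    roi_rows = []
    clusters = []
    for _, cell in cells.iterrows():
        mix = (
            params.roi_mix_place_cell
            if cell.cell_class == "place"
            else params.roi_mix_nonplace_cell
        )
        for b in range(params.branches_per_cell):
            branch = f"{cell.cell_id}b{b}"
            pmix = np.asarray(mix, dtype=float)
            classes = rng.choice(ROI_CLASSES, size=params.rois_per_branch,
                                 p=pmix / pmix.sum())
            n_place_rois = int((classes == "place").sum())
            strata = rng.permutation(n_place_rois)
            k_place = 0
            for r, rcls in enumerate(classes):
                if rcls == "place":
                    width = float(_sample_width(params, rng))
                    if params.stratified_tuning:
                        # spread centers evenly (with jitter) over the
                        # extended track so each branch's realized coverage
                        # is balanced, not a binomial draw
                        frac = (strata[k_place] + rng.random()) / n_place_rois
                        center = float(np.clip(
                            -width / 2 + frac * (L + width),
                            -width / 2, L + width / 2))
                        k_place += 1
                    elif cell.cell_class == "place":
                        center = _sample_enriched_center(
                            params, cell.field_center_cm, cell.field_width_cm,
                            rng, margin=width / 2,
                        )
                    else:
                        center = rng.uniform(-width / 2, L + width / 2)
                else:
                    center, width = np.nan, np.nan
                roi_rows.append(
                    (f"{branch}r{r:03d}", branch, cell.cell_id, rcls, center, width)
                )
            for _ in range(params.clusters_per_branch):
                size = int(rng.integers(params.cluster_size_min, params.cluster_size_max + 1))
                frag = plant_clusters(
                    branch_rois=[f"{branch}r{r:03d}" for r in range(params.rois_per_branch)],
                    size=size,
                    seed=int(rng.integers(2**31)),
                    gap_prob=params.cluster_gap_prob,
                    min_size=params.cluster_size_min,
                )
                frag["branch_id"] = branch
                frag["cell_id"] = cell.cell_id
                if cell.cell_class == "place" and params.cluster_cotuning:
                    frag["tuning_center_cm"] = float(cell.field_center_cm)
                    frag["tuning_width_cm"] = float(cell.field_width_cm)
                elif cell.cell_class == "place":
                    # co-activation without somatic-field coupling
                    frag["tuning_center_cm"] = float(rng.uniform(0, L))
                    frag["tuning_width_cm"] = float(_sample_width(params, rng))
                else:
                    frag["tuning_center_cm"] = None
                    frag["tuning_width_cm"] = None
                clusters.append(frag)

    rois = pd.DataFrame(
        roi_rows,
        columns=["roi_id", "branch_id", "cell_id", "roi_class",
                 "tuning_center_cm", "field_width_cm"],
    )
    events = pd.DataFrame(
        columns=["roi_id", "onset_frame", "amplitude_dff", "duration_s",
                 "extent_rois", "source"]
    )
    return GroundTruth(cells=cells, rois=rois, events=events, clusters=clusters)


def plant_clusters(branch_rois: list, size: int, seed: int,
                   gap_prob: float = 0.25, min_size: int = 4,
                   contributing_fraction: float = 0.70,
                   exclude: set | None = None) -> dict:
    """Choose a cluster member set on one branch.

    Members are contiguous up to single-ROI gaps, and the number of gaps
    is capped so the members make up at least ``contributing_fraction``
    of their span — the defining property of a functional cluster, so a
    planted cluster is detectable by its own definition.  ``size`` below
    ``min_size`` (4) or above the branch capacity is a parameter error.
    """
    if size < min_size:
        raise ValueError(f"cluster size {size} below minimum {min_size}")
    n = len(branch_rois)
    if size > n:
        raise ValueError(f"cluster size {size} exceeds branch length {n}")
    max_gaps = int(size / contributing_fraction) - size
    rng = np.random.default_rng(seed)
    exclude = exclude or set()
    for _ in range(200):
        start = int(rng.integers(0, n))
        members = [start]
        gaps = 0
        while len(members) < size:
            gap = gaps < max_gaps and rng.random() < gap_prob
            nxt = members[-1] + (2 if gap else 1)
            if nxt >= n:
                break
            gaps += gap
            members.append(nxt)
        if len(members) == size and not (set(members) & exclude):
            return {"member_rois": [branch_rois[m] for m in members],
                    "member_index": members}
    raise ValueError(f"could not place a size-{size} cluster on branch of {n} ROIs")


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------

def _lognormal_pars(mean, sd):
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def _draw_trunc_lognormal(rng, mean, sd, lo, size):
    mu, s = _lognormal_pars(mean, sd)
    out = rng.lognormal(mu, s, size)
    for _ in range(50):
        bad = out < lo
        if not bad.any():
            break
        out[bad] = rng.lognormal(mu, s, int(bad.sum()))
    return np.maximum(out, lo)


def _position_rate(params, behavior, center, width, peak, base):
    """Per-frame event rate (events/s): Gaussian bump over position during
    running.  A field of full width w (10%-of-peak bounds) has Gaussian
    sd ~ w/4.3."""
    sd = width / 4.3
    lam = base + (peak - base) * np.exp(
        -0.5 * ((behavior.position - center) / sd) ** 2
    )
    return np.where(behavior.run_mask, lam, 0.0)


def _uniform_rate(params, behavior, rate):
    return np.where(behavior.run_mask, rate, 0.0)


def _poisson_event_frames(rng, lam_per_s, fps):
    p = np.clip(lam_per_s / fps, 0, 1)
    return np.flatnonzero(rng.random(p.shape[0]) < p)


def _render_events(dff_col, onsets, amps, durs, fps, noise_sigma):
    """Add sharp-rise / exponential-decay transients in place.

    The decay constant is set so the drawn duration is the time for the
    kernel to fall to the noise floor (1 sigma): tau = d / ln(a / sigma).
    """
    n = dff_col.shape[0]
    for t0, a, d in zip(onsets, amps, durs):
        ratio = max(a / noise_sigma, 1.5)
        tau = d / np.log(ratio)
        n_k = min(n - t0, max(int(np.ceil(5 * tau * fps)), 2))
        t = np.arange(n_k) / fps
        dff_col[t0:t0 + n_k] += a * np.exp(-t / tau)


def generate_dendrite_traces(
    params: GeneratorParams,
    behavior: BehaviorSession,
    plan: GroundTruth,
    seed: int,
) -> tuple[RoiTraceSet, GroundTruth]:
    """Render the dendritic (glu channel) trace matrix from a plan.

    Place-ROIs emit position-gated Poisson transient trains, active-
    nonplace-ROIs position-independent trains, silent-ROIs noise only.
    Cluster members share activation times with partial participation.
    Each non-cluster event draws a spatial extent from the 76/15/6/3%
    mixture and is copied into adjacent ROIs accordingly.  Transients are
    rendered as instantaneous rise + exponential decay, then scaled to raw
    counts with multiplicative bleaching and additive Gaussian noise.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    fps = params.frame_rate
    n = behavior.n_frames
    rois = plan.rois.reset_index(drop=True)
    n_rois = len(rois)
    idx_of = {rid: j for j, rid in enumerate(rois["roi_id"])}
    branch_members: dict = {}
    for branch, grp in rois.groupby("branch_id", sort=False):
        branch_members[branch] = list(grp.index)

    # centers may sit up to half a field width off-track (edge-truncated
    # fields); anything beyond that is a parameter error
    tuned = rois["tuning_center_cm"].notna()
    margin = rois.loc[tuned, "field_width_cm"].to_numpy(dtype=float) / 2
    centers = rois.loc[tuned, "tuning_center_cm"].to_numpy(dtype=float)
    if ((centers < -margin) | (centers > params.track_length + margin)).any():
        raise ValueError("tuning center off-track")

    dff = np.zeros((n, n_rois))
    ev_roi, ev_onset, ev_amp, ev_dur, ev_ext, ev_src = [], [], [], [], [], []

    def add_events(j, onsets, source, extents=None):
        k = len(onsets)
        if k == 0:
            return
        amps = _draw_trunc_lognormal(rng, params.amp_mean, params.amp_sd,
                                     params.amp_min, k)
        durs = _draw_trunc_lognormal(rng, params.dur_mean, params.dur_sd,
                                     params.dur_min, k)
        if extents is None:
            extents = np.ones(k, dtype=int)
        _render_events(dff[:, j], onsets, amps, durs, fps, params.noise_sigma)
        ev_roi.extend([rois.at[j, "roi_id"]] * k)
        ev_onset.extend(int(t) for t in onsets)
        ev_amp.extend(float(a) for a in amps)
        ev_dur.extend(float(d) for d in durs)
        ev_ext.extend(int(e) for e in extents)
        ev_src.extend([source] * k)
        # copy multi-ROI events into neighbors (each neighbor re-draws its
        # own amplitude/duration around the shared onset)
        members = branch_members[rois.at[j, "branch_id"]]
        pos_in_branch = members.index(j)
        for i_ev, ext in enumerate(extents):
            if ext <= 1:
                continue
            side = 1 if rng.random() < 0.5 else -1
            for step in range(1, int(ext)):
                q = pos_in_branch + side * step
                if not (0 <= q < len(members)):
                    q = pos_in_branch - side * step
                    if not (0 <= q < len(members)):
                        break
                jj = members[q]
                a2 = _draw_trunc_lognormal(rng, params.amp_mean, params.amp_sd,
                                           params.amp_min, 1)
                d2 = _draw_trunc_lognormal(rng, params.dur_mean, params.dur_sd,
                                           params.dur_min, 1)
                _render_events(dff[:, jj], [onsets[i_ev]], a2, d2, fps,
                               params.noise_sigma)
                ev_roi.append(rois.at[jj, "roi_id"])
                ev_onset.append(int(onsets[i_ev]))
                ev_amp.append(float(a2[0]))
                ev_dur.append(float(d2[0]))
                ev_ext.append(int(ext))
                ev_src.append("extent")

    extent_p = np.asarray(
        list(params.extent_mixture[:3])
        + [params.extent_mixture[3] / (params.extent_max - 3)] * (params.extent_max - 3)
    )
    extent_vals = np.arange(1, params.extent_max + 1)

    for j in range(n_rois):
        rcls = rois.at[j, "roi_class"]
        if rcls == "silent":
            continue
        if rcls == "place":
            lam = _position_rate(
                params, behavior,
                rois.at[j, "tuning_center_cm"], rois.at[j, "field_width_cm"],
                params.place_roi_peak_rate, params.place_roi_base_rate,
            )
        else:
            lam = _uniform_rate(params, behavior, params.nonplace_roi_rate)
        onsets = _poisson_event_frames(rng, lam, fps)
        extents = rng.choice(extent_vals, size=len(onsets), p=extent_p / extent_p.sum())
        add_events(j, onsets, "tuned", extents)

    # cluster activations: shared times, partial membership
    for clu in plan.clusters:
        if clu.get("tuning_center_cm") is not None:
            lam = _position_rate(params, behavior,
                                 clu["tuning_center_cm"], clu["tuning_width_cm"],
                                 params.cluster_rate, params.cluster_base_rate)
        else:
            lam = _uniform_rate(params, behavior, params.cluster_rate)
        act_frames = _poisson_event_frames(rng, lam, fps)
        clu["activation_frames"] = [int(t) for t in act_frames]
        members = [idx_of[r] for r in clu["member_rois"]]
        for t0 in act_frames:
            active = [m for m in members if rng.random() < params.cluster_participation]
            if not active:
                active = [members[int(rng.integers(len(members)))]]
            for j in active:
                add_events(j, np.array([t0]), "cluster")

    events = pd.DataFrame(
        {"roi_id": ev_roi, "onset_frame": ev_onset, "amplitude_dff": ev_amp,
         "duration_s": ev_dur, "extent_rois": ev_ext, "source": ev_src}
    )
    truth = GroundTruth(cells=plan.cells, rois=rois, events=events,
                        clusters=plan.clusters)

    traces, background, bg_branches = _to_counts(params, dff, rois, rng)
    roi_table = rois[["roi_id", "branch_id"]].copy()
    roi_table["position_um"] = [
        float(branch_members[b].index(j))
        for j, b in zip(rois.index, rois["branch_id"])
    ]
    roi_table["cell_id"] = rois["cell_id"]
    roi_table["channel"] = "glu"
    trace_set = RoiTraceSet(
        traces=traces, frame_rate=fps, roi_table=roi_table,
        background=background, background_branches=bg_branches,
    )
    return trace_set, truth


def _to_counts(params, dff, rois, rng):
    """dF/F -> raw counts: baseline x (1 + dff + noise) x bleach + background."""
    n, n_rois = dff.shape
    t_min5 = np.arange(n) / params.frame_rate / 300.0
    bleach = np.exp(np.log1p(-params.bleach_per_5min) * t_min5)[:, None]
    noise = rng.normal(0.0, params.noise_sigma, size=dff.shape)
    raw = params.baseline_counts * (1.0 + dff + noise) * bleach

    bg_branches = list(dict.fromkeys(rois["branch_id"]))
    background = params.background_counts + rng.normal(
        0.0, 0.5, size=(n, len(bg_branches))
    )
    col = {b: i for i, b in enumerate(bg_branches)}
    for j, b in enumerate(rois["branch_id"]):
        raw[:, j] += background[:, col[b]]
    return raw, background, bg_branches


def generate_soma_traces(
    params: GeneratorParams,
    behavior: BehaviorSession,
    plan: GroundTruth,
    seed: int,
) -> RoiTraceSet:
    """Somatic (red channel) traces, one ROI per cell, tuned per cell class."""
    rng = np.random.default_rng(seed)
    fps = params.frame_rate
    n = behavior.n_frames
    cells = plan.cells.reset_index(drop=True)
    dff = np.zeros((n, len(cells)))
    for j, cell in cells.iterrows():
        if cell.cell_class == "place":
            lam = _position_rate(params, behavior, cell.field_center_cm,
                                 cell.field_width_cm,
                                 params.soma_peak_rate, params.soma_base_rate)
        elif cell.cell_class == "active_nonplace":
            lam = _uniform_rate(params, behavior, params.soma_nonplace_rate)
        else:
            lam = np.zeros(n)
        onsets = _poisson_event_frames(rng, lam, fps)
        amps = _draw_trunc_lognormal(rng, params.amp_mean, params.amp_sd,
                                     params.amp_min, len(onsets))
        durs = _draw_trunc_lognormal(rng, params.dur_mean, params.dur_sd,
                                     params.dur_min, len(onsets))
        _render_events(dff[:, j], onsets, amps, durs, fps, params.noise_sigma)

    t_min5 = np.arange(n) / fps / 300.0
    bleach = np.exp(np.log1p(-params.bleach_per_5min) * t_min5)[:, None]
    noise = rng.normal(0.0, params.noise_sigma, size=dff.shape)
    raw = params.baseline_counts * (1.0 + dff + noise) * bleach

    roi_table = pd.DataFrame(
        {
            "roi_id": [f"{c}_soma" for c in cells["cell_id"]],
            "branch_id": [f"{c}_somaB" for c in cells["cell_id"]],
            "position_um": 0.0,
            "cell_id": cells["cell_id"],
            "channel": "soma",
        }
    )
    return RoiTraceSet(traces=raw, frame_rate=fps, roi_table=roi_table)


def generate_gfp_control(
    params: GeneratorParams,
    behavior: BehaviorSession,
    seed: int,
    n_rois: int | None = None,
) -> tuple[RoiTraceSet, GroundTruth]:
    """Pure noise + bleaching, no events; channel tag ``gfp``."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = behavior.n_frames
    if n_rois is None:
        n_rois = params.rois_per_branch
    rois = pd.DataFrame(
        {
            "roi_id": [f"gfpR{r:03d}" for r in range(n_rois)],
            "branch_id": "gfpB0",
            "cell_id": None,
            "roi_class": "silent",
            "tuning_center_cm": np.nan,
            "field_width_cm": np.nan,
        }
    )
    dff = np.zeros((n, n_rois))
    traces, background, bg_branches = _to_counts(params, dff, rois, rng)
    roi_table = rois[["roi_id", "branch_id"]].copy()
    roi_table["position_um"] = np.arange(n_rois, dtype=float)
    roi_table["cell_id"] = None
    roi_table["channel"] = "gfp"
    trace_set = RoiTraceSet(
        traces=traces, frame_rate=params.frame_rate, roi_table=roi_table,
        background=background, background_branches=bg_branches,
    )
    truth = GroundTruth(
        cells=pd.DataFrame(columns=["cell_id", "cell_class",
                                    "field_center_cm", "field_width_cm"]),
        rois=rois,
        events=pd.DataFrame(columns=["roi_id", "onset_frame", "amplitude_dff",
                                     "duration_s", "extent_rois", "source"]),
    )
    return trace_set, truth


def generate_session(
    params: GeneratorParams,
    seed: int,
    out_dir=None,
    include_soma: bool = True,
) -> tuple[BehaviorSession, RoiTraceSet, GroundTruth]:
    """Full bundle: behavior + dendritic (and somatic) traces + truth.

    Deterministic in ``(params, seed)``.  If ``out_dir`` is given the
    bundle is written to disk with the ground truth as ``truth.json``.
    """
    root = np.random.default_rng(seed)
    s_beh, s_plan, s_glu, s_soma = (int(root.integers(2**31)) for _ in range(4))
    behavior = generate_behavior(params, s_beh)
    plan = plan_ground_truth(params, s_plan)
    glu, truth = generate_dendrite_traces(params, behavior, plan, s_glu)
    if include_soma:
        soma = generate_soma_traces(params, behavior, truth, s_soma)
        combined = RoiTraceSet(
            traces=np.hstack([glu.traces, soma.traces]),
            frame_rate=glu.frame_rate,
            roi_table=pd.concat([glu.roi_table, soma.roi_table],
                                ignore_index=True),
            background=glu.background,
            background_branches=glu.background_branches,
        )
    else:
        combined = glu
    if out_dir is not None:
        write_session(behavior, combined, out_dir)
        truth.to_json(Path(out_dir) / "truth.json")
    return behavior, combined, truth
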