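"""Mean dF/F-vs-position maps, shuffle-based place-field detection,
cell/ROI classification, and dispersion/COM statistics.

The substrate is the significant transient-only trace restricted to valid
run-period frames.  Maps use 80 spatial bins over the track; bin-level
significance compares the 3-bin-boxcar-smoothed map against maps of the
same trace with its transients relocated uniformly at random within the
valid time base (shape-preserving, overlap-free).  A place field is a run
of 5-46 contiguous significant bins that is active on more than 1/3 of
traversals, extended outward until the smoothed map falls to 10% of the
field peak or begins to increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .detection import find_runs
from .session import BehaviorSession

__all__ = [
    "SpatialMap",
    "PlaceField",
    "ClassLabel",
    "compute_spatial_map",
    "shuffle_null",
    "detect_place_fields",
    "activity_fraction",
    "classify",
    "classify_unit",
    "spatial_dispersion",
    "crossval_sort",
]


@dataclass
class SpatialMap:
    """Mean significant-only dF/F per spatial bin with occupancy and
    per-traversal sub-maps."""

    f: np.ndarray                      # n_bins mean dF/F
    occupancy: np.ndarray              # frames per bin (valid frames only)
    bin_edges: np.ndarray              # cm, n_bins + 1
    per_traversal: np.ndarray | None = None   # n_traversals x n_bins
    traversal_ids: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.f.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def smoothed(self, boxcar: int = 3) -> np.ndarray:
        return uniform_filter1d(self.f, size=boxcar, mode="nearest")


def position_bins(position: np.ndarray, track_length: float, n_bins: int) -> np.ndarray:
    """Half-open bins [x, x + L/N); the last bin is closed at L."""
    b = np.floor(position / track_length * n_bins).astype(np.int64)
    return np.clip(b, 0, n_bins - 1)


def compute_spatial_map(
    sig: np.ndarray,
    behavior: BehaviorSession,
    n_bins: int = 80,
    valid: np.ndarray | None = None,
    per_traversal: bool = True,
) -> SpatialMap:
    """f_i = mean of the trace over valid frames whose position falls in
    bin i; empty bins are 0 with occupancy 0.  Errors if no valid frame."""
    sig = np.asarray(sig, dtype=float)
    if valid is None:
        valid = behavior.run_mask
    if not valid.any():
        raise ValueError("no valid (masked-in) frames to map")
    bins = position_bins(behavior.position, behavior.track_length, n_bins)
    occ = np.bincount(bins[valid], minlength=n_bins).astype(float)
    sums = np.bincount(bins[valid], weights=sig[valid], minlength=n_bins)
    f = np.where(occ > 0, sums / np.maximum(occ, 1), 0.0)
    edges = np.linspace(0, behavior.track_length, n_bins + 1)

    per_trav = trav_ids = None
    if per_traversal:
        trav_ids = np.unique(behavior.traversal_id[valid])
        per_trav = np.zeros((trav_ids.size, n_bins))
        for k, t in enumerate(trav_ids):
            m = valid & (behavior.traversal_id == t)
            o = np.bincount(bins[m], minlength=n_bins).astype(float)
            s = np.bincount(bins[m], weights=sig[m], minlength=n_bins)
            per_trav[k] = np.where(o > 0, s / np.maximum(o, 1), 0.0)
    return SpatialMap(f=f, occupancy=occ, bin_edges=edges,
                      per_traversal=per_trav, traversal_ids=trav_ids)


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

def _segments(comp: np.ndarray):
    starts, ends = find_runs(comp != 0)
    return [(s, e) for s, e in zip(starts, ends)]


def shuffle_null(
    sig: np.ndarray,
    behavior: BehaviorSession,
    n_shuffles: int,
    seed: int,
    n_bins: int = 80,
    valid: np.ndarray | None = None,
    boxcar: int = 3,
    mode: str = "relocate",
) -> np.ndarray:
    """Stack of ``n_shuffles`` smoothed null maps.

    Each shuffle relocates every significant transient, shape-preserved,
    to a uniformly random start on the compressed valid time base without
    overlap, then recomputes the boxcar-smoothed map.  If transients
    occupy more than half the valid time (overlap-free placement may
    fail), or when ``mode='rotate'``, a circular rotation of the
    compressed trace is used instead.
    """
    rng = np.random.default_rng(seed)
    if valid is None:
        valid = behavior.run_mask
    comp = np.asarray(sig, dtype=float)[valid]
    T = comp.shape[0]
    if T == 0:
        raise ValueError("no valid frames")
    bins = position_bins(behavior.position, behavior.track_length, n_bins)[valid]
    occ = np.bincount(bins, minlength=n_bins).astype(float)
    occ_safe = np.maximum(occ, 1)

    segs = _segments(comp)
    if not segs:
        raise ValueError("no significant transients to shuffle")
    seg_vals = [comp[s:e] for s, e in segs]
    lens = np.array([e - s for s, e in segs])
    total = int(lens.sum())

    if mode == "relocate" and total > 0.5 * T:
        mode = "rotate"

    maps = np.zeros((n_shuffles, n_bins))
    if mode == "relocate":
        free = T - total
        n_seg = len(segs)
        all_vals = np.concatenate(seg_vals)
        offsets_within = np.concatenate([np.arange(l) for l in lens])
        seg_of_frame = np.repeat(np.arange(n_seg), lens)
        for s_i in range(n_shuffles):
            order = rng.permutation(n_seg)
            gaps = np.sort(rng.integers(0, free + 1, size=n_seg))
            starts_in_order = gaps + np.concatenate(([0], np.cumsum(lens[order])[:-1]))
            starts = np.empty(n_seg, dtype=np.int64)
            starts[order] = starts_in_order
            new_pos = starts[seg_of_frame] + offsets_within
            np.add.at(maps[s_i], bins[new_pos], all_vals)
    else:
        shifts = rng.integers(0, T, size=n_shuffles)
        idx = (np.arange(T)[None, :] + shifts[:, None]) % T
        for s_i in range(n_shuffles):
            np.add.at(maps[s_i], bins[idx[s_i]], comp)

    maps /= occ_safe[None, :]
    maps[:, occ == 0] = 0.0
    return uniform_filter1d(maps, size=boxcar, axis=1, mode="nearest")


# ---------------------------------------------------------------------------
# place fields
# ---------------------------------------------------------------------------

@dataclass
class PlaceField:
    """One place field on the 80-bin track axis.

    ``core`` bins passed the significance test; ``start``/``end`` include
    the outward extension to 10% of the field peak.  Width for fields
    touching a track edge is twice the peak-to-interior-edge distance.
    """

    start: int
    end: int                       # inclusive bin indices after extension
    core_start: int
    core_end: int
    peak_bin: int
    peak_dff: float
    width_cm: float
    peak_cm: float
    at_track_edge: bool = False


def _extend_field(sm: np.ndarray, start: int, end: int, peak: float):
    """Extend outward while the smoothed map keeps descending and stays
    above 10% of the field peak."""
    n = sm.size
    lo, hi = start, end
    while lo > 0:
        nxt = sm[lo - 1]
        if nxt >= sm[lo] or nxt <= 0.1 * peak:
            break
        lo -= 1
    while hi < n - 1:
        nxt = sm[hi + 1]
        if nxt >= sm[hi] or nxt <= 0.1 * peak:
            break
        hi += 1
    return lo, hi


def detect_place_fields(
    smap: SpatialMap,
    null_stack: np.ndarray,
    behavior: BehaviorSession,
    sig: np.ndarray,
    valid: np.ndarray | None = None,
    min_bins: int = 5,
    max_bins: int = 46,
    traversal_fraction: float = 1.0 / 3.0,
    boxcar: int = 3,
) -> list[PlaceField]:
    """Significant bins -> 5-46-bin contiguous runs -> traversal-activity
    filter (unsmoothed trace restricted to field bins) -> boundary
    extension.  An empty list is a valid outcome."""
    if valid is None:
        valid = behavior.run_mask
    sm = smap.smoothed(boxcar)
    n_sh = null_stack.shape[0]
    need = int(round(0.95 * n_sh))
    sig_bins = (sm[None, :] > null_stack).sum(axis=0) >= need

    bins = position_bins(behavior.position, behavior.track_length, smap.n_bins)
    trav_all = np.unique(behavior.traversal_id[valid])
    fields: list[PlaceField] = []
    for s, e in zip(*find_runs(sig_bins)):
        n_run = e - s
        if not (min_bins <= n_run <= max_bins):
            continue
        in_field = valid & (bins >= s) & (bins < e) & (np.asarray(sig) > 0)
        active_trav = np.unique(behavior.traversal_id[in_field])
        if trav_all.size == 0 or active_trav.size / trav_all.size <= traversal_fraction:
            continue
        core = slice(s, e)
        peak_bin = int(s + np.argmax(sm[core]))
        peak = float(sm[peak_bin])
        lo, hi = _extend_field(sm, s, e - 1, peak)
        at_edge = lo == 0 or hi == smap.n_bins - 1
        bw = smap.bin_width
        peak_cm = float(smap.bin_centers[peak_bin])
        if at_edge:
            interior = smap.bin_centers[hi] if lo == 0 else smap.bin_centers[lo]
            width = 2.0 * abs(peak_cm - float(interior))
            width = max(width, bw)
        else:
            width = (hi - lo + 1) * bw
        fields.append(PlaceField(
            start=lo, end=hi, core_start=s, core_end=e - 1,
            peak_bin=peak_bin, peak_dff=peak, width_cm=float(width),
            peak_cm=peak_cm, at_track_edge=at_edge,
        ))
    return fields


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassLabel:
    """place / active_nonplace / silent with the activity fraction
    (significant time over running time) that decided it."""

    label: str
    activity_fraction: float
    fields: list = field(default_factory=list)


def activity_fraction(sig: np.ndarray, valid: np.ndarray) -> float:
    """Fraction of valid running time with a significant transient."""
    n = int(valid.sum())
    if n == 0:
        return 0.0
    return float((np.asarray(sig)[valid] > 0).sum() / n)


def classify(fields: list, act_fraction: float, threshold: float = 0.01) -> ClassLabel:
    """>= 1 field -> place; else < 1% active time -> silent; else
    active_nonplace.  Multi-field units keep all fields."""
    if fields:
        return ClassLabel("place", act_fraction, list(fields))
    if act_fraction < threshold:
        return ClassLabel("silent", act_fraction)
    return ClassLabel("active_nonplace", act_fraction)


def classify_unit(
    sig: np.ndarray,
    behavior: BehaviorSession,
    n_shuffles: int,
    seed: int,
    n_bins: int = 80,
    valid: np.ndarray | None = None,
    boxcar: int = 3,
    activity_threshold: float = 0.01,
    shuffle_mode: str = "relocate",
) -> tuple[ClassLabel, SpatialMap]:
    """Map -> shuffle null -> fields -> label, for one ROI or soma."""
    if valid is None:
        valid = behavior.run_mask
    smap = compute_spatial_map(sig, behavior, n_bins=n_bins, valid=valid)
    act = activity_fraction(sig, valid)
    if act == 0.0 or not (np.asarray(sig)[valid] != 0).any():
        return classify([], act, activity_threshold), smap
    null = shuffle_null(sig, behavior, n_shuffles, seed, n_bins=n_bins,
                        valid=valid, boxcar=boxcar, mode=shuffle_mode)
    fields = detect_place_fields(smap, null, behavior, sig, valid=valid,
                                 boxcar=boxcar)
    return classify(fields, act, activity_threshold), smap


# ---------------------------------------------------------------------------
# dispersion / COM / cross-validated sorting
# ---------------------------------------------------------------------------

def spatial_dispersion(smap: SpatialMap) -> tuple[float, float]:
    """Activity-weighted spread about the center of mass.

    COM (cm) = sum(f_i x_i) / sum(f_i); dispersion (m) =
    sqrt(sum(f_i (COM - x_i)^2) / sum(f_i)) / 100, with x_i the bin
    centers.  All-zero maps are undefined -> (nan, nan).
    """
    f = smap.f
    total = f.sum()
    if total <= 0:
        return float("nan"), float("nan")
    x = smap.bin_centers
    com = float((f * x).sum() / total)
    var_cm2 = float((f * (com - x) ** 2).sum() / total)
    return float(np.sqrt(var_cm2) / 100.0), com


def crossval_sort(per_traversal_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated population display.

    ``per_traversal_maps``: units x traversals x bins.  Sort order is the
    peak position of each unit's first-half mean map (ties by unit
    index); the returned display matrix holds the second-half maps in
    that order.
    """
    maps = np.asarray(per_traversal_maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("expected units x traversals x bins")
    n_trav = maps.shape[1]
    if n_trav < 2:
        raise ValueError("need at least 2 traversals to cross-validate")
    half = n_trav // 2
    first = maps[:, :half].mean(axis=1)
    second = maps[:, half:].mean(axis=1)
    peak_pos = first.argmax(axis=1)
    order = np.lexsort((np.arange(maps.shape[0]), peak_pos))
    return order, second[order]
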