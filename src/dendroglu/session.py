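"""Session bundle data model, on-disk formats, configuration, and validation.

A *session* couples a behavior table (time, linear-track position, velocity,
traversal labels) to one or more fluorescence trace matrices (frames x ROIs)
with per-ROI geometry (branch id, micrometer position along the branch,
parent cell, channel).  Every analysis stage consumes or produces these
types, so all invariants are enforced here once.

On disk a session is a directory::

    session_dir/
        behavior.tsv    time_s, position_cm, velocity_cms, traversal_id, reward_flag
        rois.tsv        roi_id, branch_id, position_um, cell_id, channel
        traces.h5       /traces/raw (frames x ROIs), /traces/background (frames x branches)
        manifest.json   file names, shapes, per-array SHA-256 checksums

Positions are 0-based cm from the track start; ROI positions are the ROI
center's micrometer offset from the branch's proximal end.  Teleports are
encoded as a ``traversal_id`` increment with no interpolated positions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BehaviorSession",
    "RoiTraceSet",
    "AnalysisConfig",
    "ValidationReport",
    "SessionValidationError",
    "read_session",
    "write_session",
    "validate_session",
]

CHANNELS = ("glu", "soma", "gfp")


class SessionValidationError(ValueError):
    """A session bundle violates one of the documented invariants."""


@dataclass
class BehaviorSession:
    """Time-stamped track position/velocity; the clock all traces align to.

    Parameters
    ----------
    time : array of float
        Seconds from session start, uniformly sampled at the frame rate,
        strictly increasing.
    position : array of float
        Track position in cm, within ``[0, track_length]``.
    velocity : array of float
        Running speed in cm/s.
    traversal_id : array of int
        Nondecreasing label, incremented at each teleport back to the
        track start.
    run_mask : array of bool
        True on frames belonging to qualifying run periods (velocity above
        threshold over a stretch covering the minimum distance).
    track_length : float
        Track length in cm (default 300, a 3-m virtual linear track).
    reward_flag : array of bool, optional
        True on reward-delivery frames.
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    traversal_id: np.ndarray
    run_mask: np.ndarray
    track_length: float = 300.0
    reward_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.traversal_id = np.asarray(self.traversal_id, dtype=np.int64)
        self.run_mask = np.asarray(self.run_mask, dtype=bool)
        if self.reward_flag is not None:
            self.reward_flag = np.asarray(self.reward_flag, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    @property
    def frame_rate(self) -> float:
        """Frames per second, from the median sample interval."""
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def n_traversals(self) -> int:
        return int(np.unique(self.traversal_id).size)


@dataclass
class RoiTraceSet:
    """Frames x ROIs raw fluorescence with ROI geometry and channel metadata.

    ``traces`` holds raw fluorescence in detector counts; conversion to
    dF/F happens in :mod:`dendroglu.detection`.  ``roi_table`` has one row
    per trace column, in column order, with fields ``roi_id``,
    ``branch_id``, ``position_um``, ``cell_id`` (nullable) and ``channel``
    (one of ``glu``/``soma``/``gfp``).  ``background`` holds one background
    trace per branch (frames x branches), in ``background_branches`` order.
    """

    traces: np.ndarray
    frame_rate: float
    roi_table: pd.DataFrame
    background: np.ndarray | None = None
    background_branches: list | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise SessionValidationError("traces must be a 2-D frames x ROIs matrix")
        self.roi_table = self.roi_table.reset_index(drop=True)
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background_branches is None:
                raise SessionValidationError(
                    "background given without background_branches"
                )
            self.background_branches = list(self.background_branches)

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_rois(self) -> int:
        return self.traces.shape[1]

    def subtract_background(self) -> "RoiTraceSet":
        """Return a copy with each branch's background trace subtracted
        (timepoint by timepoint) from every ROI on that branch."""
        out = self.traces.copy()
        if self.background is not None:
            col = {b: i for i, b in enumerate(self.background_branches)}
            for j, branch in enumerate(self.roi_table["branch_id"].to_numpy()):
                if branch in col:
                    out[:, j] -= self.background[:, col[branch]]
        return RoiTraceSet(
            traces=out,
            frame_rate=self.frame_rate,
            roi_table=self.roi_table.copy(),
            background=None if self.background is None else np.zeros_like(self.background),
            background_branches=self.background_branches,
        )

    def select(self, mask: np.ndarray) -> "RoiTraceSet":
        """Column subset (boolean or index array over ROIs)."""
        mask = np.asarray(mask)
        return RoiTraceSet(
            traces=self.traces[:, mask],
            frame_rate=self.frame_rate,
            roi_table=self.roi_table.iloc[np.arange(self.n_rois)[mask]].reset_index(drop=True),
            background=self.background,
            background_branches=self.background_branches,
        )


@dataclass
class AnalysisConfig:
    """Named thresholds of the pipeline, each with its documented unit.

    Defaults are the study's values: the 0.40 dF/F amplitude gate, 80
    spatial bins over the track, 3-bin boxcar smoothing, 10000/1000 map
    shuffles (somata/ROIs), 5-46 contiguous significant bins, the >1/3
    traversal-activity requirement, the 1% running-time activity threshold,
    the 20%/70% ICA contribution thresholds and minimum cluster size 4, the
    0.5-s decoder window and the 100-ms coactivation bin.
    """

    amplitude_gate: float = 0.40           # dF/F
    n_bins: int = 80                       # spatial bins over the track
    boxcar_bins: int = 3                   # map smoothing
    n_shuffles_soma: int = 10000
    n_shuffles_roi: int = 1000
    field_min_bins: int = 5
    field_max_bins: int = 46
    traversal_fraction: float = 1.0 / 3.0  # active-traversal requirement
    activity_threshold: float = 0.01       # fraction of running time
    ica_weight_threshold: float = 0.20     # of component peak weight
    ica_contributing_fraction: float = 0.70
    min_cluster_size: int = 4
    max_cluster_size: int = 9
    decoder_dt: float = 0.5                # s
    coactivation_bin_s: float = 0.1        # s
    run_velocity_threshold: float = 4.0    # cm/s
    run_min_distance: float = 40.0         # cm covered per run period
    baseline_window_s: float = 1.5         # +/- s, dendritic percentile baseline
    baseline_window_s_soma: float = 3.0    # +/- s, somatic percentile baseline
    baseline_percentile: float = 8.0
    dim_roi_counts: float = 1.5            # mean-count exclusion threshold
    frame_exclude_pos_std: float = 2.0
    frame_exclude_neg_std: float = 1.0
    onset_sigma_grid: list = field(default_factory=lambda: [2.0, 2.5, 3.0, 3.5, 4.0, 4.5])
    offset_sigma: float = 0.5              # event termination threshold
    fp_ratio_max: float = 0.01             # accepted-class negative/positive ratio
    max_duration_s: float = 1.0            # durations pooled above this
    shuffle_mode: str = "relocate"         # or "rotate"
    occupancy_prior: bool = True           # decoder position prior
    rate_floor: float = 0.01               # frames/s, decoder epsilon
    seed: int = 0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if f.name != "seed" and v <= 0:
                    raise ValueError(f"config field {f.name} must be positive, got {v}")
        if self.shuffle_mode not in ("relocate", "rotate"):
            raise ValueError(f"unknown shuffle_mode {self.shuffle_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of invariant checks; failures are entries, never exceptions."""

    failures: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def __str__(self) -> str:
        lines = [f"{len(self.failures)} failure(s), {len(self.warnings)} warning(s)"]
        lines += [f"FAIL: {f}" for f in self.failures]
        lines += [f"warn: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate_session(
    behavior: BehaviorSession,
    traces: RoiTraceSet,
    velocity_threshold: float = 4.0,
) -> ValidationReport:
    """Check every documented invariant; pure (never mutates inputs)."""
    rep = ValidationReport()
    b, t = behavior, traces

    if b.n_frames == 0:
        rep.failures.append("behavior has zero frames")
        return rep
    if not np.all(np.diff(b.time) > 0):
        rep.failures.append("time not strictly increasing")
    if np.any(b.position < 0) or np.any(b.position > b.track_length):
        rep.failures.append(
            f"position out of range [0, {b.track_length}] cm"
        )
    if np.any(np.diff(b.traversal_id) < 0):
        rep.failures.append("traversal_id decreases")
    if np.any(b.run_mask & ~(b.velocity > velocity_threshold)):
        rep.failures.append(
            f"run_mask true where velocity <= {velocity_threshold} cm/s"
        )
    for name, arr in (
        ("position", b.position),
        ("velocity", b.velocity),
        ("run_mask", b.run_mask),
        ("traversal_id", b.traversal_id),
    ):
        if arr.shape[0] != b.n_frames:
            rep.failures.append(f"behavior field {name} has wrong length")

    if t.n_frames != b.n_frames:
        rep.failures.append(
            f"trace frame count {t.n_frames} != behavior frame count {b.n_frames}"
        )
    if len(t.roi_table) != t.n_rois:
        rep.failures.append("roi_table row count != trace column count")
    else:
        ids = t.roi_table["roi_id"]
        if ids.duplicated().any():
            rep.failures.append("roi_id not unique")
        bad = ~t.roi_table["channel"].isin(CHANNELS)
        if bad.any():
            rep.failures.append(
                f"unknown channel value(s): {sorted(t.roi_table.loc[bad, 'channel'].unique())}"
            )
        for branch, grp in t.roi_table[t.roi_table["channel"] != "soma"].groupby("branch_id"):
            pos = np.sort(grp["position_um"].to_numpy(dtype=float))
            if len(pos) > 1 and not np.allclose(np.diff(pos), 1.0, atol=1e-6):
                rep.warnings.append(
                    f"branch {branch}: ROI spacing is not uniformly 1 um"
                )
    if not np.isfinite(t.traces).all():
        rep.failures.append("traces contain non-finite values")
    if t.background is not None and t.background.shape[0] != t.n_frames:
        rep.failures.append("background trace frame count mismatch")
    return rep


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def _array_checksum(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes()).hexdigest()


def write_session(behavior: BehaviorSession, traces: RoiTraceSet, path) -> dict:
    """Write a session bundle to ``path`` and return its manifest.

    The manifest lists file names, array shapes, and SHA-256 checksums of
    the array contents (so a checksum changes iff any array byte changes).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    beh = pd.DataFrame(
        {
            "time_s": behavior.time,
            "position_cm": behavior.position,
            "velocity_cms": behavior.velocity,
            "traversal_id": behavior.traversal_id,
            "reward_flag": (
                behavior.reward_flag.astype(int)
                if behavior.reward_flag is not None
                else np.zeros(behavior.n_frames, dtype=int)
            ),
        }
    )
    beh.to_csv(path / "behavior.tsv", sep="\t", index=False, float_format="%.17g")
    traces.roi_table.to_csv(path / "rois.tsv", sep="\t", index=False,
                            float_format="%.17g")

    with h5py.File(path / "traces.h5", "w") as h5:
        g = h5.create_group("traces")
        g.create_dataset("raw", data=traces.traces, track_times=False)
        if traces.background is not None:
            g.create_dataset("background", data=traces.background, track_times=False)
            g.attrs["background_branches"] = [str(b) for b in traces.background_branches]
        h5.attrs["frame_rate"] = traces.frame_rate
        h5.attrs["track_length"] = behavior.track_length
        h5.create_dataset("run_mask", data=behavior.run_mask, track_times=False)

    manifest = {
        "files": ["behavior.tsv", "rois.tsv", "traces.h5"],
        "n_frames": int(behavior.n_frames),
        "n_rois": int(traces.n_rois),
        "frame_rate": float(traces.frame_rate),
        "track_length": float(behavior.track_length),
        "checksums": {
            "traces/raw": _array_checksum(traces.traces),
            "behavior": _array_checksum(
                np.column_stack([behavior.time, behavior.position, behavior.velocity])
            ),
        },
        "shapes": {"traces/raw": list(traces.traces.shape)},
    }
    if traces.background is not None:
        manifest["checksums"]["traces/background"] = _array_checksum(traces.background)
        manifest["shapes"]["traces/background"] = list(traces.background.shape)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_session(path) -> tuple[BehaviorSession, RoiTraceSet]:
    """Read and validate a session bundle written by :func:`write_session`.

    Raises ``FileNotFoundError`` naming the missing file, or
    :class:`SessionValidationError` listing failed invariants.
    """
    path = Path(path)
    for fname in ("behavior.tsv", "rois.tsv", "traces.h5"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session bundle missing file: {path / fname}")

    beh = pd.read_csv(path / "behavior.tsv", sep="\t",
                      float_precision="round_trip")
    rois = pd.read_csv(path / "rois.tsv", sep="\t",
                       float_precision="round_trip")
    if "cell_id" in rois.columns:
        rois["cell_id"] = rois["cell_id"].astype("object").where(rois["cell_id"].notna(), None)
    with h5py.File(path / "traces.h5", "r") as h5:
        raw = h5["traces/raw"][()]
        frame_rate = float(h5.attrs["frame_rate"])
        track_length = float(h5.attrs["track_length"])
        run_mask = np.asarray(h5["run_mask"][()], dtype=bool)
        background = None
        background_branches = None
        if "background" in h5["traces"]:
            background = h5["traces/background"][()]
            background_branches = list(h5["traces"].attrs["background_branches"])

    behavior = BehaviorSession(
        time=beh["time_s"].to_numpy(),
        position=beh["position_cm"].to_numpy(),
        velocity=beh["velocity_cms"].to_numpy(),
        traversal_id=beh["traversal_id"].to_numpy(),
        run_mask=run_mask,
        track_length=track_length,
        reward_flag=beh["reward_flag"].to_numpy().astype(bool),
    )
    traces = RoiTraceSet(
        traces=raw,
        frame_rate=frame_rate,
        roi_table=rois,
        background=background,
        background_branches=background_branches,
    )
    report = validate_session(behavior, traces)
    if not report.ok:
        raise SessionValidationError(str(report))
    return behavior, traces
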