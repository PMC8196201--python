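"""Bayesian position decoding from significant-frame counts.

The decoder scores each spatial bin x_i given the vector n of
significant-frame counts per ROI in a Delta-t window:

    p(x_i | n)  proportional to  p_X(x_i) * prod_j f_ij^{n_j} * exp(-Delta_t * sum_j f_ij)

with p_X the (occupancy) position prior and f_ij the training-epoch rate
of significant frames of ROI j in bin i (frames/s, floored at a small
epsilon so unvisited (i, j) pairs do not zero the likelihood).  The
decoded position is the maximum-likelihood bin.  Training uses the first
80% of the session, testing the last 20%, in 0.5-s windows.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .mapping import position_bins
from .session import BehaviorSession

__all__ = [
    "BayesianPositionDecoder",
    "train_decoder",
    "decode_window",
    "evaluate_decoder",
]


class BayesianPositionDecoder(BaseEstimator):
    """Maximum-likelihood position decoder over spatial bins.

    Parameters
    ----------
    n_bins : int
        Spatial bins over the track (shared with the mapping stage).
    dt : float
        Decoding window length in seconds.
    rate_floor : float
        Epsilon floor on f_ij in frames/s.
    occupancy_prior : bool
        Occupancy-based p_X if True, uniform otherwise.

    Fitted attributes: ``rates_`` (bins x ROIs, frames/s), ``prior_``
    (bins,), ``usable_bins_`` (bins visited in training).
    """

    def __init__(self, n_bins: int = 80, dt: float = 0.5,
                 rate_floor: float = 0.01, occupancy_prior: bool = True):
        self.n_bins = n_bins
        self.dt = dt
        self.rate_floor = rate_floor
        self.occupancy_prior = occupancy_prior

    def fit(self, sig: np.ndarray, behavior: BehaviorSession,
            valid: np.ndarray | None = None,
            train_frames: np.ndarray | None = None):
        """Estimate per-bin significant-frame rates and the position prior.

        ``train_frames``: boolean mask of frames in the training epoch
        (defaults to all valid frames).  Bins never visited during
        training are excluded from decoding (tracked in
        ``usable_bins_``).
        """
        sig = np.atleast_2d(np.asarray(sig, dtype=float))
        if sig.shape[0] == 1 and sig.shape[1] == behavior.n_frames:
            sig = sig.T
        if valid is None:
            valid = behavior.run_mask
        if train_frames is None:
            train_frames = np.ones(behavior.n_frames, dtype=bool)
        use = valid & train_frames
        if not use.any():
            raise ValueError("no training frames")
        fps = behavior.frame_rate
        bins = position_bins(behavior.position, behavior.track_length, self.n_bins)
        occ_frames = np.bincount(bins[use], minlength=self.n_bins).astype(float)
        occ_s = occ_frames / fps
        active = (sig > 0).astype(float)
        counts = np.zeros((self.n_bins, sig.shape[1]))
        np.add.at(counts, bins[use], active[use])
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = counts / occ_s[:, None]
        rates[occ_s == 0] = self.rate_floor
        self.rates_ = np.maximum(rates, self.rate_floor)
        self.usable_bins_ = occ_frames > 0
        if self.occupancy_prior:
            prior = occ_frames / occ_frames.sum()
        else:
            prior = np.full(self.n_bins, 1.0 / self.n_bins)
        self.prior_ = prior
        self.frame_rate_ = fps
        self.track_length_ = behavior.track_length
        return self

    def log_likelihood(self, counts: np.ndarray) -> np.ndarray:
        """Per-bin log conditional likelihood for one window's counts."""
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("negative significant-frame counts")
        with np.errstate(divide="ignore"):
            log_prior = np.where(self.usable_bins_, np.log(
                np.maximum(self.prior_, 1e-300)), -np.inf)
        ll = (log_prior
              + (np.log(self.rates_) * counts[None, :]).sum(axis=1)
              - self.dt * self.rates_.sum(axis=1))
        return ll

    def predict(self, counts: np.ndarray) -> np.ndarray:
        """Decoded bin per window; ties resolve to the lowest bin index."""
        counts = np.atleast_2d(counts)
        out = np.empty(counts.shape[0], dtype=int)
        for i, n in enumerate(counts):
            out[i] = int(np.argmax(self.log_likelihood(n)))
        return out

    def predict_cm(self, counts: np.ndarray) -> np.ndarray:
        centers = (np.arange(self.n_bins) + 0.5) * self.track_length_ / self.n_bins
        return centers[self.predict(counts)]


def train_decoder(
    sig: np.ndarray,
    behavior: BehaviorSession,
    split: float = 0.8,
    n_bins: int = 80,
    dt: float = 0.5,
    rate_floor: float = 0.01,
    occupancy_prior: bool = True,
    valid: np.ndarray | None = None,
) -> tuple[BayesianPositionDecoder, np.ndarray]:
    """Fit on the first ``split`` of the session; returns the model and
    the boolean test-epoch frame mask (the remainder)."""
    n = behavior.n_frames
    cut = int(round(split * n))
    train = np.zeros(n, dtype=bool)
    train[:cut] = True
    model = BayesianPositionDecoder(
        n_bins=n_bins, dt=dt, rate_floor=rate_floor,
        occupancy_prior=occupancy_prior,
    ).fit(sig, behavior, valid=valid, train_frames=train)
    return model, ~train


def decode_window(model: BayesianPositionDecoder, counts: np.ndarray):
    """Likelihood over bins and the argmax bin for one window."""
    ll = model.log_likelihood(np.asarray(counts))
    return ll, int(np.argmax(ll))


def window_counts(sig: np.ndarray, frames: np.ndarray, frame_rate: float,
                  dt: float):
    """Slice the test epoch into Delta-t windows; per window the
    significant-frame count per ROI and the member frame indices."""
    idx = np.flatnonzero(frames)
    per = max(int(round(dt * frame_rate)), 1)
    windows = []
    active = np.atleast_2d(np.asarray(sig) > 0)
    if active.shape[0] != sig.shape[0]:
        active = active.T
    for s in range(0, idx.size - per + 1, per):
        w = idx[s:s + per]
        if np.any(np.diff(w) != 1):   # keep windows contiguous in time
            continue
        windows.append((w, active[w].sum(axis=0)))
    return windows


def evaluate_decoder(
    model: BayesianPositionDecoder,
    sig: np.ndarray,
    behavior: BehaviorSession,
    test_frames: np.ndarray,
    valid: np.ndarray | None = None,
) -> dict:
    """Per-window decoded vs true (window-mean) position with absolute
    errors, plus the prior-only chance level on the same windows."""
    if valid is None:
        valid = behavior.run_mask
    frames = test_frames & valid
    if not frames.any():
        raise ValueError("empty test epoch")
    wins = window_counts(sig, frames, model.frame_rate_, model.dt)
    if not wins:
        raise ValueError("test epoch shorter than one decoding window")
    centers = (np.arange(model.n_bins) + 0.5) * model.track_length_ / model.n_bins
    true_pos, decoded, chance = [], [], []
    with np.errstate(divide="ignore"):
        prior_ll = np.where(model.usable_bins_,
                            np.log(np.maximum(model.prior_, 1e-300)), -np.inf)
    chance_bin = int(np.argmax(prior_ll))
    for w, n in wins:
        true_pos.append(float(behavior.position[w].mean()))
        decoded.append(centers[int(np.argmax(model.log_likelihood(n)))])
        chance.append(centers[chance_bin])
    true_pos = np.asarray(true_pos)
    decoded = np.asarray(decoded)
    chance = np.asarray(chance)
    err = np.abs(decoded - true_pos)
    chance_err = np.abs(chance - true_pos)
    return {
        "n_windows": len(wins),
        "true_cm": true_pos,
        "decoded_cm": decoded,
        "abs_error_cm": err,
        "median_error_cm": float(np.median(err)),
        "mean_error_cm": float(err.mean()),
        "chance_median_error_cm": float(np.median(chance_err)),
        "chance_mean_error_cm": float(chance_err.mean()),
    }
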