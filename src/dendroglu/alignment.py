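"""Field-aligned pooling of ROI maps.

ROI maps are re-expressed in units of the parent soma's place-field width,
centered on the somatic field peak (0 = peak; in-field means normalized
distance within +/-0.5).  Because the track is finite, each ROI
contributes data only over the aligned positions its track covers —
missing positions are masked, never zero-filled.  Profiles pool ROI-bin
datapoints into adaptive bins holding similar numbers of points (larger
bins further from the field center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mapping import PlaceField, SpatialMap

__all__ = [
    "AlignedMap",
    "AlignedProfile",
    "align_roi_map",
    "adaptive_bins",
    "pooled_points",
    "total_input_profile",
    "field_coverage_profile",
    "per_field_dff_profile",
    "infield_outfield_test",
]


@dataclass
class AlignedMap:
    """One ROI map on the normalized (somatic field width) axis.

    ``u`` are aligned bin centers, ``values`` the mean dF/F, ``valid``
    masks positions with data.  ``peak_cm``/``width_cm`` retain the
    affine transform so it can be inverted exactly.
    """

    u: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    peak_cm: float
    width_cm: float
    roi_id: object = None
    field_id: object = None
    roi_class: str | None = None

    def to_track_cm(self, u: np.ndarray) -> np.ndarray:
        """Inverse of the alignment: normalized distance -> track cm."""
        return np.asarray(u) * self.width_cm + self.peak_cm


@dataclass
class AlignedProfile:
    """Binned pooled profile: mean +/- SE per adaptive bin."""

    centers: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    count: np.ndarray
    edges: np.ndarray


def align_roi_map(
    roi_map: SpatialMap,
    soma_field: PlaceField,
    bounds_cm: tuple[float, float] | None = None,
) -> AlignedMap:
    """x -> (x - peak) / width on the ROI map's bin centers.

    ``bounds_cm`` truncates the contribution (for multi-field somata: up
    to the edge of the next place field or the track edge).  Raises if
    the somatic field is degenerate (soma not a place cell).
    """
    if soma_field is None or soma_field.width_cm <= 0:
        raise ValueError("parent soma has no place field; cannot align")
    x = roi_map.bin_centers
    u = (x - soma_field.peak_cm) / soma_field.width_cm
    valid = np.ones(x.size, dtype=bool)
    if bounds_cm is not None:
        valid &= (x >= bounds_cm[0]) & (x <= bounds_cm[1])
    return AlignedMap(u=u, values=roi_map.f.copy(), valid=valid,
                      peak_cm=soma_field.peak_cm, width_cm=soma_field.width_cm)


def adaptive_bins(u: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin edges at empirical quantiles of |u|, mirrored about 0, so each
    bin holds a similar number of datapoints (bins widen away from the
    field center)."""
    u = np.asarray(u, dtype=float)
    u = u[np.isfinite(u)]
    if u.size < n_bins:
        raise ValueError(f"need at least {n_bins} datapoints, got {u.size}")
    hi = float(np.abs(u).max()) + 1e-9
    if n_bins == 1:
        return np.array([-hi, hi])
    m = max(n_bins // 2, 1)
    qs = np.quantile(np.abs(u), np.linspace(0, 1, m + 1))
    qs[0], qs[-1] = 0.0, hi
    qs = np.maximum.accumulate(qs)
    # nudge exact duplicates so edges stay strictly increasing
    for i in range(1, qs.size):
        if qs[i] <= qs[i - 1]:
            qs[i] = qs[i - 1] + 1e-9
    return np.concatenate([-qs[::-1], qs[1:]])


def pooled_points(aligned_maps: list[AlignedMap],
                  classes: tuple = ("place", "active_nonplace")):
    """Concatenate (u, value) datapoints over ROIs of the given classes."""
    us, vals = [], []
    for am in aligned_maps:
        if am.roi_class is not None and am.roi_class not in classes:
            continue
        us.append(am.u[am.valid])
        vals.append(am.values[am.valid])
    if not us:
        raise ValueError("no aligned maps of the requested classes")
    return np.concatenate(us), np.concatenate(vals)


def _bin_profile(u, values, edges) -> AlignedProfile:
    idx = np.digitize(u, edges) - 1
    nb = edges.size - 1
    mean = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    for b in range(nb):
        v = values[idx == b]
        count[b] = v.size
        if v.size:
            mean[b] = v.mean()
            se[b] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AlignedProfile(centers=centers, mean=mean, se=se, count=count,
                          edges=edges)


def total_input_profile(
    aligned_maps: list[AlignedMap],
    classes: tuple = ("place", "active_nonplace"),
    n_bins: int = 40,
    edges: np.ndarray | None = None,
) -> AlignedProfile:
    """Mean +/- SE dF/F per aligned bin over all active (place and
    active-nonplace) ROIs; silent-ROIs are excluded by the class filter.
    SE pools ROI-bin datapoints."""
    u, vals = pooled_points(aligned_maps, classes)
    if edges is None:
        edges = adaptive_bins(u, n_bins)
    return _bin_profile(u, vals, edges)


def field_coverage_profile(
    roi_fields: list[dict],
    n_bins: int = 20,
    edges: np.ndarray | None = None,
) -> AlignedProfile:
    """Percentage of place-ROIs whose ROI field covers each aligned bin.

    ``roi_fields``: one dict per place-ROI with keys ``field_u``
    (list of (lo, hi) aligned intervals of its fields) and ``data_u``
    ((lo, hi) aligned span the ROI has data for).  Per bin:
    100 * (#ROIs with a field covering the bin center) /
    (#ROIs with valid data at the bin center).
    """
    if not roi_fields:
        raise ValueError("no place-ROIs to profile")
    if edges is None:
        pts = np.concatenate([
            np.asarray(r["data_u"], dtype=float) for r in roi_fields
        ])
        edges = adaptive_bins(pts, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    covered = np.zeros(centers.size)
    have_data = np.zeros(centers.size)
    for r in roi_fields:
        lo_d, hi_d = r["data_u"]
        in_data = (centers >= lo_d) & (centers <= hi_d)
        have_data += in_data
        hit = np.zeros(centers.size, dtype=bool)
        for lo, hi in r["field_u"]:
            hit |= (centers >= lo) & (centers <= hi)
        covered += hit & in_data
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * covered / have_data
    pct[have_data == 0] = np.nan
    se = np.full(centers.size, np.nan)
    ok = have_data > 0
    p = pct[ok] / 100.0
    se[ok] = 100.0 * np.sqrt(np.maximum(p * (1 - p), 0) / have_data[ok])
    return AlignedProfile(centers=centers, mean=pct, se=se,
                          count=have_data.astype(int), edges=edges)


def per_field_dff_profile(
    roi_fields: list[dict],
    n_bins: int = 20,
    edges: np.ndarray | None = None,
) -> AlignedProfile:
    """Mean dF/F per place-ROI field versus aligned position.

    Each field contributes its single field-mean dF/F at every aligned
    position it covers; per bin the values of covering fields are
    averaged (bins nothing covers are missing).  ``roi_fields`` entries
    need ``field_u`` intervals zipped with ``field_mean_dff`` values.
    """
    if not roi_fields:
        raise ValueError("no place-ROI fields to profile")
    intervals, means = [], []
    for r in roi_fields:
        for (lo, hi), m in zip(r["field_u"], r["field_mean_dff"]):
            intervals.append((lo, hi))
            means.append(m)
    if edges is None:
        pts = np.asarray(intervals, dtype=float).ravel()
        edges = adaptive_bins(pts, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = np.full(centers.size, np.nan)
    se = np.full(centers.size, np.nan)
    count = np.zeros(centers.size, dtype=int)
    for b, c in enumerate(centers):
        vals = [m for (lo, hi), m in zip(intervals, means) if lo <= c <= hi]
        count[b] = len(vals)
        if vals:
            v = np.asarray(vals)
            mean[b] = v.mean()
            se[b] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return AlignedProfile(centers=centers, mean=mean, se=se, count=count,
                          edges=edges)


def infield_outfield_test_rois(
    aligned_maps: list[AlignedMap],
    classes: tuple = ("place", "active_nonplace"),
    infield_halfwidth: float = 0.5,
):
    """In/out-of-field comparison with the ROI as the sampling unit.

    Bins of a pooled profile share contributing ROIs and are therefore
    correlated; this variant pairs each ROI's mean dF/F inside the somatic
    field (|u| <= 0.5) with its mean outside and tests the mean paired
    difference across ROIs (two-sided one-sample t).  ROIs are
    independent units, and the difference distribution is strongly
    skewed, which rules out the signed-rank's symmetry assumption.
    """
    in_means, out_means = [], []
    for am in aligned_maps:
        if am.roi_class is not None and am.roi_class not in classes:
            continue
        u = am.u[am.valid]
        v = am.values[am.valid]
        inside = np.abs(u) <= infield_halfwidth
        if inside.any() and (~inside).any():
            in_means.append(float(v[inside].mean()))
            out_means.append(float(v[~inside].mean()))
    if not in_means:
        raise ValueError("no ROI has data on both sides of the field edge")
    a = np.asarray(in_means)
    b = np.asarray(out_means)
    diff = a - b
    if np.all(diff == diff[0]):
        stat, p = float("nan"), 1.0
    else:
        stat, p = stats.ttest_1samp(diff, 0.0)
    return {
        "in_mean": float(a.mean()), "out_mean": float(b.mean()),
        "n_rois": int(a.size), "statistic": float(stat), "p": float(p),
    }


def infield_outfield_test(profile: AlignedProfile, infield_halfwidth: float = 0.5):
    """Two-sided rank-sum on per-bin values grouped by |distance| <= 0.5
    (one somatic field width centered on the peak) vs outside."""
    ok = np.isfinite(profile.mean)
    c, v = profile.centers[ok], profile.mean[ok]
    inf = np.abs(c) <= infield_halfwidth
    a, b = v[inf], v[~inf]
    if a.size == 0 or b.size == 0:
        raise ValueError("one of the in/out-of-field groups is empty")
    result = {
        "in_mean": float(a.mean()),
        "out_mean": float(b.mean()),
        "n_in": int(a.size),
        "n_out": int(b.size),
        "degenerate": bool(a.size < 2 and b.size < 2),
    }
    if result["degenerate"]:
        result["statistic"], result["p"] = float("nan"), 1.0
        return result
    stat, p = stats.ranksums(a, b)
    result["statistic"], result["p"] = float(stat), float(p)
    return result
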