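# Methods

`dendroglu` analyzes micron-scale dendritic glutamate imaging (iGluSnFR)
recorded while an animal runs a virtual linear track. This note documents
the models and procedures each stage implements, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Signal model and dF/F

Raw traces are per-ROI mean pixel counts with a per-branch background
trace subtracted timepoint by timepoint. Slow trends (photobleaching,
on the order of 16% per 5 min) are removed by a sliding-percentile
baseline: F0(t) is the 8th percentile of F in a centered ±1.5 s window
(±3 s for somatic traces, whose indicator kinetics are slower), and
dF/F = (F − F0)/F0. Windows are truncated at the trace edges rather than
padded — padding would fabricate data. ROIs whose baseline is ever
nonpositive are flagged and excluded.

QC exclusions: ROIs at branch ends (most prone to out-of-plane motion);
ROIs with mean fluorescence below 1.5 counts (too dim for a stable
ratio); and frames where the field-mean fluorescence deviates more than
+2 STD or −1 STD from its mean (out-of-plane motion affecting many ROIs
at once). The frame rule is applied to the field-mean trace after
removing its slow trend with a wide (20 s) rolling median: the rule
targets fast movements, and on a bleaching trace the trend otherwise
dominates the STD and flags ordinary late-session frames wholesale.
Excluded frames are dropped from statistics but do not split run
periods.

Only run periods count: velocity above 4 cm/s sustained over a stretch
covering more than 40 cm of track.

## Significant-transient detection

The detector is the positive/negative transient-ratio criterion. Noise
sigma per ROI is estimated from the positive-going deviations about the
trace mean (keeping that mean in the calculation), which avoids the
floor-effect underestimate on baseline-corrected traces. Candidate
events are contiguous excursions above 0.5 sigma (about the mean) that
reach at least 2 sigma, in both polarities; each is classed by peak
amplitude (2, 2.5, 3, 3.5, 4, ≥4.5 sigma) and duration (1-frame steps up
to 1 s, pooled above). Counts are pooled over ROIs. A class is accepted
when its negative/positive count ratio is below 0.01 — events in
accepted classes have under a 1% chance of arising from noise, which the
acceptance battery verifies directly on pure-noise traces. The exact
grid of the originally cited ratio analysis is not published; this grid
is recorded in `AnalysisConfig` so it is auditable, and the false-positive
guarantee is enforced by test rather than assumed.

Significant events additionally need a peak of at least 0.40 dF/F
(inclusive — "minimum amplitude threshold" reads as ≥). The significant
transient-only trace equals dF/F inside significant events and zero
elsewhere; every downstream statistic consumes this trace. Event
duration is the full excursion duration; peak is the maximum dF/F within
it.

Event dendritic extent is computed per branch (≥ 8 ROIs) on a ROI ×
100-ms-bin matrix: events are connected components of co-active
(nonzero) cells; length is the largest number of contiguous co-active
ROIs at any time point of the event, peak the maximum dF/F among those
ROIs at those time points. Mean input per ROI is the trapezoidal
integral of the significant-only trace over valid time divided by valid
seconds.

## Spatial maps and place fields

Maps are means of the significant-only trace over 80 equal position bins
(half-open, last bin closed), valid run frames only; empty bins are zero
with zero occupancy. Field statistics use a 3-bin boxcar smoothing
(nearest-edge handling).

The null model relocates every transient — shape preserved — to a
uniformly random, overlap-free start time on the compressed valid time
base, then recomputes the smoothed map (1000 shuffles for ROIs, 10000
for somata). Overlap-free placement uses the standard sorted-gap
construction; if transients occupy more than half the valid time the
shuffle falls back to circular rotation (logged via the config). A bin
is significant when its smoothed value exceeds the corresponding bin in
at least 95% of shuffles (strictly greater, per the 9500-of-10000 rule).

A place field is a run of 5–46 contiguous significant bins that contains
a significant transient on more than 1/3 of traversals (tested on the
unsmoothed trace restricted to field bins — smoothing is a map-level
operation only). Field bounds extend outward while the smoothed map
keeps descending and stays above 10% of the field peak. Fields touching
a track edge are flagged and their width is twice the peak-to-interior-
edge distance; otherwise width is the extended bin span. Units with at
least one field are *place*; otherwise *silent* if significant transients
occupy less than 1% of running time, else *active-nonplace*. Multi-field
units keep every field.

Spatial dispersion is the activity-weighted spread about the map's
center of mass, COM = Σ f_i x_i / Σ f_i, dispersion =
sqrt(Σ f_i (COM − x_i)² / Σ f_i). The defining expression is a variance
(cm²); the reported quantity is its square root converted to meters,
matching how dispersion is quoted in the field (fractions of a meter on
a 3-m track).

Cross-validated population displays sort units by the peak position of
their first-half-of-session mean map and display the second-half maps;
ties break by unit index so reruns are stable.

## Field-aligned pooling

Each ROI map is re-expressed in units of its parent soma's place-field
width, centered on the somatic field peak: u = (x − peak)/width;
in-field means |u| ≤ 0.5. The transform is affine and exactly
invertible; aligned positions the track does not cover are masked, never
zero-filled. For multi-field somata each field is treated separately,
truncated at the next field or the track edge. Profiles pool ROI-bin
datapoints into adaptive bins — edges at quantiles of |u| mirrored about
zero — so each bin holds a similar number of points (bins widen away
from the field center). Total-input profiles average over place and
active–nonplace ROIs (silent excluded); coverage profiles report the
percentage of place-ROIs whose ROI field covers each bin among those
with data there; per-field profiles assign each field its mean dF/F over
its span.

Two in/out-of-field tests are provided. The profile-level test is a
two-sided rank-sum on per-bin values grouped by |u| ≤ 0.5, the form the
field reports. For simulation studies a calibrated variant is also
provided: per-bin values of one pooled profile share contributing ROIs
and are correlated, which inflates the rank-sum false-positive rate, so
the cohort-level test pairs each ROI's in-field mean with its own
out-of-field mean and applies a one-sample t test to the paired
differences — ROIs are independent units under the generator, and a t
test (unlike the signed-rank) does not assume the strongly skewed
difference distribution is symmetric. The acceptance battery uses the
ROI-paired form for exactly this reason.

## Functional dendritic organization

Pairwise Pearson correlations between active ROIs (> 1 µm apart on one
branch; silent excluded) are computed on mean maps (spatial mode) or
100-ms-binned significant-only traces (temporal mode), binned at 1 µm
from 2–30 µm; inter-dendrite pairs use Euclidean distance across
co-recorded branches. Falloffs are fit with A·exp(−d/τ) + c from three
deterministic starts; a nested fit shares τ across groups with per-group
A and c (τ profiled by bounded scalar minimization, A and c by linear
least squares). Under stationary Gaussian noise with one shared sigma,
the likelihood ratio is (N − p)·ln(RSS_nested/RSS_full) — the (N − p)/N
Bartlett-style factor keeps the chi-square reference honest at these bin
counts (calibration is verified at ~5% over 200 simulations). Groups
with no resolvable decay (amplitude indistinguishable from flat) are
flagged and excluded from the comparison.

Functional clusters: per branch with more than 8 active ROIs, the ROI ×
100-ms activity matrix is decomposed with FastICA using PCA as the
initial guess (identity rotation on the whitened principal components),
for component counts k = 2 up to half the active-ROI count, scanning
while the detected-cluster count is nondecreasing (stop at first
decrease; switchable). Each component is sign-aligned so its
largest-magnitude weight is positive — clamping is meaningless without a
sign convention — then projected to the Frobenius-nearest nonnegative
matrix, which is the element-wise clamp at zero (verified against a
quadratic-program oracle). Weights are normalized by the component peak;
ROIs above 20% of peak are contributing; clusters are groups of ≥ 4
contributing ROIs with at most single-ROI gaps and ≥ 70% of the spanned
ROIs contributing (gap ROIs count in the denominator). Duplicate member
sets across k keep the smallest-k weights. ICA seeds derive from the
global seed per (branch, k) so cluster sets are reproducible.

The shuffle control permutes the ROI (row) order 1000 times. PCA/ICA is
invariant to row order, so the permutation is applied to the fitted
weight matrices and only the spatial grouping and k-scan are re-run —
mathematically identical to refitting on the permuted matrix and what
makes 1000 shuffles tractable. Controls are reported per branch and
pooled across branches (the pooled original count versus per-shuffle
pooled null is the form in which planted structure exceeds every
shuffle). Cluster traces are component-weighted sums of member
significant-only traces; activations are 100-ms bins where the trace is
positive; coactivation is the fraction of members active in such a bin,
with the > 70% level defining high coactivation. Nonanatomical
components are those whose contributing ROIs form ≥ 4 isolated groups of
1–3 ROIs separated by ≥ 2 ROIs.

## Bayesian position decoding

With p_X the occupancy prior (uniform available in config) and f_ij the
training-epoch rate of significant frames of ROI j in bin i, a Δt = 0.5 s
window with counts n scores
log p(x_i | n) = log p_X(x_i) + Σ_j n_j log f_ij − Δt Σ_j f_ij,
decoded position = argmax (ties to the lowest bin). Rates are floored at
ε = 0.01 frames/s because an unvisited (i, j) with n_j > 0 would
otherwise zero the likelihood. Training uses the first 80% of the
session, testing the last 20%; windows are contiguous runs of valid test
frames; the error is |decoded − window-mean true position|, with chance
defined by decoding the same windows from the prior alone.

## Synthetic sessions

The generator renders full bundles (behavior, dendritic and somatic
traces, ground truth). Behavior: Ornstein–Uhlenbeck-smoothed running at
25 ± 3 cm/s with exponential pauses (hazard 0.02/s, mean 2 s), a reward
and 1-s hold at the 300-cm track end, then teleport to the start.
Defaults give roughly 18–20 traversals in a 5-min, 30-Hz session.

ROI classes are drawn per cell type (place cells 19/41/40% place/
active-nonplace/silent, nonplace cells 11/56/34%, renormalized — the
printed percentages sum to 101% from independent rounding). Place-ROI
tuning is Gaussian over position with full field width drawn from
N(59.5, 14.5) cm (clipped to 20–120 cm); a width-w field corresponds to
Gaussian sd w/4.3 so the 10%-of-peak bounds match the width. Tuning
centers may lie up to half a width off-track: edge-truncated fields are
real (and explicitly retained in the field's analyses), and confining
centers to the track would depress the pooled input rate near track
edges — an artifact that by itself produces in-field > out-of-field on
aligned profiles. In place cells, center density is 1.6× higher inside
the somatic field than outside (the in-field enrichment factor);
`cluster_cotuning` controls whether planted clusters share the somatic
field center (default) or tune independently — the enrichment-off control
condition must switch both off to be a true null. With iid center
sampling each cohort's realized in/out coverage additionally fluctuates
(a binomial draw of field placements), so the control condition also
offers `stratified_tuning`: per-branch centers spread evenly (with
jitter) over the extended track, making the realized — not only the
expected — composition balanced.

Event rates are the one set of parameters the source conditions do not
fix: place-ROIs fire Poisson events at 0.8 Hz at field peak and 0.01 Hz
elsewhere during running; active-nonplace ROIs at 0.2 Hz; cluster
activations at 0.15 Hz (co-tuned) with 0.3 member participation, giving
~20% mean coactivation at sizes 4–9; somata at 1.2/0.3 Hz. These were
chosen once so a session yields tens of transients per active ROI —
the order of magnitude real sessions show — and are not tuned per test.

Transients are instantaneous rises with exponential decay; the decay
constant is τ = duration / ln(amplitude/noise-sigma), i.e. the drawn
duration is the time to fall to the 1-sigma noise floor, where an event
becomes indistinguishable from noise. Amplitudes and durations are
truncated lognormals moment-matched to 1.11 ± 0.65 dF/F and 0.35 ± 0.21 s
and drawn independently (no joint distribution is available). Each
non-cluster event draws a dendritic extent from the 76/15/6/3% mixture
(1/2/3/≥4 ROIs) and is copied to adjacent ROIs with independently drawn
amplitudes. Traces are scaled to counts as
baseline × (1 + dF/F + N(0, 0.19)) × bleach(t) with a single-exponential
bleach of 15.9% per 5 min, plus a per-branch background. The GFP mode
renders noise and bleach only.

What the generator does not emulate: motion artifacts (the ±2/−1 STD
frame rule therefore excludes only the Gaussian tail, ~16% of frames,
rather than rare artifact frames), pixel-level structure, joint
amplitude–duration dependence, theta-timescale temporal structure, and
any postsynaptic coupling. Passing tests demonstrate that the pipeline
recovers planted structure under in-vivo-like amplitude/duration/noise
statistics — not that real tissue obeys the generator's independence
assumptions.

## Problem sizes and runtime choices

Test and acceptance workloads use 5-min, 30-Hz sessions (the scale of
the real recordings): 200 noise ROIs for the false-positive bound,
50 + 50 planted ROIs at 1000 shuffles for field recovery, 20 seeds /
1000 shuffles for cluster recovery and control, 200 simulations for the
LR and rank-sum calibrations, and 20 cohorts of 40 place cells per
condition for the enrichment direction study. Somatic classification
inside simulation studies uses the 1000-shuffle ROI setting; the 10000-
shuffle somatic default applies to real sessions.

## Known limitations

- The transient-ratio class grid is a reconstruction; only its
  false-positive property (< 1%) is guaranteed, not bin-for-bin identity
  with the originally cited analysis.
- The decay of the transient kernel displaces map mass slightly in the
  running direction (~1 bin at 25 cm/s), so detected field peaks sit a
  small distance downstream of planted centers.
- Decoding assumes independent ROI counts given position; planted
  clusters and multi-ROI events violate independence, which flattens but
  does not invalidate the likelihood.
- The profile-level rank-sum is reported because it is the field's
  convention; its per-bin values are not independent samples, and the
  calibrated ROI-paired variant should be preferred for inference on
  simulated cohorts.
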