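# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic generators do and do not emulate, and
the known limitations.

## Sarcomere FFT scoring

A striation profile is a 1-D fluorescence signal I(x) sampled uniformly
(`pixel_um` per sample, ≥16 samples) along a myofibril. The spectrum is
computed as: subtract the mean, multiply by a periodic Hann window, zero-pad
4×, take the real FFT. The reported "power" is the window-compensated
amplitude spectrum `2|X|/Σw`, so a pure cosine of amplitude A produces a
main peak of height A and the unit-amplitude calibration equals 1.0. Two
score contracts coexist deliberately: the raw peak power scales linearly
with staining gain (comparable only across identically acquired images),
while `regularity_score(..., normalize="amplitude")` divides by the
profile amplitude `(max−min)/2` and is gain-free.

The main peak is the maximum-power bin whose period lies in the search
band (default 1.0–5.0 µm, bracketing the ~2 µm physiological spacing and
pathologically lengthened spacings; the band is clipped to the Nyquist
period and profile length). The period is the reciprocal of that bin's
frequency — no sub-bin interpolation, so the period resolution is one
zero-padded frequency bin (≈0.01 µm at 2 µm, ≈0.05 µm at 2.7 µm for a
40 µm profile at 0.1 µm/px). Exact power ties resolve to the lowest
frequency. A constant profile yields an explicit no-periodicity result
that scores 0 with a warning. Windowing and padding are our choices to
control leakage while keeping peak localization; absolute power values
are therefore comparable only within this implementation.

Profiles can be extracted from 2-D images by bilinear interpolation along
a user-supplied line (0-based pixel-center coordinates), averaging an odd
number of parallel offset lines; out-of-bounds samples are rejected
rather than padded.

## Calcium transient analysis

Traces are uniform-grid time series (1% relative step tolerance, ≥2 s).
ΔF/F0 uses F0 = a low percentile of the trace (default 10th, a robust
diastolic proxy); the Fura-2 ratio is `(F340−bg340)/(F380−bg380)` with a
hard error if the denominator is ever non-positive.

**Detection.** Candidate peaks come from a moving-average-smoothed copy
(default 0.3 s — noise suppression only; reduce for rhythms faster than
~2 Hz), requiring prominence ≥ 0.3 × the 5–95 percentile span and
separation ≥ 0.25 s, then each candidate is refined to the raw-signal
maximum within the smoothing window. On noiseless input the refined peaks
are exact; detection is thus stable across noise realizations down to
SNR ≈ 5 while kinetics are always measured on raw samples.

**Segmentation.** Per peak: the local diastolic level is the mean over
the 100 ms ending at the pre-peak minimum; onset is the last upward
crossing of diastolic + 10% of amplitude before the peak, located to
sub-sample precision by linear interpolation. The 10% foot is a standard
transient-onset convention that keeps time-to-peak well defined on noisy
data — reported TTP is therefore onset(10%)→peak, which for a half-cosine
rise equals 0.795× the geometric rise time. Beat windows are half-open
`[onset_k, onset_{k+1})`; the final beat is flagged incomplete when its
decay is truncated above 1/e of amplitude. Per-beat local baselines make
the metrics robust to slow drift; a global-minimum diastolic is not used.

**Decay fit.** `y(t) = A·exp(−(t−t_peak)/τ) + C` by Levenberg–Marquardt,
initialized from a log-linear fit of `y − diastolic`, on the window from
the peak to the earlier of the next onset and the first sample within 5%
of the diastolic level. Fits with fewer than 5 decay samples, τ ≤ 0 or
τ longer than the beat window are reported missing with a reason code.
The fitted offset C absorbs baseline shifts, so τ is invariant to
constant offsets and tolerant of ≲1%/s linear drift (verified <3% shift).

**Summaries.** Beating rate = (n−1)/(span of peak times); interval SD is
the sample SD (n−1 denominator) of successive peak-to-peak intervals,
computed in sample-index space so that exactly equal intervals give an
SD of exactly zero; an interval is an irregular event when it deviates
more than 25% (configurable) from the median interval — both the SD and
the event fraction are emitted since either may serve as the arrhythmia
readout. Kinetic means use complete beats only. Rates are reported in Hz
and bpm; all times in seconds.

## Mitochondrial morphometry and ROS

Segmentation: 3×3 median filter, Otsu (or fixed) threshold, removal of
components <4 px. Morphometry: topological skeletonization
(scikit-image), pixel taxonomy by 8-neighbor count — endpoint (1), slab
(2), junction (≥3) — with 8-connected junction pixels merged into one
junction node so 2×2 junction clusters do not inflate branch counts.
Components without a junction are individuals; with ≥1 junction,
networks. Branches are maximal slab paths between nodes (closed loops
count as a single branch); lengths sum 1 per axial and √2 per diagonal
step. Footprint is the mask area. Pixel units by default; µm/µm² when
`pixel_um` is given. The branch taxonomy is exactly invariant to
rotations/reflections of a given skeleton; the skeletonizer itself is
only near-equivariant at mask level (end retraction of ~1 px per rounded
cap, occasional diagonal-step substitutions), which bounds agreement
with layout ground truth to a couple of pixels per branch.

ROS: mitochondrial superoxide = mean MitoSOX / mean MitoTracker over the
same mask (gain-ratio invariant, optional background subtraction);
cytosolic ROS = mean CellROX intensity over a cell mask (linear in gain,
hence "relative" fluorescent units). Masks are user-supplied or derived
from the tracker channel; no nuclei-based cell splitting.

## Quantification statistics

2^−ΔΔCT with ΔCT = CT_target − CT_reference per condition; swapping
sample and control inverts the fold change. Band ratios are plain
intensity ratios, with `normalize_to_control` mapping the control-group
mean to exactly 1. Pairwise comparisons are two-sided two-sample t-tests
(pooled variance by default — the classical post-hoc convention — Welch
optional since the source protocols rarely state which was used).
Holm–Šidák is implemented directly: sort raw p ascending, adjust the
i-th to `1−(1−p_(i))^(m−i+1)`, enforce monotonicity by running maximum.
Tukey adjusted p-values use the studentized range over all groups
(scipy), with the pooled pairwise t as the raw p; because Tukey pools
the MSE across all groups its p can in edge cases dip below the two-group
raw p, so adjusted values are clipped to ≥ raw. A full two-way ANOVA
decomposition is deliberately out of scope: every reported contrast is a
pairwise comparison with adjustment, which reproduces the decision
structure without re-deriving unpublished design matrices.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (seed, params); truth is attached
to every artifact and written as a JSON sidecar by the CLI.

* **Striation profiles** — `baseline + amplitude·cos(φ) + ε`, with φ
  advancing 2π·pixel/period per sample plus a cumulative Gaussian phase
  walk (SD `jitter_sigma` per period). The cumulative walk, not i.i.d.
  phase noise, is chosen so disorder destroys long-range periodicity the
  way sarcomere disarray does. Default conditions for protocol-level
  checks: 0.1 µm pixels, 40 µm length, jitter 0.03 rad/period, noise 10%
  of amplitude — "moderate disorder" for a healthy cell.
* **Calcium traces** — beats rise from the diastolic level by a
  half-cosine ramp over `ttp_s` (smooth, monotone, unambiguous peak at
  onset+ttp; the measured feature set, not a biophysical release model)
  and decay monoexponentially with `tau_s`. Defaults mirror the paced
  protocol: 0.5 Hz stimulation sampled at 50 Hz. Successive intervals
  get i.i.d. Gaussian jitter (so the interval SD estimator should
  recover the jitter SD exactly), floored at `ttp+tau` to guarantee
  non-overlap; an optional ectopic-beat probability inserts mid-diastole
  beats, off by default. Noise is additive white Gaussian; drift linear.
* **Fura-2 pairs** — `F380 = bg + B`, `F340 = bg + ratio·B` plus noise;
  the noiseless pair inverts exactly under background-corrected division.
* **Mitochondrial images** — straight-segment skeleton layouts (split
  automatically where a segment endpoint touches another segment, so
  T-junctions are expressible), dilated, blurred, noised; layouts whose
  components merge when drawn are rejected because the truth would be
  ambiguous. Branch-length truth uses the Bresenham chain length.
* **ROS pairs** — uniform in-mask levels plus noise.

Not emulated: photophysics (bleaching beyond linear drift, dye
saturation), motion, cell segmentation, full-resolution 2048² videos
(small frames and ≤ minutes of trace suffice for parameter recovery),
curved or branched myofibrils, 3-D stacks. Passing tests therefore
demonstrate correct recovery of the stated signal models under additive
noise — not robustness to every artifact of live-cell imaging.

## Problem sizes and determinism

Protocol-level checks use 20-seed batches of 40 µm profiles, 60 s traces
at 50 Hz, 50-seed Monte-Carlo batches for monotonicity properties and a
2000-replicate null for family-wise error control — sizes at which every
estimate is stable to well inside its acceptance tolerance. All suite
randomness is seeded (hypothesis runs derandomized); `scripts/acceptance.py`
derives every generator seed from its `--seed` argument.

## Known limitations

* Period resolution is bin-quantized (no peak interpolation) by design,
  to keep the period/power invariants exact; at 2.7 µm this contributes
  up to ~±0.025 µm.
* The detection smoothing default (0.3 s) assumes ≤~2 Hz rhythms.
* Tukey p-values require all groups to enter the pooled MSE; comparisons
  among a subset are still adjusted against the full group set.
* Skeleton statistics inherit the skeletonizer's end-retraction and
  junction-clustering discretization; counts are exact on clean layouts,
  lengths are accurate to a few pixels.
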