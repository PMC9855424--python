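"""Calcium-transient kinetics and arrhythmia statistics from fluorescence traces.

Extracts per-beat features (time to peak, monoexponential decay tau,
amplitude, diastolic level) and per-cell summaries (beating rate,
beat-interval SD, irregular-event fraction) from single-dye ``ΔF/F0``
traces or ratiometric Fura-2 340/380 traces.

The analysis chain is::

    Trace -> detect_beats -> segment_transients -> fit_decay_tau -> summarize_trace

``extract_beats`` runs detection/segmentation/fitting in one call.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, signal

__all__ = [
    "Trace",
    "Beat",
    "TraceSummary",
    "compute_dff",
    "compute_ratio",
    "detect_beats",
    "segment_transients",
    "fit_decay_tau",
    "extract_beats",
    "summarize_trace",
]

log = logging.getLogger(__name__)

_SIGNAL_KINDS = ("raw", "dff", "ratio")


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled single-cell calcium signal.

    Parameters
    ----------
    time_s : array
        Sample timestamps in seconds, uniform grid starting at the first
        frame center. Uniformity is enforced within 1% relative step
        tolerance.
    values : array
        Signal values: raw fluorescence, ΔF/F0 (dimensionless) or a
        340/380 excitation ratio, per ``signal_kind``.
    signal_kind : {"raw", "dff", "ratio"}
    name : str, optional
        Cell/ROI label carried through to outputs.
    """

    time_s: np.ndarray
    values: np.ndarray
    signal_kind: str = "raw"
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "values", v)
        if self.signal_kind not in _SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {_SIGNAL_KINDS}")
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("time_s and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise ValueError("trace contains non-finite samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > 0.01 * step:
            bad = int(np.argmax(np.abs(dt - step)))
            raise ValueError(
                f"non-uniform time grid: step at row {bad + 1} is {dt[bad]:.6g} s, "
                f"expected {step:.6g} s"
            )
        # >= 2 s of data: shorter snippets cannot carry a beat interval
        if t.size < 2.0 / step:
            raise ValueError(
                f"trace too short: {t.size} samples at {1.0 / step:.3g} Hz "
                "(need at least 2 s)"
            )

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(np.median(np.diff(self.time_s)))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class Beat:
    """Per-transient features. Times in seconds, signal units as the trace."""

    onset_s: float
    peak_s: float
    amplitude: float
    diastolic: float
    complete: bool
    peak_idx: int
    end_idx: int           # half-open window end (next onset or trace end)
    window_end_s: float
    tau_s: float | None = None
    fit_r2: float | None = None
    tau_missing_reason: str | None = None

    @property
    def ttp_s(self) -> float:
        """Rise time (time to peak), onset to peak."""
        return self.peak_s - self.onset_s


@dataclass
class TraceSummary:
    """Per-cell summary metrics; missing quantities are NaN and flagged."""

    n_beats: int
    beat_rate_hz: float
    beat_rate_bpm: float
    mean_ttp_s: float
    mean_tau_s: float
    mean_amplitude: float
    mean_diastolic: float
    interval_sd_s: float
    irregular_event_fraction: float
    name: str = ""
    flags: list[str] = field(default_factory=list)


def compute_dff(trace: Trace, baseline_percentile: float = 10.0) -> Trace:
    """Convert a raw fluorescence trace to ΔF/F0.

    F0 is the given percentile of the trace (default 10th, a robust
    diastolic estimate); output is ``(F - F0) / F0``.
    """
    if trace.signal_kind != "raw":
        raise ValueError("compute_dff expects a raw fluorescence trace")
    f0 = float(np.percentile(trace.values, baseline_percentile))
    if f0 <= 0:
        raise ValueError(
            f"baseline F0 = {f0:.4g} <= 0; subtract background before ΔF/F0 "
            "or supply a background-corrected trace"
        )
    return replace(trace, values=(trace.values - f0) / f0, signal_kind="dff")


def compute_ratio(
    f340: Trace,
    f380: Trace,
    bg340: float = 0.0,
    bg380: float = 0.0,
) -> Trace:
    """Background-corrected Fura-2 ratio (F340 - bg340) / (F380 - bg380)."""
    if f340.time_s.shape != f380.time_s.shape or not np.allclose(
        f340.time_s, f380.time_s, rtol=0, atol=1e-9 / f340.fs_hz + 1e-12
    ):
        raise ValueError("340/380 traces are not on the same time grid")
    den = f380.values - bg380
    bad = np.nonzero(den <= 0)[0]
    if bad.size:
        raise ValueError(
            f"F380 - background <= 0 at sample {int(bad[0])} "
            f"(value {den[bad[0]]:.4g}); check bg380"
        )
    ratio = (f340.values - bg340) / den
    return Trace(f340.time_s, ratio, signal_kind="ratio", name=f340.name or f380.name)


def detect_beats(
    trace: Trace,
    min_prominence_frac: float = 0.3,
    min_interval_s: float = 0.25,
    smooth_s: float = 0.3,
) -> np.ndarray:
    """Detect transient peaks; returns peak times in seconds (time order).

    Candidate peaks are local maxima of a lightly smoothed copy of the
    trace (moving average over ``smooth_s``; detection only — kinetics
    are always measured on the raw samples) with prominence of at least
    ``min_prominence_frac`` times the 5–95 percentile span, separated by
    at least ``min_interval_s``. Each candidate is then refined to the
    raw-signal maximum within the smoothing window, so noiseless peak
    positions are exact. A flat trace yields no peaks. Reduce
    ``smooth_s`` for rhythms faster than ~2 Hz.
    """
    v = trace.values
    w = max(1, int(round(smooth_s * trace.fs_hz)))
    smoothed = ndimage.uniform_filter1d(v, w) if w > 1 else v
    lo, hi = np.percentile(smoothed, [5.0, 95.0])
    span = hi - lo
    if span <= 0:
        return np.empty(0, dtype=float)
    distance = max(1, int(round(min_interval_s * trace.fs_hz)))
    idx, _ = signal.find_peaks(
        smoothed, prominence=min_prominence_frac * span, distance=distance
    )
    refined = np.unique(
        [max(0, i - w) + int(np.argmax(v[max(0, i - w) : i + w + 1])) for i in idx]
    )
    return trace.time_s[refined.astype(int)] if refined.size else np.empty(0, dtype=float)


def _peak_indices(trace: Trace, peak_times: np.ndarray) -> np.ndarray:
    idx = np.rint((np.asarray(peak_times, float) - trace.time_s[0]) * trace.fs_hz)
    return idx.astype(int)


def segment_transients(
    trace: Trace,
    peak_times: Sequence[float] | np.ndarray,
    onset_frac: float = 0.10,
    baseline_window_s: float = 0.1,
) -> list[Beat]:
    """Segment a trace into per-beat windows around detected peaks.

    For each peak, the local diastolic level is the mean over the
    ``baseline_window_s`` (default 100 ms) ending at the pre-peak minimum;
    the onset is the last upward crossing of
    ``diastolic + onset_frac * (peak - diastolic)`` before the peak
    (sub-sample, by linear interpolation). Windows are half-open
    ``[onset_k, onset_{k+1})``; the final window runs to the trace end and
    is marked incomplete if the decay is truncated before falling to 1/e
    of the amplitude. Peaks whose onset cannot be located (e.g. a peak at
    the very start of the trace) are dropped with a log entry.
    """
    peak_times = np.sort(np.asarray(peak_times, dtype=float))
    if peak_times.size == 0:
        return []
    t, v = trace.time_s, trace.values
    fs = trace.fs_hz
    n = len(trace)
    pk_idx = _peak_indices(trace, peak_times)
    nb = max(1, int(round(baseline_window_s * fs)))

    raw: list[tuple[float, int, float, float]] = []  # (onset_s, peak_idx, dias, amp)
    for j, pk in enumerate(pk_idx):
        lo = pk_idx[j - 1] if j > 0 else 0
        if pk <= lo:
            log.warning("beat at t=%.3f s dropped: no rise segment before peak", t[pk])
            continue
        seg = v[lo : pk + 1]
        base_i = lo + int(np.argmin(seg))
        b0 = max(lo, base_i - nb + 1)
        diastolic = float(np.mean(v[b0 : base_i + 1]))
        amp = float(v[pk] - diastolic)
        if amp <= 0:
            log.warning("beat at t=%.3f s dropped: non-positive amplitude", t[pk])
            continue
        thr = diastolic + onset_frac * amp
        below = np.nonzero(v[lo:pk] <= thr)[0]
        if below.size == 0:
            log.warning("beat at t=%.3f s dropped: onset not found", t[pk])
            continue
        i = lo + int(below[-1])  # last sample at/below threshold before peak
        # linear interpolation of the upward crossing inside [i, i+1]
        if v[i + 1] > v[i]:
            frac = (thr - v[i]) / (v[i + 1] - v[i])
        else:
            frac = 1.0
        onset_s = float(t[i] + frac * (t[i + 1] - t[i]))
        raw.append((onset_s, int(pk), diastolic, amp))

    beats: list[Beat] = []
    for j, (onset_s, pk, dias, amp) in enumerate(raw):
        if j + 1 < len(raw):
            end_s = raw[j + 1][0]
            end_idx = int(np.searchsorted(t, end_s, side="left"))
            complete = True
        else:
            end_s = float(t[-1])
            end_idx = n
            tail_min = float(np.min(v[pk:end_idx])) if end_idx > pk else v[pk]
            complete = tail_min <= dias + amp / math.e
        beats.append(
            Beat(
                onset_s=onset_s,
                peak_s=float(t[pk]),
                amplitude=amp,
                diastolic=dias,
                complete=complete,
                peak_idx=int(pk),
                end_idx=end_idx,
                window_end_s=end_s,
            )
        )
    return beats


def _exp_decay(t: np.ndarray, a: float, tau: float, c: float) -> np.ndarray:
    return a * np.exp(-t / tau) + c


def fit_decay_tau(
    trace: Trace, beat: Beat, diastolic_tol_frac: float = 0.05
) -> tuple[float | None, float | None, str | None]:
    """Fit ``y(t) = A·exp(-(t - t_peak)/τ) + C`` to a beat's decay.

    The fit window runs from the peak to the earlier of the next onset and
    the first sample within ``diastolic_tol_frac`` of the diastolic level
    (the decay has effectively finished there). Initialization comes from
    a log-linear fit of ``y - diastolic``. Returns ``(tau_s, r2, reason)``
    where ``reason`` is a code when the fit is unavailable: fewer than 5
    decay samples, or a fitted τ that is non-positive or longer than the
    beat window.
    """
    t, v = trace.time_s, trace.values
    i0, i1 = beat.peak_idx, beat.end_idx
    target = beat.diastolic + diastolic_tol_frac * beat.amplitude
    seg = v[i0:i1]
    reached = np.nonzero(seg <= target)[0]
    if reached.size:
        i1 = i0 + int(reached[0]) + 1
    if i1 - i0 - 1 < 5:
        return None, None, "too_few_decay_samples"
    tt = t[i0:i1] - t[i0]
    yy = v[i0:i1]

    z = yy - beat.diastolic
    pos = z > 0
    if np.count_nonzero(pos) >= 2:
        slope, intercept = np.polyfit(tt[pos], np.log(z[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else beat.window_end_s - beat.peak_s
        a0 = float(np.exp(intercept))
    else:
        tau0 = (beat.window_end_s - beat.peak_s) / 2
        a0 = beat.amplitude
    tau0 = max(tau0, 2.0 / trace.fs_hz)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _exp_decay, tt, yy, p0=[a0, tau0, beat.diastolic], maxfev=5000
            )
    except RuntimeError:
        return None, None, "fit_failed"
    _, tau, _ = (float(p) for p in popt)
    window_len = beat.window_end_s - beat.onset_s
    if tau <= 0 or tau > window_len:
        return None, None, "tau_out_of_range"
    resid = yy - _exp_decay(tt, *popt)
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return tau, float(np.clip(r2, 0.0, 1.0)), None


def extract_beats(
    trace: Trace,
    min_prominence_frac: float = 0.3,
    min_interval_s: float = 0.25,
    onset_frac: float = 0.10,
) -> list[Beat]:
    """Detect, segment and decay-fit all beats of a trace."""
    peaks = detect_beats(trace, min_prominence_frac, min_interval_s)
    beats = segment_transients(trace, peaks, onset_frac=onset_frac)
    for b in beats:
        b.tau_s, b.fit_r2, b.tau_missing_reason = fit_decay_tau(trace, b)
    return beats


def _nanmean(xs: list[float]) -> float:
    return float(np.mean(xs)) if xs else float("nan")


def summarize_trace(
    trace: Trace,
    beats: Sequence[Beat],
    irregular_threshold_frac: float = 0.25,
) -> TraceSummary:
    """Per-cell summary of beat kinetics and rhythm regularity.

    Beating rate is ``(n_beats - 1) / (last peak - first peak)``;
    ``interval_sd_s`` is the sample SD (n-1 denominator) of successive
    peak-to-peak intervals; an interval is an irregular event when it
    deviates from the median interval by more than
    ``irregular_threshold_frac`` (default 25%). Kinetic means are taken
    over complete beats only. With fewer than two beats the rate and SD
    are NaN and the summary is flagged.
    """
    flags: list[str] = []
    n = len(beats)
    nan = float("nan")
    rate_hz = interval_sd = irregular = nan
    if n >= 2:
        # peaks sit on the sample grid; integer-index arithmetic keeps
        # equal pacing intervals exactly equal (SD identically zero)
        dt = 1.0 / trace.fs_hz
        pk_idx = np.array([b.peak_idx for b in beats], dtype=float)
        rate_hz = (n - 1) / ((pk_idx[-1] - pk_idx[0]) * dt)
        intervals_idx = np.diff(pk_idx)
        if intervals_idx.size >= 2:
            interval_sd = float(np.std(intervals_idx, ddof=1)) * dt
        else:
            flags.append("single_interval_no_sd")
        med = float(np.median(intervals_idx))
        irregular = float(
            np.mean(np.abs(intervals_idx - med) > irregular_threshold_frac * med)
        )
    else:
        flags.append("fewer_than_2_beats")

    done = [b for b in beats if b.complete]
    taus = [b.tau_s for b in done if b.tau_s is not None]
    if done and not taus:
        flags.append("no_tau_fits")
    return TraceSummary(
        n_beats=n,
        beat_rate_hz=rate_hz,
        beat_rate_bpm=60.0 * rate_hz if math.isfinite(rate_hz) else nan,
        mean_ttp_s=_nanmean([b.ttp_s for b in done]),
        mean_tau_s=_nanmean(taus),
        mean_amplitude=_nanmean([b.amplitude for b in done]),
        mean_diastolic=_nanmean([b.diastolic for b in done]),
        interval_sd_s=interval_sd,
        irregular_event_fraction=irregular,
        name=trace.name,
        flags=flags,
    )
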