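"""Automatic sharp-wave-ripple (SWR) detection on hippocampal field recordings.

The pipeline mirrors the in-vitro adaptation of threshold-based ripple
detection: the raw trace is band-pass filtered to the ripple band
(150-250 Hz), its sliding RMS is thresholded at 4 SD above background, each
supra-threshold excursion yields a candidate centred on the nearest RMS
peak, a +/-100 ms window of the *unfiltered* trace around each candidate is
Morlet-transformed, event boundaries are the 2-SD crossings of ripple-band
wavelet power above a baseline taken from the first 50 ms of the window at
250 Hz, and two rejection rules are applied: events shorter than 10 ms and
events whose boundary-average RMS is below 1.5 SD above background are
discarded.

"Background" RMS statistics are the mean and SD of the sliding-RMS signal
over the whole recording (optionally median/1.4826*MAD for robustness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .signal import LfpRecording, TimeFrequencyPower, band_pass, morlet_cwt, sliding_rms

REJECT_SHORT = "duration<min"
REJECT_WEAK = "mean_rms<threshold"


@dataclass
class SwrDetectionParams:
    """Parameters of the SWR detector; defaults are the published values.

    ``boundary_power`` selects the wavelet-power trace on which the 2-SD
    boundary crossings are evaluated: the mean power over the ripple band
    (``"band_mean"``, default), the power at ``baseline_freq_hz``
    (``"baseline_freq"``), or the power at the event's peak frequency
    (``"peak_freq"``). ``center_on`` selects whether candidate centres sit
    on peaks of the RMS envelope (default) or of the filtered trace.
    """

    band_hz: tuple = (150.0, 250.0)
    detect_threshold_sd: float = 4.0
    window_halfwidth_ms: float = 100.0
    boundary_threshold_sd: float = 2.0
    baseline_window_ms: float = 50.0
    baseline_freq_hz: float = 250.0
    rms_reject_sd: float = 1.5
    min_duration_ms: float = 10.0
    rms_window_ms: float = 5.0
    min_center_separation_ms: float = 50.0
    cwt_grid_hz: tuple = (100.0, 300.0, 2.0)  # (min, max, step)
    omega0: float = 6.0
    robust_background: bool = False
    boundary_power: str = "band_mean"
    center_on: str = "rms"

    def __post_init__(self) -> None:
        for name in (
            "detect_threshold_sd",
            "boundary_threshold_sd",
            "rms_reject_sd",
            "min_duration_ms",
            "rms_window_ms",
            "window_halfwidth_ms",
            "baseline_window_ms",
            "min_center_separation_ms",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.min_duration_ms >= 2 * self.window_halfwidth_ms:
            raise ValueError("min_duration_ms must be < 2 * window_halfwidth_ms")
        lo, hi, step = self.cwt_grid_hz
        if not (lo < hi and step > 0):
            raise ValueError("cwt_grid_hz must be (min, max, step) with min < max, step > 0")
        if not (lo <= self.band_hz[0] < self.band_hz[1] <= hi):
            raise ValueError("ripple band must lie within the CWT grid")
        if self.boundary_power not in ("band_mean", "baseline_freq", "peak_freq"):
            raise ValueError("boundary_power must be band_mean | baseline_freq | peak_freq")
        if self.center_on not in ("rms", "filtered"):
            raise ValueError("center_on must be rms | filtered")

    def freq_grid(self) -> np.ndarray:
        lo, hi, step = self.cwt_grid_hz
        return np.arange(lo, hi + step / 2, step)


@dataclass
class SwrEvent:
    """One detected ripple, measured inside its wavelet-defined boundaries."""

    center_s: float
    onset_s: float
    offset_s: float
    duration_ms: float
    peak_freq_hz: float
    amplitude_uv: float
    mean_rms_sd: float
    accepted: bool = True
    reject_reason: str = ""


@dataclass
class SwrSummary:
    """Per-recording summary over *accepted* events."""

    n_events: int
    duration_s: float
    incidence_hz: float
    mean_peak_freq_hz: Optional[float] = None
    mean_amplitude_uv: Optional[float] = None
    mean_duration_ms: Optional[float] = None


def background_stats(rms: LfpRecording, robust: bool = False) -> tuple:
    """Background (mean, SD) of the sliding-RMS signal over the whole trace."""
    x = rms.samples
    if robust:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        return med, 1.4826 * mad
    return float(np.mean(x)), float(np.std(x))


def _runs(mask: np.ndarray) -> list:
    """Contiguous True runs of a boolean mask as (start, stop) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_candidates(
    rms: LfpRecording,
    params: SwrDetectionParams = None,
    background: Optional[tuple] = None,
    peak_signal: Optional[np.ndarray] = None,
) -> list:
    """Candidate SWR centre times from supra-threshold RMS excursions.

    One candidate per excursion of the RMS above
    ``background mean + detect_threshold_sd * SD``, placed at the maximum of
    the peak signal (the RMS itself by default) within the excursion.
    Candidates closer than ``min_center_separation_ms`` are merged, keeping
    the one with the larger peak.
    """
    params = params or SwrDetectionParams()
    if rms.n_samples < 2:
        raise ValueError("RMS trace too short")
    mu, sd = background if background is not None else background_stats(
        rms, params.robust_background
    )
    threshold = mu + params.detect_threshold_sd * sd
    x = rms.samples
    sig = rms.samples if peak_signal is None else np.asarray(peak_signal, dtype=np.float64)
    cands = []  # (time_s, peak_value)
    for i0, i1 in _runs(x > threshold):
        peak_idx = i0 + int(np.argmax(sig[i0:i1]))
        t = rms.start_time_s + peak_idx / rms.sampling_rate_hz
        cands.append((t, float(sig[peak_idx])))
    min_sep = params.min_center_separation_ms / 1000.0
    merged: list = []
    for t, v in cands:  # already time-ordered
        if merged and t - merged[-1][0] < min_sep:
            if v > merged[-1][1]:
                merged[-1] = (t, v)
        else:
            merged.append((t, v))
    return [t for t, _ in merged]


def event_boundaries(
    tf: TimeFrequencyPower, params: SwrDetectionParams = None
) -> Optional[tuple]:
    """Wavelet-power boundaries of a candidate event, or None to reject.

    Baseline mean/SD come from the power at ``baseline_freq_hz`` during the
    first ``baseline_window_ms`` of the window. Boundaries are the edges of
    the supra-threshold run (power > baseline mean + 2 SD) of the
    ripple-band mean power containing the window centre; if the centre
    itself is sub-threshold the nearest run within 10 ms is used; with no
    such run the candidate is rejected.
    """
    params = params or SwrDetectionParams()
    freqs, times, P = tf.freqs_hz, tf.times_s, tf.power
    n_t = times.size
    if n_t < 4:
        raise ValueError("time-frequency window too short")
    dt = times[1] - times[0]
    n_base = max(1, int(round(params.baseline_window_ms / 1000.0 / dt)))
    base_row = int(np.argmin(np.abs(freqs - params.baseline_freq_hz)))
    baseline = P[base_row, :n_base]
    b_mu, b_sd = float(np.mean(baseline)), float(np.std(baseline))

    lo, hi = params.band_hz
    band_mask = (freqs >= lo) & (freqs <= hi)
    if params.boundary_power == "baseline_freq":
        signal = P[base_row]
    elif params.boundary_power == "peak_freq":
        band_avg = P[band_mask].mean(axis=1)
        peak_row = np.flatnonzero(band_mask)[int(np.argmax(band_avg))]
        signal = P[peak_row]
    else:
        signal = P[band_mask].mean(axis=0)

    threshold = b_mu + params.boundary_threshold_sd * b_sd
    runs = _runs(signal > threshold)
    if not runs:
        return None
    center_idx = n_t // 2
    containing = [(i0, i1) for i0, i1 in runs if i0 <= center_idx < i1]
    if containing:
        i0, i1 = containing[0]
    else:
        # nearest run within 10 ms of the centre
        def dist(run):
            i0, i1 = run
            return min(abs(i0 - center_idx), abs(i1 - 1 - center_idx))

        i0, i1 = min(runs, key=dist)
        if dist((i0, i1)) * dt > 0.010:
            return None
    return float(times[i0]), float(times[i1 - 1])


def measure_event(
    bp_window: LfpRecording,
    rms_window: LfpRecording,
    tf: TimeFrequencyPower,
    boundaries: tuple,
    background: tuple,
    params: SwrDetectionParams = None,
) -> SwrEvent:
    """Measure one event inside its boundaries.

    Peak frequency is the frequency of maximal time-averaged wavelet power
    within the boundaries (lowest frequency wins ties); amplitude is the
    peak-to-trough of the band-passed trace; mean_rms_sd is the event
    average of (RMS - background mean)/background SD.
    """
    params = params or SwrDetectionParams()
    onset_s, offset_s = boundaries
    if not (tf.times_s[0] <= onset_s <= offset_s <= tf.times_s[-1] + 1e-12):
        raise ValueError("boundaries outside the analysis window")
    t_mask = (tf.times_s >= onset_s) & (tf.times_s <= offset_s)
    avg_power = tf.power[:, t_mask].mean(axis=1)
    peak_freq = float(tf.freqs_hz[int(np.argmax(avg_power))])

    bp_mask = (bp_window.times_s >= onset_s) & (bp_window.times_s <= offset_s)
    seg = bp_window.samples[bp_mask]
    amplitude = float(seg.max() - seg.min())

    mu, sd = background
    rms_mask = (rms_window.times_s >= onset_s) & (rms_window.times_s <= offset_s)
    rms_seg = rms_window.samples[rms_mask]
    mean_rms_sd = float(np.mean((rms_seg - mu) / sd)) if sd > 0 else np.inf

    center_idx = np.flatnonzero(rms_mask)[int(np.argmax(rms_seg))]
    center_s = float(rms_window.times_s[center_idx])
    return SwrEvent(
        center_s=center_s,
        onset_s=onset_s,
        offset_s=offset_s,
        duration_ms=(offset_s - onset_s) * 1000.0,
        peak_freq_hz=peak_freq,
        amplitude_uv=amplitude,
        mean_rms_sd=mean_rms_sd,
    )


def apply_rejection(
    events: Sequence[SwrEvent], params: SwrDetectionParams = None
) -> list:
    """Keep events with duration >= 10 ms and mean RMS >= 1.5 SD above background.

    Events are returned in their input order; the rejected ones have their
    ``accepted``/``reject_reason`` fields set in place on the inputs.
    """
    params = params or SwrDetectionParams()
    accepted = []
    for ev in events:
        if ev.duration_ms < params.min_duration_ms:
            ev.accepted, ev.reject_reason = False, REJECT_SHORT
        elif ev.mean_rms_sd < params.rms_reject_sd:
            ev.accepted, ev.reject_reason = False, REJECT_WEAK
        else:
            ev.accepted, ev.reject_reason = True, ""
            accepted.append(ev)
    return accepted


def summarize(events: Sequence[SwrEvent], duration_s: float) -> SwrSummary:
    """Summary over the accepted events of a recording."""
    acc = [e for e in events if e.accepted]
    n = len(acc)
    summary = SwrSummary(
        n_events=n, duration_s=duration_s, incidence_hz=n / duration_s if duration_s > 0 else 0.0
    )
    if n:
        summary.mean_peak_freq_hz = float(np.mean([e.peak_freq_hz for e in acc]))
        summary.mean_amplitude_uv = float(np.mean([e.amplitude_uv for e in acc]))
        summary.mean_duration_ms = float(np.mean([e.duration_ms for e in acc]))
    return summary


def detect_swrs(rec: LfpRecording, params: SwrDetectionParams = None):
    """Full SWR detection on a recording.

    Returns ``(events, summary)`` where ``events`` lists every measured
    event (rejected ones carry ``accepted=False`` and a reason) and the
    summary covers accepted events only. Candidates whose +/-100 ms window
    is truncated by a recording edge, or with no boundary crossing, are
    dropped (counted in ``summary``'s event list only implicitly; they never
    become events).
    """
    params = params or SwrDetectionParams()
    if rec.duration_s < 1.0:
        raise ValueError("recording must be at least 1 s long")
    fs = rec.sampling_rate_hz
    bp = band_pass(rec, *params.band_hz)
    rms = sliding_rms(bp, params.rms_window_ms)
    bg = background_stats(rms, params.robust_background)
    peak_sig = np.abs(bp.samples) if params.center_on == "filtered" else None
    centers = detect_candidates(rms, params, background=bg, peak_signal=peak_sig)

    half = int(round(params.window_halfwidth_ms / 1000.0 * fs))
    grid = params.freq_grid()
    events: list = []
    for c in centers:
        i_c = int(round((c - rec.start_time_s) * fs))
        i0, i1 = i_c - half, i_c + half + 1
        if i0 < 0 or i1 > rec.n_samples:
            continue  # window truncated by a recording edge
        window = rec.slice(i0, i1)
        tf = morlet_cwt(window, grid, params.omega0)
        bounds = event_boundaries(tf, params)
        if bounds is None:
            continue
        ev = measure_event(bp.slice(i0, i1), rms.slice(i0, i1), tf, bounds, bg, params)
        events.append(ev)
    apply_rejection(events, params)
    return events, summarize(events, rec.duration_s)


def match_events(
    detected_centers_s: Sequence[float],
    truth_centers_s: Sequence[float],
    tolerance_s: float = 0.020,
) -> list:
    """Greedy one-to-one matching of detections to ground truth.

    Pairs within ``tolerance_s`` are matched in order of increasing time
    difference; each detection and each truth event is used at most once.
    Returns a list of (detected_index, truth_index) pairs.
    """
    pairs = []
    for i, d in enumerate(detected_centers_s):
        for j, t in enumerate(truth_centers_s):
            delta = abs(d - t)
            if delta <= tolerance_s:
                pairs.append((delta, i, j))
    pairs.sort()
    used_d: set = set()
    used_t: set = set()
    matches = []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((i, j))
    return matches


def evaluate_detection(
    detected_centers_s: Sequence[float],
    truth_centers_s: Sequence[float],
    tolerance_s: float = 0.020,
) -> dict:
    """Sensitivity and false-discovery rate against implanted ground truth."""
    matches = match_events(detected_centers_s, truth_centers_s, tolerance_s)
    n_d, n_t, n_m = len(detected_centers_s), len(truth_centers_s), len(matches)
    return {
        "n_detected": n_d,
        "n_truth": n_t,
        "n_matched": n_m,
        "sensitivity": n_m / n_t if n_t else np.nan,
        "fdr": (n_d - n_m) / n_d if n_d else 0.0,
        "matches": matches,
    }
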