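"""Gamma-oscillation spectra and unit/burst detection.

Carbachol-induced gamma in hippocampal slices is quantified from 400 s of
unfiltered recording: the Welch power spectrum is whitened by multiplying by
frequency (undoing the 1/f background), z-scored over the 3-300 Hz
normalisation band, and the gamma peak is read off the z-scored spectrum.

Network hyperexcitability is quantified on the 300 Hz high-passed trace:
deflections with peak absolute amplitude of at least 3 SD (RMS) of the
high-passed trace are single units, and at least 10 SD are hypersynchronous
bursts / population spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .signal import LfpRecording, high_pass, welch_spectrum


@dataclass
class GammaParams:
    analysis_duration_s: float = 400.0
    norm_band_hz: tuple = (3.0, 300.0)
    gamma_band_hz: tuple = (20.0, 60.0)
    hp_cutoff_hz: float = 300.0
    unit_threshold_sd: float = 3.0
    burst_threshold_sd: float = 10.0
    burst_refractory_ms: float = 20.0
    welch_segment_s: float = 2.0
    welch_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.norm_band_hz[0] < self.norm_band_hz[1]):
            raise ValueError("norm_band_hz must be an increasing positive pair")
        if not (self.unit_threshold_sd < self.burst_threshold_sd):
            raise ValueError("unit threshold must be below burst threshold")
        if self.analysis_duration_s <= 0 or self.burst_refractory_ms <= 0:
            raise ValueError("durations must be positive")


@dataclass
class GammaSpectrum:
    """Raw, 1/f-normalised, and z-scored power with the gamma-band peak.

    ``power_z`` has mean 0 and SD 1 over the normalisation band by
    construction. ``band_mean_z`` is the mean z over the gamma search band,
    reported alongside the peak because group-level figures may use either.
    """

    freqs_hz: np.ndarray
    power_raw: np.ndarray
    power_norm: np.ndarray
    power_z: np.ndarray
    peak_freq_hz: float
    peak_power_z: float
    band_mean_z: float


@dataclass
class BurstReport:
    unit_times_s: np.ndarray
    burst_times_s: np.ndarray
    unit_count: int
    burst_count: int
    burst_rate_hz: float


def gamma_spectrum(
    rec: LfpRecording, params: GammaParams = None, allow_short: bool = False
) -> GammaSpectrum:
    """1/f-normalised, z-scored power spectrum with gamma peak extraction.

    The first ``analysis_duration_s`` seconds are used; shorter recordings
    are an error unless ``allow_short`` explicitly overrides. Whitening is
    ``power_norm(f) = power_raw(f) * f``; z moments are taken over the
    normalisation band (3-300 Hz); the peak is the argmax of the z-scored
    spectrum within the gamma search band.
    """
    params = params or GammaParams()
    n_needed = int(round(params.analysis_duration_s * rec.sampling_rate_hz))
    if rec.n_samples < n_needed:
        if not allow_short:
            raise ValueError(
                f"recording ({rec.duration_s:.1f} s) shorter than analysis duration "
                f"({params.analysis_duration_s:.0f} s); pass allow_short=True to override"
            )
    else:
        rec = rec.slice(0, n_needed)
    spec = welch_spectrum(rec, params.welch_segment_s, params.welch_overlap)
    f, p_raw = spec.freqs_hz, spec.power
    p_norm = p_raw * f
    lo, hi = params.norm_band_hz
    band = (f >= lo) & (f <= hi)
    if band.sum() < 2:
        raise ValueError("normalisation band contains fewer than 2 frequency bins")
    mu = float(p_norm[band].mean())
    sd = float(p_norm[band].std())
    if sd == 0:
        raise ValueError("spectrum has zero variance over the normalisation band")
    p_z = (p_norm - mu) / sd
    glo, ghi = params.gamma_band_hz
    gmask = (f >= glo) & (f <= ghi)
    g_idx = np.flatnonzero(gmask)
    peak_idx = g_idx[int(np.argmax(p_z[gmask]))]
    return GammaSpectrum(
        freqs_hz=f,
        power_raw=p_raw,
        power_norm=p_norm,
        power_z=p_z,
        peak_freq_hz=float(f[peak_idx]),
        peak_power_z=float(p_z[peak_idx]),
        band_mean_z=float(p_z[gmask].mean()),
    )


def detect_units_bursts(rec: LfpRecording, params: GammaParams = None) -> BurstReport:
    """Tiered unit/burst detection on the high-passed trace.

    The amplitude scale is the RMS of the 300 Hz high-passed trace (equal to
    its SD for a zero-mean signal, so thresholds are scale-invariant). Local
    peaks of the absolute trace with amplitude in [3 SD, 10 SD) are units;
    >= 10 SD are bursts, deduplicated by the refractory interval (larger
    peak kept).
    """
    params = params or GammaParams()
    if rec.duration_s < 1.0:
        raise ValueError("recording must be at least 1 s long")
    fs = rec.sampling_rate_hz
    hp = high_pass(rec, params.hp_cutoff_hz)
    scale = float(np.sqrt(np.mean(hp.samples ** 2)))
    if scale == 0:
        empty = np.empty(0)
        return BurstReport(empty, empty, 0, 0, 0.0)
    absx = np.abs(hp.samples)
    min_dist = max(1, int(round(0.001 * fs)))  # one spike width
    peaks, props = scipy.signal.find_peaks(
        absx, height=params.unit_threshold_sd * scale, distance=min_dist
    )
    heights = props["peak_heights"]
    is_burst = heights >= params.burst_threshold_sd * scale
    unit_times = hp.start_time_s + peaks[~is_burst] / fs

    refr = params.burst_refractory_ms / 1000.0
    burst_peaks = peaks[is_burst]
    burst_heights = heights[is_burst]
    kept_times: list = []
    kept_heights: list = []
    for pk, h in zip(burst_peaks, burst_heights):
        t = hp.start_time_s + pk / fs
        if kept_times and t - kept_times[-1] < refr:
            if h > kept_heights[-1]:
                kept_times[-1], kept_heights[-1] = t, h
        else:
            kept_times.append(t)
            kept_heights.append(h)
    burst_times = np.asarray(kept_times)
    return BurstReport(
        unit_times_s=np.asarray(unit_times),
        burst_times_s=burst_times,
        unit_count=int(unit_times.size),
        burst_count=int(burst_times.size),
        burst_rate_hz=burst_times.size / rec.duration_s,
    )
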