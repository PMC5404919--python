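"""Seeded synthetic benchmarks: LFP traces with implanted ground truth, and
two-group biomarker cohorts with targeted correlations.

The LFP generator emulates the statistical structure the detectors assume:
a 1/f^beta background (exact spectral shaping of seeded Gaussian noise),
ripple packets (sinusoid under a Hann envelope riding a negative Gaussian
sharp wave), an optional continuous gamma tone, 1 ms biphasic unit spikes
and 5 ms high-frequency burst packets whose amplitudes are expressed as
multiples of the high-passed background RMS so the 3 SD / 10 SD detector
tiers are directly exercisable. Event times are homogeneous Poisson with a
refractory gap so implanted events never overlap and recall is well
defined. Identical (config, seed) produces bit-identical output.

The cohort generator draws analytes, cognitive scores and regional volumes
from a Gaussian copula per diagnostic group, hitting requested
(analyte, score) Pearson correlations in expectation, with group means
matching the published CSF levels (control NPTX2 1067 pg/ml vs AD
296 pg/ml). Standard deviations, the non-NPTX2 analytes and the volume
parameters are synthetic choices (no cohort-level raw data is published)
picked to give the moderate group overlap typical of CSF biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .signal import LfpRecording, high_pass

EVENT_KINDS = ("swr", "burst", "unit", "gamma_epoch")


@dataclass
class GroundTruthEvent:
    """An implanted transient with its true timing and parameters."""

    kind: str
    onset_s: float
    offset_s: float
    center_s: float
    osc_freq_hz: Optional[float] = None
    amplitude_uv: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}")
        if not (self.onset_s < self.offset_s):
            raise ValueError("onset_s must be < offset_s")
        if not (self.onset_s <= self.center_s <= self.offset_s):
            raise ValueError("center_s must lie within [onset_s, offset_s]")


@dataclass
class SynthLfpConfig:
    """Parameters of the LFP simulator.

    Defaults represent a quiet CA3 stratum-pyramidale recording at 10 kHz:
    pink (1/f) background of 5 µV SD, spontaneous ripples at 0.5 events/s
    (the published incidence range spans ~0.3-1.5 Hz) with the published
    duration (26.6 +/- 1.4 ms) and peak-to-trough amplitude
    (17.9 +/- 2.3 µV), carrier frequencies around the reported ~190-200 Hz
    peak. Gamma, units and bursts are off by default and enabled per
    scenario. ``swr_count`` overrides ``swr_rate_hz`` with an exact number
    of implanted ripples for benchmark traces.
    """

    duration_s: float = 100.0
    sampling_rate_hz: float = 10_000.0
    noise_exponent: float = 1.0
    noise_sd_uv: float = 5.0
    swr_rate_hz: float = 0.5
    swr_count: Optional[int] = None
    swr_freq_range_hz: Tuple[float, float] = (180.0, 220.0)
    swr_duration_ms: Tuple[float, float] = (26.6, 1.4)  # (mean, sd)
    swr_amplitude_uv: Tuple[float, float] = (17.9, 2.3)  # peak-to-trough (mean, sd)
    sharpwave_amplitude_uv: float = 12.0
    gamma_freq_hz: float = 35.0
    gamma_amplitude_uv: float = 0.0
    burst_rate_hz: float = 0.0
    burst_amplitude_sd_multiples: float = 12.0
    unit_rate_hz: float = 0.0
    unit_amplitude_sd_multiples: float = 5.0
    seed: int = 0

    swr_refractory_s: float = 0.2
    edge_margin_s: float = 0.25

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be positive")
        for name in ("swr_rate_hz", "burst_rate_hz", "unit_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.swr_freq_range_hz
        if not (0 < lo <= hi < self.sampling_rate_hz / 2):
            raise ValueError("swr_freq_range_hz must satisfy 0 < low <= high < Nyquist")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        if self.swr_count is not None and self.swr_count < 0:
            raise ValueError("swr_count must be >= 0")


def _powerlaw_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with power spectral density proportional to 1/f^beta."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shape, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _poisson_times(
    rng: np.random.Generator, rate_hz: float, t0: float, t1: float, refractory_s: float
) -> List[float]:
    """Homogeneous Poisson event times on [t0, t1) with a refractory gap."""
    times: List[float] = []
    if rate_hz <= 0 or t1 <= t0:
        return times
    t = t0
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if t >= t1:
            return times
        times.append(t)
        t += refractory_s


def _fixed_count_times(
    rng: np.random.Generator, count: int, t0: float, t1: float, refractory_s: float
) -> List[float]:
    """Exactly ``count`` uniform times on [t0, t1), >= refractory apart."""
    times: List[float] = []
    attempts = 0
    while len(times) < count:
        c = rng.uniform(t0, t1)
        if all(abs(c - other) >= refractory_s for other in times):
            times.append(c)
        attempts += 1
        if attempts > 1000 * max(count, 1):
            raise ValueError("cannot place the requested event count with this refractory gap")
    return sorted(times)


def generate_lfp(config: SynthLfpConfig):
    """Simulate one recording; returns (LfpRecording, ground-truth list).

    The ground-truth list is sorted by onset. Ripple ``amplitude_uv`` is the
    peak-to-trough of the implanted ripple at its envelope maximum; unit and
    burst amplitudes are the peak µV amplitudes actually implanted (the
    configured SD multiple times the high-passed background RMS).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate_hz
    n = int(round(cfg.duration_s * fs))
    noise = _powerlaw_noise(n, cfg.noise_exponent, rng) * cfg.noise_sd_uv
    x = noise.copy()
    t = np.arange(n) / fs
    events: List[GroundTruthEvent] = []
    t0 = cfg.edge_margin_s
    t1 = max(cfg.duration_s - cfg.edge_margin_s, t0)

    # --- sharp-wave ripples ---------------------------------------------
    if cfg.swr_count is not None:
        centers = _fixed_count_times(rng, cfg.swr_count, t0, t1, cfg.swr_refractory_s)
    else:
        centers = _poisson_times(rng, cfg.swr_rate_hz, t0, t1, cfg.swr_refractory_s)
    for c in centers:
        f0 = rng.uniform(*cfg.swr_freq_range_hz)
        dur = rng.normal(cfg.swr_duration_ms[0], cfg.swr_duration_ms[1]) / 1000.0
        dur = max(dur, 0.004)
        amp = max(rng.normal(*cfg.swr_amplitude_uv), 0.0)
        onset, offset = c - dur / 2, c + dur / 2
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        seg = slice(i0, i1)
        env = np.hanning(i1 - i0)
        x[seg] += (amp / 2.0) * env * np.cos(2 * np.pi * f0 * (t[seg] - c))
        if cfg.sharpwave_amplitude_uv > 0:
            j0 = max(int(round((c - 4 * dur) * fs)), 0)
            j1 = min(int(round((c + 4 * dur) * fs)), n)
            x[j0:j1] -= cfg.sharpwave_amplitude_uv * np.exp(
                -0.5 * ((t[j0:j1] - c) / dur) ** 2
            )
        events.append(GroundTruthEvent("swr", onset, offset, c, f0, amp))

    # --- continuous gamma tone ------------------------------------------
    if cfg.gamma_amplitude_uv > 0:
        x += cfg.gamma_amplitude_uv * np.sin(2 * np.pi * cfg.gamma_freq_hz * t)
        events.append(
            GroundTruthEvent(
                "gamma_epoch",
                0.0,
                cfg.duration_s,
                cfg.duration_s / 2,
                cfg.gamma_freq_hz,
                cfg.gamma_amplitude_uv,
            )
        )

    # --- units and bursts ------------------------------------------------
    if cfg.unit_rate_hz > 0 or cfg.burst_rate_hz > 0:
        # amplitude scale: RMS of the high-passed *background*, so implanted
        # multiples line up with the detector's SD-relative thresholds
        hp = high_pass(LfpRecording(noise, fs), 300.0)
        sigma_hp = float(np.sqrt(np.mean(hp.samples ** 2)))

        for c in _poisson_times(rng, cfg.unit_rate_hz, t0, t1, 0.005):
            amp = cfg.unit_amplitude_sd_multiples * sigma_hp
            m = max(int(round(0.001 * fs)), 2)  # 1 ms biphasic spike
            i0 = int(round(c * fs))
            shape = amp * np.sin(2 * np.pi * np.arange(m) / m)
            x[i0 : i0 + m] += shape[: max(0, min(m, n - i0))]
            peak = c + 0.25e-3  # positive lobe of the biphasic waveform
            events.append(GroundTruthEvent("unit", c, c + 1e-3, peak, None, amp))

        for c in _poisson_times(rng, cfg.burst_rate_hz, t0, t1, 0.025):
            amp = cfg.burst_amplitude_sd_multiples * sigma_hp
            m = max(int(round(0.005 * fs)), 4)  # 5 ms packet at 600 Hz
            i0 = int(round((c - 0.0025) * fs))
            seg = slice(max(i0, 0), min(i0 + m, n))
            env = np.hanning(m)[seg.start - i0 : seg.stop - i0]
            x[seg] += amp * env * np.cos(2 * np.pi * 600.0 * (t[seg] - c))
            events.append(GroundTruthEvent("burst", c - 0.0025, c + 0.0025, c, None, amp))

    events.sort(key=lambda e: e.onset_s)
    return LfpRecording(x, fs), events


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

#: (control_mean, control_sd, case_mean, case_sd) in pg/ml. NPTX2 means are
#: the published ELISA group means; the SDs and the other analytes are
#: synthetic, typical-of-the-literature values.
DEFAULT_ANALYTE_PARAMS: Dict[str, Tuple[float, float, float, float]] = {
    "NPTX2": (1067.0, 350.0, 296.0, 130.0),
    "abeta42": (800.0, 200.0, 450.0, 150.0),
    "tau": (300.0, 100.0, 600.0, 250.0),
    "ptau181": (55.0, 15.0, 85.0, 25.0),
}

DEFAULT_SCORE_PARAMS: Dict[str, Tuple[float, float]] = {"DRS": (130.0, 10.0)}

#: default correlation target: CSF NPTX2 vs Dementia Rating Scale, the
#: strongest published analyte-cognition association (r = 0.467).
DEFAULT_TARGET_CORRELATIONS: Dict[Tuple[str, str], float] = {("NPTX2", "DRS"): 0.467}

#: per-group ((hippocampus mean, sd), (temporal horn mean, sd)) in mm³;
#: synthetic values giving control HOC ~0.8 and case HOC ~0.6.
DEFAULT_VOLUME_PARAMS = {
    "control": ((3600.0, 350.0), (900.0, 300.0)),
    "case": ((2900.0, 400.0), (1800.0, 600.0)),
}


@dataclass
class CohortConfig:
    """Parameters of the two-group cohort simulator."""

    n_control: int = 36
    n_case: int = 30
    analyte_params: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_PARAMS)
    )
    score_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_PARAMS)
    )
    target_correlations: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CORRELATIONS)
    )
    volume_params: Dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError("group sizes must be >= 0")
        for name, (_, csd, _, asd) in self.analyte_params.items():
            if csd <= 0 or asd <= 0:
                raise ValueError(f"SDs for analyte '{name}' must be positive")
        for name, (_, sd) in self.score_params.items():
            if sd <= 0:
                raise ValueError(f"SD for score '{name}' must be positive")
        for (a, s), rho in self.target_correlations.items():
            if abs(rho) > 1:
                raise ValueError(f"|rho| for ({a}, {s}) must be <= 1, got {rho}")
            if a not in self.analyte_params:
                raise ValueError(f"correlation target references unknown analyte '{a}'")
            if s not in self.score_params:
                raise ValueError(f"correlation target references unknown score '{s}'")


def _copula_root(names: List[str], targets: Dict[Tuple[str, str], float]) -> np.ndarray:
    """Square root of the copula correlation matrix (handles |rho| = 1)."""
    k = len(names)
    corr = np.eye(k)
    idx = {n: i for i, n in enumerate(names)}
    for (a, s), rho in targets.items():
        corr[idx[a], idx[s]] = corr[idx[s], idx[a]] = rho
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise ValueError("requested correlation targets are not jointly attainable")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a two-group biomarker cohort as a pandas DataFrame.

    Columns: subject_id, group, one column per analyte (pg/ml, clipped at
    zero), one per cognitive score, hippocampal_volume and
    temporal_horn_volume (mm³, clipped at zero). The requested
    (analyte, score) Pearson correlations hold within each group in
    expectation (Gaussian copula with linear marginal scaling).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    analytes = list(cfg.analyte_params)
    scores = list(cfg.score_params)
    names = analytes + scores
    root = _copula_root(names, cfg.target_correlations)

    frames = []
    for group, n_g, prefix in (
        ("control", cfg.n_control, "C"),
        ("case", cfg.n_case, "A"),
    ):
        z = rng.standard_normal((n_g, len(names))) @ root.T
        data = {"subject_id": [f"{prefix}{i:04d}" for i in range(n_g)], "group": group}
        for j, name in enumerate(analytes):
            cm, csd, am, asd = cfg.analyte_params[name]
            mean, sd = (cm, csd) if group == "control" else (am, asd)
            data[name] = np.clip(mean + sd * z[:, j], 0.0, None)
        for j, name in enumerate(scores):
            mean, sd = cfg.score_params[name]
            data[name] = mean + sd * z[:, len(analytes) + j]
        (hm, hs), (tm, ts) = cfg.volume_params[group]
        data["hippocampal_volume"] = np.clip(rng.normal(hm, hs, n_g), 0.0, None)
        data["temporal_horn_volume"] = np.clip(rng.normal(tm, ts, n_g), 0.0, None)
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    return out
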