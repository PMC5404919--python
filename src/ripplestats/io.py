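"""File formats, configuration and run provenance.

Recording formats
-----------------
* Delimited text: CSV with columns ``time_s,voltage_uv``. On read the time
  column must be uniformly sampled — residual jitter beyond 1 ppm of the
  sampling interval is rejected (guards against silently resampled or
  event-aligned exports).
* Raw binary: little-endian float32 samples plus a JSON sidecar
  ``<path>.json`` holding ``{"sampling_rate_hz": ..., "units": "uV",
  "start_time_s": ...}``.

Event, spectrum, summary, cohort, ROC and correlation tables are plain CSV
with fixed headers; ROC summaries and run manifests are JSON. Every writer
has a matching reader (round-trip tested).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import RocResult
from .gamma import GammaSpectrum
from .signal import LfpRecording
from .swr import SwrEvent, SwrSummary
from .synth import GroundTruthEvent

EVENT_COLUMNS = [
    "id",
    "center_s",
    "onset_s",
    "offset_s",
    "duration_ms",
    "peak_freq_hz",
    "amplitude_uv",
    "mean_rms_sd",
    "accepted",
    "reject_reason",
]

SUMMARY_COLUMNS = [
    "recording_id",
    "n_events",
    "duration_s",
    "incidence_hz",
    "mean_peak_freq_hz",
    "mean_amplitude_uv",
    "mean_duration_ms",
]


# --------------------------------------------------------------------------
# LFP recordings
# --------------------------------------------------------------------------

def write_lfp_text(rec: LfpRecording, path) -> None:
    t = rec.times_s
    with open(path, "w") as fh:
        fh.write("time_s,voltage_uv\n")
        for ti, vi in zip(t, rec.samples):
            fh.write(f"{ti:.17g},{vi:.17g}\n")


def write_lfp_binary(rec: LfpRecording, path) -> None:
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "units": "uV",
        "start_time_s": rec.start_time_s,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def write_lfp(rec: LfpRecording, path, fmt: str = "auto") -> None:
    fmt = _lfp_format(path, fmt)
    if fmt == "text":
        write_lfp_text(rec, path)
    else:
        write_lfp_binary(rec, path)


def _lfp_format(path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("text", "binary"):
            raise ValueError("format must be text | binary | auto")
        return fmt
    suffix = Path(path).suffix.lower()
    return "text" if suffix in (".csv", ".txt", ".tsv") else "binary"


def read_lfp_text(path) -> LfpRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "voltage_uv"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    t = df["time_s"].to_numpy(dtype=np.float64)
    v = df["voltage_uv"].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer the sampling rate")
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise ValueError(f"{path}: non-finite sample at line {bad + 2}")
    dt = (t[-1] - t[0]) / (t.size - 1)
    if dt <= 0:
        raise ValueError(f"{path}: time column must be strictly increasing")
    jitter = np.abs(t - (t[0] + dt * np.arange(t.size)))
    worst = int(np.argmax(jitter))
    if jitter[worst] > 1e-6 * dt:
        raise ValueError(
            f"{path}: irregular sampling at line {worst + 2} "
            f"(jitter {jitter[worst]:.3g} s exceeds 1 ppm of dt={dt:.3g} s)"
        )
    return LfpRecording(v, 1.0 / dt, float(t[0]))


def read_lfp_binary(path, sidecar_path=None) -> LfpRecording:
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"{path}: missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate_hz",):
        if key not in meta:
            raise ValueError(f"{sidecar_path}: missing key '{key}'")
    v = np.fromfile(path, dtype="<f4").astype(np.float64)
    if v.size == 0:
        raise ValueError(f"{path}: empty recording")
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise ValueError(f"{path}: non-finite sample at byte {bad * 4}")
    return LfpRecording(v, float(meta["sampling_rate_hz"]), float(meta.get("start_time_s", 0.0)))


def read_lfp(path, fmt: str = "auto") -> LfpRecording:
    if _lfp_format(path, fmt) == "text":
        return read_lfp_text(path)
    return read_lfp_binary(path)


# --------------------------------------------------------------------------
# event/summary/spectrum tables
# --------------------------------------------------------------------------

def events_frame(events: Sequence[SwrEvent]) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(events):
        rows.append(
            {
                "id": i,
                "center_s": e.center_s,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "duration_ms": e.duration_ms,
                "peak_freq_hz": e.peak_freq_hz,
                "amplitude_uv": e.amplitude_uv,
                "mean_rms_sd": e.mean_rms_sd,
                "accepted": e.accepted,
                "reject_reason": e.reject_reason,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_csv(events: Sequence[SwrEvent], path) -> None:
    events_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> List[SwrEvent]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[], float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SwrEvent(
                center_s=float(row.center_s),
                onset_s=float(row.onset_s),
                offset_s=float(row.offset_s),
                duration_ms=float(row.duration_ms),
                peak_freq_hz=float(row.peak_freq_hz),
                amplitude_uv=float(row.amplitude_uv),
                mean_rms_sd=float(row.mean_rms_sd),
                accepted=str(row.accepted) in ("True", "true", "1"),
                reject_reason=str(row.reject_reason),
            )
        )
    return out


def write_summary_csv(summary: SwrSummary, path, recording_id: str = "recording") -> None:
    row = {
        "recording_id": recording_id,
        "n_events": summary.n_events,
        "duration_s": summary.duration_s,
        "incidence_hz": summary.incidence_hz,
        "mean_peak_freq_hz": summary.mean_peak_freq_hz,
        "mean_amplitude_uv": summary.mean_amplitude_uv,
        "mean_duration_ms": summary.mean_duration_ms,
    }
    pd.DataFrame([row], columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def write_spectrum_csv(spec: GammaSpectrum, path) -> None:
    pd.DataFrame(
        {
            "freq_hz": spec.freqs_hz,
            "power_raw": spec.power_raw,
            "power_norm": spec.power_norm,
            "power_z": spec.power_z,
        }
    ).to_csv(path, index=False)


def write_ground_truth_csv(events: Sequence[GroundTruthEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "kind": e.kind,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "center_s": e.center_s,
                "osc_freq_hz": e.osc_freq_hz,
                "amplitude_uv": e.amplitude_uv,
            }
            for e in events
        ],
        columns=["kind", "onset_s", "offset_s", "center_s", "osc_freq_hz", "amplitude_uv"],
    ).to_csv(path, index=False)


def read_ground_truth_csv(path) -> List[GroundTruthEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        freq = None if pd.isna(row.osc_freq_hz) else float(row.osc_freq_hz)
        out.append(
            GroundTruthEvent(
                str(row.kind),
                float(row.onset_s),
                float(row.offset_s),
                float(row.center_s),
                freq,
                float(row.amplitude_uv),
            )
        )
    return out


# --------------------------------------------------------------------------
# cohorts and biomarker outputs
# --------------------------------------------------------------------------

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    return df


def write_roc_csv(roc: RocResult, path) -> None:
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    ).to_csv(path, index=False)


def write_roc_summary_json(roc: RocResult, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "auc": roc.auc,
                "cutoff": roc.optimal_cutoff,
                "youden_j": roc.youden_j,
                "accuracy": roc.accuracy,
                "direction": roc.direction,
                "n_positive": roc.n_positive,
                "n_negative": roc.n_negative,
            },
            indent=2,
        )
    )


def write_correlation_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# flat configuration files
# --------------------------------------------------------------------------

#: stage prefix -> config dataclass field names users may set in a config file
_CONFIG_STAGES = ("lfp", "swr", "gamma", "cohort")


def load_config(path) -> Dict[str, Dict[str, object]]:
    """Load a flat, stage-namespaced key-value config file (YAML).

    Keys look like ``swr.detect_threshold_sd: 4``. Unknown stages or
    parameter names are hard errors so a typo cannot silently fall back to
    a default.
    """
    from .gamma import GammaParams
    from .swr import SwrDetectionParams
    from .synth import CohortConfig, SynthLfpConfig

    known = {
        "lfp": set(SynthLfpConfig.__dataclass_fields__),
        "swr": set(SwrDetectionParams.__dataclass_fields__),
        "gamma": set(GammaParams.__dataclass_fields__),
        "cohort": set(CohortConfig.__dataclass_fields__),
    }
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    out: Dict[str, Dict[str, object]] = {stage: {} for stage in _CONFIG_STAGES}
    for key, value in raw.items():
        if "." not in str(key):
            raise ValueError(f"{path}: key '{key}' is not stage-namespaced (stage.param)")
        stage, param = str(key).split(".", 1)
        if stage not in known:
            raise ValueError(f"{path}: unknown stage '{stage}' in key '{key}'")
        if param not in known[stage]:
            raise ValueError(f"{path}: unknown parameter '{param}' for stage '{stage}'")
        if isinstance(value, list):
            value = tuple(value)
        out[stage][param] = value
    return out


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    tool_version: str
    command: str
    config_hash: str
    seed: Optional[int]
    input_checksums: Dict[str, str]
    started_utc: str
    finished_utc: str
    event_counts: Dict[str, int]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(
    command: str,
    config: dict,
    seed: Optional[int],
    inputs: Sequence[str],
    started: datetime,
    event_counts: Optional[Dict[str, int]] = None,
) -> RunManifest:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return RunManifest(
        tool_version=__version__,
        command=command,
        config_hash=hashlib.sha256(blob).hexdigest(),
        seed=seed,
        input_checksums={str(p): _sha256(p) for p in inputs},
        started_utc=started.isoformat(),
        finished_utc=datetime.now(timezone.utc).isoformat(),
        event_counts=event_counts or {},
    )


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2))
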