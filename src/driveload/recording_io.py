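"""Readers and writers for EEG recordings, events, and telemetry.

Supported dialects:

* BrainVision triplet (``.vhdr``/``.vmrk``/``.eeg``), IEEE float32
  multiplexed, microvolt units.  Reading goes through :mod:`mne`.
* A plain-text tabular dialect (TSV, one column per channel, ``%.17g``
  floats) that round-trips ``float64`` data bit-exactly.
* BIDS-style ``events.tsv`` with onset (seconds, 1-ms precision),
  duration, trial_type, direction, sacc_type and quality columns.
* Telemetry CSV (time s, velocity km/h, steering deg).

Telemetry recorded at 100 Hz is attached to the 500-Hz EEG timeline by
linear interpolation; samples outside the telemetry span are filled with
edge values and flagged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ContinuousRecording, FormatError, OcularEvent, Telemetry

_BV_HEADER = """Brain Vision Data Exchange Header File Version 1.0
; Written by driveload

[Common Infos]
Codepage=UTF-8
DataFile={data}
MarkerFile={marker}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={nchan}
SamplingInterval={sampint}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channels}
"""

_BV_MARKER = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={data}

[Marker Infos]
{markers}
"""


def write_recording(rec: ContinuousRecording, path: str | Path,
                    dialect: str = "brainvision") -> Path:
    """Write a recording; ``path`` is the basename (extensions added)."""
    path = Path(path)
    if dialect == "brainvision":
        return _write_brainvision(rec, path)
    if dialect == "tsv":
        return _write_tabular(rec, path.with_suffix(".tsv"))
    raise FormatError(f"unknown recording dialect {dialect!r}")


def _write_brainvision(rec: ContinuousRecording, path: Path) -> Path:
    stem = path.stem
    vhdr, vmrk, eeg = (path.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    channels = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.channel_names))
    vhdr.write_text(_BV_HEADER.format(
        data=f"{stem}.eeg", marker=f"{stem}.vmrk",
        nchan=rec.n_channels, sampint=int(round(1e6 / rec.sample_rate)),
        channels=channels), encoding="utf-8")
    markers = ["Mk1=New Segment,,1,1,0,00000000000000000000"]
    for j, (sample, _dist) in enumerate(rec.trigger_samples):
        markers.append(f"Mk{j + 2}=Stimulus,S  1,{sample + 1},1,0")
    vmrk.write_text(_BV_MARKER.format(data=f"{stem}.eeg",
                                      markers="\n".join(markers)),
                    encoding="utf-8")
    rec.data.astype("<f4").T.tofile(eeg)
    return vhdr


def _write_tabular(rec: ContinuousRecording, path: Path) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate!r}\n")
        if rec.trigger_samples:
            trig = ";".join(f"{s}:{d!r}" for s, d in rec.trigger_samples)
            fh.write(f"# triggers={trig}\n")
        fh.write("\t".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter="\t")
    return path


def load_recording(path: str | Path) -> ContinuousRecording:
    """Load a BrainVision triplet (``.vhdr``) or tabular (``.tsv``) file."""
    path = Path(path)
    if path.suffix == ".vhdr":
        return _load_brainvision(path)
    if path.suffix == ".tsv":
        return _load_tabular(path)
    raise FormatError(f"unrecognized recording file {path.name}")


def _load_brainvision(vhdr: Path) -> ContinuousRecording:
    import mne

    for companion in (vhdr.with_suffix(".vmrk"), vhdr.with_suffix(".eeg")):
        if not companion.exists():
            raise FormatError(f"missing companion file {companion.name}")
    text = vhdr.read_text(encoding="utf-8", errors="replace")
    if "IEEE_FLOAT_32" not in text:
        raise FormatError(
            f"{vhdr.name}: only IEEE float32 multiplexed BrainVision data "
            "is supported")
    raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    triggers = []
    for ann in raw.annotations:
        if str(ann["description"]).startswith("Stimulus"):
            triggers.append((int(round(ann["onset"] * raw.info["sfreq"])),
                             float("nan")))
    return ContinuousRecording(data=data, sample_rate=float(raw.info["sfreq"]),
                               channel_names=tuple(raw.ch_names),
                               trigger_samples=triggers)


def _load_tabular(path: Path) -> ContinuousRecording:
    sample_rate = None
    triggers = []
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "sample_rate_hz":
                sample_rate = float(value)
            elif key.strip() == "triggers":
                for part in value.split(";"):
                    s, _, d = part.partition(":")
                    triggers.append((int(s), float(d)))
            pos = fh.tell()
            line = fh.readline()
        if sample_rate is None:
            raise FormatError(f"{path.name}: missing '# sample_rate_hz=' line")
        names = tuple(line.rstrip("\n").split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ContinuousRecording(data=data.T, sample_rate=sample_rate,
                               channel_names=names, trigger_samples=triggers)


# ---------------------------------------------------------------------------
# telemetry


def write_telemetry(tel: Telemetry, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": tel.time, "velocity_kmh": tel.velocity,
                       "steering_deg": tel.steering})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_telemetry(path: str | Path, sample_rate: float = 100.0) -> Telemetry:
    df = pd.read_csv(path)
    for col in ("time_s", "velocity_kmh", "steering_deg"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    return Telemetry(time=df["time_s"].to_numpy(),
                     velocity=df["velocity_kmh"].to_numpy(),
                     steering=df["steering_deg"].to_numpy(),
                     sample_rate=sample_rate)


def attach_telemetry(rec: ContinuousRecording, tel: Telemetry,
                     trigger_table=None) -> ContinuousRecording:
    """Interpolate 100-Hz telemetry onto the EEG timeline.

    Linear interpolation (no overshoot; preserves the telemetry min/max);
    EEG samples outside the telemetry time span are filled with the edge
    value and flagged in ``telemetry_extrapolated``.  ``trigger_table`` is
    an optional list of ``(time_s, known_distance_m)`` landmark rows.
    """
    if len(tel.time) == 0:
        raise ValueError("telemetry is empty")
    t_eeg = np.arange(rec.n_samples) / rec.sample_rate
    out = rec.copy()
    out.telemetry = {
        "velocity": np.interp(t_eeg, tel.time, tel.velocity),
        "steering": np.interp(t_eeg, tel.time, tel.steering),
    }
    out.telemetry_extrapolated = (t_eeg < tel.time[0]) | (t_eeg > tel.time[-1])
    if trigger_table is not None:
        out.trigger_samples = [
            (int(round(t * rec.sample_rate)), float(d)) for t, d in trigger_table]
    return out


# ---------------------------------------------------------------------------
# events


_EVENT_COLUMNS = ["onset", "duration", "trial_type", "direction", "sacc_type",
                  "quality"]


def write_events(events: list[OcularEvent], path: str | Path,
                 sample_rate: float) -> Path:
    """BIDS-style events.tsv; onsets in seconds at 1-ms precision."""
    path = Path(path)
    rows = [{
        "onset": f"{ev.sample / sample_rate:.3f}",
        "duration": "0.000",
        "trial_type": ev.kind,
        "direction": ev.direction,
        "sacc_type": ev.sacc_type,
        "quality": "n/a" if np.isnan(ev.quality) else f"{ev.quality:.4f}",
    } for ev in events]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def load_events(path: str | Path, sample_rate: float) -> list[OcularEvent]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _EVENT_COLUMNS[:3]:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    events = []
    for i, row in df.iterrows():
        try:
            onset = float(row["onset"])
            quality = (float("nan") if row.get("quality", "n/a") in ("n/a", "")
                       else float(row["quality"]))
            events.append(OcularEvent(
                kind=row["trial_type"],
                sample=int(round(onset * sample_rate)),
                direction=row.get("direction", "none") or "none",
                sacc_type=row.get("sacc_type", "none") or "none",
                quality=quality))
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path.name}: malformed row {i + 2}: {exc}") from exc
    return events


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth(truth, path: str | Path, sample_rate: float) -> Path:
    import json

    path = Path(path)
    payload = {
        "events": [dict(kind=e.kind, sample=int(e.sample), direction=e.direction,
                        sacc_type=e.sacc_type, load_level=e.load_level)
                   for e in truth.events],
        "segment_demand": np.asarray(truth.segment_demand).tolist(),
        "segment_load": [str(x) for x in truth.segment_load],
        "injected_components": truth.injected_components,
        "event_rates": truth.event_rates,
        "sample_rate": sample_rate,
    }
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return path
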