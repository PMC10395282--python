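"""Eye-event-locked epoching, ERP component measures, jackknife peaks,
and lateralized (contra-minus-ipsi) measures.

Epochs span -500..1000 ms around blinks (locked to the fitted Gaussian
center), fixation onsets and saccade onsets (saccade-locked spectral epochs
use -1000..500 ms, see :mod:`driveload.lateralized`).  Baselines: blink
-400..-200 ms, fixation -200..0 ms (saccadic occlusion), saccade-locked
-500..-400 ms so the baseline precedes the earliest pre-saccadic analysis
window (-400 ms).

Component amplitudes are measured on electrode-cluster waveforms: peak
components take the signed extremum matching their polarity inside the
detection window; slow components (CNV, tonic lateralization, the phasic
N1pc-like lateralization) take the window mean.  Peak amplitudes are
estimated with a leave-one-subject-out jackknife whose F statistics must be
rescaled by (n-1)^2 (see :func:`driveload.anova.jackknife_f_correction`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    FRONTOCENTRAL_CLUSTER,
    OCCIPITAL_CLUSTER,
    PARIETAL_P2_CLUSTER,
    POSTERIOR_PAIRS,
    ComponentMeasure,
    ContinuousRecording,
    EventLockedSet,
)

logger = logging.getLogger(__name__)

#: baseline windows in ms, half-open [start, stop)
BASELINES = {
    "blink": (-400.0, -200.0),
    "fixation": (-200.0, 0.0),
    "saccade": (-500.0, -400.0),
}

_KIND_TO_LOCK = {"blink": "blink", "fixation_onset": "fixation",
                 "saccade_onset": "saccade"}


def component_table() -> list[ComponentMeasure]:
    """All amplitude measures with their windows, clusters and polarity."""
    return [
        # blink-evoked
        ComponentMeasure("N1", "blink", (20, 200), OCCIPITAL_CLUSTER, "negative"),
        ComponentMeasure("P2_parietal", "blink", (80, 200), PARIETAL_P2_CLUSTER, "positive"),
        ComponentMeasure("P2_occipital", "blink", (80, 250), OCCIPITAL_CLUSTER, "positive"),
        ComponentMeasure("N2", "blink", (100, 600), FRONTOCENTRAL_CLUSTER, "negative"),
        # fixation-evoked
        ComponentMeasure("P1_lambda", "fixation", (0, 200), OCCIPITAL_CLUSTER, "positive"),
        ComponentMeasure("N1", "fixation", (20, 200), OCCIPITAL_CLUSTER, "negative"),
        ComponentMeasure("P2_parietal", "fixation", (100, 300), PARIETAL_P2_CLUSTER, "positive"),
        ComponentMeasure("P2_occipital", "fixation", (100, 400), OCCIPITAL_CLUSTER, "positive"),
        ComponentMeasure("N2", "fixation", (150, 400), FRONTOCENTRAL_CLUSTER, "negative"),
        # lateralized / slow
        ComponentMeasure("phasic_ERL", "fixation", (80, 120), (), "mean", lateralized=True),
        ComponentMeasure("CNV", "saccade", (-200, -50), FRONTOCENTRAL_CLUSTER, "mean"),
        ComponentMeasure("tonic_ERL1", "saccade", (-400, -200), (), "mean", lateralized=True),
        ComponentMeasure("tonic_ERL2", "saccade", (-200, -50), (), "mean", lateralized=True),
    ]


def get_measure(name: str, lock_kind: str) -> ComponentMeasure:
    for m in component_table():
        if m.name == name and m.lock_kind == lock_kind:
            return m
    raise KeyError(f"no measure {name!r} for lock kind {lock_kind!r}")


# ---------------------------------------------------------------------------
# epoching


def epoch_events(rec: ContinuousRecording, events, lock_kind: str,
                 window_s=(-0.5, 1.0), subject=0,
                 require_load: bool = True) -> EventLockedSet:
    """Extract baseline-corrected event x channel x time epochs.

    Events of the matching kind are selected; events whose window exceeds
    the recording bounds, or (if ``require_load``) without a load label,
    are dropped and counted.  The per-epoch baseline mean (window per lock
    kind, see :data:`BASELINES`) is subtracted channel-wise.
    """
    if lock_kind not in BASELINES:
        raise ValueError(f"unknown lock kind {lock_kind!r}")
    fs = rec.sample_rate
    n0 = int(round(-window_s[0] * fs))
    n1 = int(round(window_s[1] * fs))
    n_t = n0 + n1
    times = (np.arange(n_t) - n0) * 1000.0 / fs

    wanted = [e for e in events if _KIND_TO_LOCK.get(e.kind) == lock_kind]
    keep, meta, dropped = [], [], 0
    for ev in wanted:
        if ev.sample - n0 < 0 or ev.sample + n1 > rec.n_samples:
            dropped += 1
            continue
        if require_load and ev.load_level is None:
            dropped += 1
            continue
        keep.append(ev)
        meta.append(dict(load=ev.load_level, direction=ev.direction,
                         sacc_type=ev.sacc_type, subject=subject,
                         sample=ev.sample))
    if dropped:
        logger.info("dropped %d/%d %s events (bounds or missing load)",
                    dropped, len(wanted), lock_kind)
    data = np.empty((len(keep), rec.n_channels, n_t))
    for i, ev in enumerate(keep):
        data[i] = rec.data[:, ev.sample - n0:ev.sample + n1]
    out = EventLockedSet(data=data, times=times, lock_kind=lock_kind,
                         channel_names=rec.channel_names,
                         metadata=pd.DataFrame(meta), sample_rate=fs,
                         n_dropped=dropped)
    return apply_baseline(out)


def apply_baseline(els: EventLockedSet) -> EventLockedSet:
    """Subtract the lock kind's baseline mean per event and channel.

    Idempotent: re-baselining a baselined set changes nothing.
    """
    b0, b1 = BASELINES[els.lock_kind]
    mask = (els.times >= b0) & (els.times < b1)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    els.data = els.data - els.data[:, :, mask].mean(axis=2, keepdims=True)
    return els


def grand_average(els: EventLockedSet, by=("load",)) -> dict:
    """Mean waveform per condition cell: ``{key: (channels x time, n)}``.

    Cells are tuples over the ``by`` metadata columns; empty cells are
    absent from the result.
    """
    by = list(by)
    out = {}
    if els.n_events == 0:
        return out
    for key, idx in els.metadata.groupby(by).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        rows = els.metadata.index.get_indexer(idx)
        out[tuple(key)] = (els.data[rows].mean(axis=0), len(rows))
    return out


# ---------------------------------------------------------------------------
# component measurement


def window_indices(times: np.ndarray, window_ms) -> np.ndarray:
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} outside epoch "
                         f"({times[0]:.0f}..{times[-1]:.0f} ms)")
    return mask


def measure_component(trace: np.ndarray, times: np.ndarray,
                      spec: ComponentMeasure) -> float:
    """Amplitude of one component on a cluster (or difference) waveform."""
    mask = window_indices(times, spec.window_ms)
    seg = trace[mask]
    if spec.polarity == "positive":
        return float(seg.max())
    if spec.polarity == "negative":
        return float(seg.min())
    return float(seg.mean())


def cluster_trace(avg: np.ndarray, channel_names, cluster) -> np.ndarray:
    idx = [list(channel_names).index(c) for c in cluster]
    return avg[idx].mean(axis=0)


def measure_on_average(avg: np.ndarray, els_or_names, times,
                       spec: ComponentMeasure) -> float:
    names = (els_or_names.channel_names
             if hasattr(els_or_names, "channel_names") else els_or_names)
    return measure_component(cluster_trace(avg, names, spec.cluster),
                             times, spec)


# ---------------------------------------------------------------------------
# jackknife


def jackknife_peaks(subject_averages: dict, times: np.ndarray,
                    channel_names, spec: ComponentMeasure) -> dict:
    """Leave-one-subject-out component values on grand averages.

    ``subject_averages`` maps subject id to a channels x time average (one
    condition cell).  Returns ``{left_out_subject: value}``; F statistics
    computed from these values must be divided by (n-1)^2.
    """
    subjects = sorted(subject_averages)
    n = len(subjects)
    if n < 3:
        raise ValueError(f"jackknife needs at least 3 subjects, got {n}")
    stack = np.stack([subject_averages[s] for s in subjects])
    total = stack.sum(axis=0)
    out = {}
    for i, s in enumerate(subjects):
        loo = (total - stack[i]) / (n - 1)
        out[s] = measure_on_average(loo, channel_names, times, spec)
    return out


# ---------------------------------------------------------------------------
# lateralization


def contra_ipsi(els: EventLockedSet, pairs=POSTERIOR_PAIRS) -> np.ndarray:
    """Average contra-minus-ipsi difference waveform over events and pairs.

    For right-directed events the contralateral electrode of each pair is
    its left-hemisphere member (pairs are given as (left, right)); events
    without a direction are excluded.
    """
    traces = _contra_ipsi_per_event(els, pairs)
    if traces.size == 0:
        return np.zeros_like(els.times)
    return traces.mean(axis=0)


def _contra_ipsi_per_event(els: EventLockedSet, pairs=POSTERIOR_PAIRS
                           ) -> np.ndarray:
    keep = els.metadata["direction"].isin(["left", "right"]).to_numpy()
    if els.n_events == 0 or not keep.any():
        return np.empty((0, len(els.times)))
    idx_pairs = [(els.channel_index(a), els.channel_index(b)) for a, b in pairs]
    rows = np.flatnonzero(keep)
    dirs = els.metadata["direction"].to_numpy()[rows]
    out = np.empty((len(rows), len(els.times)))
    for j, (r, d) in enumerate(zip(rows, dirs)):
        diffs = []
        for li, ri in idx_pairs:
            contra, ipsi = (li, ri) if d == "right" else (ri, li)
            diffs.append(els.data[r, contra] - els.data[r, ipsi])
        out[j] = np.mean(diffs, axis=0)
    return out


def lateralized_measures(fixation_els: EventLockedSet,
                         saccade_els: EventLockedSet,
                         pairs=POSTERIOR_PAIRS) -> pd.DataFrame:
    """Per load x saccade-type slow/lateralized amplitudes for one subject.

    phasic_ERL: fixation-locked contra-ipsi mean 80..120 ms; CNV: saccade-
    locked fronto-central cluster mean -200..-50 ms; tonic_ERL1/2: saccade-
    locked contra-ipsi means -400..-200 and -200..-50 ms.  Returns a long
    DataFrame (measure, load, sacc_type, value, n_events) shaped for the
    repeated-measures ANOVA with factors task load and type of saccade.
    """
    rows = []
    specs = {m.name: m for m in component_table()}
    for load in ("low", "medium", "high"):
        for st in ("outward", "inward"):
            sel_f = _subset(fixation_els, load, st)
            sel_s = _subset(saccade_els, load, st)
            ph = (measure_component(contra_ipsi(sel_f, pairs), sel_f.times,
                                    specs["phasic_ERL"])
                  if sel_f.n_events else np.nan)
            if sel_s.n_events:
                avg = sel_s.data.mean(axis=0)
                cnv = measure_on_average(avg, sel_s.channel_names, sel_s.times,
                                         specs["CNV"])
                lat = contra_ipsi(sel_s, pairs)
                t1 = measure_component(lat, sel_s.times, specs["tonic_ERL1"])
                t2 = measure_component(lat, sel_s.times, specs["tonic_ERL2"])
            else:
                cnv = t1 = t2 = np.nan
            for name, val, n in (("phasic_ERL", ph, sel_f.n_events),
                                 ("CNV", cnv, sel_s.n_events),
                                 ("tonic_ERL1", t1, sel_s.n_events),
                                 ("tonic_ERL2", t2, sel_s.n_events)):
                rows.append(dict(measure=name, load=load, sacc_type=st,
                                 value=val, n_events=n))
    return pd.DataFrame(rows)


def _subset(els: EventLockedSet, load=None, sacc_type=None) -> EventLockedSet:
    mask = np.ones(els.n_events, dtype=bool)
    if load is not None:
        mask &= (els.metadata["load"] == load).to_numpy()
    if sacc_type is not None:
        mask &= (els.metadata["sacc_type"] == sacc_type).to_numpy()
    return EventLockedSet(
        data=els.data[mask], times=els.times, lock_kind=els.lock_kind,
        channel_names=els.channel_names,
        metadata=els.metadata.loc[mask].reset_index(drop=True),
        sample_rate=els.sample_rate)


def subset_events(els: EventLockedSet, **conditions) -> EventLockedSet:
    """Public metadata-based subsetting (load=..., sacc_type=...)."""
    return _subset(els, conditions.get("load"), conditions.get("sacc_type"))
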