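"""Track-based task-load estimation.

The drive is mapped onto 10-m spatial segments: the vehicle position is
reconstructed from the (100-Hz, resampled) velocity trace and corrected
("morphed") so that it is exact at known trigger landmarks; continuous
wavelet band power (2-30 Hz in 29 linear steps) is z-transformed over the
whole recording, averaged per segment and smoothed over +-50 m; the
difference between posterior alpha and frontal theta z-power, median across
subjects, is split into terciles: alpha-dominant segments are labelled low
task load, theta-dominant segments high.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, fft, ifft

from .datatypes import (
    FRONTAL_THETA_CLUSTER,
    POSTERIOR_ALPHA_CLUSTER,
    LOAD_LEVELS,
    ContinuousRecording,
    LoadMap,
    TrackSegment,
)

logger = logging.getLogger(__name__)

SEGMENT_LENGTH_M = 10.0
THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 12.0)


# ---------------------------------------------------------------------------
# position reconstruction


def reconstruct_position(velocity_kmh: np.ndarray, trigger_samples,
                         sample_rate: float) -> np.ndarray:
    """Integrate velocity and morph the distance between trigger points.

    ``trigger_samples`` is a list of ``(sample_index, known_distance_m)``.
    Cumulative trapezoidal integration of the (km/h -> m/s converted)
    velocity gives a raw distance trace; each inter-trigger interval is then
    linearly rescaled so the reconstructed distance at every trigger equals
    its known distance exactly.  Outside the first/last trigger the nearest
    interval's scale is extended.
    """
    if len(trigger_samples) < 2:
        raise ValueError("need at least 2 trigger points for morphing")
    idx = np.array([s for s, _ in trigger_samples], dtype=int)
    dist = np.array([d for _, d in trigger_samples], dtype=float)
    if np.any(np.diff(dist) <= 0):
        raise ValueError("trigger distances must be strictly increasing")
    v = np.clip(np.asarray(velocity_kmh, dtype=float), 0.0, None) / 3.6
    raw = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]))]) / sample_rate

    out = np.empty_like(raw)
    scales = []
    for a, b, da, db in zip(idx[:-1], idx[1:], dist[:-1], dist[1:]):
        span = raw[b] - raw[a]
        scale = (db - da) / span if span > 0 else 0.0
        scales.append(scale)
        out[a:b] = da + (raw[a:b] - raw[a]) * scale
    out[idx[-1]] = dist[-1]
    # extrapolate with the neighbouring interval's scale
    out[:idx[0]] = dist[0] - (raw[idx[0]] - raw[:idx[0]]) * scales[0]
    tail = slice(idx[-1] + 1, None)
    out[tail] = dist[-1] + (raw[tail] - raw[idx[-1]]) * scales[-1]
    return np.maximum.accumulate(out)


# ---------------------------------------------------------------------------
# segmentation


def segment_track(distance: np.ndarray, seg_len: float = SEGMENT_LENGTH_M,
                  max_distance: float | None = None) -> list[TrackSegment]:
    """Cut the drive into half-open ``[i*L, (i+1)*L)`` spatial bins.

    Returns ``floor(max_distance / seg_len)`` segments; each carries the
    EEG sample span during which the vehicle was inside the bin.  Segments
    the vehicle never reached get empty spans.
    """
    if seg_len <= 0:
        raise ValueError("seg_len must be positive")
    distance = np.asarray(distance, dtype=float)
    if max_distance is None:
        max_distance = float(distance[-1])
    n_seg = int(max_distance // seg_len)
    if n_seg == 0:
        warnings.warn("track shorter than one segment; returning empty list")
        return []
    edges = np.arange(n_seg + 1) * seg_len
    starts = np.searchsorted(distance, edges[:-1], side="left")
    ends = np.searchsorted(distance, edges[1:], side="left")
    return [
        TrackSegment(index=i,
                     distance_span=(float(edges[i]), float(edges[i + 1])),
                     sample_span=(int(a), int(b)))
        for i, (a, b) in enumerate(zip(starts, ends))
    ]


# ---------------------------------------------------------------------------
# wavelet power


def wavelet_grid(f_min: float = 2.0, f_max: float = 30.0, n_freqs: int = 29,
                 cycles_min: float = 3.0, cycles_max: float = 8.0):
    freqs = np.linspace(f_min, f_max, n_freqs)
    cycles = np.linspace(cycles_min, cycles_max, n_freqs)
    return freqs, cycles


def _morlet_kernel(f: float, n_cyc: float, fs: float) -> np.ndarray:
    sigma_t = n_cyc / (2 * np.pi * f)
    half = int(np.ceil(5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def cwt_power(data: np.ndarray, sample_rate: float, f_min: float = 2.0,
              f_max: float = 30.0, n_freqs: int = 29,
              cycles=(3.0, 8.0), freq_indices=None) -> np.ndarray:
    """Morlet wavelet power, ``channels x freqs x samples``.

    The frequency grid is linear (1-Hz spacing for the 2-30/29 default);
    wavelet width rises linearly from ``cycles[0]`` at ``f_min`` to
    ``cycles[1]`` at ``f_max``.  ``freq_indices`` restricts computation to
    a subset of grid bins (each bin's transform is independent, so the
    values are identical to the full grid's).  Use :func:`cwt_edge_mask`
    for the samples contaminated by the wavelet's finite support.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    freqs, n_cycles = wavelet_grid(f_min, f_max, n_freqs, *cycles)
    if freq_indices is not None:
        freqs = freqs[freq_indices]
        n_cycles = n_cycles[freq_indices]
        n_freqs = len(freqs)
    n = data.shape[1]
    min_len = int(3 * sample_rate / f_min)
    if n < min_len:
        raise ValueError(
            f"recording of {n} samples is shorter than 3 cycles of "
            f"{f_min} Hz ({min_len} samples)")
    kernels = [_morlet_kernel(f, c, sample_rate) for f, c in zip(freqs, n_cycles)]
    n_fft = next_fast_len(n + max(len(k) for k in kernels) - 1)
    kf = np.stack([fft(np.conj(k[::-1]), n_fft) for k in kernels])
    out = np.empty((data.shape[0], n_freqs, n), dtype=float)
    for ci in range(data.shape[0]):
        xf = fft(data[ci], n_fft)
        conv = ifft(xf[None, :] * kf, axis=1)
        for fi, k in enumerate(kernels):
            lag = len(k) - 1 - (len(k) // 2)
            out[ci, fi] = np.abs(conv[fi, lag:lag + n]) ** 2
    return out


def cwt_edge_mask(n_samples: int, sample_rate: float, f_min: float = 2.0,
                  f_max: float = 30.0, n_freqs: int = 29,
                  cycles=(3.0, 8.0)) -> np.ndarray:
    """Boolean ``freqs x samples`` mask of edge-contaminated samples."""
    freqs, n_cycles = wavelet_grid(f_min, f_max, n_freqs, *cycles)
    mask = np.zeros((n_freqs, n_samples), dtype=bool)
    for fi, (f, c) in enumerate(zip(freqs, n_cycles)):
        half = int(np.ceil(5 * c / (2 * np.pi * f) * sample_rate))
        mask[fi, :half] = True
        mask[fi, n_samples - half:] = True
    return mask


def zscore_trace(power: np.ndarray) -> np.ndarray:
    """z-transform each channel x frequency trace over the entire time."""
    mean = power.mean(axis=-1, keepdims=True)
    sd = power.std(axis=-1, keepdims=True)
    bad = np.argwhere(sd[..., 0] == 0)
    if len(bad):
        raise ValueError(f"zero-variance trace at (channel, freq) index {tuple(bad[0])}")
    return (power - mean) / sd


def segment_average_and_smooth(z_power: np.ndarray, segments,
                               smooth_segments: int = 5) -> np.ndarray:
    """Per-segment mean of a ``... x samples`` trace, then a +-``smooth``
    segment moving average (11-segment window for the +-50 m default),
    shrinking at track edges.  Segments without samples become NaN.
    """
    lead = z_power.shape[:-1]
    n_seg = len(segments)
    seg_vals = np.full(lead + (n_seg,), np.nan)
    for seg in segments:
        a, b = seg.sample_span
        if b > a:
            seg_vals[..., seg.index] = z_power[..., a:b].mean(axis=-1)
        else:
            logger.info("segment %d has no samples; value set to NaN", seg.index)
    flat = seg_vals.reshape(-1, n_seg)
    sm = (pd.DataFrame(flat.T)
          .rolling(2 * smooth_segments + 1, center=True, min_periods=1)
          .mean().to_numpy().T)
    return sm.reshape(lead + (n_seg,))


def band_cluster_power(seg_values: np.ndarray, freqs: np.ndarray,
                       channel_names, theta_band=THETA_BAND,
                       alpha_band=ALPHA_BAND,
                       frontal=FRONTAL_THETA_CLUSTER,
                       posterior=POSTERIOR_ALPHA_CLUSTER):
    """(theta_z frontal, alpha_z posterior) per segment.

    ``seg_values`` is ``channels x freqs x segments`` of z-power.
    """
    channel_names = list(channel_names)
    for ch in (*frontal, *posterior):
        if ch not in channel_names:
            raise KeyError(f"cluster channel {ch!r} missing from recording")
    fr = [channel_names.index(c) for c in frontal]
    po = [channel_names.index(c) for c in posterior]
    tmask = (freqs >= theta_band[0]) & (freqs <= theta_band[1])
    amask = (freqs >= alpha_band[0]) & (freqs <= alpha_band[1])
    theta = seg_values[np.ix_(fr, np.flatnonzero(tmask))].mean(axis=(0, 1))
    alpha = seg_values[np.ix_(po, np.flatnonzero(amask))].mean(axis=(0, 1))
    return theta, alpha


# ---------------------------------------------------------------------------
# load assignment


def tercile_partition(values: np.ndarray) -> np.ndarray:
    """Rank-based tercile bins (0 = lowest values, 2 = highest).

    Counts differ by at most one; ties are broken by the stable rank of the
    segment index.  NaNs get bin -1.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(len(values), -1, dtype=int)
    valid = np.flatnonzero(~np.isnan(values))
    n = len(valid)
    if n == 0:
        return out
    order = valid[np.argsort(values[valid], kind="stable")]
    sizes = np.full(3, n // 3)
    for i in range(n % 3):
        sizes[i] += 1
    stops = np.cumsum(sizes)
    out[order[:stops[0]]] = 0
    out[order[stops[0]:stops[1]]] = 1
    out[order[stops[1]:]] = 2
    return out


def assign_task_load(subject_scores: np.ndarray) -> LoadMap:
    """Terciles of the across-subject median alpha-minus-theta score.

    ``subject_scores`` is ``subjects x segments`` (one row per subject, the
    smoothed per-segment ``alpha_z - theta_z``).  The highest-score third is
    labelled low load (alpha-dominant), the lowest third high load.
    """
    subject_scores = np.atleast_2d(np.asarray(subject_scores, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(subject_scores, axis=0)
    bins = tercile_partition(median)
    labels = np.full(len(median), "unassigned", dtype=object)
    labels[bins == 2] = "low"
    labels[bins == 1] = "medium"
    labels[bins == 0] = "high"
    cut_hi = median[bins == 2].min() if np.any(bins == 2) else np.nan
    cut_lo = median[bins == 0].max() if np.any(bins == 0) else np.nan
    return LoadMap(score=median, cutpoints=(float(cut_lo), float(cut_hi)),
                   labels=labels)


# ---------------------------------------------------------------------------
# memory-lean composition used at cohort scale


def segment_band_scores(rec: ContinuousRecording, segments,
                        smooth_segments: int = 5, bands_only: bool = True,
                        **cwt_kw) -> tuple[np.ndarray, np.ndarray]:
    """(theta_z, alpha_z) per segment for one subject, channel-block-wise.

    Numerically equivalent to composing :func:`cwt_power`,
    :func:`zscore_trace`, :func:`segment_average_and_smooth` and
    :func:`band_cluster_power`, but never holds the full channel x freq x
    time power array in memory.  With ``bands_only`` (default) only the
    grid bins inside the theta/alpha bands are computed, which leaves the
    result unchanged (bins are independent) but saves two thirds of the
    transform work.
    """
    names = list(FRONTAL_THETA_CLUSTER) + list(POSTERIOR_ALPHA_CLUSTER)
    freqs, _ = wavelet_grid(**{k: v for k, v in cwt_kw.items()
                               if k in ("f_min", "f_max", "n_freqs")})
    if bands_only:
        idx = np.flatnonzero(
            ((freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1]))
            | ((freqs >= ALPHA_BAND[0]) & (freqs <= ALPHA_BAND[1])))
        cwt_kw = dict(cwt_kw, freq_indices=idx)
        freqs = freqs[idx]
    seg_z = np.empty((len(names), len(freqs), len(segments)))
    for i, name in enumerate(names):
        ci = rec.channel_index(name)
        p = cwt_power(rec.data[ci:ci + 1], rec.sample_rate, **cwt_kw)
        z = zscore_trace(p)
        seg_z[i] = segment_average_and_smooth(z, segments, smooth_segments)[0]
    return band_cluster_power(seg_z, freqs, names)


# ---------------------------------------------------------------------------
# behavioral summaries


def summarize_behavior(segments, rec: ContinuousRecording, events,
                       load_map: LoadMap) -> pd.DataFrame:
    """Per-load means of velocity, steering acceleration and event rates.

    Steering acceleration is the mean absolute second difference of the
    steering angle scaled to degrees/s^2.  Event rates are per-segment
    counts divided by segment dwell time, averaged within each load level.
    Returns a DataFrame indexed by load level.
    """
    if rec.telemetry is None:
        raise ValueError("recording carries no telemetry")
    fs = rec.sample_rate
    vel = rec.telemetry["velocity"]
    steer = rec.telemetry["steering"]
    acc = np.abs(np.diff(steer, 2)) * fs ** 2

    ev_samples = {
        "blink": np.array([e.sample for e in events if e.kind == "blink"]),
        "outward": np.array([e.sample for e in events
                             if e.kind == "saccade_onset" and e.sacc_type == "outward"]),
        "inward": np.array([e.sample for e in events
                            if e.kind == "saccade_onset" and e.sacc_type == "inward"]),
    }
    rows = []
    for seg in segments:
        a, b = seg.sample_span
        if b <= a:
            continue
        load = load_map.labels[seg.index]
        if load == "unassigned":
            continue
        dwell = (b - a) / fs
        row = dict(load=load, velocity=vel[a:b].mean(),
                   steering_acc=acc[max(0, a - 1):b - 1].mean()
                   if b - 1 > max(0, a - 1) else 0.0)
        for key, samples in ev_samples.items():
            count = int(np.count_nonzero((samples >= a) & (samples < b)))
            row[f"{key}_per_min"] = count / dwell * 60.0
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby("load").mean().reindex(list(LOAD_LEVELS))
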