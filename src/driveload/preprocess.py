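"""Preprocessing: filtering, robust channel repair, ICA, IC classification.

The chain mirrors common mobile-EEG practice: a 0.1-40 Hz zero-phase
band-pass; an iterative robust-average-reference step that detects corrupt
channels (extreme robust-z of the channel SD, low correlation with the rest,
or flat) and replaces them by spherical-spline interpolation; a 1-Hz
high-passed, 250-Hz resampled, artifact-screened copy for ICA training; a
PCA-rank-reduced linear ICA whose weights are applied back to the 0.1-Hz
filtered 500-Hz data; and a deterministic heuristic IC classifier
(topography template correlation, spectral slope, burstiness) that maps each
component to brain / eye_vertical / eye_horizontal / other pseudo-
probabilities.  Components with a brain probability of at most 0.30 are
removed for EEG analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.stats import kurtosis

from .datatypes import (
    ConfigurationError,
    ContinuousRecording,
    ICDecomposition,
)
from .synthetic import BLINK_TOPOGRAPHY, HEOG_TOPOGRAPHY

BRAIN_PROBABILITY_THRESHOLD = 0.30


# ---------------------------------------------------------------------------
# filtering


def bandpass_filter(rec: ContinuousRecording, low_hz: float = 0.1,
                    high_hz: float = 40.0) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (forward-backward).

    Implemented as separate high- and low-pass passes: an IIR edge at
    0.1 Hz needs a low order (poles sit nearly on the unit circle and
    higher orders leak numerical noise), while the 40-Hz edge gets order 8
    for more than 20 dB attenuation an octave out.
    """
    nyq = rec.sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ConfigurationError(
            f"invalid band ({low_hz}, {high_hz}) for fs={rec.sample_rate}")
    hp = signal.butter(2, low_hz, btype="high", fs=rec.sample_rate,
                       output="sos")
    lp = signal.butter(8, high_hz, btype="low", fs=rec.sample_rate,
                       output="sos")
    data = signal.sosfiltfilt(lp, signal.sosfiltfilt(hp, rec.data, axis=1),
                              axis=1)
    return rec.copy(data=data)


def highpass_filter(data: np.ndarray, cutoff_hz: float, fs: float,
                    order: int = 2) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="high", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


# ---------------------------------------------------------------------------
# robust channel repair + average reference


def _bad_channel_mask(data, z_thresh=5.0, corr_thresh=0.4, raw_data=None):
    """Flat, extreme-amplitude, or decorrelated channels.

    Amplitude uses the robust SD (0.7413 * IQR, insensitive to sparse
    physiological artifacts like blinks) compared across channels on a log
    scale with a floored spread, so a channel is only flagged when its
    typical amplitude is off by far more than topography can explain.  The
    correlation criterion only applies when the recording is spatially
    correlated overall (volume conduction), so independent-noise inputs do
    not get flagged wholesale.
    """
    q75, q25 = np.percentile(data, [75, 25], axis=1)
    rsd = 0.7413 * (q75 - q25)
    # flatness is a sensor property: judge it before referencing
    raw = data if raw_data is None else raw_data
    flat = 0.7413 * np.squeeze(np.diff(
        np.percentile(raw, [25, 75], axis=1), axis=0)) < 1e-10
    rsd = np.where(flat, 0.0, rsd)
    ok = ~flat
    noisy = np.zeros_like(flat)
    if ok.sum() > 2:
        logs = np.log10(rsd[ok])
        med = np.median(logs)
        spread = max(1.4826 * np.median(np.abs(logs - med)), 0.25)
        noisy[np.flatnonzero(ok)] = (logs - med) / spread > z_thresh
    low_corr = np.zeros_like(flat)
    if ok.sum() > 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = np.corrcoef(data[ok])
        np.fill_diagonal(cm, np.nan)
        max_corr = np.nanmax(np.abs(cm), axis=1)
        if np.median(max_corr) >= 0.5:
            low_corr[np.flatnonzero(ok)] = max_corr < corr_thresh
    return flat | noisy | low_corr


def detect_and_repair_channels(rec: ContinuousRecording, z_thresh: float = 5.0,
                               corr_thresh: float = 0.4, max_iter: int = 4
                               ) -> tuple[ContinuousRecording, list[str]]:
    """Iterative robust average reference with bad-channel interpolation.

    Channels are flagged if flat, if the robust z-score of their SD exceeds
    ``z_thresh``, or if their maximal correlation with any other channel is
    below ``corr_thresh``.  Flagged channels are replaced by spherical-
    spline interpolation from the montage positions and the data are
    re-referenced to the average of the good channels; the procedure
    iterates (at most ``max_iter`` times) until no new channel is flagged.
    Aborts if more than 25% of channels are corrupt.
    """
    data = rec.data.copy()
    bad: set[str] = set()
    for _ in range(max_iter):
        good_idx = [i for i, ch in enumerate(rec.channel_names) if ch not in bad]
        ref = data[good_idx].mean(axis=0)
        referenced = data - ref
        new_bad = _bad_channel_mask(referenced, z_thresh, corr_thresh,
                                    raw_data=data)
        names = {rec.channel_names[i] for i in np.flatnonzero(new_bad)}
        if names <= bad:
            break
        bad |= names
        if len(bad) > 0.25 * rec.n_channels:
            raise RuntimeError(
                f"{len(bad)}/{rec.n_channels} channels corrupt: {sorted(bad)}")
        data = _interpolate_channels(rec, data, sorted(bad))
    good_idx = [i for i, ch in enumerate(rec.channel_names) if ch not in bad]
    data = data - data[good_idx].mean(axis=0)
    return rec.copy(data=data), sorted(bad)


def _interpolate_channels(rec, data, bad_names):
    import mne

    info = mne.create_info(list(rec.channel_names), rec.sample_rate, "eeg")
    raw = mne.io.RawArray(data * 1e-6, info, verbose="error")
    raw.set_montage(mne.channels.make_standard_montage("standard_1020"),
                    verbose="error")
    raw.info["bads"] = list(bad_names)
    raw.interpolate_bads(reset_bads=True, verbose="error")
    return raw.get_data() * 1e6


# ---------------------------------------------------------------------------
# ICA preparation and decomposition


def prepare_ica_input(rec: ContinuousRecording, hp_hz: float = 1.0,
                      target_fs: float = 250.0, epoch_s: float = 1.0,
                      p2p_limit_uv: float = 500.0):
    """High-pass at 1 Hz, resample to 250 Hz, drop artifactual 1-s epochs.

    Epochs whose peak-to-peak amplitude exceeds ``p2p_limit_uv`` in any
    channel are excluded from the ICA training data.  Returns
    ``(training_data, info)`` where ``training_data`` is channels x samples
    (clean epochs concatenated) and ``info`` records the retained epochs.
    Raises if fewer than 60 s of clean data remain.
    """
    hp = highpass_filter(rec.data, hp_hz, rec.sample_rate)
    decim = int(round(rec.sample_rate / target_fs))
    if abs(rec.sample_rate / decim - target_fs) > 1e-9:
        raise ConfigurationError(
            f"sample rate {rec.sample_rate} not an integer multiple of "
            f"{target_fs}")
    ds = signal.resample_poly(hp, 1, decim, axis=1)
    ep_len = int(round(epoch_s * target_fs))
    n_ep = ds.shape[1] // ep_len
    epochs = ds[:, :n_ep * ep_len].reshape(ds.shape[0], n_ep, ep_len)
    p2p = epochs.max(axis=2) - epochs.min(axis=2)
    keep = ~(p2p > p2p_limit_uv).any(axis=0)
    clean = epochs[:, keep].reshape(ds.shape[0], -1)
    if clean.shape[1] < 60 * target_fs:
        raise ValueError(
            f"only {clean.shape[1] / target_fs:.1f} s of clean data; ICA "
            "needs at least 60 s")
    info = dict(sample_rate=target_fs, kept_epochs=np.flatnonzero(keep),
                n_epochs=n_ep, resampled=ds)
    return clean, info


def decompose_ica(training_data: np.ndarray, rank: int, seed: int = 0
                  ) -> ICDecomposition:
    """PCA-compressed linear ICA (FastICA, logcosh) on the training data.

    ``rank`` should be the number of non-corrupt channels minus one.  The
    unmixing matrix operates on channel data in the original units, so the
    weights transfer directly to the 0.1-Hz filtered 500-Hz recording.
    """
    from sklearn.decomposition import FastICA

    if rank <= 1:
        raise ConfigurationError("ICA rank must exceed 1")
    ica = FastICA(n_components=rank, whiten="unit-variance",
                  fun="logcosh", max_iter=2000, tol=1e-5, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(training_data.T)
    return ICDecomposition(mixing=ica.mixing_.copy(),
                           unmixing=ica.components_.copy(),
                           mean=ica.mean_.copy(), rank=rank)


# ---------------------------------------------------------------------------
# IC classification (heuristic stand-in with the 0.30 brain rule)


def _template_vector(channel_names, topo: dict) -> np.ndarray:
    v = np.array([topo.get(ch, 0.0) for ch in channel_names])
    return v - v.mean()


def _safe_corr(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def classify_components(ica: ICDecomposition, training_data: np.ndarray,
                        channel_names, sample_rate: float = 250.0
                        ) -> ICDecomposition:
    """Deterministic heuristic IC classifier.

    Scores each IC's scalp map against a bilateral frontopolar template
    (vertical eye activity) and an antisymmetric F7/F8 template (horizontal
    eye activity); burstiness (activation kurtosis) corroborates the eye
    classes, a negative log-log spectral slope corroborates brain activity.
    Scores are normalized into pseudo-probabilities.  Eye-IC polarity is
    fixed in place: vertical so blink deflections are positive, horizontal
    so the F7-minus-F8 weight is negative (positive trace = rightward gaze).
    """
    names = list(channel_names)
    v_tmpl = _template_vector(names, BLINK_TOPOGRAPHY)
    h_tmpl = _template_vector(names, HEOG_TOPOGRAPHY)
    acts = ica.activations(training_data)
    labels = []
    f7, f8 = names.index("F7"), names.index("F8")
    for k in range(ica.rank):
        topo = ica.mixing[:, k] - ica.mixing[:, k].mean()
        rv = abs(_safe_corr(topo, v_tmpl))
        rh = abs(_safe_corr(topo, h_tmpl))
        kurt = kurtosis(acts[k])
        freqs, psd = signal.welch(acts[k], fs=sample_rate, nperseg=512)
        band = (freqs >= 2) & (freqs <= 40)
        slope = np.polyfit(np.log10(freqs[band]), np.log10(psd[band] + 1e-30), 1)[0]
        burst = min(1.0, max(kurt, 0.0) / 5.0)
        score_v = rv * (0.5 + 0.5 * burst)
        score_h = rh
        score_brain = max(0.0, 1.0 - max(rv, rh)) * (1.0 if slope < 0 else 0.6)
        raw = np.array([score_brain, score_v, score_h, 0.15])
        probs = raw / raw.sum()
        classes = ("brain", "eye_vertical", "eye_horizontal", "other")
        label = classes[int(np.argmax(probs))]
        if label == "eye_vertical":
            act = acts[k]
            thr = np.percentile(np.abs(act), 99)
            peaks = act[np.abs(act) > thr]
            if len(peaks) and np.mean(peaks > 0) < 0.5:
                _flip_component(ica, k)
        elif label == "eye_horizontal":
            if ica.mixing[f7, k] - ica.mixing[f8, k] > 0:
                _flip_component(ica, k)
        labels.append((label, dict(zip(classes, probs))))
    ica.ic_labels = labels
    if not any(lbl == "eye_horizontal" for lbl, _ in labels):
        warnings.warn("no horizontal-eye IC found; saccade detection disabled")
    return ica


def _flip_component(ica: ICDecomposition, k: int):
    ica.mixing[:, k] *= -1
    ica.unmixing[k] *= -1


def select_brain(ica: ICDecomposition,
                 threshold: float = BRAIN_PROBABILITY_THRESHOLD) -> list[int]:
    """Indices of ICs retained for EEG analyses (brain probability > 0.30)."""
    if ica.ic_labels is None:
        raise ValueError("run classify_components first")
    return [k for k, (_, probs) in enumerate(ica.ic_labels)
            if probs["brain"] > threshold]


def eye_component(ica: ICDecomposition, which: str) -> int | None:
    """Index of the best vertical/horizontal eye IC, or None."""
    if ica.ic_labels is None:
        raise ValueError("run classify_components first")
    key = f"eye_{which}"
    best, best_p = None, 0.0
    for k, (label, probs) in enumerate(ica.ic_labels):
        if label == key and probs[key] > best_p:
            best, best_p = k, probs[key]
    return best
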