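"""Blink, saccade and fixation detection from eye-IC activations.

Blinks are found as Gaussian fits to suprathreshold peaks of the vertical
eye component (retained if the fit explains at least 90% of the variance in
a +-400 ms window and its width lies between 25 and 150 ms); the event time
is the fitted center.  Saccades are found in the horizontal eye component:
velocity maxima propose candidates, candidate snippets are clustered into
three amplitude classes whose averages serve as templates, and a sliding
Pearson correlation above 0.8 with any template confirms a saccade.  Onset
and offset (the offset marks a new fixation) are the 10%-of-peak-velocity
crossings around the velocity maximum.  Each saccade is labelled for its
direction (left/right; positive trace = rightward by convention) and for
whether it moves away from (outward) or back toward (inward) the running
central fixation position.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .datatypes import BlinkFit, OcularEvent, SaccadeTemplate

TEMPLATE_CORR_THRESHOLD = 0.8
REFRACTORY_S = 0.1


# ---------------------------------------------------------------------------
# blinks


def _gauss(t, a, c, s, b):
    return a * np.exp(-0.5 * ((t - c) / s) ** 2) + b


def detect_blinks(v_trace: np.ndarray, sample_rate: float,
                  r2_min: float = 0.9, sigma_bounds_ms=(25.0, 150.0),
                  window_ms: float = 400.0
                  ) -> tuple[list[OcularEvent], list[BlinkFit]]:
    """Gaussian-fit blink detection on the vertical eye IC activation.

    The trace polarity must already be normalized so blinks deflect
    positively (the IC classifier does this).  Returns events with
    ``sample`` at the fitted Gaussian center rounded to the nearest sample.
    """
    v_trace = np.asarray(v_trace, dtype=float)
    if v_trace.std() == 0:
        warnings.warn("zero-variance vertical trace; no blinks detected")
        return [], []
    med = np.median(v_trace)
    mad = np.median(np.abs(v_trace - med)) * 1.4826
    thr = med + 4.0 * (mad if mad > 0 else v_trace.std())
    half = int(window_ms / 1000.0 * sample_rate)
    peaks, _ = signal.find_peaks(v_trace, height=thr,
                                 distance=int(0.2 * sample_rate))
    events, fits = [], []
    for j, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(len(v_trace), p + half + 1)
        # keep neighbouring blink candidates out of this fit's window
        if j > 0:
            lo = max(lo, (p + peaks[j - 1]) // 2)
        if j + 1 < len(peaks):
            hi = min(hi, (p + peaks[j + 1]) // 2)
        t = np.arange(lo, hi, dtype=float)
        y = v_trace[lo:hi]
        sig0 = 0.05 * sample_rate
        try:
            popt, _ = curve_fit(
                _gauss, t, y,
                p0=[v_trace[p] - med, float(p), sig0, med],
                bounds=([0, lo, 2.0, -np.inf], [np.inf, hi, sample_rate, np.inf]),
                maxfev=2000)
        except RuntimeError:
            continue
        # goodness of fit judged on the +-2 sigma shape region: the far
        # tails of the window carry no blink signal and would dilute r2
        core = np.abs(t - popt[1]) <= 2.0 * popt[2]
        resid = (y - _gauss(t, *popt))[core]
        ss_tot = np.sum((y[core] - y[core].mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
        sigma_ms = popt[2] / sample_rate * 1000.0
        if r2 >= r2_min and sigma_bounds_ms[0] <= sigma_ms <= sigma_bounds_ms[1]:
            center = int(round(popt[1]))
            events.append(OcularEvent("blink", center, quality=r2))
            fits.append(BlinkFit(amplitude=popt[0], center=popt[1],
                                 sigma_ms=sigma_ms, r2=r2))
    order = np.argsort([e.sample for e in events])
    return [events[i] for i in order], [fits[i] for i in order]


# ---------------------------------------------------------------------------
# saccades


def _velocity(h_trace: np.ndarray, sample_rate: float) -> np.ndarray:
    smooth = signal.savgol_filter(h_trace, window_length=max(
        5, int(0.015 * sample_rate) * 2 + 1), polyorder=2)
    return np.gradient(smooth) * sample_rate


def find_saccade_candidates(h_trace: np.ndarray, sample_rate: float,
                            z_thresh: float = 5.0) -> np.ndarray:
    """Local maxima of |velocity| of the horizontal eye IC above a robust
    threshold, with a 100-ms refractory period."""
    h_trace = np.asarray(h_trace, dtype=float)
    if h_trace.std() == 0:
        return np.array([], dtype=int)
    vel_signed = _velocity(h_trace, sample_rate)
    vel = np.abs(vel_signed)
    center = np.median(vel_signed)
    sd_rob = 1.4826 * np.median(np.abs(vel_signed - center))
    thr = z_thresh * (sd_rob if sd_rob > 0 else vel.std())
    peaks, _ = signal.find_peaks(vel, height=thr,
                                 distance=max(1, int(REFRACTORY_S * sample_rate)))
    return peaks


AMPLITUDE_CLASS_NAMES = ("small", "medium", "large")


def build_saccade_templates(h_trace: np.ndarray, candidates: np.ndarray,
                            sample_rate: float, template_ms: float = 200.0,
                            seed: int = 0) -> list[SaccadeTemplate]:
    """Three amplitude-class templates from candidate snippets.

    Candidate snippets (+-100 ms, sign-normalized so the step rises) are
    clustered by peak-to-peak amplitude with k-means into three classes;
    cluster averages are unit-normalized.  A monotone step-shape check over
    the central half of each template replaces a visual inspection.
    """
    from sklearn.cluster import KMeans

    if len(candidates) < 9:
        raise ValueError(
            f"only {len(candidates)} saccade candidates; need at least 9 "
            "(record a longer session)")
    half = int(template_ms / 2000.0 * sample_rate)
    snippets, amps = [], []
    for c in candidates:
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > len(h_trace):
            continue
        s = h_trace[lo:hi].astype(float)
        if s[-1] < s[0]:
            s = -s
        s = s - s.mean()
        snippets.append(s)
        amps.append(s.max() - s.min())
    snippets = np.asarray(snippets)
    amps = np.asarray(amps)
    if np.ptp(amps) < 1e-12:
        warnings.warn("all candidates identical; degenerate clustering")
        km_labels = np.zeros(len(amps), dtype=int)
        order = [0, 0, 0]
    else:
        km = KMeans(n_clusters=3, n_init=10, random_state=seed)
        km_labels = km.fit_predict(amps[:, None])
        order = np.argsort(km.cluster_centers_.ravel())
    templates = []
    for rank, cls in enumerate(AMPLITUDE_CLASS_NAMES):
        members = snippets[km_labels == (order[rank] if np.ptp(amps) >= 1e-12
                                         else 0)]
        avg = members.mean(axis=0)
        wave = avg / np.linalg.norm(avg)
        center = wave[len(wave) // 4: 3 * len(wave) // 4]
        # tolerate flat-plateau noise: only count meaningful reversals
        tol = 0.02 * (np.ptp(center) or 1.0)
        mono = np.mean(np.diff(center) >= -tol)
        if mono < 0.9:
            warnings.warn(
                f"{cls} saccade template is not monotone over its central "
                f"span (fraction {mono:.2f}); check the horizontal IC")
        templates.append(SaccadeTemplate(waveform=wave, amplitude_class=cls,
                                         mean_p2p=float(amps[km_labels == (
                                             order[rank] if np.ptp(amps) >= 1e-12
                                             else 0)].mean())))
    return templates


def _sliding_correlation(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson r of ``template`` against every length-L window of ``x``;
    output[i] corresponds to the window centered at i."""
    L = len(template)
    t = template - template.mean()
    nt = np.linalg.norm(t)
    ones = np.ones(L)
    sx = signal.fftconvolve(x, ones[::-1], mode="same")
    sxx = signal.fftconvolve(x * x, ones[::-1], mode="same")
    sxy = signal.fftconvolve(x, t[::-1], mode="same")
    var = np.maximum(sxx - sx ** 2 / L, 0.0)
    denom = np.sqrt(var) * nt
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, sxy / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def detect_saccades(h_trace: np.ndarray, templates, sample_rate: float,
                    corr_threshold: float = TEMPLATE_CORR_THRESHOLD
                    ) -> list[OcularEvent]:
    """Template-correlation saccade detection with onset/offset estimation.

    Segments where the maximum over the three templates of the sliding
    correlation exceeds ``corr_threshold`` (non-maximum suppression within
    100 ms) and that coincide with a suprathreshold velocity excursion (the
    candidate criterion; correlation alone is scale-invariant and would
    match creep in the background) are saccades; onsets and offsets are the
    10%-of-peak-velocity crossings, and every offset is emitted as a
    fixation_onset event.
    """
    h_trace = np.asarray(h_trace, dtype=float)
    if h_trace.std() == 0 or not templates:
        return []
    corr = np.max([np.abs(_sliding_correlation(h_trace, t.waveform))
                   for t in templates], axis=0)
    peaks, _ = signal.find_peaks(
        corr, height=corr_threshold,
        distance=max(1, int(REFRACTORY_S * sample_rate)))
    vel = _velocity(h_trace, sample_rate)
    sd_rob = 1.4826 * np.median(np.abs(vel - np.median(vel)))
    vel_thr = 5.0 * (sd_rob if sd_rob > 0 else np.abs(vel).std())
    events = []
    half = int(0.05 * sample_rate)
    for p in peaks:
        lo, hi = max(0, p - half), min(len(vel), p + half + 1)
        vm = lo + int(np.argmax(np.abs(vel[lo:hi])))
        vpeak = abs(vel[vm])
        if vpeak == 0 or vpeak < vel_thr:
            continue
        thr = 0.1 * vpeak
        onset = vm
        while onset > 0 and abs(vel[onset - 1]) > thr:
            onset -= 1
        offset = vm
        while offset < len(vel) - 1 and abs(vel[offset + 1]) > thr:
            offset += 1
        quality = float(corr[p])
        events.append(OcularEvent("saccade_onset", onset, quality=quality))
        events.append(OcularEvent("fixation_onset", offset, quality=quality))
    events.sort(key=lambda e: (e.sample, e.kind != "saccade_onset"))
    return events


def label_saccades(events: list[OcularEvent], h_trace: np.ndarray,
                   sample_rate: float, center_window_s: float = 600.0,
                   ambiguity_frac: float = 0.05) -> list[OcularEvent]:
    """Attach direction (left/right) and type (outward/inward) labels.

    Direction is the sign of the position change between onset and offset
    (positive = rightward).  The central fixation position is a running
    median of the trace over ``center_window_s``; a saccade is outward if
    the offset is farther from the center than the onset.  Saccades whose
    eccentricity change is below ``ambiguity_frac`` of their amplitude are
    labelled type ``none``.
    """
    h_trace = np.asarray(h_trace, dtype=float)
    center = _running_median(h_trace, int(center_window_s * sample_rate))
    pairs = _pair_events(events)
    k = max(1, int(0.02 * sample_rate))
    for onset_ev, offset_ev in pairs:
        a, b = onset_ev.sample, offset_ev.sample
        # short pre-onset / post-offset medians are robust to trace noise
        pos_pre = float(np.median(h_trace[max(0, a - k):a + 1]))
        pos_post = float(np.median(h_trace[b:min(len(h_trace), b + k + 1)]))
        delta = pos_post - pos_pre
        direction = "right" if delta > 0 else "left"
        c = center[a]
        ecc_change = abs(pos_post - c) - abs(pos_pre - c)
        if abs(ecc_change) < ambiguity_frac * abs(delta):
            sacc_type = "none"
        else:
            sacc_type = "outward" if ecc_change > 0 else "inward"
        for ev in (onset_ev, offset_ev):
            ev.direction = direction
            ev.sacc_type = sacc_type
    return events


def _pair_events(events):
    """Pair each saccade_onset with its following fixation_onset."""
    pairs = []
    pending = None
    for ev in sorted(events, key=lambda e: (e.sample, e.kind != "saccade_onset")):
        if ev.kind == "saccade_onset":
            pending = ev
        elif ev.kind == "fixation_onset" and pending is not None:
            pairs.append((pending, ev))
            pending = None
    return pairs


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Coarse running median: per-second medians, median-smoothed, then
    interpolated back to the sample grid (exact enough for a slowly moving
    central fixation)."""
    if window >= len(x):
        return np.full_like(x, np.median(x))
    block = max(1, window // 600)
    n_blocks = len(x) // block
    bm = np.median(x[:n_blocks * block].reshape(n_blocks, block), axis=1)
    k = max(1, window // block)
    if k > 1 and len(bm) > k:
        bm = signal.medfilt(bm, kernel_size=k + (k % 2 == 0))
    centers = np.arange(n_blocks) * block + block / 2
    return np.interp(np.arange(len(x)), centers, bm)
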