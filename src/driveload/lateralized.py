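"""Saccade-locked ERSPs, lateralized time-frequency maps, the cluster-based
permutation test against zero, and pre-saccadic alpha asymmetry.

ERSPs are single-trial Morlet power maps (29 linear frequencies, 2-30 Hz —
the same grid as the track-load wavelet transform) averaged within
condition.  Lateralized maps subtract the ipsilateral from the
contralateral member of posterior channel pairs, which removes power common
to both hemispheres, so no dB baseline is applied.  The cluster test forms
4-connected clusters of supra-threshold one-sample t values in the
freq x time plane, uses the summed t as cluster mass, and builds the null
from random sign flips of subjects with the max-statistic convention, so
the family-wise error across the map is controlled at the cluster
significance level.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats

from .datatypes import TF_PAIRS, ClusterResult, EventLockedSet, TFMap
from .trackload import wavelet_grid

SACCADE_TF_WINDOW_S = (-1.5, 1.0)
ALPHA_ASYMMETRY_WINDOW_MS = (-800.0, -50.0)
ALPHA_BAND = (8.0, 12.0)


def ersp(els: EventLockedSet, channels=None, decim: int = 5,
         f_min: float = 2.0, f_max: float = 30.0, n_freqs: int = 29,
         cycles=(3.0, 8.0), average: bool = True) -> TFMap:
    """Morlet-wavelet event-related spectral power.

    Returns ``freq x time x channel`` power averaged over events (or
    ``event x channel x freq x time`` with ``average=False``).  The epoch
    must be long enough for the lowest-frequency wavelet.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs, n_cycles = wavelet_grid(f_min, f_max, n_freqs, *cycles)
    fs = els.sample_rate
    # the Morlet kernel spans ~10 Gaussian SDs (sigma_t = cycles / (2 pi f))
    min_len = int(np.ceil(10 * n_cycles[0] / (2 * np.pi * f_min) * fs)) + 1
    if els.data.shape[2] < min_len:
        raise ValueError(
            f"epochs of {els.data.shape[2]} samples are too short; the "
            f"{f_min}-Hz wavelet needs at least {min_len} samples")
    if channels is None:
        idx = list(range(len(els.channel_names)))
        names = els.channel_names
    else:
        idx = [els.channel_index(c) for c in channels]
        names = tuple(channels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = tfr_array_morlet(els.data[:, idx], sfreq=fs, freqs=freqs,
                                 n_cycles=n_cycles, output="power",
                                 decim=decim, verbose="error")
    times = els.times[::decim][:power.shape[-1]]
    if average:
        return TFMap(power=power.mean(axis=0).transpose(1, 2, 0), freqs=freqs,
                     times=times, channel_names=names)
    return TFMap(power=power, freqs=freqs, times=times, channel_names=names)


def lateralize_tf(els: EventLockedSet, pairs=TF_PAIRS, decim: int = 5,
                  **ersp_kw) -> dict:
    """Contra/ipsi pair-collapsed power maps and their difference.

    Single-trial power is computed for the pair channels only; for each
    event the contralateral channel is the pair member opposite the
    saccade direction.  Returns ``{"contra", "ipsi", "diff"}`` TFMaps
    (freq x time, averaged over events and pairs).
    """
    for pair in pairs:
        for ch in pair:
            if ch not in els.channel_names:
                raise KeyError(f"pair channel {ch!r} missing from recording")
    chans = [c for pair in pairs for c in pair]
    tf = ersp(els, channels=chans, decim=decim, average=False, **ersp_kw)
    keep = els.metadata["direction"].isin(["left", "right"]).to_numpy()
    rows = np.flatnonzero(keep)
    dirs = els.metadata["direction"].to_numpy()[rows]
    contra_maps, ipsi_maps = [], []
    for r, d in zip(rows, dirs):
        for pi, (left, right) in enumerate(pairs):
            li, ri = 2 * pi, 2 * pi + 1
            c, i = (li, ri) if d == "right" else (ri, li)
            contra_maps.append(tf.power[r, c])
            ipsi_maps.append(tf.power[r, i])
    contra = np.mean(contra_maps, axis=0)
    ipsi = np.mean(ipsi_maps, axis=0)
    mk = lambda p: TFMap(power=p, freqs=tf.freqs, times=tf.times)
    return {"contra": mk(contra), "ipsi": mk(ipsi), "diff": mk(contra - ipsi)}


# ---------------------------------------------------------------------------
# cluster-based permutation test


def cluster_permutation_test(maps: np.ndarray, n_perm: int = 1000,
                             cluster_forming_p: float = 0.01,
                             alpha: float = 0.05, seed: int = 0
                             ) -> ClusterResult:
    """One-sample cluster-based permutation test of subject maps against 0.

    ``maps`` is ``subjects x freq x time``.  Cells with |t| above the
    two-sided critical value at ``cluster_forming_p`` are joined by
    4-connectivity; cluster mass is the summed t.  The null distribution of
    the maximal |mass| is built from ``n_perm`` random sign flips of whole
    subjects; cluster p-values use the add-one convention
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    maps = np.asarray(maps, dtype=float)
    n_sub = maps.shape[0]
    if n_sub < 5:
        raise ValueError(f"need at least 5 subjects, got {n_sub}")
    shape = maps.shape[1:]
    X = maps.reshape(n_sub, -1)
    ssq = np.sum(X ** 2, axis=0)
    valid = (ssq - n_sub * (X.mean(axis=0)) ** 2) > 1e-24
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} zero-variance cells excluded "
                      "from clustering")
    tcrit = stats.t.ppf(1 - cluster_forming_p / 2.0, n_sub - 1)

    def t_from_mean(m):
        var = np.maximum(ssq - n_sub * m ** 2, 0.0) / (n_sub - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(valid, m * np.sqrt(n_sub) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
        return t

    t_obs = t_from_mean(X.mean(axis=0)).reshape(shape)
    clusters = _find_clusters(t_obs, tcrit)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    means = signs @ X / n_sub
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        t_p = t_from_mean(means[p]).reshape(shape)
        masses = [abs(m) for _, m in _find_clusters(t_p, tcrit)]
        null_max[p] = max(masses) if masses else 0.0

    results = []
    for mask, mass in clusters:
        pval = (1 + np.count_nonzero(null_max >= abs(mass))) / (n_perm + 1)
        results.append((mask, mass, float(pval)))
    significant = np.zeros(shape, dtype=bool)
    for mask, _, pval in results:
        if pval <= alpha:
            significant |= mask
    return ClusterResult(clusters=results, significant=significant,
                         t_map=t_obs, threshold=float(tcrit),
                         n_permutations=n_perm)


def _find_clusters(t_map: np.ndarray, tcrit: float):
    """4-connected supra-threshold clusters, positive and negative apart."""
    out = []
    structure = ndimage.generate_binary_structure(t_map.ndim, 1)
    for sign in (1.0, -1.0):
        above = sign * t_map > tcrit
        labels, n = ndimage.label(above, structure=structure)
        if n == 0:
            continue
        sums = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
        for k in range(n):
            out.append((labels == k + 1, float(sums[k])))
    return out


# ---------------------------------------------------------------------------
# alpha asymmetry


def alpha_asymmetry(diff_map: TFMap, band=ALPHA_BAND,
                    window_ms=ALPHA_ASYMMETRY_WINDOW_MS) -> float:
    """Mean contra-minus-ipsi power over the alpha band and the pre-saccade
    window (-800..-50 ms by default)."""
    fmask = (diff_map.freqs >= band[0]) & (diff_map.freqs <= band[1])
    tmask = (diff_map.times >= window_ms[0]) & (diff_map.times <= window_ms[1])
    if not tmask.any():
        raise ValueError(f"window {window_ms} outside epoch "
                         f"({diff_map.times[0]:.0f}..{diff_map.times[-1]:.0f} ms)")
    return float(diff_map.power[np.ix_(fmask, tmask)].mean())
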