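"""Ground-truth generator for driving-EEG datasets.

The generator emulates the statistical structure the downstream analyses
assume: a scripted route with a distance-dependent demand profile in [0, 1],
driving telemetry coupled to that demand (slower and with more steering
activity under high demand), and a 32-channel, 500-Hz EEG containing

* 1/f background noise,
* posterior alpha (10 Hz) whose amplitude decreases with demand and frontal
  theta (5.5 Hz) whose amplitude increases with demand,
* blink artifacts (Gaussian EOG deflections, rate decreasing with demand)
  and horizontal saccade steps (outward then return-to-center pairs, rate
  increasing with demand, three discrete amplitude classes),
* eye-event-locked neural components (lambda/P1, N1, P2, N2, a lateralized
  N1pc, a pre-saccadic CNV and tonic lateralization, and pre-saccadic
  contralateral alpha suppression before inward saccades).

Every injected event and component is recorded in a :class:`GroundTruth`
object so parameter-recovery tests can compare pipeline output with truth.
Default event rates and component amplitudes follow the magnitudes reported
for on-road simulator driving (blink rate around 9-11 per minute and falling
with load, saccade rate around 15-17 per minute per type and rising, ERP
amplitudes of a few microvolts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datatypes import (
    MONTAGE_32,
    FRONTAL_THETA_CLUSTER,
    POSTERIOR_ALPHA_CLUSTER,
    OCCIPITAL_CLUSTER,
    PARIETAL_P2_CLUSTER,
    FRONTOCENTRAL_CLUSTER,
    POSTERIOR_PAIRS,
    LOAD_LEVELS,
    ConfigurationError,
    ContinuousRecording,
    GroundTruth,
    OcularEvent,
    RouteProfile,
    Telemetry,
)
from .trackload import tercile_partition

# ---------------------------------------------------------------------------
# topographies (weights per channel label; unlisted channels are zero)

BLINK_TOPOGRAPHY = {
    "Fp1": 1.0, "Fp2": 1.0, "F3": 0.45, "F4": 0.45, "F7": 0.35, "F8": 0.35,
    "Fz": 0.5, "FC1": 0.25, "FC2": 0.25, "FC5": 0.15, "FC6": 0.15,
}
#: horizontal EOG dipole; sign convention: positive source value = rightward
#: gaze, so the weight difference F7 - F8 is negative.
HEOG_TOPOGRAPHY = {
    "F7": -0.5, "F8": 0.5, "Fp1": -0.2, "Fp2": 0.2, "FC5": -0.15, "FC6": 0.15,
}
ALPHA_TOPO_LEFT = {
    "O1": 1.0, "PO9": 0.85, "P3": 0.55, "P7": 0.5, "Oz": 0.5,
    "Pz": 0.3, "CP1": 0.2, "CP5": 0.2,
}
ALPHA_TOPO_RIGHT = {
    "O2": 1.0, "PO10": 0.85, "P4": 0.55, "P8": 0.5, "Oz": 0.5,
    "Pz": 0.3, "CP2": 0.2, "CP6": 0.2,
}
THETA_TOPOGRAPHY = {
    "Fz": 1.0, "FC1": 0.8, "FC2": 0.8, "F3": 0.6, "F4": 0.6,
    "Cz": 0.6, "Fp1": 0.3, "Fp2": 0.3,
}

# ---------------------------------------------------------------------------
# event-locked component layout: (cluster, peak latency ms, width ms)
# Peaks are kept narrow and well separated so cluster waveforms superpose
# with negligible crosstalk; mean-amplitude components use plateaus matched
# to their measurement windows.

BLINK_COMPONENT_TIMING = {
    "N1": (OCCIPITAL_CLUSTER, 120.0, 15.0),
    "P2_parietal": (PARIETAL_P2_CLUSTER, 140.0, 15.0),
    "P2_occipital": (OCCIPITAL_CLUSTER, 190.0, 15.0),
    "N2": (FRONTOCENTRAL_CLUSTER, 300.0, 30.0),
}
FIXATION_COMPONENT_TIMING = {
    "P1_lambda": (OCCIPITAL_CLUSTER, 80.0, 13.0),
    "N1": (OCCIPITAL_CLUSTER, 140.0, 13.0),
    "P2_parietal": (PARIETAL_P2_CLUSTER, 200.0, 18.0),
    "P2_occipital": (OCCIPITAL_CLUSTER, 280.0, 25.0),
    "N2": (FRONTOCENTRAL_CLUSTER, 275.0, 30.0),
}
#: plateau spans in ms relative to the lock event
PHASIC_ERL_SPAN = (78.0, 122.0)           # relative to fixation onset
CNV_SPAN = (-205.0, -45.0)                # relative to saccade onset
TONIC_SPANS = ((-410.0, -205.0), (-195.0, -45.0))
PLATEAU_EDGE_MS = 8.0

# Default amplitude tables in microvolts, per load level (low, medium, high)
# and, for fixation/saccade components, per saccade type.  Values mirror the
# magnitudes and effect directions observed in simulator driving.
DEFAULT_BLINK_AMPLITUDES = {
    "N1": {"low": -1.72, "medium": -1.20, "high": -0.62},
    "P2_parietal": {"low": 1.61, "medium": 1.65, "high": 1.58},
    "P2_occipital": {"low": 2.26, "medium": 2.07, "high": 1.97},
    "N2": {"low": -0.64, "medium": -0.83, "high": -0.73},
}
DEFAULT_FIXATION_AMPLITUDES = {
    "P1_lambda": {
        "outward": {"low": 7.51, "medium": 7.22, "high": 7.25},
        "inward": {"low": 5.98, "medium": 6.30, "high": 6.67},
    },
    "N1": {
        "outward": {"low": -1.45, "medium": -1.58, "high": -1.02},
        "inward": {"low": -0.21, "medium": 0.21, "high": 0.49},
    },
    "P2_parietal": {
        "outward": {"low": 0.82, "medium": 0.58, "high": 0.59},
        "inward": {"low": 1.60, "medium": 1.81, "high": 1.72},
    },
    "P2_occipital": {
        "outward": {"low": 4.66, "medium": 4.36, "high": 4.46},
        "inward": {"low": 4.74, "medium": 5.22, "high": 5.41},
    },
    "N2": {
        "outward": {"low": -1.65, "medium": -1.28, "high": -1.26},
        "inward": {"low": -0.39, "medium": -0.21, "high": -0.21},
    },
}
DEFAULT_LATERALIZED_AMPLITUDES = {
    "phasic_ERL": {
        "outward": {"low": 0.82, "medium": 0.99, "high": 1.00},
        "inward": {"low": -0.11, "medium": -0.14, "high": -0.30},
    },
    "CNV": {
        "outward": {"low": 0.07, "medium": -0.09, "high": -0.06},
        "inward": {"low": -0.66, "medium": -0.93, "high": -0.81},
    },
    "tonic_ERL1": {
        "outward": {"low": 0.15, "medium": -0.06, "high": 0.13},
        "inward": {"low": -0.14, "medium": -0.33, "high": -0.35},
    },
    "tonic_ERL2": {
        "outward": {"low": 0.18, "medium": -0.01, "high": 0.20},
        "inward": {"low": -0.22, "medium": -0.37, "high": -0.34},
    },
}

SECTION_PLAN = [
    (0.22, "freeway"), (0.18, "rural"), (0.08, "fog"), (0.14, "freeway"),
    (0.06, "construction"), (0.12, "rural"), (0.20, "city"),
]
SECTION_DEMAND = {
    "freeway": 0.15, "rural": 0.45, "city": 0.78, "fog": 0.90,
    "construction": 0.82,
}


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic recording.

    ``snr`` scales the 1/f background: its RMS is ``10 / snr`` microvolts
    (``None`` disables background noise entirely).  Rates are in events per
    minute; demand slopes are dimensionless fractions applied to the local
    route demand in [0, 1].
    """

    sample_rate: float = 500.0
    channel_names: tuple = MONTAGE_32
    snr: float | None = 5.0
    background_rms_ref: float = 10.0
    include_oscillations: bool = True
    include_eog: bool = True
    include_erp: bool = True
    alpha_freq: float = 10.0
    alpha_amp: float = 6.0
    alpha_demand_slope: float = 0.7
    theta_freq: float = 5.5
    theta_amp: float = 3.0
    theta_base: float = 0.5
    theta_demand_slope: float = 1.0
    phase_jitter: float = 0.15
    blink_rate_per_min: float = 13.0
    blink_demand_slope: float = 0.5
    blink_refractory_s: float = 1.0
    blink_amp_uv: float = 100.0
    blink_sigma_ms: float = 50.0
    saccade_pair_rate_per_min: float = 15.2
    saccade_rate_demand_slope: float = 0.12
    saccade_amp_classes_uv: tuple = (20.0, 40.0, 60.0)
    saccade_duration_ms: float = 20.0
    fixation_dwell_s: tuple = (1.1, 1.9)
    min_pair_gap_s: float = 1.1
    alpha_suppression: float = 0.5
    suppression_window_ms: tuple = (-800.0, -50.0)
    blink_amplitudes: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BLINK_AMPLITUDES.items()})
    fixation_amplitudes: dict = field(
        default_factory=lambda: {k: {s: dict(d) for s, d in v.items()}
                                 for k, v in DEFAULT_FIXATION_AMPLITUDES.items()})
    lateralized_amplitudes: dict = field(
        default_factory=lambda: {k: {s: dict(d) for s, d in v.items()}
                                 for k, v in DEFAULT_LATERALIZED_AMPLITUDES.items()})

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# route


def simulate_route(total_distance: float = 5_000.0, n_triggers: int | None = None,
                   seed: int = 0, section_plan=None,
                   transition_sigma_m: float = 30.0) -> RouteProfile:
    """Generate a scripted route with a smooth demand profile.

    Sections (freeway, rural, city, fog, construction) contribute piecewise
    base demands that are smoothed over ``transition_sigma_m`` and overlaid
    with a gentle within-section modulation.  Trigger points (landmarks with
    exactly known positions) are placed on an even grid inside the track.
    """
    if total_distance <= 0:
        raise ConfigurationError("total_distance must be positive")
    rng = np.random.default_rng(seed)
    plan = SECTION_PLAN if section_plan is None else section_plan
    if n_triggers is None:
        n_triggers = max(2, int(round(85 * total_distance / 50_000.0)))
    if n_triggers < 1:
        raise ConfigurationError("need at least one trigger point")

    grid = np.arange(0.0, total_distance + 1.0, 1.0)
    base = np.empty_like(grid)
    labels = []
    start = 0.0
    for frac, tag in plan:
        stop = start + frac * total_distance
        base[(grid >= start) & (grid < stop)] = SECTION_DEMAND[tag]
        labels.append((start, min(stop, total_distance), tag))
        start = stop
    base[grid >= start] = SECTION_DEMAND[plan[-1][1]]

    smooth = gaussian_filter1d(base, sigma=transition_sigma_m, mode="nearest")
    phase = rng.uniform(0, 2 * np.pi)
    wiggle = 0.05 * np.sin(2 * np.pi * grid / 350.0 + phase)
    profile = np.clip(smooth + wiggle, 0.02, 0.98)

    def demand(d):
        return np.interp(np.asarray(d, dtype=float), grid, profile)

    triggers = total_distance * (np.arange(1, n_triggers + 1)) / (n_triggers + 1)
    return RouteProfile(total_distance=float(total_distance), demand=demand,
                        trigger_points=triggers, section_labels=labels)


# ---------------------------------------------------------------------------
# telemetry


def simulate_telemetry(route: RouteProfile, seed: int = 0, sample_rate: float = 100.0,
                       v_max: float = 120.0, v_min: float = 40.0,
                       velocity_lag_s: float = 2.0, velocity_noise: float = 0.8,
                       steer_base: float = 1.0, steer_gain: float = 8.0) -> Telemetry:
    """Drive the route: velocity tracks ``v_max - (v_max - v_min) * demand``
    with first-order lag, steering is demand-scaled low-passed noise.

    The distance trace is the running sum of the recorded velocity samples,
    so the velocity integral reproduces the total distance by construction.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    total = route.total_distance
    vel, dist = [], []
    s = 0.0
    v = float(v_max - (v_max - v_min) * route.demand(0.0))
    while s < total:
        vel.append(v)
        dist.append(s)
        target = v_max - (v_max - v_min) * float(route.demand(min(s, total)))
        v += (target - v) * dt / velocity_lag_s
        v += velocity_noise * np.sqrt(dt) * rng.normal()
        v = max(v, 3.0)
        s += v / 3.6 * dt
    vel = np.asarray(vel)
    dist = np.asarray(dist)
    n = len(vel)
    time = np.arange(n) * dt

    demand_t = route.demand(dist)
    sigma = steer_base + steer_gain * demand_t
    white = rng.normal(size=n) * sigma
    from scipy.signal import butter, sosfiltfilt
    sos = butter(2, 1.5, btype="low", fs=sample_rate, output="sos")
    steering = sosfiltfilt(sos, white) if n > 50 else white

    trig_idx = np.searchsorted(dist, route.trigger_points)
    trig_idx = np.clip(trig_idx, 0, n - 1)
    trigger_samples = [(int(i), float(d)) for i, d in zip(trig_idx, route.trigger_points)]
    return Telemetry(time=time, velocity=vel, steering=steering,
                     sample_rate=sample_rate, trigger_samples=trigger_samples,
                     distance=dist)


# ---------------------------------------------------------------------------
# waveform primitives


def _gaussian_wave(fs: float, amp: float, peak_ms: float, sigma_ms: float):
    """Return (offset_samples, waveform) for a Gaussian bump, +-4 sigma."""
    sigma = sigma_ms * fs / 1000.0
    center = peak_ms * fs / 1000.0
    half = int(np.ceil(4 * sigma))
    k = np.arange(int(np.floor(center)) - half, int(np.ceil(center)) + half + 1)
    return k[0], amp * np.exp(-0.5 * ((k - center) / sigma) ** 2)


def _plateau_wave(fs: float, amp: float, start_ms: float, stop_ms: float,
                  edge_ms: float = PLATEAU_EDGE_MS):
    """Plateau with raised-cosine edges of ``edge_ms`` outside the span."""
    t0 = (start_ms - edge_ms) * fs / 1000.0
    t1 = (stop_ms + edge_ms) * fs / 1000.0
    k = np.arange(int(np.floor(t0)), int(np.ceil(t1)) + 1)
    t_ms = k * 1000.0 / fs
    w = np.ones_like(t_ms)
    rise = (t_ms >= start_ms - edge_ms) & (t_ms < start_ms)
    fall = (t_ms > stop_ms) & (t_ms <= stop_ms + edge_ms)
    w[t_ms < start_ms - edge_ms] = 0.0
    w[t_ms > stop_ms + edge_ms] = 0.0
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - (start_ms - edge_ms)) / edge_ms))
    w[fall] = 0.5 * (1 + np.cos(np.pi * (t_ms[fall] - stop_ms) / edge_ms))
    return k[0], amp * w


def _tonic_wave(fs: float, e1: float, e2: float):
    """Two-level pre-saccadic plateau: ``e1`` then ``e2`` with smooth joins."""
    k0a, w1 = _plateau_wave(fs, e1, *TONIC_SPANS[0])
    k0b, w2 = _plateau_wave(fs, e2, *TONIC_SPANS[1])
    k0 = min(k0a, k0b)
    k1 = max(k0a + len(w1), k0b + len(w2))
    out = np.zeros(k1 - k0)
    out[k0a - k0:k0a - k0 + len(w1)] += w1
    out[k0b - k0:k0b - k0 + len(w2)] += w2
    return k0, out


def _smoothstep(n: int) -> np.ndarray:
    """Raised-cosine ramp 0 -> 1 over n samples."""
    x = np.linspace(0.0, 1.0, n)
    return 0.5 * (1 - np.cos(np.pi * x))


def _add(data: np.ndarray, channels, weights, wave: np.ndarray, start: int):
    """Add ``wave`` (starting at absolute sample ``start``) to channels."""
    n = data.shape[1]
    lo = max(0, start)
    hi = min(n, start + len(wave))
    if hi <= lo:
        return
    seg = wave[lo - start:hi - start]
    for ch, w in zip(channels, weights):
        data[ch, lo:hi] += w * seg


# ---------------------------------------------------------------------------
# events


def _renewal_times(rng, duration, rate_fn, refractory):
    """Event times of a renewal process with demand-modulated mean rate.

    Intervals are ``refractory + Exp(mean - refractory)`` so the realized
    mean rate matches ``rate_fn`` while the count variance stays slightly
    sub-Poisson (blinks are not memoryless at short lags).
    """
    times = []
    t = float(rng.exponential(1.0 / max(rate_fn(0.0), 1e-9)))
    while t < duration:
        times.append(t)
        mean = 1.0 / max(rate_fn(t), 1e-9)
        scale = max(mean - refractory, 0.05)
        t += refractory + float(rng.exponential(scale))
    return np.asarray(times)


def _saccade_pairs(rng, duration, cfg: GeneratorConfig, demand_at):
    """Outward/return saccade pairs; returns per-saccade records."""
    dur_s = cfg.saccade_duration_ms / 1000.0
    records = []
    if cfg.saccade_pair_rate_per_min <= 0:
        return records
    t = float(rng.uniform(0.5, 2.0))
    while True:
        dwell = float(rng.uniform(*cfg.fixation_dwell_s))
        t_in = t + dur_s + dwell
        if t_in + dur_s + 0.5 > duration:
            break
        side = "left" if rng.random() < 0.5 else "right"
        amp_class = int(rng.integers(len(cfg.saccade_amp_classes_uv)))
        amp = cfg.saccade_amp_classes_uv[amp_class]
        records.append(dict(onset=t, direction=side, sacc_type="outward",
                            amp=amp, amp_class=amp_class))
        records.append(dict(onset=t_in,
                            direction="right" if side == "left" else "left",
                            sacc_type="inward", amp=amp, amp_class=amp_class))
        rate = cfg.saccade_pair_rate_per_min / 60.0 * (
            1 + cfg.saccade_rate_demand_slope * demand_at(t_in))
        mean_gap = max(1.0 / rate - dwell - 2 * dur_s - cfg.min_pair_gap_s, 0.05)
        t = t_in + dur_s + cfg.min_pair_gap_s + float(rng.exponential(mean_gap))
    return records


# ---------------------------------------------------------------------------
# recording


def _background_1f(rng, n_channels, n, fs, rms, n_fields=8,
                   shared_fraction=0.6):
    """Spatially correlated 1/f background noise.

    A small set of 1/f "field" sources with random topographies emulates
    volume conduction (neighbouring channels correlate, as in real EEG);
    the remainder is channel-specific 1/f plus a little white sensor noise.
    Per-channel RMS is scaled to ``rms``.
    """
    from scipy.fft import rfft, irfft, next_fast_len

    nf = next_fast_len(n)
    f = np.fft.rfftfreq(nf, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 0.5))

    def one_over_f(rows):
        spec = rfft(rng.normal(size=(rows, nf)), axis=1)
        x = irfft(spec * shape, n=nf, axis=1)[:, :n]
        return x / x.std(axis=1, keepdims=True)

    fields = one_over_f(n_fields)
    topo = rng.normal(size=(n_channels, n_fields))
    topo /= np.linalg.norm(topo, axis=1, keepdims=True)
    shared = topo @ fields
    own = one_over_f(n_channels)
    x = np.sqrt(shared_fraction) * shared + np.sqrt(1 - shared_fraction) * own
    x *= rms / x.std(axis=1, keepdims=True)
    x += 0.1 * rms * rng.normal(size=(n_channels, n))
    return x


def _topo_vector(cfg, topo: dict) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array([cfg.channel_names.index(k) for k in topo], dtype=int)
    w = np.array(list(topo.values()))
    return idx, w


def _event_load(dist_eeg, sample, seg_load, seg_len=10.0):
    i = int(min(dist_eeg[min(sample, len(dist_eeg) - 1)] // seg_len,
                len(seg_load) - 1))
    return str(seg_load[i])


def segment_demand_truth(route: RouteProfile, seg_len: float = 10.0):
    """Mean demand per 10-m segment plus its tercile load labels."""
    n_seg = int(route.total_distance // seg_len)
    centers = np.arange(n_seg)[:, None] * seg_len + np.linspace(0.5, seg_len - 0.5, 10)
    demand = route.demand(centers).mean(axis=1)
    bins = tercile_partition(demand)
    labels = np.array(LOAD_LEVELS, dtype=object)[bins]  # high demand -> high load
    return demand, labels


def simulate_recording(route: RouteProfile, telemetry: Telemetry,
                       cfg: GeneratorConfig | None = None, seed: int = 0
                       ) -> tuple[ContinuousRecording, GroundTruth]:
    """Render the synthetic EEG for one subject and return it with truth."""
    cfg = cfg or GeneratorConfig()
    missing = [ch for ch in ("Fp1", "Fp2", "F7", "F8", *FRONTAL_THETA_CLUSTER,
                             *POSTERIOR_ALPHA_CLUSTER)
               if ch not in cfg.channel_names]
    if missing:
        raise ConfigurationError(f"montage is missing required channels: {missing}")
    rng = np.random.default_rng(seed)
    fs = cfg.sample_rate
    ratio = int(round(fs / telemetry.sample_rate))
    n = len(telemetry.velocity) * ratio
    t_eeg = np.arange(n) / fs
    dist_eeg = np.interp(t_eeg, telemetry.time, telemetry.distance)
    demand_eeg = route.demand(dist_eeg)
    duration = n / fs

    def demand_at(t):
        return float(np.interp(t, t_eeg, demand_eeg))

    n_ch = len(cfg.channel_names)
    data = np.zeros((n_ch, n))

    seg_demand, seg_load = segment_demand_truth(route)

    # ---- ocular events -------------------------------------------------
    blink_times = _renewal_times(
        rng, duration - 0.5,
        lambda t: cfg.blink_rate_per_min / 60.0 * (1 - cfg.blink_demand_slope * demand_at(t)),
        cfg.blink_refractory_s)
    saccades = _saccade_pairs(rng, duration, cfg, demand_at)

    events: list[OcularEvent] = []
    dur_samp = int(round(cfg.saccade_duration_ms / 1000.0 * fs))
    for bt in blink_times:
        s = int(round(bt * fs))
        events.append(OcularEvent("blink", s,
                                  load_level=_event_load(dist_eeg, s, seg_load)))
    for recd in saccades:
        s_on = int(round(recd["onset"] * fs))
        s_fix = s_on + dur_samp
        load_on = _event_load(dist_eeg, s_on, seg_load)
        events.append(OcularEvent("saccade_onset", s_on, recd["direction"],
                                  recd["sacc_type"], load_level=load_on))
        events.append(OcularEvent("fixation_onset", s_fix, recd["direction"],
                                  recd["sacc_type"],
                                  load_level=_event_load(dist_eeg, s_fix, seg_load)))
    events.sort(key=lambda e: e.sample)

    # ---- EOG sources ---------------------------------------------------
    if cfg.include_eog:
        idx_b, w_b = _topo_vector(cfg, BLINK_TOPOGRAPHY)
        for bt in blink_times:
            k0, wave = _gaussian_wave(fs, cfg.blink_amp_uv, 0.0, cfg.blink_sigma_ms)
            _add(data, idx_b, w_b, wave, int(round(bt * fs)) + k0)
        idx_h, w_h = _topo_vector(cfg, HEOG_TOPOGRAPHY)
        h_src = np.zeros(n)
        ramp = _smoothstep(dur_samp)
        for recd in saccades:
            s_on = int(round(recd["onset"] * fs))
            sign = 1.0 if recd["direction"] == "right" else -1.0
            step = sign * recd["amp"]
            hi = min(n, s_on + dur_samp)
            if s_on < n:
                h_src[s_on:hi] += step * ramp[:hi - s_on]
                if hi < n:
                    h_src[hi:] += step
        for ch, w in zip(idx_h, w_h):
            data[ch] += w * h_src

    # ---- oscillations --------------------------------------------------
    if cfg.include_oscillations:
        gain_l = np.ones(n)
        gain_r = np.ones(n)
        if cfg.alpha_suppression > 0:
            w0, w1 = cfg.suppression_window_ms
            for recd in saccades:
                if recd["sacc_type"] != "inward":
                    continue
                s_on = int(round(recd["onset"] * fs))
                a = max(0, s_on + int(w0 / 1000.0 * fs))
                b = max(0, s_on + int(w1 / 1000.0 * fs))
                gain = gain_l if recd["direction"] == "right" else gain_r
                gain[a:b] = 1.0 - cfg.alpha_suppression
        gain_l = gaussian_filter1d(gain_l, 0.02 * fs)
        gain_r = gaussian_filter1d(gain_r, 0.02 * fs)

        env_alpha = np.clip(cfg.alpha_amp * (1 - cfg.alpha_demand_slope * demand_eeg), 0, None)
        env_theta = np.clip(cfg.theta_amp * (cfg.theta_base
                                             + cfg.theta_demand_slope * demand_eeg), 0, None)
        for topo, env in ((ALPHA_TOPO_LEFT, env_alpha * gain_l),
                          (ALPHA_TOPO_RIGHT, env_alpha * gain_r)):
            pn = np.cumsum(rng.normal(0, cfg.phase_jitter / np.sqrt(fs), n))
            osc = env * np.sin(2 * np.pi * cfg.alpha_freq * t_eeg
                               + rng.uniform(0, 2 * np.pi) + pn)
            idx, w = _topo_vector(cfg, topo)
            for ch, wi in zip(idx, w):
                data[ch] += wi * osc
        pn = np.cumsum(rng.normal(0, cfg.phase_jitter / np.sqrt(fs), n))
        osc = env_theta * np.sin(2 * np.pi * cfg.theta_freq * t_eeg
                                 + rng.uniform(0, 2 * np.pi) + pn)
        idx, w = _topo_vector(cfg, THETA_TOPOGRAPHY)
        for ch, wi in zip(idx, w):
            data[ch] += wi * osc

    # ---- event-locked neural components --------------------------------
    if cfg.include_erp:
        _inject_components(data, cfg, fs, events)

    # ---- background ----------------------------------------------------
    if cfg.snr is not None and np.isfinite(cfg.snr):
        rms = cfg.background_rms_ref / cfg.snr
        data += _background_1f(rng, n_ch, n, fs, rms)

    velocity_500 = np.interp(t_eeg, telemetry.time, telemetry.velocity)
    steering_500 = np.interp(t_eeg, telemetry.time, telemetry.steering)
    trigger_samples = [(int(i) * ratio, d) for i, d in telemetry.trigger_samples]
    rec = ContinuousRecording(
        data=data, sample_rate=fs, channel_names=cfg.channel_names,
        telemetry={"velocity": velocity_500, "steering": steering_500},
        trigger_samples=trigger_samples)

    truth = GroundTruth(
        events=events, segment_demand=seg_demand, segment_load=seg_load,
        injected_components={
            "blink": cfg.blink_amplitudes,
            "fixation": cfg.fixation_amplitudes,
            "lateralized": cfg.lateralized_amplitudes,
        },
        event_rates={
            "blinks_per_min": len(blink_times) / duration * 60.0,
            "saccade_pairs_per_min": len(saccades) / 2 / duration * 60.0,
        })
    return rec, truth


def _contra_channels(cfg, direction: str):
    """Contralateral member of each posterior pair for a saccade direction."""
    out = []
    for left, right in POSTERIOR_PAIRS:
        out.append(left if direction == "right" else right)
    return [cfg.channel_names.index(c) for c in out]


def _inject_components(data, cfg, fs, events):
    cluster_idx = {
        c: [cfg.channel_names.index(ch) for ch in c]
        for c in (OCCIPITAL_CLUSTER, PARIETAL_P2_CLUSTER, FRONTOCENTRAL_CLUSTER)
    }
    for ev in events:
        if ev.kind == "blink":
            for name, (cluster, peak, sig) in BLINK_COMPONENT_TIMING.items():
                amp = cfg.blink_amplitudes[name][ev.load_level]
                k0, wave = _gaussian_wave(fs, amp, peak, sig)
                idx = cluster_idx[cluster]
                _add(data, idx, np.ones(len(idx)), wave, ev.sample + k0)
        elif ev.kind == "fixation_onset":
            for name, (cluster, peak, sig) in FIXATION_COMPONENT_TIMING.items():
                amp = cfg.fixation_amplitudes[name][ev.sacc_type][ev.load_level]
                k0, wave = _gaussian_wave(fs, amp, peak, sig)
                idx = cluster_idx[cluster]
                _add(data, idx, np.ones(len(idx)), wave, ev.sample + k0)
            amp = cfg.lateralized_amplitudes["phasic_ERL"][ev.sacc_type][ev.load_level]
            k0, wave = _plateau_wave(fs, amp, *PHASIC_ERL_SPAN)
            idx = _contra_channels(cfg, ev.direction)
            _add(data, idx, np.ones(len(idx)), wave, ev.sample + k0)
        elif ev.kind == "saccade_onset":
            amp = cfg.lateralized_amplitudes["CNV"][ev.sacc_type][ev.load_level]
            k0, wave = _plateau_wave(fs, amp, *CNV_SPAN)
            idx = cluster_idx[FRONTOCENTRAL_CLUSTER]
            _add(data, idx, np.ones(len(idx)), wave, ev.sample + k0)
            e1 = cfg.lateralized_amplitudes["tonic_ERL1"][ev.sacc_type][ev.load_level]
            e2 = cfg.lateralized_amplitudes["tonic_ERL2"][ev.sacc_type][ev.load_level]
            k0, wave = _tonic_wave(fs, e1, e2)
            idx = _contra_channels(cfg, ev.direction)
            _add(data, idx, np.ones(len(idx)), wave, ev.sample + k0)


# ---------------------------------------------------------------------------
# analytic expectation of every amplitude measure


def render_condition(cfg: GeneratorConfig, lock_kind: str, load: str,
                     sacc_type: str = "none", direction: str = "right",
                     window_s=(-0.5, 1.0), fs: float | None = None) -> np.ndarray:
    """Noiseless channel x time epoch of the injected neural components.

    Renders exactly what the generator adds around one event of the given
    condition (EOG artifacts, oscillations and noise excluded), with the
    deterministic relative timing between a saccade and its fixation.
    """
    cfg = cfg or GeneratorConfig()
    fs = fs or cfg.sample_rate
    n0 = int(round(-window_s[0] * fs))
    n1 = int(round(window_s[1] * fs))
    n = n0 + n1
    data = np.zeros((len(cfg.channel_names), n))
    dur = int(round(cfg.saccade_duration_ms / 1000.0 * fs))

    cluster_idx = {
        c: [cfg.channel_names.index(ch) for ch in c]
        for c in (OCCIPITAL_CLUSTER, PARIETAL_P2_CLUSTER, FRONTOCENTRAL_CLUSTER)
    }

    def add_fixation(at):
        for name, (cluster, peak, sig) in FIXATION_COMPONENT_TIMING.items():
            amp = cfg.fixation_amplitudes[name][sacc_type][load]
            k0, wave = _gaussian_wave(fs, amp, peak, sig)
            _add(data, cluster_idx[cluster],
                 np.ones(len(cluster_idx[cluster])), wave, at + k0)
        amp = cfg.lateralized_amplitudes["phasic_ERL"][sacc_type][load]
        k0, wave = _plateau_wave(fs, amp, *PHASIC_ERL_SPAN)
        idx = _contra_channels(cfg, direction)
        _add(data, idx, np.ones(len(idx)), wave, at + k0)

    def add_presaccade(at):
        amp = cfg.lateralized_amplitudes["CNV"][sacc_type][load]
        k0, wave = _plateau_wave(fs, amp, *CNV_SPAN)
        idx = cluster_idx[FRONTOCENTRAL_CLUSTER]
        _add(data, idx, np.ones(len(idx)), wave, at + k0)
        e1 = cfg.lateralized_amplitudes["tonic_ERL1"][sacc_type][load]
        e2 = cfg.lateralized_amplitudes["tonic_ERL2"][sacc_type][load]
        k0, wave = _tonic_wave(fs, e1, e2)
        idx = _contra_channels(cfg, direction)
        _add(data, idx, np.ones(len(idx)), wave, at + k0)

    if lock_kind == "blink":
        for name, (cluster, peak, sig) in BLINK_COMPONENT_TIMING.items():
            amp = cfg.blink_amplitudes[name][load]
            k0, wave = _gaussian_wave(fs, amp, peak, sig)
            _add(data, cluster_idx[cluster],
                 np.ones(len(cluster_idx[cluster])), wave, n0 + k0)
    elif lock_kind == "fixation":
        add_fixation(n0)
        add_presaccade(n0 - dur)
    elif lock_kind == "saccade":
        add_presaccade(n0)
        add_fixation(n0 + dur)
    else:
        raise ValueError(f"unknown lock kind {lock_kind!r}")
    return data


def expected_measures(cfg: GeneratorConfig | None = None) -> "object":
    """Analytic expectation of each amplitude measure per condition.

    Applies the same baseline and window rules as the analysis layer to
    noiseless rendered condition templates; component overlap (for example
    the pre-saccadic CNV bleeding into the fixation baseline) is therefore
    reflected in the expected values, exactly as it is in the data.
    Returns a DataFrame with columns lock_kind, measure, load, sacc_type,
    value.
    """
    import pandas as pd
    from .eventlocked import (component_table, measure_component,
                              BASELINES, window_indices)

    cfg = cfg or GeneratorConfig()
    fs = cfg.sample_rate
    rows = []
    window_by_lock = {"blink": (-0.5, 1.0), "fixation": (-0.5, 1.0),
                      "saccade": (-1.0, 0.5)}
    for lock in ("blink", "fixation", "saccade"):
        window = window_by_lock[lock]
        n0 = int(round(-window[0] * fs))
        times = (np.arange(int(round((window[1] - window[0]) * fs))) - n0) * 1000.0 / fs
        b0, b1 = BASELINES[lock]
        bmask = (times >= b0) & (times < b1)
        specs = [m for m in component_table() if m.lock_kind == lock]
        conditions = ([("none", lvl) for lvl in LOAD_LEVELS] if lock == "blink"
                      else [(st, lvl) for st in ("outward", "inward")
                            for lvl in LOAD_LEVELS])
        for sacc_type, load in conditions:
            rendered = {
                d: render_condition(cfg, lock, load, sacc_type, d, window, fs)
                for d in ("left", "right")
            }
            baselined = {d: r - r[:, bmask].mean(axis=1, keepdims=True)
                         for d, r in rendered.items()}
            for spec in specs:
                if spec.lateralized:
                    vals = []
                    for d, r in baselined.items():
                        for left, right in POSTERIOR_PAIRS:
                            li = cfg.channel_names.index(left)
                            ri = cfg.channel_names.index(right)
                            contra, ipsi = (li, ri) if d == "right" else (ri, li)
                            vals.append(r[contra] - r[ipsi])
                    trace = np.mean(vals, axis=0)
                else:
                    idx = [cfg.channel_names.index(c) for c in spec.cluster]
                    trace = np.mean([r[idx].mean(axis=0)
                                     for r in baselined.values()], axis=0)
                value = measure_component(trace, times, spec)
                rows.append(dict(lock_kind=lock, measure=spec.name, load=load,
                                 sacc_type=sacc_type, value=value))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(n_subjects: int = 15, route: RouteProfile | None = None,
                    cfg: GeneratorConfig | None = None, seed: int = 0,
                    total_distance: float = 5_000.0):
    """Simulate a multi-subject study on a shared route.

    Returns ``(route, subjects)`` where each subject is a dict with keys
    ``telemetry``, ``recording`` and ``truth``.  The default desk-scale
    cohort is 15 subjects on a 5-km route (500 segments).
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    if route is None:
        route = simulate_route(total_distance, seed=int(rng.integers(2 ** 31)))
    subjects = []
    for _ in range(n_subjects):
        tel = simulate_telemetry(route, seed=int(rng.integers(2 ** 31)))
        rec, truth = simulate_recording(route, tel, cfg,
                                        seed=int(rng.integers(2 ** 31)))
        subjects.append(dict(telemetry=tel, recording=rec, truth=truth))
    return route, subjects
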