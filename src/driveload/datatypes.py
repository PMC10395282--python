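"""Core data containers shared across the pipeline.

Conventions used throughout the package (stated once):

* sample indices are 0-based,
* event onsets are in seconds, epoch time axes in milliseconds,
* track distances are in meters, spatial bins half-open ``[i*10, (i+1)*10)``,
* EEG amplitudes are in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

#: 32-channel actiCap layout (10-20 system).  All electrode clusters used by
#: the analyses are subsets of this montage.
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

# Electrode clusters for band power and ERP component extraction.
FRONTAL_THETA_CLUSTER = ("F3", "Fz", "F4", "FC1", "FC2")
POSTERIOR_ALPHA_CLUSTER = ("P3", "Pz", "P4", "PO9", "PO10", "O1", "Oz", "O2")
OCCIPITAL_CLUSTER = ("O1", "Oz", "O2")
PARIETAL_P2_CLUSTER = ("CP1", "CP2", "P3", "Pz", "P4")
FRONTOCENTRAL_CLUSTER = ("Cz", "FC1", "FC2", "Fz")
#: left/right electrode pairs for lateralized (contra - ipsi) measures
POSTERIOR_PAIRS = (("P7", "P8"), ("PO9", "PO10"), ("O1", "O2"))
#: pairs used for time-frequency lateralization maps.  The montage carries
#: PO9/PO10 rather than PO7/PO8; the parieto-occipital pair is configurable.
TF_PAIRS = (("PO9", "PO10"), ("O1", "O2"))

LOAD_LEVELS = ("low", "medium", "high")
SACCADE_TYPES = ("outward", "inward")


class FormatError(RuntimeError):
    """Raised when an on-disk file does not follow the documented dialect."""


class ConfigurationError(ValueError):
    """Raised for invalid generator or pipeline configuration."""


@dataclass
class ContinuousRecording:
    """Multichannel EEG with optionally attached, sample-aligned telemetry.

    ``data`` is ``channels x samples`` in microvolts.  ``telemetry`` maps
    trace names (``velocity`` in km/h, ``steering`` in degrees) to arrays
    with the same sample count as ``data``.  ``trigger_samples`` is a list
    of ``(sample_index, known_distance_m)`` pairs, strictly increasing in
    sample index.
    """

    data: np.ndarray
    sample_rate: float
    channel_names: tuple[str, ...]
    telemetry: Optional[dict] = None
    telemetry_extrapolated: Optional[np.ndarray] = None
    trigger_samples: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.data.ndim != 2:
            raise ConfigurationError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        if self.telemetry is not None:
            for key, trace in self.telemetry.items():
                if len(trace) != self.n_samples:
                    raise ConfigurationError(
                        f"telemetry trace {key!r} has {len(trace)} samples, "
                        f"expected {self.n_samples}"
                    )
        samples = [s for s, _ in self.trigger_samples]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ConfigurationError("trigger samples must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def copy(self, data: Optional[np.ndarray] = None) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy() if data is None else data,
            sample_rate=self.sample_rate,
            channel_names=self.channel_names,
            telemetry=None if self.telemetry is None
            else {k: v.copy() for k, v in self.telemetry.items()},
            telemetry_extrapolated=None if self.telemetry_extrapolated is None
            else self.telemetry_extrapolated.copy(),
            trigger_samples=list(self.trigger_samples),
        )


@dataclass
class OcularEvent:
    """A blink, saccade onset, or fixation onset detected (or injected)."""

    kind: str  # blink | saccade_onset | fixation_onset
    sample: int
    direction: str = "none"  # left | right | none
    sacc_type: str = "none"  # outward | inward | none
    quality: float = float("nan")
    load_level: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("blink", "saccade_onset", "fixation_onset"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "blink" and self.direction != "none":
            raise ValueError("blink events carry no direction")

    def onset_seconds(self, sample_rate: float) -> float:
        return self.sample / sample_rate


@dataclass
class RouteProfile:
    """A scripted driving route: distance-dependent demand plus landmarks."""

    total_distance: float
    demand: Callable[[np.ndarray], np.ndarray]
    trigger_points: np.ndarray
    section_labels: list  # (start_m, end_m, tag)

    def __post_init__(self):
        if self.total_distance <= 0:
            raise ConfigurationError("total_distance must be positive")
        self.trigger_points = np.asarray(self.trigger_points, dtype=float)
        if self.trigger_points.size == 0:
            raise ConfigurationError("route needs at least one trigger point")
        if np.any(np.diff(self.trigger_points) <= 0):
            raise ConfigurationError("trigger distances must be strictly increasing")
        if (self.trigger_points.min() < 0
                or self.trigger_points.max() > self.total_distance):
            raise ConfigurationError("trigger points must lie within the track")


@dataclass
class Telemetry:
    """Driving simulator traces sampled at (nominally) 100 Hz."""

    time: np.ndarray       # seconds
    velocity: np.ndarray   # km/h
    steering: np.ndarray   # degrees
    sample_rate: float
    trigger_samples: list = field(default_factory=list)  # (sample, distance m)
    distance: Optional[np.ndarray] = None  # generator-truth distance, meters


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    events: list                    # OcularEvent with true samples/labels
    segment_demand: np.ndarray      # mean demand per 10-m segment
    segment_load: np.ndarray        # tercile label per segment (low/medium/high)
    injected_components: dict       # name -> amplitude/latency/cluster metadata
    event_rates: dict = field(default_factory=dict)


@dataclass
class ICDecomposition:
    """Linear ICA decomposition with per-component class labels."""

    mixing: np.ndarray      # channels x ICs
    unmixing: np.ndarray    # ICs x channels
    mean: np.ndarray        # channel means removed before unmixing
    rank: int
    ic_labels: Optional[list] = None  # per IC: (label, {class: prob})

    def activations(self, data: np.ndarray) -> np.ndarray:
        return self.unmixing @ (data - self.mean[:, None])

    def project_out(self, data: np.ndarray, remove: list[int]) -> np.ndarray:
        """Remove the listed ICs from channel data (weight transfer)."""
        if not len(remove):
            return data.copy()
        act = self.activations(data)
        return data - self.mixing[:, remove] @ act[remove]


@dataclass
class TrackSegment:
    """A half-open 10-m spatial bin of the track."""

    index: int
    distance_span: tuple[float, float]
    sample_span: tuple[int, int]   # [start, end) EEG samples
    theta_z: float = float("nan")
    alpha_z: float = float("nan")
    load: str = "unassigned"

    @property
    def n_samples(self) -> int:
        return self.sample_span[1] - self.sample_span[0]


@dataclass
class LoadMap:
    """Per-segment task-load terciles from the across-subject median score."""

    score: np.ndarray       # median across subjects of alpha_z - theta_z
    cutpoints: tuple        # (low/medium, medium/high) score boundaries
    labels: np.ndarray      # 'low' | 'medium' | 'high' | 'unassigned'

    def label_for_segment(self, index: int) -> str:
        return str(self.labels[index])


@dataclass
class EventLockedSet:
    """Event x channel x time array with per-event metadata."""

    data: np.ndarray        # events x channels x time, microvolts
    times: np.ndarray       # milliseconds relative to the lock event
    lock_kind: str          # blink | fixation | saccade
    channel_names: tuple[str, ...]
    metadata: "object"      # pandas DataFrame: load, direction, sacc_type, subject
    sample_rate: float
    n_dropped: int = 0

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch set") from None


@dataclass(frozen=True)
class ComponentMeasure:
    """Definition of one amplitude measure: window, cluster and polarity."""

    name: str
    lock_kind: str
    window_ms: tuple[float, float]
    cluster: tuple[str, ...]
    polarity: str           # positive | negative | mean
    lateralized: bool = False


@dataclass
class BlinkFit:
    amplitude: float
    center: float           # fractional sample of the fitted Gaussian center
    sigma_ms: float
    r2: float


@dataclass
class SaccadeTemplate:
    waveform: np.ndarray    # unit-norm, ~200 ms
    amplitude_class: str    # small | medium | large
    mean_p2p: float = float("nan")


@dataclass
class TFMap:
    power: np.ndarray       # ... x freq x time (documented per producer)
    freqs: np.ndarray
    times: np.ndarray       # milliseconds relative to lock event
    channel_names: Optional[tuple] = None
    units: str = "raw"


@dataclass
class ClusterResult:
    clusters: list          # (mask freq x time, mass, p-value)
    significant: np.ndarray # union mask of clusters below alpha
    t_map: np.ndarray
    threshold: float
    n_permutations: int

    @property
    def p_values(self) -> list[float]:
        return [p for _, _, p in self.clusters]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_effect: float
    df_error: float
    epsilon_gg: float
    p_uncorrected: float
    p_gg: float
    adj_eta_p2: Optional[float] = None
    jackknife_corrected: bool = False
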