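"""Core domain containers shared across the pipeline.

The unit of analysis is a subject who sits through a fixed session layout
(rest, digit repetition, trauma narration, digit repetition) while a
48-channel continuous-wave fNIRS montage records two-wavelength optical
density and a microphone records the narration.  These dataclasses carry
the raw and derived representations between pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

PTSD = "PTSD"
TEC = "TEC"
GROUPS = (PTSD, TEC)

TOKEN_CATEGORIES = ("negative", "positive", "neutral", "factual")


class ConfigurationError(ValueError):
    """Raised when a spec/config object violates its invariants."""


class InputError(ValueError):
    """Raised when runtime data violates an operation's preconditions."""


@dataclass
class SessionLayout:
    """Timing and probe geometry of one recording session.

    Segments are contiguous: rest, first digit repetition, narration,
    second digit repetition.  Durations in seconds.
    """

    rest_s: float = 300.0
    digits1_s: float = 30.0
    narration_s: float = 180.0
    digits2_s: float = 30.0
    fs_hz: float = 11.0
    n_channels: int = 48
    target_channel: int = 27
    wavelengths_nm: tuple[float, float] = (730.0, 850.0)
    sd_separation_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")
        if not 0 <= self.target_channel < self.n_channels:
            raise ConfigurationError("target_channel out of range")
        for name in ("rest_s", "digits1_s", "narration_s", "digits2_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.narration_s <= 0:
            raise ConfigurationError("narration segment must have positive duration")

    @property
    def total_s(self) -> float:
        return self.rest_s + self.digits1_s + self.narration_s + self.digits2_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.fs_hz))

    def segments(self) -> dict[str, tuple[float, float]]:
        """Segment name -> (start_s, end_s), contiguous and ordered."""
        t0 = 0.0
        out: dict[str, tuple[float, float]] = {}
        for name, dur in (
            ("rest", self.rest_s),
            ("digits1", self.digits1_s),
            ("narration", self.narration_s),
            ("digits2", self.digits2_s),
        ):
            out[name] = (t0, t0 + dur)
            t0 += dur
        return out

    @property
    def narration_bounds(self) -> tuple[float, float]:
        return self.segments()["narration"]


@dataclass
class NoiseParams:
    """Additive noise model applied in optical-density space.

    Amplitudes are dimensionless delta-OD.  Defaults were chosen so that
    the rest-segment fluctuation budget is dominated by slow drift and the
    cardiac pulsation, with only a small in-band (0.01-0.20 Hz) residual,
    which is the regime continuous-wave prefrontal recordings sit in.
    """

    drift_amp: float = 6.0e-4
    cardiac_hz: float = 1.1
    cardiac_amp: float = 2.0e-3
    respiratory_hz: float = 0.25
    respiratory_amp: float = 4.0e-4
    white_sd: float = 1.0e-4
    motion_spike_rate: float = 0.005  # spikes per second
    motion_spike_amp: float = 2.0e-2

    def __post_init__(self) -> None:
        for name in ("drift_amp", "cardiac_amp", "respiratory_amp", "white_sd",
                     "motion_spike_rate", "motion_spike_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def silent(self) -> "NoiseParams":
        """Copy with every noise source switched off (round-trip tests)."""
        return NoiseParams(drift_amp=0.0, cardiac_amp=0.0, respiratory_amp=0.0,
                           white_sd=0.0, motion_spike_rate=0.0,
                           cardiac_hz=self.cardiac_hz,
                           respiratory_hz=self.respiratory_hz,
                           motion_spike_amp=0.0)


@dataclass
class HrfLandmarks:
    """Piecewise-linear event-response landmarks (seconds after word onset).

    The delayed rise-fall shape: flat until ``onset_s``, linear rise to
    ``peak_amp`` at ``peak_s``, linear return to zero at ``return_s``.
    With ``shape='plateau'`` the response instead holds its full amplitude
    from ``onset_s`` until ``peak_s`` (a short 0.3 s rise for numerical
    smoothness) before declining to zero at ``return_s``.
    """

    onset_s: float = 3.82
    peak_s: float = 7.55
    return_s: float = 12.0
    peak_amp: float = 0.184
    shape: str = "risefall"

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_s < self.return_s):
            raise ConfigurationError("require onset_s <= peak_s < return_s")
        if not np.isfinite(self.peak_amp):
            raise ConfigurationError("peak_amp must be finite")
        if self.shape not in ("risefall", "plateau"):
            raise ConfigurationError(f"unknown HRF shape {self.shape!r}")


@dataclass
class EffectParams:
    """Group-level effect sizes the synthetic cohort is calibrated to.

    Rates are percent of tokens; pitch in Hz; semitone change over the
    narration; pause counts per narration; activation targets are the
    windowed, baseline-subtracted Oxy-Hb group means in rest-referenced
    z-units that the full pipeline should recover.
    """

    neg_rate_mean_ptsd: float = 5.89
    neg_rate_sd_ptsd: float = 3.00
    neg_rate_mean_tec: float = 4.21
    neg_rate_sd_tec: float = 2.83
    pos_rate_mean_ptsd: float = 2.2
    pos_rate_mean_tec: float = 2.5
    factual_rate_mean: float = 30.0

    honore_target_ptsd: float = 30.23
    honore_target_tec: float = 34.59

    pitch_mean_ptsd: float = 201.21
    pitch_sd_ptsd: float = 32.84
    pitch_mean_tec: float = 180.47
    pitch_sd_tec: float = 43.91
    semitone_mean_ptsd: float = -15.11
    semitone_sd_ptsd: float = 6.53
    semitone_mean_tec: float = -17.10
    semitone_sd_tec: float = 6.59
    pause_count_mean_ptsd: float = 385.09
    pause_count_sd_ptsd: float = 118.34
    pause_count_mean_tec: float = 362.60
    pause_count_sd_tec: float = 316.22

    hrf_tec: HrfLandmarks = field(default_factory=HrfLandmarks)
    # plateau: tonic elevation already present before each word onset,
    # held through the 10 s analysis window, with a late decline — the
    # "no apparent latency" sustained-activation state
    hrf_ptsd: HrfLandmarks = field(
        default_factory=lambda: HrfLandmarks(onset_s=-2.0, peak_s=11.0,
                                             return_s=15.0, peak_amp=0.153,
                                             shape="plateau"))
    activation_target_ptsd: float = 0.153
    activation_target_tec: float = 0.047
    hbr_ratio: float = 0.3           # delta-HbR = -ratio * delta-HbO
    amp_subject_cv: float = 0.45     # inter-subject response-amplitude CV

    token_rate_hz: float = 2.5       # spoken tokens per second
    capsD_correlation_target: float = 0.349

    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        for name in ("neg_rate_mean_ptsd", "neg_rate_mean_tec",
                     "pos_rate_mean_ptsd", "pos_rate_mean_tec",
                     "factual_rate_mean", "token_rate_hz"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def neg_rate(self, group: str) -> tuple[float, float]:
        if group == PTSD:
            return self.neg_rate_mean_ptsd, self.neg_rate_sd_ptsd
        return self.neg_rate_mean_tec, self.neg_rate_sd_tec

    def hrf(self, group: str) -> HrfLandmarks:
        return self.hrf_ptsd if group == PTSD else self.hrf_tec

    def activation_target(self, group: str) -> float:
        return (self.activation_target_ptsd if group == PTSD
                else self.activation_target_tec)


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; (spec, seed) fixes every bit."""

    n_ptsd: int = 35
    n_tec: int = 37
    seed: int = 0
    effect: EffectParams = field(default_factory=EffectParams)
    session: SessionLayout = field(default_factory=SessionLayout)

    def __post_init__(self) -> None:
        if self.n_ptsd < 2 or self.n_tec < 2:
            raise ConfigurationError("need at least 2 subjects per group")

    def subject_rng(self, subject_index: int, purpose: str) -> np.random.Generator:
        """Independent seeded stream per (subject, purpose).

        Splitting by purpose keeps e.g. the prosody draw of subject 7
        identical whether or not fNIRS was also generated.
        """
        code = int.from_bytes(purpose.encode("utf8"), "little") % (2**31)
        ss = np.random.SeedSequence((int(self.seed), int(subject_index), code))
        return np.random.Generator(np.random.PCG64(ss))


@dataclass
class SubjectRecord:
    """One participant: group membership, demographics, clinical scores."""

    id: str
    group: str
    age: float
    sex: str
    education: float
    caps5_total: float
    capsD: float
    neg_rate_true: float  # percent of tokens

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.neg_rate_true < 0:
            raise ConfigurationError("neg_rate_true must be non-negative")

    @property
    def index(self) -> int:
        return int(self.id.split("-")[-1])


@dataclass
class TimedTranscript:
    """Tokenized narration with per-token onset/offset markers (seconds)."""

    tokens: pd.DataFrame  # columns: token, onset_s, offset_s, category
    narration_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        required = {"token", "onset_s", "offset_s"}
        if not required.issubset(self.tokens.columns):
            raise InputError(f"transcript missing columns {required}")
        on = self.tokens["onset_s"].to_numpy()
        if len(on) > 1 and not np.all(np.diff(on) > 0):
            raise InputError("token onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def onsets(self) -> np.ndarray:
        return self.tokens["onset_s"].to_numpy(float)

    def onsets_for(self, category: str) -> np.ndarray:
        if "category" not in self.tokens.columns:
            raise InputError("transcript has no category labels")
        m = self.tokens["category"] == category
        return self.tokens.loc[m, "onset_s"].to_numpy(float)


@dataclass
class ProsodyTrack:
    """Frame-level fundamental-frequency track at a uniform frame rate."""

    frame_hz: float
    f0_hz: np.ndarray      # NaN on unvoiced frames
    voiced: np.ndarray     # bool

    def __post_init__(self) -> None:
        self.f0_hz = np.asarray(self.f0_hz, float)
        self.voiced = np.asarray(self.voiced, bool)
        if self.frame_hz <= 0:
            raise ConfigurationError("frame_hz must be positive")
        if self.f0_hz.shape != self.voiced.shape:
            raise InputError("f0 and voiced arrays must align")
        if np.any(self.f0_hz[self.voiced] <= 0):
            raise InputError("voiced frames must carry positive f0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.f0_hz)) / self.frame_hz


@dataclass
class OpticalRecording:
    """Two-wavelength delta optical density for every channel.

    ``od`` has shape (n_channels, n_wavelengths, n_samples); wavelength
    axis ordered as ``wavelengths_nm``.
    """

    fs_hz: float
    od: np.ndarray
    wavelengths_nm: tuple[float, float]
    segments: dict[str, tuple[float, float]]
    sd_separation_cm: float = 3.0
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, float)
        if self.od.ndim != 3 or self.od.shape[1] != len(self.wavelengths_nm):
            raise InputError("od must be (channels, wavelengths, samples)")
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")
        n = self.od.shape[2]
        for name, (a, b) in self.segments.items():
            if not (0 <= a <= b <= n / self.fs_hz + 1e-9):
                raise InputError(f"segment {name} outside recording")

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]

    def segment_slice(self, name: str) -> slice:
        a, b = self.segments[name]
        return slice(int(round(a * self.fs_hz)), int(round(b * self.fs_hz)))


@dataclass
class HemoSeries:
    """Per-channel Oxy-Hb / Deoxy-Hb concentration-change series.

    Units are micromolar-scale concentration changes after inversion and
    rest-referenced z-units once ``zscored`` is set.
    """

    fs_hz: float
    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    segments: dict[str, tuple[float, float]]
    zscored: bool = False
    bad_channels: tuple[int, ...] = ()
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 2:
            raise InputError("hbo/hbr must be matching 2-D arrays")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def segment_slice(self, name: str) -> slice:
        a, b = self.segments[name]
        return slice(int(round(a * self.fs_hz)), int(round(b * self.fs_hz)))


@dataclass
class EventWindowSet:
    """Event-locked windows for one subject at one channel (z-units)."""

    subject_id: str
    channel: int
    onsets_s: np.ndarray
    windows: np.ndarray  # (n_events, n_window_samples)
    fs_hz: float

    @property
    def n_events(self) -> int:
        return self.windows.shape[0]


@dataclass
class TimecourseProfile:
    """Landmark characterisation of a group-average event-locked curve."""

    latency_s: Optional[float]
    slope_per_sample: Optional[float]
    slope_per_second: Optional[float]
    peak_value: float
    peak_time_s: float
    difference: float
    spearman_r: float
    spearman_p: float
    no_latency: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ChannelTestResult:
    """Channelwise Mann-Whitney group comparison with BH-FDR adjustment."""

    channel: int
    u_stat: float
    p_value: float
    q_value: float
    cliffs_delta: float
    median_ptsd: float
    median_tec: float
    n_ptsd: int
    n_tec: int
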