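"""Synthetic postural-perturbation sessions: EEG, handle force, ground truth.

The generator emulates a support-withdrawal balance experiment: a standing
subject leans on two handles; at unpredictable times one handle drops,
evoking a fronto-central perturbation-evoked potential (PEP) in the EEG and
a rapid loss of reaction force on the perturbed handle.  Every downstream
stage of the package (filtering, onset marking, spatial filtering,
classification, evaluation) can therefore be exercised end to end without
any recorded data.

The evoked model has three components, all time-locked to perturbation
onset:

* **N1** - a large fronto-central negativity (default -14.75 uV at FCZ,
  62 ms), the primary feature of balance perturbations;
* **P2** - a smaller frontal positivity (default +5 uV at FZ, 167 ms);
* a **sustained negativity** over fronto-central sites while the subject is
  actively destabilised and recovering (default 30 % of the N1 amplitude,
  plateau from ~0.4 s to 1.2 s, resolved by 1.8 s).

Background activity is spatially correlated 1/f^gamma noise built from a
small number of smooth latent scalp sources plus independent sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import fft

from .montage import DEFAULT_60, electrode_xy

Side = Literal["left", "right"]


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EventMarker:
    """A single perturbation event: sample index of onset and perturbed side."""

    onset_sample: int
    side: Side

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError("onset_sample must be >= 0")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class Recording:
    """Continuous multichannel EEG (uV) with 10-10 labels and event markers."""

    data: np.ndarray  # (n_channels, n_samples)
    channel_labels: tuple[str, ...]
    sampling_rate: float
    events: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_labels = tuple(str(c).upper() for c in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        onsets = [e.onset_sample for e in self.events]
        if any(o2 <= o1 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.n_samples):
            raise ValueError("event onsets must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label.upper())
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_sample for e in self.events], dtype=int)


@dataclass
class ForceTrace:
    """Left/right handle reaction force (N) sampled in sync with the EEG."""

    left: np.ndarray
    right: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise ValueError("left and right traces must be 1-D and equal length")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("force values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.left.size

    def side(self, which: Side) -> np.ndarray:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise ValueError(f"side must be 'left' or 'right', got {which!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic perturbation session.

    Amplitudes are in uV, latencies/widths in ms, durations in s, forces
    in N.  ``seed`` fully determines every random draw.
    """

    channel_labels: tuple[str, ...] = DEFAULT_60
    sampling_rate: float = 1000.0
    n_trials: int = 50
    rest_duration_range: tuple[float, float] = (5.0, 15.0)

    # evoked response
    n1_amplitude: float = -14.75
    n1_latency: float = 62.0
    n1_half_width: float = 60.0
    p2_amplitude: float = 5.0
    p2_latency: float = 167.0
    p2_half_width: float = 100.0
    # sustained instability-state negativity, as a fraction of the N1
    # amplitude (same fronto-central topography, opposite of none -> knob
    # scales to zero together with the transient peaks)
    sustained_ratio: float = 0.3
    sustained_rise: tuple[float, float] = (280.0, 420.0)
    sustained_fall: tuple[float, float] = (1200.0, 1800.0)
    # Gaussian scalp gain: fraction of the peak amplitude retained at C3/C4
    lateral_gain: float = 0.4
    # optional per-trial N1 amplitude jitter (uV, truncated to keep N1 < 0)
    amplitude_jitter_sd: float = 0.0
    # optional left/right template asymmetry (0 = identical templates)
    asymmetry: float = 0.0

    # background noise
    noise_rms: float = 12.0
    noise_spectral_exponent: float = 1.0
    n_noise_sources: int = 12
    sensor_noise_fraction: float = 0.1

    # handle force
    force_baseline: float = 180.0
    force_drop: float = 130.0
    force_drop_window: float = 300.0
    force_increase: float = 60.0

    side_sequence: str | tuple[Side, ...] = "random"
    lead_in: float = 5.0
    lead_out: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "channel_labels", tuple(str(c).upper() for c in self.channel_labels)
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        lo, hi = self.rest_duration_range
        if not (0 < lo < hi):
            raise ConfigurationError("rest_duration_range must satisfy 0 < low < high")
        if self.n_trials <= 0:
            raise ConfigurationError("n_trials must be positive")
        if not self.n1_latency < self.p2_latency:
            raise ConfigurationError("n1_latency must precede p2_latency")
        if not (self.n1_amplitude <= 0 <= self.p2_amplitude):
            raise ConfigurationError("need n1_amplitude <= 0 <= p2_amplitude")
        if self.noise_rms < 0:
            raise ConfigurationError("noise_rms must be non-negative")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")
        if not (0 < self.lateral_gain < 1):
            raise ConfigurationError("lateral_gain must be in (0, 1)")
        if not (0 <= self.sensor_noise_fraction < 1):
            raise ConfigurationError("sensor_noise_fraction must be in [0, 1)")
        if isinstance(self.side_sequence, str):
            if self.side_sequence != "random":
                raise ConfigurationError("side_sequence must be 'random' or a tuple")
        elif any(s not in ("left", "right") for s in self.side_sequence):
            raise ConfigurationError("side_sequence entries must be 'left'/'right'")
        for name in ("FCZ", "FZ"):
            if name not in self.channel_labels:
                raise ConfigurationError(f"channel labels must include {name}")
        return self

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def template_duration(self) -> float:
        """Template length in ms (>= 500; longer when the sustained part is on)."""
        if self.sustained_ratio != 0.0:
            return max(500.0, self.sustained_fall[1])
        return 500.0

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# evoked template
# --------------------------------------------------------------------------


def _hann_lobe(t_ms: np.ndarray, amplitude: float, latency: float, half_width: float) -> np.ndarray:
    """Raised-cosine lobe peaking at `latency`, supported on +-half_width."""
    u = (t_ms - latency) / half_width
    lobe = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    return amplitude * lobe


def _plateau(t_ms: np.ndarray, rise: tuple[float, float], fall: tuple[float, float]) -> np.ndarray:
    """Smooth 0->1->0 envelope: cosine ramps over `rise` and `fall`."""
    r0, r1 = rise
    f0, f1 = fall
    env = np.zeros_like(t_ms)
    up = (t_ms >= r0) & (t_ms < r1)
    env[up] = 0.5 * (1.0 - np.cos(np.pi * (t_ms[up] - r0) / (r1 - r0)))
    env[(t_ms >= r1) & (t_ms <= f0)] = 1.0
    down = (t_ms > f0) & (t_ms < f1)
    env[down] = 0.5 * (1.0 + np.cos(np.pi * (t_ms[down] - f0) / (f1 - f0)))
    return env


def scalp_gain(config: SimulationConfig, center: str) -> np.ndarray:
    """Gaussian spatial gain over the cap, 1 at `center`.

    The width is calibrated so that C3 (when present; otherwise the most
    distant electrode at the C3 distance scale) retains ``lateral_gain`` of
    the peak amplitude.
    """
    xy = electrode_xy(config.channel_labels)
    cxy = electrode_xy([center])[0]
    ref = electrode_xy(["FCZ", "C3"])
    d_ref = float(np.linalg.norm(ref[0] - ref[1]))
    sigma = d_ref / np.sqrt(2.0 * np.log(1.0 / config.lateral_gain))
    d2 = np.sum((xy - cxy) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def make_erp_template(config: SimulationConfig) -> np.ndarray:
    """Evoked-response template (channels x samples, uV), t = 0 at onset.

    The FCZ channel attains its minimum, exactly ``n1_amplitude``, at
    ``n1_latency``; the FZ channel attains its maximum, exactly
    ``p2_amplitude``, at ``p2_latency``.  The sustained negativity begins
    after the P2 lobe has resolved, so it does not disturb either peak.
    """
    config.validate()
    fs = config.sampling_rate
    n = int(round(config.template_duration * fs / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / fs

    n1 = _hann_lobe(t_ms, config.n1_amplitude, config.n1_latency, config.n1_half_width)
    p2 = _hann_lobe(t_ms, config.p2_amplitude, config.p2_latency, config.p2_half_width)
    g_fcz = scalp_gain(config, "FCZ")
    g_fz = scalp_gain(config, "FZ")

    template = np.outer(g_fcz, n1) + np.outer(g_fz, p2)
    if config.sustained_ratio != 0.0:
        sp_amp = config.sustained_ratio * config.n1_amplitude
        sp = sp_amp * _plateau(t_ms, config.sustained_rise, config.sustained_fall)
        template += np.outer(g_fcz, sp)
    return template


# --------------------------------------------------------------------------
# background noise
# --------------------------------------------------------------------------


def _powerlaw_rows(rng: np.random.Generator, n_rows: int, n_samples: int, exponent: float) -> np.ndarray:
    """Unit-RMS rows with power spectral density proportional to 1/f^exponent.

    The FFT length is padded to a fast (5-smooth) size and the result
    trimmed, which changes runtime, not the statistics.
    """
    n_fft = fft.next_fast_len(n_samples)
    white = rng.standard_normal((n_rows, n_samples))
    spec = fft.rfft(white, n=n_fft, axis=1)
    f = fft.rfftfreq(n_fft)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = fft.irfft(spec * shaping, n=n_fft, axis=1)[:, :n_samples]
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def make_background_noise(
    config: SimulationConfig,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Spatially correlated 1/f^gamma background EEG (channels x samples, uV).

    A handful of latent power-law sources with smooth Gaussian scalp maps are
    mixed into the channels; independent per-channel power-law sensor noise
    is added, and every channel is scaled to exactly ``noise_rms``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    config.validate()
    if config.noise_rms == 0.0:
        return np.zeros((config.n_channels, n_samples))
    if rng is None:
        rng = np.random.default_rng(config.seed)

    xy = electrode_xy(config.channel_labels)
    k = min(config.n_noise_sources, config.n_channels)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    centers = rng.uniform(lo, hi, size=(k, 2))
    spread = 0.35 * float(np.linalg.norm(hi - lo))
    d2 = np.sum((xy[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    mixing = np.exp(-d2 / (2.0 * spread**2)) * rng.standard_normal(k)

    sources = _powerlaw_rows(rng, k, n_samples, config.noise_spectral_exponent)
    mixed = mixing @ sources
    row_rms = np.sqrt(np.mean(mixed**2, axis=1, keepdims=True))
    row_rms[row_rms == 0] = 1.0
    mixed /= row_rms

    frac = config.sensor_noise_fraction
    if frac > 0:
        sensor = _powerlaw_rows(
            rng, config.n_channels, n_samples, config.noise_spectral_exponent
        )
        noise = np.sqrt(1.0 - frac) * mixed + np.sqrt(frac) * sensor
    else:
        noise = mixed
    noise *= config.noise_rms / np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
    return noise


# --------------------------------------------------------------------------
# handle force
# --------------------------------------------------------------------------

_FORCE_TAU_FRACTION = 0.2  # decline time constant as fraction of the drop window
_RECOVERY_START = 0.5      # s after onset at which the subject regains force
_RECOVERY_TAU = 1.2        # s, exponential recovery
_PROFILE_END = 4.0         # s; transient returns exactly to baseline here


def _event_profiles(config: SimulationConfig, n_post: int) -> tuple[np.ndarray, np.ndarray]:
    """(perturbed-side drop, contralateral rise) force deviations from onset on."""
    fs = config.sampling_rate
    t = np.arange(n_post) / fs
    tau_d = _FORCE_TAU_FRACTION * config.force_drop_window / 1000.0
    window_s = config.force_drop_window / 1000.0
    drop_inf = config.force_drop / (1.0 - np.exp(-window_s / tau_d))
    decline = drop_inf * (1.0 - np.exp(-t / tau_d))
    rise = config.force_increase * (1.0 - np.exp(-t / (3.0 * tau_d)))

    recovery = np.exp(-np.maximum(0.0, t - _RECOVERY_START) / _RECOVERY_TAU)
    taper = np.ones_like(t)
    ramp = (t > _PROFILE_END - 1.0) & (t < _PROFILE_END)
    taper[ramp] = 0.5 * (1.0 + np.cos(np.pi * (t[ramp] - (_PROFILE_END - 1.0))))
    taper[t >= _PROFILE_END] = 0.0
    env = recovery * taper
    return decline * env, rise * env


def make_force_trace(
    config: SimulationConfig, onset_sample: int, n_samples: int, side: Side
) -> ForceTrace:
    """Single-event handle-force trace.

    The perturbed side holds a constant baseline, then loses ``force_drop``
    N within ``force_drop_window`` ms along a fast saturating decline (over
    80 N in the first 100 ms at defaults); the contralateral side pushes
    harder as the subject compensates; both sides drift back to baseline
    within a few seconds.
    """
    config.validate()
    if not (0 <= onset_sample < n_samples):
        raise ValueError("onset_sample must lie within [0, n_samples)")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    base = config.force_baseline
    perturbed = np.full(n_samples, base)
    contra = np.full(n_samples, base)
    drop, rise = _event_profiles(config, n_samples - onset_sample)
    perturbed[onset_sample:] -= drop
    contra[onset_sample:] += rise
    left, right = (perturbed, contra) if side == "left" else (contra, perturbed)
    return ForceTrace(left=left, right=right, sampling_rate=config.sampling_rate)


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------


def draw_rest_intervals(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Inter-event rest durations (s), uniform over ``rest_duration_range``."""
    lo, hi = config.rest_duration_range
    return rng.uniform(lo, hi, size=config.n_trials)


def draw_sides(config: SimulationConfig, rng: np.random.Generator) -> list[Side]:
    """Perturbation side per trial: configured sequence or fair coin flips."""
    if isinstance(config.side_sequence, tuple):
        seq = list(config.side_sequence)
        if len(seq) != config.n_trials:
            raise ConfigurationError("side_sequence length must equal n_trials")
        return seq
    return ["left" if u < 0.5 else "right" for u in rng.uniform(size=config.n_trials)]


def generate_session(
    config: SimulationConfig,
) -> tuple[Recording, ForceTrace, list[EventMarker]]:
    """Simulate one full session: EEG recording, handle force, ground truth.

    Events are separated by uniform rests; the EEG is background noise plus
    the evoked template added at each onset (optionally jittered in
    amplitude and/or scaled asymmetrically by side); the force trace carries
    the matching drop/compensation transient, sample-aligned with the EEG.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate

    rests = draw_rest_intervals(config, rng)
    sides = draw_sides(config, rng)
    onset_times = config.lead_in + np.cumsum(rests)
    onsets = np.round(onset_times * fs).astype(int)
    n_samples = int(round((onset_times[-1] + config.lead_out) * fs))

    jitter = np.zeros(config.n_trials)
    if config.amplitude_jitter_sd > 0 and config.n1_amplitude != 0:
        jitter = rng.normal(0.0, config.amplitude_jitter_sd, size=config.n_trials)
        # keep the jittered N1 strictly negative
        jitter = np.clip(jitter, None, -config.n1_amplitude - 1e-9)

    data = make_background_noise(config, n_samples, rng=rng)
    template = make_erp_template(config)
    tlen = template.shape[1]
    events: list[EventMarker] = []
    for onset, side, dj in zip(onsets, sides, jitter):
        scale = 1.0
        if config.n1_amplitude != 0:
            scale = (config.n1_amplitude + dj) / config.n1_amplitude
        if config.asymmetry != 0.0:
            scale *= 1.0 + (0.5 if side == "left" else -0.5) * config.asymmetry
        stop = min(onset + tlen, n_samples)
        data[:, onset:stop] += scale * template[:, : stop - onset]
        events.append(EventMarker(onset_sample=int(onset), side=side))

    recording = Recording(
        data=data,
        channel_labels=config.channel_labels,
        sampling_rate=fs,
        events=events,
    )

    left = np.full(n_samples, config.force_baseline)
    right = np.full(n_samples, config.force_baseline)
    for ev in events:
        drop, rise = _event_profiles(config, n_samples - ev.onset_sample)
        if ev.side == "left":
            left[ev.onset_sample :] -= drop
            right[ev.onset_sample :] += rise
        else:
            right[ev.onset_sample :] -= drop
            left[ev.onset_sample :] += rise
    force = ForceTrace(left=left, right=right, sampling_rate=fs)
    return recording, force, events
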