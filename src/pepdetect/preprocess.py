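"""Signal conditioning, force-based onset marking, epoching and windowing.

The conditioning chain follows common event-related-potential practice for
slow perturbation-evoked components: a zero-phase 0.1-10 Hz Butterworth
bandpass (suppressing EMG, slow cortical drift and most sensorimotor
rhythms), decimation to 50 Hz, epoching from -2 s to +4 s around each
perturbation onset, and 500 ms sliding windows for single-trial
classification.  Window coordinates are 0-based, half-open
``[start, start + window)`` in ms relative to the perturbation onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import ConfigurationError, ForceTrace, Recording, Side

logger = logging.getLogger(__name__)

REST = "rest"
INSTABILITY = "instability"
#: test windows overlapping the onset; excluded from scalar rate aggregates
TRANSITION = "transition"


# --------------------------------------------------------------------------
# epoch container
# --------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Fixed-length EEG windows with trial identity and onset-relative offsets.

    ``offset_ms[i]`` is the start of window ``i`` relative to its trial's
    perturbation onset.  ``labels`` may be ``None`` for raw onset-locked
    epochs that have not yet been windowed.
    """

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    trial_id: np.ndarray  # (n_epochs,) int
    offset_ms: np.ndarray  # (n_epochs,) float
    sampling_rate: float
    labels: np.ndarray | None = None  # (n_epochs,) str
    sides: np.ndarray | None = None  # (n_epochs,) str, perturbation side

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs x channels x samples)")
        n = self.epochs.shape[0]
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.offset_ms = np.asarray(self.offset_ms, dtype=float)
        for name in ("trial_id", "offset_ms"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per epoch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per epoch")
        if self.sides is not None:
            self.sides = np.asarray(self.sides, dtype=object)
            if self.sides.shape != (n,):
                raise ValueError("sides must have one entry per epoch")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            epochs=self.epochs[mask],
            trial_id=self.trial_id[mask],
            offset_ms=self.offset_ms[mask],
            sampling_rate=self.sampling_rate,
            labels=None if self.labels is None else self.labels[mask],
            sides=None if self.sides is None else self.sides[mask],
        )

    def for_trials(self, trial_ids) -> "EpochSet":
        return self.subset(np.isin(self.trial_id, np.asarray(trial_ids)))

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        fs = parts[0].sampling_rate
        if any(p.sampling_rate != fs for p in parts):
            raise ValueError("sampling rates differ")
        has_labels = all(p.labels is not None for p in parts)
        has_sides = all(p.sides is not None for p in parts)
        return EpochSet(
            epochs=np.concatenate([p.epochs for p in parts]),
            trial_id=np.concatenate([p.trial_id for p in parts]),
            offset_ms=np.concatenate([p.offset_ms for p in parts]),
            sampling_rate=fs,
            labels=np.concatenate([p.labels for p in parts]) if has_labels else None,
            sides=np.concatenate([p.sides for p in parts]) if has_sides else None,
        )


@dataclass
class SplitPlan:
    """Trial-wise train/test assignments, one pair of id arrays per fold.

    Folds are independent random subsamples (default 45 train / 5 test of 50
    trials), not a disjoint partition; within each fold train and test are
    guaranteed disjoint so no trial contributes to both.
    """

    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


# --------------------------------------------------------------------------
# filtering / resampling
# --------------------------------------------------------------------------


def bandpass(recording: Recording, low: float = 0.1, high: float = 10.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass, applied forward-backward per channel.

    Zero-phase (``sosfiltfilt``) filtering is used so that component
    latencies are not shifted by the filter's group delay.
    """
    nyq = recording.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ConfigurationError(
            f"need 0 < low < high < Nyquist ({nyq} Hz); got [{low}, {high}]"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(
        data=filtered,
        channel_labels=recording.channel_labels,
        sampling_rate=recording.sampling_rate,
        events=list(recording.events),
    )


def downsample(recording: Recording, target: float = 50.0) -> Recording:
    """Decimate to `target` Hz; the preceding bandpass is the anti-alias stage.

    Event onsets are mapped by integer division of the decimation factor.
    """
    ratio = recording.sampling_rate / target
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ConfigurationError(
            f"sampling rate {recording.sampling_rate} not divisible by {target}"
        )
    from .simulate import EventMarker

    events = [
        EventMarker(onset_sample=e.onset_sample // factor, side=e.side)
        for e in recording.events
    ]
    return Recording(
        data=recording.data[:, ::factor].copy(),
        channel_labels=recording.channel_labels,
        sampling_rate=target,
        events=events,
    )


# --------------------------------------------------------------------------
# onset marking from handle force
# --------------------------------------------------------------------------


class OnsetNotFoundError(RuntimeError):
    """No perturbation onset detected in the force trace."""


def mark_onset_from_force(
    force: ForceTrace,
    search_window: tuple[int, int] | None = None,
    side: Side | str = "auto",
    smooth_width: int = 11,
) -> int:
    """Perturbation onset = argmax |second difference| of the handle force.

    The perturbed-side force is lightly smoothed (moving average of
    ``smooth_width`` samples, odd) and the sample with the largest-magnitude
    discrete second difference inside ``search_window`` is returned.  With
    ``side='auto'`` the side with the stronger curvature is used.
    """
    if smooth_width < 1 or smooth_width % 2 == 0:
        raise ValueError("smooth_width must be a positive odd integer")
    if force.n_samples < 3:
        raise ValueError("force trace too short (need >= 3 samples)")
    lo, hi = (0, force.n_samples) if search_window is None else search_window
    if not (0 <= lo < hi <= force.n_samples):
        raise ValueError("search_window must lie within the trace")

    def curvature(x: np.ndarray) -> np.ndarray:
        if smooth_width > 1:
            kernel = np.ones(smooth_width) / smooth_width
            pad = smooth_width // 2
            xp = np.pad(x, pad, mode="edge")
            x = np.convolve(xp, kernel, mode="valid")
        d2 = np.zeros_like(x)
        d2[1:-1] = np.abs(np.diff(x, n=2))
        return d2

    if side == "auto":
        cands = [curvature(force.left), curvature(force.right)]
        c = max(cands, key=lambda d: d[lo:hi].max())
    else:
        c = curvature(force.side(side))
    window = c[lo:hi]
    if window.max() <= 0.0:
        raise OnsetNotFoundError("no onset detected: force curvature is zero")
    return lo + int(np.argmax(window))


# --------------------------------------------------------------------------
# epoching and windowing
# --------------------------------------------------------------------------


def segment(recording: Recording, pre: float = 2.0, post: float = 4.0) -> EpochSet:
    """One onset-locked epoch per event, spanning ``[-pre, +post)`` seconds.

    Events too close to a recording edge are dropped with a logged warning.
    """
    fs = recording.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    length = n_pre + n_post
    epochs, trial_ids, sides = [], [], []
    for i, ev in enumerate(recording.events):
        start = ev.onset_sample - n_pre
        stop = ev.onset_sample + n_post
        if start < 0 or stop > recording.n_samples:
            logger.warning(
                "dropping event %d at sample %d: epoch [-%g, %g] s exceeds recording",
                i, ev.onset_sample, pre, post,
            )
            continue
        epochs.append(recording.data[:, start:stop])
        trial_ids.append(i)
        sides.append(ev.side)
    shape = (len(epochs), recording.n_channels, length)
    return EpochSet(
        epochs=np.array(epochs, dtype=float).reshape(shape),
        trial_id=np.array(trial_ids, dtype=int),
        offset_ms=np.full(len(epochs), -pre * 1000.0),
        sampling_rate=fs,
        sides=np.array(sides, dtype=object) if sides else np.empty(0, dtype=object),
    )


def make_split(trial_ids, n_test: int = 5, n_folds: int = 10, seed: int = 0) -> SplitPlan:
    """Random train/test subsampling plan: per fold, `n_test` held-out trials.

    Folds are drawn independently (with a fresh subsample each), so the same
    trial may be tested in several folds but never trains and tests in one.
    """
    trial_ids = np.asarray(trial_ids)
    if n_test <= 0:
        raise ConfigurationError("n_test must be positive")
    if n_test >= trial_ids.size:
        raise ConfigurationError("n_test must be smaller than the number of trials")
    if n_folds <= 0:
        raise ConfigurationError("n_folds must be positive")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        test = rng.choice(trial_ids, size=n_test, replace=False)
        train = np.setdiff1d(trial_ids, test)
        folds.append((np.sort(train), np.sort(test)))
    return SplitPlan(folds=folds)


def _window_index(epochset: EpochSet, start_ms: float, window_samples: int) -> int:
    """Sample index of a window start inside the stored epochs; bounds-checked."""
    fs = epochset.sampling_rate
    idx_f = (start_ms - epochset.offset_ms[0]) * fs / 1000.0
    idx = int(round(idx_f))
    if abs(idx_f - idx) > 1e-6:
        raise ConfigurationError(
            f"window start {start_ms} ms does not fall on the {fs} Hz sample grid"
        )
    if idx < 0 or idx + window_samples > epochset.n_samples:
        raise ConfigurationError(
            f"window [{start_ms}, {start_ms + window_samples * 1000.0 / fs}) ms "
            "exceeds epoch bounds"
        )
    return idx


def _slice_windows(epochset: EpochSet, starts_ms: np.ndarray, window_samples: int,
                   labels: list[str]) -> EpochSet:
    """Cut one window per (epoch, start) pair; epochs iterate outermost."""
    fs = epochset.sampling_rate
    out, tids, offs, labs, sds = [], [], [], [], []
    for i in range(len(epochset)):
        for s_ms, lab in zip(starts_ms, labels):
            idx = _window_index(epochset, s_ms, window_samples)
            out.append(epochset.epochs[i, :, idx : idx + window_samples])
            tids.append(epochset.trial_id[i])
            offs.append(s_ms)
            labs.append(lab)
            if epochset.sides is not None:
                sds.append(epochset.sides[i])
    return EpochSet(
        epochs=np.array(out, dtype=float),
        trial_id=np.array(tids, dtype=int),
        offset_ms=np.array(offs, dtype=float),
        sampling_rate=fs,
        labels=np.array(labs, dtype=object),
        sides=np.array(sds, dtype=object) if sds else None,
    )


def augment_training_windows(
    epochset: EpochSet,
    window_ms: float = 500.0,
    n_rest: int = 20,
    slide_start: float = -300.0,
    slide_stop: float = 100.0,
    step: float = 20.0,
    rest_start_range: tuple[float, float] = (-2000.0, -500.0),
    seed: int = 0,
) -> EpochSet:
    """Training-set augmentation: random rest + sliding instability windows.

    Per trial: ``n_rest`` windows with start times drawn uniformly on the
    sample grid over ``rest_start_range`` (defaults keep them entirely
    pre-onset), labelled rest; and instability windows whose starts slide
    from ``slide_start`` up to (excluding) ``slide_stop`` in ``step`` ms
    increments - 20 windows at the defaults.
    """
    fs = epochset.sampling_rate
    w = int(round(window_ms * fs / 1000.0))
    inst_starts = np.arange(slide_start, slide_stop - 1e-9, step)
    rng = np.random.default_rng(seed)

    lo_idx = _window_index(epochset, rest_start_range[0], w)
    # rest windows must fit: latest admissible start
    hi_ms = rest_start_range[1]
    hi_idx = _window_index(epochset, hi_ms, w)
    if hi_idx < lo_idx:
        raise ConfigurationError("rest_start_range is empty")

    parts = []
    for i in range(len(epochset)):
        one = epochset.subset(np.arange(len(epochset)) == i)
        rest_idx = rng.integers(lo_idx, hi_idx + 1, size=n_rest)
        rest_starts = epochset.offset_ms[0] + rest_idx * 1000.0 / fs
        parts.append(_slice_windows(one, rest_starts, w, [REST] * n_rest))
        parts.append(_slice_windows(one, inst_starts, w, [INSTABILITY] * len(inst_starts)))
    return EpochSet.concatenate(parts)


def extract_test_windows(
    epochset: EpochSet,
    window_ms: float = 500.0,
    start: float = -500.0,
    stop: float = 500.0,
    step: float = 20.0,
) -> EpochSet:
    """Sequential test windows with starts from `start` to `stop` inclusive.

    Ground-truth labels follow the window-position convention: instability
    if the start is at or after onset, rest if the window ends at or before
    onset, transition otherwise (scored per offset but excluded from scalar
    rate aggregates).
    """
    fs = epochset.sampling_rate
    w = int(round(window_ms * fs / 1000.0))
    starts = np.arange(start, stop + 1e-9, step)

    def label(s_ms: float) -> str:
        if s_ms >= 0:
            return INSTABILITY
        if s_ms + window_ms <= 0:
            return REST
        return TRANSITION

    labels = [label(s) for s in starts]
    return _slice_windows(epochset, starts, w, labels)
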