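"""Detection performance: per-offset curves, latency, false alarms, transfer.

The detector is scored the way an online system would be used: 500 ms test
windows slide across each held-out trial from 500 ms before to 500 ms after
the perturbation onset, and the per-offset fraction of windows classified
"instability" forms the detection curve.  From it come the scalar metrics:

* **false alarm rate** - fraction of fully pre-onset windows classified
  instability;
* **maximum detection rate** and its **peak timing** over post-onset
  offsets;
* **detection latency** - the earliest post-onset window-start offset whose
  detection rate reaches the criterion (90 % by default).

`cross_validate` repeats the whole train/test pipeline over random 45/5
trial splits; `cross_task` trains on one perturbation side and tests on the
other to measure generalization to an unlearned event type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import blda as _blda
from . import preprocess as prep
from . import xdawn as _xdawn
from .config import EvaluationSection, ModelSection, PipelineConfig, PreprocessSection
from .preprocess import INSTABILITY, REST, EpochSet
from .simulate import Recording

logger = logging.getLogger(__name__)

NOT_REACHED = "not reached"


# --------------------------------------------------------------------------
# curves and scalar metrics
# --------------------------------------------------------------------------


@dataclass
class DetectionCurve:
    """Fraction of test windows classified instability, per window offset."""

    offsets_ms: np.ndarray
    rate: np.ndarray
    n_windows: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_ms = np.asarray(self.offsets_ms, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.n_windows = np.asarray(self.n_windows, dtype=int)
        if not (self.offsets_ms.shape == self.rate.shape == self.n_windows.shape):
            raise ValueError("offsets, rate and n_windows must align")
        if np.any(np.diff(self.offsets_ms) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any((self.rate < 0) | (self.rate > 1)):
            raise ValueError("rates must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_ms": self.offsets_ms, "rate": self.rate, "n": self.n_windows}
        )


def detection_curve(
    offset_ms: np.ndarray, scores: np.ndarray, model: _blda.BLDAModel
) -> DetectionCurve:
    """Group window scores by offset and threshold them with the model.

    Every trial must contribute a score at every offset, so each offset's
    rate is computed over the same number of windows.
    """
    offset_ms = np.asarray(offset_ms, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if offset_ms.size == 0:
        raise ValueError("no windows to score")
    if np.isnan(model.threshold):
        raise ValueError("model threshold has not been set")
    uniq = np.unique(offset_ms)
    counts = np.array([(offset_ms == o).sum() for o in uniq])
    if len(set(counts.tolist())) != 1:
        raise ValueError("every trial must have scores at the same offsets")
    rate = np.array(
        [(scores[offset_ms == o] > model.threshold).mean() for o in uniq]
    )
    return DetectionCurve(offsets_ms=uniq, rate=rate, n_windows=counts)


def detection_latency(curve: DetectionCurve, criterion: float = 90.0) -> float | str:
    """Earliest offset >= 0 ms with rate >= criterion (%), else "not reached"."""
    if curve.offsets_ms.size == 0:
        raise ValueError("empty detection curve")
    post = curve.offsets_ms >= 0
    hits = post & (curve.rate >= criterion / 100.0)
    if not hits.any():
        return NOT_REACHED
    return float(curve.offsets_ms[hits][0])


def false_alarm_rate(labels, decisions) -> float:
    """Percent of rest-labelled windows classified instability."""
    labels = np.asarray(labels, dtype=object)
    decisions = np.asarray(decisions, dtype=bool)
    rest = labels == REST
    if not rest.any():
        raise ValueError("no rest-labelled windows")
    return 100.0 * float(decisions[rest].mean())


# --------------------------------------------------------------------------
# fold execution
# --------------------------------------------------------------------------


@dataclass
class FoldResult:
    """Metrics of one train/test split."""

    curve: DetectionCurve
    false_alarm_rate: float  # %
    detection_rate_max: float  # %
    peak_timing_ms: float
    detection_latency_ms: float  # nan when the criterion is never reached
    latency_reached: bool
    n_train_trials: int
    n_test_trials: int
    spatial_model: _xdawn.SpatialFilterModel | None = None
    classifier: _blda.BLDAModel | None = None


def _epochs_as_continuous(train_epochs: EpochSet) -> tuple[Recording, np.ndarray]:
    """Concatenate onset-locked training epochs into one continuous signal.

    Fitting xDAWN on this concatenation keeps the fit strictly inside the
    training trials.  Onsets sit at the epochs' stored offset.
    """
    n, _, s = train_epochs.epochs.shape
    fs = train_epochs.sampling_rate
    data = np.concatenate(list(train_epochs.epochs), axis=1)
    onset_in_epoch = int(round(-train_epochs.offset_ms[0] * fs / 1000.0))
    onsets = onset_in_epoch + s * np.arange(n)
    rec = Recording(
        data=data,
        channel_labels=[f"CH{i}" for i in range(train_epochs.n_channels)],
        sampling_rate=fs,
    )
    return rec, onsets


def train_detector(
    train_epochs: EpochSet,
    pp: PreprocessSection,
    mdl: ModelSection,
    seed: int = 0,
) -> tuple[_xdawn.SpatialFilterModel, _blda.BLDAModel]:
    """Augment, fit xDAWN + normalizer + BLDA, and set the median threshold."""
    augmented = prep.augment_training_windows(
        train_epochs,
        window_ms=pp.window_ms,
        n_rest=pp.n_rest,
        slide_start=pp.slide_start,
        slide_stop=pp.slide_stop,
        step=pp.slide_step,
        rest_start_range=pp.rest_start_range,
        seed=seed,
    )
    window = int(round(pp.window_ms * train_epochs.sampling_rate / 1000.0))
    continuous, onsets = _epochs_as_continuous(train_epochs)
    spatial = _xdawn.fit_xdawn(continuous, onsets, window, n_components=mdl.n_components)

    feats = _xdawn.apply_xdawn(spatial, augmented)
    _xdawn.fit_normalizer(spatial, feats)
    feats = _xdawn.apply_normalizer(spatial, feats)
    classifier = _blda.fit_blda(
        feats,
        augmented.labels,
        max_iter=mdl.blda_max_iter,
        tol=mdl.blda_tol,
        balanced_targets=mdl.balanced_targets,
    )
    scores = _blda.decision_values(classifier, feats)
    _blda.set_threshold(classifier, scores)
    return spatial, classifier


def score_windows(
    spatial: _xdawn.SpatialFilterModel,
    classifier: _blda.BLDAModel,
    windows: EpochSet,
) -> np.ndarray:
    """Discriminant scores of test windows under a fitted detector."""
    feats = _xdawn.apply_normalizer(spatial, _xdawn.apply_xdawn(spatial, windows))
    return _blda.decision_values(classifier, feats)


def evaluate_fold(
    epochs: EpochSet,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    pp: PreprocessSection,
    mdl: ModelSection,
    criterion: float = 90.0,
    seed: int = 0,
    permute_labels_rng: np.random.Generator | None = None,
    keep_models: bool = False,
) -> FoldResult:
    """Run one complete train/test split and compute its metrics.

    ``permute_labels_rng`` shuffles the augmented training labels before the
    classifier fit - the permutation control used to verify that detection
    collapses to chance when the label/feature link is broken.
    """
    overlap = np.intersect1d(train_ids, test_ids)
    if overlap.size:
        raise ValueError(f"train/test trial overlap: {overlap}")
    train_epochs = epochs.for_trials(train_ids)
    test_epochs = epochs.for_trials(test_ids)
    if len(train_epochs) < 2 or len(test_epochs) < 1:
        raise ValueError("not enough trials in the split")

    if permute_labels_rng is None:
        spatial, classifier = train_detector(train_epochs, pp, mdl, seed=seed)
    else:
        spatial, classifier = _train_permuted(
            train_epochs, pp, mdl, seed, permute_labels_rng
        )

    windows = prep.extract_test_windows(
        test_epochs,
        window_ms=pp.window_ms,
        start=pp.test_start,
        stop=pp.test_stop,
        step=pp.test_step,
    )
    scores = score_windows(spatial, classifier, windows)
    curve = detection_curve(windows.offset_ms, scores, classifier)

    fa = false_alarm_rate(windows.labels, scores > classifier.threshold)
    post = curve.offsets_ms >= 0
    peak_idx = int(np.argmax(curve.rate[post]))
    peak_timing = float(curve.offsets_ms[post][peak_idx])
    dr_max = 100.0 * float(curve.rate[post].max())
    lat = detection_latency(curve, criterion)
    reached = lat != NOT_REACHED
    return FoldResult(
        curve=curve,
        false_alarm_rate=fa,
        detection_rate_max=dr_max,
        peak_timing_ms=peak_timing,
        detection_latency_ms=float(lat) if reached else float("nan"),
        latency_reached=reached,
        n_train_trials=len(train_epochs),
        n_test_trials=len(test_epochs),
        spatial_model=spatial if keep_models else None,
        classifier=classifier if keep_models else None,
    )


def _train_permuted(train_epochs, pp, mdl, seed, rng):
    """train_detector with the augmented labels shuffled (permutation null)."""
    augmented = prep.augment_training_windows(
        train_epochs,
        window_ms=pp.window_ms,
        n_rest=pp.n_rest,
        slide_start=pp.slide_start,
        slide_stop=pp.slide_stop,
        step=pp.slide_step,
        rest_start_range=pp.rest_start_range,
        seed=seed,
    )
    augmented.labels = rng.permutation(augmented.labels)
    window = int(round(pp.window_ms * train_epochs.sampling_rate / 1000.0))
    continuous, onsets = _epochs_as_continuous(train_epochs)
    spatial = _xdawn.fit_xdawn(continuous, onsets, window, n_components=mdl.n_components)
    feats = _xdawn.apply_xdawn(spatial, augmented)
    _xdawn.fit_normalizer(spatial, feats)
    feats = _xdawn.apply_normalizer(spatial, feats)
    classifier = _blda.fit_blda(
        feats, augmented.labels, max_iter=mdl.blda_max_iter, tol=mdl.blda_tol,
        balanced_targets=mdl.balanced_targets,
    )
    _blda.set_threshold(classifier, _blda.decision_values(classifier, feats))
    return spatial, classifier


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------


@dataclass
class PerformanceReport:
    """Fold-level metrics plus their mean +- sd aggregation."""

    folds: list[FoldResult]
    criterion: float
    protocol: str = "cross_validation"
    failed_folds: list[int] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def offsets_ms(self) -> np.ndarray:
        return self.folds[0].curve.offsets_ms

    @property
    def mean_curve(self) -> DetectionCurve:
        rates = np.mean([f.curve.rate for f in self.folds], axis=0)
        n = np.sum([f.curve.n_windows for f in self.folds], axis=0)
        return DetectionCurve(offsets_ms=self.offsets_ms, rate=rates, n_windows=n)

    def _agg(self, values: np.ndarray) -> tuple[float, float]:
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            return float("nan"), float("nan")
        return float(values.mean()), float(values.std(ddof=1)) if values.size > 1 else 0.0

    @property
    def false_alarm_rate(self) -> tuple[float, float]:
        return self._agg([f.false_alarm_rate for f in self.folds])

    @property
    def detection_rate_max(self) -> tuple[float, float]:
        return self._agg([f.detection_rate_max for f in self.folds])

    @property
    def detection_latency_ms(self) -> tuple[float, float]:
        return self._agg([f.detection_latency_ms for f in self.folds])

    @property
    def peak_timing_ms(self) -> tuple[float, float]:
        return self._agg([f.peak_timing_ms for f in self.folds])

    @property
    def latency_reached_fraction(self) -> float:
        return float(np.mean([f.latency_reached for f in self.folds]))

    def mean_rate(self, min_offset_ms: float = 0.0) -> float:
        """Mean detection rate (%) of the fold-averaged curve from an offset on."""
        c = self.mean_curve
        sel = c.offsets_ms >= min_offset_ms
        if not sel.any():
            raise ValueError("no offsets at or beyond the requested start")
        return 100.0 * float(c.rate[sel].mean())

    def summary(self) -> dict:
        fa = self.false_alarm_rate
        dr = self.detection_rate_max
        lat = self.detection_latency_ms
        pk = self.peak_timing_ms
        return {
            "protocol": self.protocol,
            "n_folds": self.n_folds,
            "criterion_percent": self.criterion,
            "false_alarm_rate_percent": {"mean": fa[0], "sd": fa[1]},
            "detection_rate_max_percent": {"mean": dr[0], "sd": dr[1]},
            "detection_latency_ms": {
                "mean": lat[0],
                "sd": lat[1],
                "reached_fraction": self.latency_reached_fraction,
            },
            "peak_timing_ms": {"mean": pk[0], "sd": pk[1]},
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds):
            rows.append(
                {
                    "fold": i,
                    "false_alarm_rate": f.false_alarm_rate,
                    "detection_rate_max": f.detection_rate_max,
                    "detection_latency_ms": f.detection_latency_ms,
                    "peak_timing_ms": f.peak_timing_ms,
                    "latency_reached": f.latency_reached,
                    "n_train_trials": f.n_train_trials,
                    "n_test_trials": f.n_test_trials,
                }
            )
        frame = pd.DataFrame(rows)
        agg = frame.drop(columns=["fold", "latency_reached"]).agg(["mean", "std"])
        agg.insert(0, "fold", agg.index)
        return pd.concat([frame, agg], ignore_index=True)


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------


def preprocess_session(recording: Recording, pp: PreprocessSection) -> tuple[Recording, EpochSet]:
    """Bandpass + decimate (if not already at the target rate) and epoch."""
    rec = recording
    if rec.sampling_rate != pp.target_rate:
        rec = prep.bandpass(rec, pp.band_low, pp.band_high, pp.filter_order)
        rec = prep.downsample(rec, pp.target_rate)
    epochs = prep.segment(rec, pre=pp.epoch_pre, post=pp.epoch_post)
    return rec, epochs


def cross_validate(
    recording: Recording,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> PerformanceReport:
    """Full pipeline under repeated random 45/5 trial splits.

    Per fold: augment the training trials, fit xDAWN + normalizer + BLDA on
    them alone, then slide test windows over the held-out trials.  A failing
    fold is recorded, excluded from the aggregates, and warned about.
    """
    config = config or PipelineConfig()
    ev = config.evaluation
    if seed is None:
        seed = ev.seed
    _, epochs = preprocess_session(recording, config.preprocessing)
    plan = prep.make_split(
        np.unique(epochs.trial_id), n_test=ev.n_test, n_folds=ev.n_folds, seed=seed
    )
    return _run_folds(epochs, plan, config, seed, protocol="cross_validation")


def _run_folds(epochs, plan, config, seed, protocol) -> PerformanceReport:
    folds, failed = [], []
    for i, (train_ids, test_ids) in enumerate(plan):
        fold_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        try:
            folds.append(
                evaluate_fold(
                    epochs,
                    train_ids,
                    test_ids,
                    config.preprocessing,
                    config.model,
                    criterion=config.evaluation.criterion,
                    seed=fold_seed,
                )
            )
        except Exception:  # noqa: BLE001 - fold failures must not kill the run
            logger.warning("fold %d failed; excluded from aggregates", i, exc_info=True)
            failed.append(i)
    if not folds:
        raise RuntimeError("every fold failed")
    return PerformanceReport(
        folds=folds, criterion=config.evaluation.criterion, protocol=protocol,
        failed_folds=failed,
    )


def cross_task(
    recording: Recording,
    train_side: str,
    test_side: str,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> PerformanceReport:
    """Train on one perturbation side, test on the other (or the same) side.

    All trials of ``train_side`` train the detector; all trials of
    ``test_side`` are evaluated.  When the sides coincide, held-out
    evaluation is preserved by splitting that side's trials 90/10.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.evaluation.seed
    for side in (train_side, test_side):
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    _, epochs = preprocess_session(recording, config.preprocessing)
    if epochs.sides is None:
        raise ValueError("epochs carry no side information")
    train_pool = np.unique(epochs.trial_id[epochs.sides == train_side])
    test_pool = np.unique(epochs.trial_id[epochs.sides == test_side])
    if train_pool.size < 2 or test_pool.size < 1:
        raise ValueError("need at least 2 trials per side")

    if train_side == test_side:
        n_test = max(1, test_pool.size // 10)
        plan = prep.make_split(train_pool, n_test=n_test, n_folds=1, seed=seed)
    else:
        plan = prep.SplitPlan(folds=[(train_pool, test_pool)])
    return _run_folds(
        epochs, plan, config, seed, protocol=f"cross_task:{train_side}->{test_side}"
    )
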