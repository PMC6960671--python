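"""On-disk formats: EDF+ recordings, CSV force/event tables, model bundles.

Recordings travel as EDF+ (one 16-bit signal per channel, events as EDF+
annotations); EDF files are read back through MNE.  Force traces and event
tables are plain CSV.  Epoch sets and fitted models are stored as an NPZ
array container with a JSON sidecar holding the bookkeeping, so the numeric
payload and the metadata stay separately inspectable.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .blda import BLDAModel
from .preprocess import EpochSet
from .simulate import EventMarker, ForceTrace, Recording
from .xdawn import SpatialFilterModel

logger = logging.getLogger(__name__)

_ANNOTATION_SAMPLES = 60  # 120 bytes of TAL space per 1-s record


def _ascii(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        raise ValueError(f"field {text!r} exceeds {width} ascii characters")
    return text.ljust(width).encode("ascii")


def _physical_limit(data: np.ndarray) -> float:
    """Symmetric physical range covering the data, short enough for EDF headers."""
    peak = float(np.max(np.abs(data))) if data.size else 1.0
    return float(np.ceil(peak)) + 1.0


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write an EDF+ file: one signal per channel plus an annotation channel.

    Samples are quantized to 16 bits over a per-channel symmetric physical
    range; the recording is zero-padded to a whole number of 1-second data
    records.  Each event becomes an EDF+ annotation whose text is the
    perturbed side.
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : recording.n_samples] = recording.data

    lims = np.array([_physical_limit(padded[c]) for c in range(n_ch)])
    # encode with the EDF decode convention: value = (digital - dmin) * scale + pmin
    scale = 2.0 * lims[:, None] / 65535.0
    digital = np.clip(
        np.round((padded + lims[:, None]) / scale) - 32768.0, -32768, 32767
    ).astype("<i2")

    ns = n_ch + 1
    header = bytearray()
    header += _ascii(0, 8)
    header += _ascii("X X X X", 80)
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (ns + 1), 8)
    header += _ascii("EDF+C", 44)
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)
    header += _ascii(ns, 4)

    labels = [f"EEG {c}" for c in recording.channel_labels] + ["EDF Annotations"]
    header += b"".join(_ascii(lab, 16) for lab in labels)
    header += b"".join(_ascii("", 80) for _ in range(ns))
    header += b"".join(_ascii("uV", 8) for _ in range(n_ch)) + _ascii("", 8)
    header += b"".join(_ascii(f"{-l:g}", 8) for l in lims) + _ascii(-1, 8)
    header += b"".join(_ascii(f"{l:g}", 8) for l in lims) + _ascii(1, 8)
    header += b"".join(_ascii(-32768, 8) for _ in range(ns))
    header += b"".join(_ascii(32767, 8) for _ in range(ns))
    header += b"".join(_ascii("", 80) for _ in range(ns))
    header += b"".join(_ascii(spr, 8) for _ in range(n_ch))
    header += _ascii(_ANNOTATION_SAMPLES, 8)
    header += b"".join(_ascii("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    events_by_record: dict[int, list[EventMarker]] = {}
    for ev in recording.events:
        events_by_record.setdefault(ev.onset_sample // spr, []).append(ev)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec_i in range(n_records):
            fh.write(digital[:, rec_i * spr : (rec_i + 1) * spr].tobytes(order="C"))
            tal = f"+{rec_i}\x14\x14\x00".encode("ascii")
            for ev in events_by_record.get(rec_i, []):
                onset_s = ev.onset_sample / fs
                tal += f"+{onset_s:.6f}\x14{ev.side}\x14\x00".encode("ascii")
            block = tal.ljust(2 * _ANNOTATION_SAMPLES, b"\x00")
            if len(block) > 2 * _ANNOTATION_SAMPLES:
                raise ValueError("annotation block overflow; too many events per second")
            fh.write(block)
    return path


def read_recording(path: str | Path, expected_channels: int | None = None) -> Recording:
    """Read an EDF+ recording (via MNE); annotations become event markers.

    Raises a descriptive error when the file carries no event annotations
    (every downstream stage is event-locked) or when ``expected_channels``
    is given and does not match the file.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> uV
    labels = [name.removeprefix("EEG ").strip().upper() for name in raw.ch_names]
    if expected_channels is not None and len(labels) != expected_channels:
        raise ValueError(
            f"{path}: expected {expected_channels} channels, found {len(labels)}"
        )

    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        desc = str(desc).strip().lower()
        if desc in ("left", "right"):
            events.append(EventMarker(onset_sample=int(round(onset * fs)), side=desc))
    if not events:
        raise ValueError(
            f"{path} contains no perturbation-event annotations "
            "(expected EDF+ annotations with text 'left' or 'right')"
        )
    return Recording(data=data, channel_labels=labels, sampling_rate=fs, events=events)


# --------------------------------------------------------------------------
# CSV tables
# --------------------------------------------------------------------------


def write_force(force: ForceTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "sample": np.arange(force.n_samples),
            "left_N": force.left,
            "right_N": force.right,
        }
    ).to_csv(path, index=False)
    return path


def read_force(path: str | Path, sampling_rate: float) -> ForceTrace:
    table = pd.read_csv(path)
    for col in ("left_N", "right_N"):
        if col not in table:
            raise ValueError(f"{path}: missing column {col!r}")
    return ForceTrace(
        left=table["left_N"].to_numpy(),
        right=table["right_N"].to_numpy(),
        sampling_rate=sampling_rate,
    )


def write_events(events: list[EventMarker], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"onset_sample": [e.onset_sample for e in events], "side": [e.side for e in events]}
    ).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[EventMarker]:
    table = pd.read_csv(path)
    return [
        EventMarker(onset_sample=int(row.onset_sample), side=str(row.side))
        for row in table.itertuples()
    ]


# --------------------------------------------------------------------------
# NPZ + JSON bundles
# --------------------------------------------------------------------------


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """EpochSet -> `<path>.npz` (tensor) + `<path>.json` (bookkeeping)."""
    path = Path(path).with_suffix("")
    np.savez_compressed(path.with_suffix(".npz"), epochs=epochs.epochs)
    meta = {
        "sampling_rate": epochs.sampling_rate,
        "trial_id": epochs.trial_id.tolist(),
        "offset_ms": epochs.offset_ms.tolist(),
        "labels": None if epochs.labels is None else [str(x) for x in epochs.labels],
        "sides": None if epochs.sides is None else [str(x) for x in epochs.sides],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npz")


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path).with_suffix("")
    with np.load(path.with_suffix(".npz")) as npz:
        tensor = npz["epochs"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        epochs=tensor,
        trial_id=np.array(meta["trial_id"], dtype=int),
        offset_ms=np.array(meta["offset_ms"], dtype=float),
        sampling_rate=float(meta["sampling_rate"]),
        labels=None if meta["labels"] is None else np.array(meta["labels"], dtype=object),
        sides=None if meta["sides"] is None else np.array(meta["sides"], dtype=object),
    )


def save_model(spatial: SpatialFilterModel, classifier: BLDAModel, path: str | Path) -> Path:
    """Detector bundle -> `<path>.npz` (arrays) + `<path>.json` (scalars)."""
    path = Path(path).with_suffix("")
    np.savez_compressed(
        path.with_suffix(".npz"),
        filters=spatial.filters,
        evoked_estimate=spatial.evoked_estimate,
        component_scores=spatial.component_scores,
        norm_mean=spatial.norm_mean,
        norm_sd=spatial.norm_sd,
        weights=classifier.weights,
    )
    meta = {
        "window": spatial.window,
        "alpha": classifier.alpha,
        "beta": classifier.beta,
        "threshold": classifier.threshold,
        "n_iterations_used": classifier.n_iterations_used,
        "converged": classifier.converged,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> tuple[SpatialFilterModel, BLDAModel]:
    path = Path(path).with_suffix("")
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    spatial = SpatialFilterModel(
        filters=arrays["filters"],
        evoked_estimate=arrays["evoked_estimate"],
        component_scores=arrays["component_scores"],
        window=int(meta["window"]),
        norm_mean=arrays["norm_mean"],
        norm_sd=arrays["norm_sd"],
    )
    classifier = BLDAModel(
        weights=arrays["weights"],
        alpha=float(meta["alpha"]),
        beta=float(meta["beta"]),
        threshold=float(meta["threshold"]),
        n_iterations_used=int(meta["n_iterations_used"]),
        converged=bool(meta["converged"]),
    )
    return spatial, classifier
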