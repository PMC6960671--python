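"""Scalp electrode geometry for the 10-10 system.

Channel labels are handled uppercase throughout the package (``FCZ``, not
``FCz``); lookups into the MNE montage are case-insensitive.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

# 60-channel cap layout (10-10 names), fronto-polar to occipital row order.
DEFAULT_60: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
)


@functools.lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            mont = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # pragma: no cover - montage renamed upstream
            mont = mne.channels.make_standard_montage("colin27_1005")
    pos = mont.get_positions()["ch_pos"]
    return {name.upper(): np.asarray(xyz, dtype=float) for name, xyz in pos.items()}


def electrode_xy(labels) -> np.ndarray:
    """2-D head-plane coordinates (metres) for 10-10 channel labels.

    The x/y components of the standard montage's 3-D positions are used as a
    flat projection; this is adequate for smooth scalp-gain models, which only
    need relative inter-electrode distances.
    """
    pos = _montage_positions()
    out = np.empty((len(labels), 2), dtype=float)
    for i, lab in enumerate(labels):
        key = str(lab).upper()
        if key not in pos:
            raise KeyError(f"unknown 10-10 channel label: {lab!r}")
        out[i] = pos[key][:2]
    return out
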