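"""Signal conditioning: Butterworth band-pass, average reference, epoching.

The conditioning chain mirrors standard resting-state microstate practice:
zero-phase band-pass filtering of the continuous recording, re-referencing to
the common average, splitting into non-overlapping 2-s epochs, and keeping the
first ``n_keep`` artefact-free epochs (an amplitude threshold stands in for
manual/ICA artefact screening, which is out of scope for synthetic inputs).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import EpochSet, Recording

__all__ = [
    "bandpass_filter",
    "average_reference",
    "epoch_and_select",
    "InsufficientEpochsError",
]


class InsufficientEpochsError(RuntimeError):
    """Raised when a recording yields fewer clean epochs than requested."""


def bandpass_filter(
    rec: Recording, low_hz: float, high_hz: float, order: int = 2
) -> Recording:
    """Zero-phase Butterworth band-pass of the stated design order.

    The filter is applied forward and backward (``sosfiltfilt``) so microstate
    timing is not phase-shifted; the effective magnitude response is the
    squared design response.  DC is removed by construction.
    """
    if not (0.0 < low_hz < high_hz < rec.fs / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < fs/2 = {rec.fs / 2}"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                     output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(out, rec.fs, list(rec.channel_labels), rec.reference)


def average_reference(rec: Recording) -> Recording:
    """Re-reference every sample to the across-channel average.

    Idempotent; invariant to any common-mode (reference) signal.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(out, rec.fs, list(rec.channel_labels), reference="average")


def epoch_and_select(
    rec: Recording,
    epoch_s: float = 2.0,
    n_keep: int = 30,
    reject_threshold_uv: float | None = None,
) -> EpochSet:
    """Cut contiguous non-overlapping epochs and keep the first clean ones.

    Epochs containing any sample with ``|value| > reject_threshold_uv`` are
    dropped; the first ``n_keep`` survivors (in temporal order) are returned.

    Raises
    ------
    InsufficientEpochsError
        If fewer than ``n_keep`` clean epochs are available, mirroring the
        exclusion of subjects with too few artefact-free epochs.
    """
    if not epoch_s > 0 or n_keep < 1:
        raise ValueError("epoch_s must be positive and n_keep >= 1")
    spe = int(round(rec.fs * epoch_s))
    n_candidates = rec.n_samples // spe
    if n_candidates < n_keep:
        raise InsufficientEpochsError(
            f"recording holds {n_candidates} epochs of {epoch_s} s, "
            f"need {n_keep}"
        )
    kept: list[np.ndarray] = []
    for i in range(n_candidates):
        ep = rec.data[:, i * spe : (i + 1) * spe]
        if reject_threshold_uv is not None and np.max(np.abs(ep)) > reject_threshold_uv:
            continue
        kept.append(ep)
        if len(kept) == n_keep:
            break
    if len(kept) < n_keep:
        raise InsufficientEpochsError(
            f"only {len(kept)} artefact-free epochs (< {n_keep}); "
            "subject would be excluded"
        )
    return EpochSet(np.stack(kept), rec.fs, epoch_s, list(rec.channel_labels))
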