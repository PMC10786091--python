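"""Minimal epoch preprocessing: band-pass filter, baseline, rejection.

Operations never alter the time axis or channel labels; rejection marks
trials in a per-subject keep mask rather than physically dropping them, so
the trial dimension stays aligned with the design table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .exceptions import DegenerateDataError, ParameterError
from .simulate import EpochSet

__all__ = ["RejectionLog", "filter_epochs", "baseline_correct", "reject_artifacts"]


@dataclass
class RejectionLog:
    """Per-trial keep/drop bookkeeping.

    ``table`` has one row per (subject, trial) with columns ``subject``,
    ``trial_index``, ``kept`` and ``reason`` (empty, ``amplitude`` or
    ``incorrect_response``); ``proportion_dropped`` = dropped / total.
    """

    table: pd.DataFrame

    @property
    def proportion_dropped(self) -> float:
        return float(1.0 - self.table["kept"].mean())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def filter_epochs(
    epochs: EpochSet, low_hz: float, high_hz: float, order: int = 4
) -> EpochSet:
    """Zero-phase Butterworth band-pass along the time axis.

    ``low_hz = 0`` gives a pure low-pass; with ``low_hz > 0`` the DC
    component is removed.  Forward-backward application (``sosfiltfilt``)
    preserves component latencies.
    """
    nyq = epochs.fs / 2.0
    if not (0.0 <= low_hz < high_hz < nyq):
        raise ParameterError(
            f"need 0 <= low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    if low_hz > 0:
        sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=epochs.fs,
                     output="sos")
    else:
        sos = butter(order, high_hz, btype="lowpass", fs=epochs.fs, output="sos")
    # a low high-pass edge has a long impulse response; extend the default
    # reflection padding accordingly (capped by the epoch length)
    n_time = epochs.data.shape[-1]
    padlen = min(n_time - 1, max(3 * (2 * len(sos) + 1),
                                 int(2 * epochs.fs / max(low_hz, 1.0))))
    out = sosfiltfilt(sos, epochs.data, axis=-1, padlen=padlen).astype(
        epochs.data.dtype
    )
    return epochs.copy_with(data=out)


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``[start, end)`` ms."""
    idx = epochs.time_indices(window_ms)
    if idx.size == 0:
        raise ParameterError(f"baseline window {window_ms} contains no samples")
    base = epochs.data[..., idx].mean(axis=-1, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def reject_artifacts(
    epochs: EpochSet,
    behavior: pd.DataFrame | None = None,
    threshold_uv: float = 70.0,
) -> tuple[EpochSet, RejectionLog]:
    """Drop trials exceeding ±``threshold_uv`` or answered incorrectly.

    A trial is rejected when its absolute amplitude on any channel/sample
    strictly exceeds the threshold, or (if ``behavior`` is given) when it
    is an incongruent trial with ``correct == False``.  Raises
    :class:`DegenerateDataError` if any subject is left with zero trials
    for some classifier, mirroring the exclusion of participants with an
    empty per-item cell.
    """
    if threshold_uv <= 0:
        raise ParameterError("threshold_uv must be positive")
    n_s, n_t = epochs.data.shape[:2]
    amp_bad = np.abs(epochs.data).max(axis=(2, 3)) > threshold_uv  # (S, T)

    resp_bad = np.zeros((n_s, n_t), dtype=bool)
    if behavior is not None:
        wrong = behavior[~behavior["correct"]]
        pos = {t: i for i, t in enumerate(epochs.design.trials["trial_index"])}
        for subj, tidx in zip(wrong["subject"], wrong["trial_index"]):
            resp_bad[int(subj), pos[int(tidx)]] = True

    keep = ~(amp_bad | resp_bad)
    if epochs.keep_mask is not None:
        keep &= epochs.keep_mask

    clf_ids = epochs.design.trials["classifier_id"].to_numpy()
    for s in range(n_s):
        surviving = set(clf_ids[keep[s]])
        missing = set(clf_ids) - surviving
        if missing:
            raise DegenerateDataError(
                f"subject {s} has no surviving trials for {sorted(missing)}"
            )

    reason = np.where(amp_bad, "amplitude",
                      np.where(resp_bad, "incorrect_response", ""))
    table = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_s), n_t),
            "trial_index": np.tile(
                epochs.design.trials["trial_index"].to_numpy(), n_s
            ),
            "kept": keep.ravel(),
            "reason": reason.ravel(),
        }
    )
    return epochs.copy_with(keep_mask=keep), RejectionLog(table)
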