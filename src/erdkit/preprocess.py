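"""Band-pass filtering and epoch windowing.

The acquisition pipeline being reproduced band-passes offline to 0.1-30 Hz;
here the filter is a zero-phase forward-backward Butterworth (4th order per
pass, applied per channel per trial), which preserves ERD latency instead of
introducing the causal delay of an online filter. Time windows are half-open
``[start, end)`` in seconds relative to MI onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .trials import TrialSet

__all__ = ["FilterSpec", "bandpass", "crop_window"]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass specification.

    ``order`` is the order of the underlying one-pass design; the effective
    magnitude response is squared by the forward-backward application.
    """

    low_cut: float = 0.1
    high_cut: float = 30.0
    order: int = 4

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= sampling_rate / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz >= Nyquist ({sampling_rate / 2} Hz)"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sampling_rate: float) -> np.ndarray:
        return signal.butter(
            self.order,
            [self.low_cut, self.high_cut],
            btype="bandpass",
            fs=sampling_rate,
            output="sos",
        )


def bandpass(trials: TrialSet, spec: FilterSpec = FilterSpec()) -> TrialSet:
    """Apply a zero-phase band-pass to every channel of every trial.

    Shape, labels and time axis are unchanged. Trials shorter than the
    filter's padding requirement are rejected rather than silently filtered
    with unusable edge transients.
    """
    spec.validate(trials.sampling_rate)
    sos = spec.sos(trials.sampling_rate)
    min_len = 3 * (2 * sos.shape[0] + 1)
    if trials.n_samples <= min_len:
        raise ValueError(
            f"trials of {trials.n_samples} samples are shorter than the filter "
            f"warm-up ({min_len} samples)"
        )
    # the low cut's long time constant needs far more reflection padding than
    # the sosfiltfilt default to keep the edge transient out of the epoch
    padlen = int(
        min(trials.n_samples - 1, 3 * trials.sampling_rate / spec.low_cut)
    )
    out = signal.sosfiltfilt(sos, trials.data, axis=-1, padlen=max(padlen, min_len))
    return replace(trials, data=np.ascontiguousarray(out))


def crop_window(trials: TrialSet, t_start: float, t_end: float) -> TrialSet:
    """Keep samples with time in ``[t_start, t_end)`` relative to MI onset."""
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    fs = trials.sampling_rate
    # integer sample arithmetic keeps repeated crops exact (idempotence)
    i0 = round((t_start - trials.time_origin) * fs)
    i1 = round((t_end - trials.time_origin) * fs)
    i0_c, i1_c = max(i0, 0), min(i1, trials.n_samples)
    if i0 != i0_c or i1 != i1_c:
        raise ValueError(
            f"window [{t_start}, {t_end}) s not inside recorded span "
            f"[{trials.time_origin}, {trials.times[-1] + 1 / fs}) s"
        )
    if i1 <= i0:
        raise ValueError("window selects no samples")
    return replace(
        trials,
        data=trials.data[:, :, i0:i1].copy(),
        time_origin=trials.time_origin + i0 / fs,
    )
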