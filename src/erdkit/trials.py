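"""Trial-structured multichannel EEG container.

A :class:`TrialSet` holds epoched EEG as a dense ``(trials, channels,
samples)`` array together with the metadata every downstream stage needs:
sampling rate, channel labels (10/20 names), one condition label per trial
and the time of the first sample relative to motor-imagery (MI) onset.
Time is anchored at MI onset throughout the package: ``t = 0`` is the start
of the imagery window, negative times are baseline/cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TrialSet"]


@dataclass
class TrialSet:
    """Epoched multichannel EEG with condition labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in arbitrary amplitude units (uV for real recordings).
    sampling_rate : float
        Sampling frequency in Hz.
    channel_labels : sequence of str
        10/20 electrode names, one per channel.
    condition_labels : sequence of str
        One condition name per trial (e.g. ``"HFMI"`` / ``"LFMI"``).
    subject_id : str
        Identifier of the recorded or simulated subject.
    time_origin : float
        Time of the first sample in seconds relative to MI onset
        (negative when the epoch starts in the pre-cue baseline).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    condition_labels: np.ndarray = field(default_factory=lambda: np.array([]))
    subject_id: str = "S?"
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got ndim={self.data.ndim}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_labels = list(self.channel_labels)
        self.condition_labels = np.asarray(self.condition_labels, dtype=object)
        n_trials, n_channels, _ = self.data.shape
        if len(self.channel_labels) != n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {n_channels} channels"
            )
        if len(self.condition_labels) != n_trials:
            raise ValueError(
                f"{len(self.condition_labels)} condition labels for {n_trials} trials"
            )

    # -- shape helpers -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds relative to MI onset."""
        return self.time_origin + np.arange(self.n_samples) / self.sampling_rate

    @property
    def conditions(self) -> list[str]:
        """Sorted unique condition names."""
        return sorted(set(self.condition_labels.tolist()))

    # -- selection -----------------------------------------------------
    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None

    def select_condition(self, condition: str) -> "TrialSet":
        """Return the subset of trials with the given condition label."""
        mask = self.condition_labels == condition
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return replace(
            self, data=self.data[mask], condition_labels=self.condition_labels[mask]
        )

    def select_trials(self, indices) -> "TrialSet":
        indices = np.asarray(indices)
        return replace(
            self,
            data=self.data[indices],
            condition_labels=self.condition_labels[indices],
        )

    def copy(self) -> "TrialSet":
        return replace(
            self, data=self.data.copy(), condition_labels=self.condition_labels.copy()
        )

    @staticmethod
    def concatenate(parts: list["TrialSet"]) -> "TrialSet":
        """Stack several trial sets recorded on the same grid."""
        first = parts[0]
        for p in parts[1:]:
            if p.n_samples != first.n_samples or p.n_channels != first.n_channels:
                raise ValueError("all parts must share channel and sample counts")
            if p.sampling_rate != first.sampling_rate:
                raise ValueError("all parts must share the sampling rate")
        return replace(
            first,
            data=np.concatenate([p.data for p in parts], axis=0),
            condition_labels=np.concatenate([p.condition_labels for p in parts]),
        )
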