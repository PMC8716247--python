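"""Time-frequency ERD quantification, energy curves and spectral entropy.

The event-related spectral perturbation (ERSP) is the trial-averaged
magnitude-squared short-time Fourier transform,

    ERSP(f, t) = (1/n) * sum_k |F_k(f, t)|^2 ,

converted to dB relative to the per-frequency mean power over a pre-cue
baseline interval (the standard ERD convention: negative dB during the task
= desynchronization). The mean ERD of a band x time window is the arithmetic
mean of the dB surface over that rectangle.

Collapsing the ERSP over the MI window gives the frequency-domain energy
curve; its minimum inside a band's search range is the *characteristic
frequency* and the contiguous below-baseline run around it is the
*characteristic band*. The spectral entropy is the Shannon entropy
``-sum p_i ln p_i`` of the STFT power density normalized to a discrete
probability over frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .trials import TrialSet

__all__ = [
    "StftParams",
    "ERSPMap",
    "ERDSummary",
    "EnergyCurve",
    "CharacteristicResult",
    "SpectralEntropyResult",
    "ersp",
    "erd_mean",
    "energy_curve",
    "characteristic_frequency",
    "spectral_entropy",
    "entropy_of_density",
    "ALPHA_BAND",
    "BETA_BAND",
]

#: Band search ranges (Hz) used for characteristic-frequency extraction.
ALPHA_BAND: tuple[float, float] = (8.0, 13.0)
BETA_BAND: tuple[float, float] = (14.0, 30.0)


@dataclass(frozen=True)
class StftParams:
    """STFT analysis parameters: Hann window, fractional overlap, and the
    frequency grid step obtained by zero-padding.

    The 1 s default window makes the effective spectral resolution match the
    1 Hz grid; shorter windows smear the alpha and beta ERD troughs into each
    other (a 0.5 s Hann main lobe is ~4 Hz wide at its nulls) and bias the
    characteristic frequency.
    """

    window_s: float = 1.0
    overlap: float = 0.9
    freq_resolution: float = 1.0

    def segment(self, fs: float) -> tuple[int, int, int]:
        """(nperseg, noverlap, nfft) for a given sampling rate."""
        nperseg = round(self.window_s * fs)
        if nperseg < 8:
            raise ValueError("STFT window shorter than 8 samples")
        noverlap = min(round(self.overlap * nperseg), nperseg - 1)
        nfft = max(nperseg, round(fs / self.freq_resolution))
        return nperseg, noverlap, nfft


@dataclass
class ERSPMap:
    """Trial-averaged time-frequency surface in dB re. baseline.

    ``values`` is frequency x time; ``power`` retains the raw (pre-dB)
    trial-averaged power on the same grid so trial-set unions stay linear.
    """

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray
    n_trials: int
    baseline_interval: tuple[float, float]
    channel: str = ""
    condition: str = ""
    subject_id: str = ""
    power: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("values must be (n_freqs, n_times)")
        if not np.all(np.diff(self.freqs) > 0) or not np.all(np.diff(self.times) > 0):
            raise ValueError("freqs and times must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("ERSP values must be finite")


@dataclass(frozen=True)
class ERDSummary:
    """Mean ERD (dB) over one band x window rectangle; smaller (more
    negative) means stronger desynchronization."""

    band: tuple[float, float]
    window: tuple[float, float]
    erd_db: float
    channel: str = ""
    condition: str = ""
    subject_id: str = ""


@dataclass
class EnergyCurve:
    """Per-frequency mean dB over a time window; 0 dB is the baseline."""

    freqs: np.ndarray
    energy_db: np.ndarray
    baseline_level: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.energy_db = np.asarray(self.energy_db, dtype=float)
        if self.freqs.shape != self.energy_db.shape:
            raise ValueError("freqs and energy_db must have equal length")
        if not np.isfinite(self.energy_db).all():
            raise ValueError("energy values must be finite")


@dataclass(frozen=True)
class CharacteristicResult:
    """Characteristic frequency/band of an energy curve.

    ``no_erd`` is set (with ``None`` frequency/band) when the curve never
    dips below baseline inside the search range — a valid outcome, distinct
    from an error.
    """

    characteristic_frequency: Optional[float]
    characteristic_band: Optional[tuple[float, float]]
    band_name: str
    no_erd: bool = False


@dataclass
class SpectralEntropyResult:
    """Normalized STFT power density over frequency bins and its Shannon
    entropy in nats (0 <= H <= ln n_bins)."""

    freqs: np.ndarray
    density_bins: np.ndarray
    entropy: float


# ----------------------------------------------------------------------


def _trial_spectrograms(
    trials: TrialSet, channel: str, params: StftParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial magnitude-squared STFT: (freqs, times, power[trial, f, t])."""
    fs = trials.sampling_rate
    nperseg, noverlap, nfft = params.segment(fs)
    if nperseg > trials.n_samples:
        raise ValueError(
            f"STFT window ({nperseg} samples) longer than trial "
            f"({trials.n_samples} samples)"
        )
    x = trials.data[:, trials.channel_index(channel), :]
    freqs, times, power = signal.spectrogram(
        x,
        fs=fs,
        window=signal.get_window("hann", nperseg),
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
        scaling="density",
        mode="psd",
        axis=-1,
    )
    return freqs, times + trials.time_origin, power


def ersp(
    trials: TrialSet,
    channel: str,
    stft_params: StftParams = StftParams(),
    baseline_interval: tuple[float, float] = (-2.5, -0.6),
    freq_range: tuple[float, float] = (1.0, 30.0),
) -> ERSPMap:
    """Trial-averaged time-frequency power in dB relative to baseline.

    Parameters
    ----------
    trials : TrialSet
        Epochs (typically one condition) containing both the baseline
        interval and the analysis span.
    channel : str
        Electrode to analyze (the vertex Cz for lower-limb imagery).
    baseline_interval : (float, float)
        Pre-MI-onset interval (s) whose per-frequency mean power is the
        0 dB reference.
    freq_range : (float, float)
        Frequency axis restriction, default 1-30 Hz.
    """
    if trials.n_trials < 2:
        raise ValueError("ERSP needs at least 2 trials")
    b0, b1 = baseline_interval
    if not b1 > b0:
        raise ValueError("baseline_interval end must exceed its start")
    if b1 > 0:
        raise ValueError("baseline_interval must precede MI onset (t = 0)")
    freqs, times, power = _trial_spectrograms(trials, channel, stft_params)
    mean_power = power.mean(axis=0)  # Eq-style average over trials

    base_mask = (times >= b0) & (times <= b1)
    if not base_mask.any():
        raise ValueError(
            f"baseline interval [{b0}, {b1}] s contains no STFT bins "
            f"(map spans [{times[0]:.3f}, {times[-1]:.3f}] s)"
        )
    baseline = mean_power[:, base_mask].mean(axis=1, keepdims=True)

    f_mask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    if not f_mask.any():
        raise ValueError("freq_range selects no STFT frequency bins")
    with np.errstate(divide="ignore"):
        values = 10.0 * np.log10(mean_power[f_mask] / baseline[f_mask])
    if not np.isfinite(values).all():
        raise ValueError("zero power encountered while converting to dB")

    conds = trials.conditions
    return ERSPMap(
        freqs=freqs[f_mask],
        times=times,
        values=values,
        n_trials=trials.n_trials,
        baseline_interval=(b0, b1),
        channel=channel,
        condition=conds[0] if len(conds) == 1 else "mixed",
        subject_id=trials.subject_id,
        power=mean_power[f_mask],
    )


def erd_mean(
    map: ERSPMap, band: tuple[float, float], window: tuple[float, float]
) -> ERDSummary:
    """Arithmetic mean of the dB surface over ``band`` x ``window``
    (bin centers inclusive at both edges)."""
    f1, f2 = band
    t1, t2 = window
    f_mask = (map.freqs >= f1) & (map.freqs <= f2)
    t_mask = (map.times >= t1) & (map.times <= t2)
    if not f_mask.any() or not t_mask.any():
        raise ValueError(
            f"band {band} Hz x window {window} s selects no ERSP bins"
        )
    value = float(map.values[np.ix_(f_mask, t_mask)].mean())
    return ERDSummary(
        band=(f1, f2),
        window=(t1, t2),
        erd_db=value,
        channel=map.channel,
        condition=map.condition,
        subject_id=map.subject_id,
    )


def energy_curve(
    map: ERSPMap, window: tuple[float, float] = (0.0, 4.0)
) -> EnergyCurve:
    """Collapse an ERSP over a time window into a frequency-domain energy
    curve (per-frequency mean dB; baseline sits at 0 dB)."""
    t1, t2 = window
    t_mask = (map.times >= t1) & (map.times <= t2)
    if not t_mask.any():
        raise ValueError(f"window {window} s selects no ERSP time bins")
    return EnergyCurve(
        freqs=map.freqs.copy(),
        energy_db=map.values[:, t_mask].mean(axis=1),
        baseline_level=0.0,
    )


def _infer_band_name(search_band: tuple[float, float]) -> str:
    if ALPHA_BAND[0] <= search_band[0] and search_band[1] <= ALPHA_BAND[1]:
        return "alpha"
    if BETA_BAND[0] <= search_band[0] and search_band[1] <= BETA_BAND[1]:
        return "beta"
    return f"{search_band[0]:g}-{search_band[1]:g}Hz"


def characteristic_frequency(
    curve: EnergyCurve,
    search_band: tuple[float, float],
    band_name: Optional[str] = None,
) -> CharacteristicResult:
    """Locate the energy-curve minimum inside a search band.

    The characteristic frequency is the frequency of the minimum energy
    value within ``search_band`` (ties broken toward the lowest frequency);
    the characteristic band is the maximal contiguous run of frequencies
    around it, inside the search range, where the curve stays strictly below
    baseline (clipping to the search range keeps the alpha and beta bands
    from merging through incidental sub-baseline bins between them). A curve
    that never dips below baseline in the band yields a flagged no-ERD
    result.
    """
    if band_name is None:
        band_name = _infer_band_name(search_band)
    lo, hi = search_band
    mask = (curve.freqs >= lo) & (curve.freqs <= hi)
    if not mask.any():
        raise ValueError(f"search band {search_band} Hz contains no curve bins")
    idx = np.flatnonzero(mask)
    sub = curve.energy_db[idx]
    if (sub >= curve.baseline_level).all():
        return CharacteristicResult(None, None, band_name, no_erd=True)
    # np.argmin returns the first (lowest-frequency) minimum on ties
    i_min = idx[int(np.argmin(sub))]
    below = (curve.energy_db < curve.baseline_level) & mask
    left = i_min
    while left > 0 and below[left - 1]:
        left -= 1
    right = i_min
    while right < curve.freqs.size - 1 and below[right + 1]:
        right += 1
    return CharacteristicResult(
        characteristic_frequency=float(curve.freqs[i_min]),
        characteristic_band=(float(curve.freqs[left]), float(curve.freqs[right])),
        band_name=band_name,
    )


def entropy_of_density(p: np.ndarray) -> float:
    """Shannon entropy ``-sum p ln p`` (nats) of nonnegative weights,
    normalized to sum to one; ``0 * ln 0 := 0``."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or not np.isfinite(p).all():
        raise ValueError("density weights must be finite and nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("density is identically zero; entropy undefined")
    p = p / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def spectral_entropy(
    trials: TrialSet,
    channel: str,
    window: tuple[float, float],
    stft_params: StftParams = StftParams(),
    freq_range: tuple[float, float] = (1.0, 30.0),
) -> SpectralEntropyResult:
    """Spectral entropy of the STFT power density over a time window.

    The trial- and time-averaged magnitude-squared STFT inside ``window``
    is normalized to a discrete probability over frequency bins (any
    constant in the density definition cancels in the normalization), and
    its Shannon entropy is returned in nats.
    """
    freqs, times, power = _trial_spectrograms(trials, channel, stft_params)
    t1, t2 = window
    t_mask = (times >= t1) & (times <= t2)
    if not t_mask.any():
        raise ValueError(f"window {window} s selects no STFT bins")
    f_mask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    density = power[:, :, t_mask].mean(axis=(0, 2))[f_mask]
    if density.sum() <= 0:
        raise ValueError("signal has no power in the analysis window")
    p = density / density.sum()
    return SpectralEntropyResult(
        freqs=freqs[f_mask], density_bins=p, entropy=entropy_of_density(p)
    )
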