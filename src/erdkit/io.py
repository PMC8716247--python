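"""Readers and writers: EDF+ epochs, delimited-text epochs, analysis exports.

EDF+ files are written natively (the format is a fixed-width header plus
16-bit little-endian samples): one file per subject, trials concatenated as
one data record per trial, with an EDF+ annotation channel carrying an
``MI/<condition>`` marker at each trial's MI onset. Reading goes through
MNE's EDF reader, which also serves as the independent check that the files
are well-formed.

The delimited-text epoch format is a plain CSV (one row per sample, one
column per channel, plus trial/sample indices) with ``#``-prefixed header
lines carrying the sampling rate, labels and time origin — bulky but fully
auditable.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectral import EnergyCurve, ERSPMap
from .synth import GeneratorConfig
from .trials import TrialSet

__all__ = [
    "write_edf",
    "read_edf",
    "write_text_epochs",
    "read_text_epochs",
    "write_ersp",
    "read_ersp",
    "write_energy_curve",
    "load_generator_config",
    "save_generator_config",
]

_ANNOT_SAMPLES = 60  # 2-byte "samples" reserved per record for the TAL channel


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def write_edf(trials: TrialSet, path) -> Path:
    """Write a TrialSet as one EDF+C file, one data record per trial.

    Samples are scaled to the 16-bit digital range per channel; an
    annotation channel marks MI onset of every trial with its condition
    label (``MI/<condition>``).
    """
    path = Path(path)
    n_trials, n_channels, n_samples = trials.data.shape
    record_duration = n_samples / trials.sampling_rate
    mi_onset = -trials.time_origin  # seconds from record start to MI onset
    if mi_onset < 0 or mi_onset > record_duration:
        raise ValueError("MI onset falls outside the trial span")

    phys_max = np.abs(trials.data).max(axis=(0, 2))
    phys_max = np.where(phys_max == 0, 1.0, phys_max)
    n_signals = n_channels + 1  # + annotations

    header = _io.BytesIO()
    header.write(_pad("0", 8))
    header.write(_pad(f"X X X {trials.subject_id}", 80))
    header.write(_pad("Startdate 01-JAN-2000 X X X", 80))
    header.write(_pad("01.01.00", 8))
    header.write(_pad("00.00.00", 8))
    header.write(_pad(str(256 * (n_signals + 1)), 8))
    header.write(_pad("EDF+C", 44))
    header.write(_pad(str(n_trials), 8))
    header.write(_pad(f"{record_duration:.6g}", 8))
    header.write(_pad(str(n_signals), 4))

    labels = [f"EEG {ch}" for ch in trials.channel_labels] + ["EDF Annotations"]
    per_signal = [
        ("".join(_pad(lab, 16).decode() for lab in labels), 16),
        ("", 80),  # transducer
        ("".join(_pad(d, 8).decode() for d in ["uV"] * n_channels + [""]), 8),
        ("".join(_pad(f"{-m:.6g}", 8).decode() for m in phys_max)
         + _pad("-1", 8).decode(), 8),
        ("".join(_pad(f"{m:.6g}", 8).decode() for m in phys_max)
         + _pad("1", 8).decode(), 8),
        ("".join(_pad("-32768", 8).decode() for _ in range(n_channels))
         + _pad("-32768", 8).decode(), 8),
        ("".join(_pad("32767", 8).decode() for _ in range(n_channels))
         + _pad("32767", 8).decode(), 8),
        ("", 80),  # prefiltering
        ("".join(_pad(str(n_samples), 8).decode() for _ in range(n_channels))
         + _pad(str(_ANNOT_SAMPLES), 8).decode(), 8),
        ("", 32),  # reserved
    ]
    for text, width in per_signal:
        if text == "":
            header.write(b" " * width * n_signals)
        else:
            header.write(text.encode("ascii"))

    scale = 32767.0 / phys_max  # digital per physical unit
    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for k in range(n_trials):
            digital = np.clip(
                np.round(trials.data[k] * scale[:, None]), -32768, 32767
            ).astype("<i2")
            fh.write(digital.tobytes())
            t0 = k * record_duration
            tal = f"+{t0:.6g}\x14\x14\x00".encode("ascii")
            label = str(trials.condition_labels[k])
            tal += f"+{t0 + mi_onset:.6g}\x14MI/{label}\x14\x00".encode("ascii")
            tal = tal.ljust(2 * _ANNOT_SAMPLES, b"\x00")
            if len(tal) > 2 * _ANNOT_SAMPLES:
                raise ValueError(f"annotation too long for record: {label!r}")
            fh.write(tal)
    return path


def read_edf(path, subject_id: str | None = None) -> TrialSet:
    """Read an EDF/EDF+ epoch file written by :func:`write_edf`.

    Trials are recovered from the ``MI/<condition>`` annotations: each marks
    one trial's MI onset, trials are assumed equal-length and concatenated
    in order. Amplitudes come back in uV (within 16-bit quantization).
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    events = [
        (onset, desc.split("/", 1)[1])
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        if desc.startswith("MI/")
    ]
    if not events:
        raise ValueError(f"{path} carries no MI/<condition> annotations")
    n_trials = len(events)
    n_total = raw.n_times
    if n_total % n_trials:
        raise ValueError("total samples not divisible by trial count")
    n_samples = n_total // n_trials
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts (mne) -> uV
    data = data.reshape(data.shape[0], n_trials, n_samples).transpose(1, 0, 2)
    time_origin = -float(events[0][0])  # first MI onset, relative to record 0
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    return TrialSet(
        data=data,
        sampling_rate=fs,
        channel_labels=labels,
        condition_labels=np.array([c for _, c in events], dtype=object),
        subject_id=subject_id or path.stem,
        time_origin=time_origin,
    )


# ----------------------------------------------------------------------
# delimited-text epochs


def write_text_epochs(trials: TrialSet, path) -> Path:
    """Write epochs as commented-header CSV (one row per sample)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# erdkit-epochs 1\n")
        fh.write(f"# subject_id: {trials.subject_id}\n")
        fh.write(f"# sampling_rate: {trials.sampling_rate!r}\n")
        fh.write(f"# time_origin: {trials.time_origin!r}\n")
        fh.write(f"# conditions: {','.join(map(str, trials.condition_labels))}\n")
        frame = pd.DataFrame(
            trials.data.transpose(0, 2, 1).reshape(-1, trials.n_channels),
            columns=trials.channel_labels,
        )
        frame.insert(0, "sample", np.tile(np.arange(trials.n_samples),
                                          trials.n_trials))
        frame.insert(0, "trial", np.repeat(np.arange(trials.n_trials),
                                           trials.n_samples))
        frame.to_csv(fh, index=False, float_format="%.6g")
    return path


def read_text_epochs(path) -> TrialSet:
    """Read the delimited-text epoch format written by
    :func:`write_text_epochs`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, comment="#")
    channels = [c for c in frame.columns if c not in ("trial", "sample")]
    n_trials = int(frame["trial"].max()) + 1
    n_samples = int(frame["sample"].max()) + 1
    data = (
        frame[channels]
        .to_numpy()
        .reshape(n_trials, n_samples, len(channels))
        .transpose(0, 2, 1)
    )
    return TrialSet(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=channels,
        condition_labels=np.array(meta["conditions"].split(","), dtype=object),
        subject_id=meta.get("subject_id", path.stem),
        time_origin=float(meta["time_origin"]),
    )


# ----------------------------------------------------------------------
# analysis exports


def write_ersp(map: ERSPMap, path) -> Path:
    """Export an ERSP map as TSV: first column frequency, one column per
    time bin (dB values)."""
    path = Path(path)
    header = (
        f"ersp subject={map.subject_id} channel={map.channel} "
        f"condition={map.condition} n_trials={map.n_trials} "
        f"baseline={float(map.baseline_interval[0])!r},"
        f"{float(map.baseline_interval[1])!r}\n"
        "times\t" + "\t".join(repr(float(t)) for t in map.times)
    )
    body = np.column_stack([map.freqs, map.values])
    np.savetxt(path, body, delimiter="\t", header=header)
    return path


def read_ersp(path) -> ERSPMap:
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline().lstrip("# ").split(None, 1)[1]
        times_line = fh.readline().lstrip("# ").split("\t")[1:]
    meta = dict(item.split("=", 1) for item in meta_line.split())
    body = np.loadtxt(path, delimiter="\t", skiprows=2)
    b0, b1 = (float(x) for x in meta["baseline"].split(","))
    return ERSPMap(
        freqs=body[:, 0],
        times=np.array([float(t) for t in times_line]),
        values=body[:, 1:],
        n_trials=int(meta["n_trials"]),
        baseline_interval=(b0, b1),
        channel=meta["channel"],
        condition=meta["condition"],
        subject_id=meta["subject"],
    )


def write_energy_curve(curve: EnergyCurve, path, label: str = "") -> Path:
    """Export an energy curve as two-column TSV (freq, dB)."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([curve.freqs, curve.energy_db]),
        delimiter="\t",
        header=f"energy-curve {label} baseline={float(curve.baseline_level)!r}\n"
               "freq_hz\tenergy_db",
    )
    return path


# ----------------------------------------------------------------------
# configuration files


def save_generator_config(config: GeneratorConfig, path) -> Path:
    path = Path(path)
    payload = asdict(config)
    if payload.get("erd_spatial_profile") is not None:
        payload["erd_spatial_profile"] = [
            float(w) for w in payload["erd_spatial_profile"]
        ]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_generator_config(path) -> GeneratorConfig:
    """Load a generator config from a YAML file mirroring
    :class:`GeneratorConfig` fields."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown generator config fields: {sorted(unknown)}")
    if payload.get("erd_spatial_profile") is not None:
        payload["erd_spatial_profile"] = np.asarray(
            payload["erd_spatial_profile"], dtype=float
        )
    config = GeneratorConfig(**payload)
    config.validate()
    return config
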