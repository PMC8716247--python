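"""Published per-subject summary values of the emulated 10-subject study.

These are the printed subject-level results of the lower-limb motor-imagery
cohort this package's simulator emulates: characteristic frequencies, mean
ERD over the characteristic bands, and per-condition recognition rates for
subjects S1-S10 under high-frequency (HFMI, four imagined leg raises per
4 s) and low-frequency (LFMI, two raises per 4 s) imagery. They serve two
purposes: closed-form worked examples for the statistics operations, and the
condition parameters the synthetic generator defaults to.

Known internal inconsistencies of the printed summary rows (documented here
so nobody chases them as bugs; recomputation from the per-subject values is
always authoritative in this package):

* ERD table, HFMI Mean cells: printed -1.827 (alpha) and -3.4756 (beta),
  but the printed columns average to -1.867 and -3.4486.
* ERD table, HFMI beta STD: printed 0.6460, recomputed 0.699.
* Recognition table Mean/STD: printed 0.8784/0.00318 (HFMI) and
  0.7646/0.00669 (LFMI), but the ten printed rates give 0.881/0.0589 and
  0.766/0.0873.
* The reported correlations r = 0.945 (characteristic frequency) and
  r = 0.212 (beta ERD) cannot be reproduced from any printed column pairing
  (the printed alpha characteristic-frequency columns give r = 0.866).

All other Mean/STD cells are exact recomputations of their columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SUBJECTS",
    "CHARACTERISTIC_FREQUENCY_HZ",
    "ERD_DB",
    "RECOGNITION_RATE",
    "characteristic_frequency_table",
    "erd_table",
    "recognition_table",
]

SUBJECTS: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 11))

#: band -> condition -> per-subject characteristic frequency (Hz), S1..S10.
CHARACTERISTIC_FREQUENCY_HZ: dict[str, dict[str, tuple[int, ...]]] = {
    "alpha": {
        "HFMI": (9, 10, 8, 10, 10, 8, 10, 8, 9, 8),
        "LFMI": (10, 11, 9, 11, 11, 9, 10, 9, 10, 10),
    },
    "beta": {
        "HFMI": (19, 17, 19, 17, 18, 19, 17, 18, 19, 17),
        "LFMI": (19, 20, 21, 20, 21, 19, 20, 21, 19, 20),
    },
}

#: band -> condition -> per-subject mean ERD over the characteristic band (dB).
ERD_DB: dict[str, dict[str, tuple[float, ...]]] = {
    "alpha": {
        "HFMI": (-2.105, -1.1536, -1.8398, -2.4525, -1.9261,
                 -2.8428, -1.7287, -1.6163, -1.5344, -1.4708),
        "LFMI": (-1.1209, -1.0336, -1.015, -1.5579, -1.3741,
                 -2.7137, -1.4509, -1.0637, -1.2998, -0.8574),
    },
    "beta": {
        "HFMI": (-3.2531, -3.9198, -3.8286, -3.5187, -3.9149,
                 -3.865, -3.5315, -2.1449, -2.303, -4.2069),
        "LFMI": (-2.3827, -2.5407, -1.6239, -2.4161, -3.4839,
                 -2.3341, -2.0094, -1.2393, -1.7632, -3.0973),
    },
}

#: condition -> per-subject cross-validated recognition rate.
RECOGNITION_RATE: dict[str, tuple[float, ...]] = {
    "HFMI": (0.91, 0.82, 0.75, 0.94, 0.85, 0.94, 0.94, 0.88, 0.88, 0.90),
    "LFMI": (0.90, 0.74, 0.73, 0.74, 0.65, 0.88, 0.78, 0.63, 0.78, 0.83),
}


def _table(nested: dict) -> pd.DataFrame:
    cols = {
        f"{cond}_{band}": np.asarray(values, dtype=float)
        for band in nested
        for cond, values in nested[band].items()
    }
    return pd.DataFrame(cols, index=pd.Index(SUBJECTS, name="subject"))


def characteristic_frequency_table() -> pd.DataFrame:
    """Per-subject characteristic frequencies as a DataFrame (Hz)."""
    return _table(CHARACTERISTIC_FREQUENCY_HZ)


def erd_table() -> pd.DataFrame:
    """Per-subject characteristic-band mean ERD as a DataFrame (dB)."""
    return _table(ERD_DB)


def recognition_table() -> pd.DataFrame:
    """Per-subject recognition rates as a DataFrame."""
    return pd.DataFrame(
        {cond: np.asarray(v, dtype=float) for cond, v in RECOGNITION_RATE.items()},
        index=pd.Index(SUBJECTS, name="subject"),
    )
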