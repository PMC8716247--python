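"""Descriptive and inferential statistics for cohort summary tables.

Conventions: sample standard deviation (n-1 denominator), two-tailed paired
t-tests on condition differences, Pearson product-moment correlation across
subjects. Degenerate inputs (zero difference variance, constant sequences)
are flagged explicitly instead of returning a silent number. No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "PairedTestResult",
    "CorrelationResult",
    "StatsReport",
    "describe",
    "paired_t",
    "pearson_r",
    "build_report",
]


@dataclass
class PairedSample:
    """Two matched sequences (same subjects under two conditions)."""

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("values_a and values_b must be equal-length 1-D")
        if self.values_a.size < 3:
            raise ValueError("paired samples need at least 3 pairs")
        if not (
            np.isfinite(self.values_a).all() and np.isfinite(self.values_b).all()
        ):
            raise ValueError("paired samples must be finite")

    def swapped(self) -> "PairedSample":
        return PairedSample(self.values_b, self.values_a, self.labels[::-1])


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    dof: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    degenerate: bool = False


def describe(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("describe needs at least 2 values")
    return float(values.mean()), float(values.std(ddof=1))


def paired_t(sample: PairedSample) -> PairedTestResult:
    """Two-tailed paired t-test on a - b, df = n - 1.

    A zero-variance difference vector (including a == b elementwise) yields
    a degenerate-flagged result with NaN statistics.
    """
    diff = sample.values_a - sample.values_b
    n = diff.size
    if np.var(diff, ddof=1) == 0:
        return PairedTestResult(float("nan"), float("nan"), n - 1, degenerate=True)
    res = sps.ttest_rel(sample.values_a, sample.values_b)
    return PairedTestResult(float(res.statistic), float(res.pvalue), n - 1)


def pearson_r(sample: PairedSample) -> CorrelationResult:
    """Pearson correlation between the two matched sequences."""
    if np.var(sample.values_a) == 0 or np.var(sample.values_b) == 0:
        return CorrelationResult(float("nan"), float("nan"), degenerate=True)
    res = sps.pearsonr(sample.values_a, sample.values_b)
    return CorrelationResult(float(res.statistic), float(res.pvalue))


# ----------------------------------------------------------------------
# cohort report assembly


@dataclass
class StatsReport:
    """Cohort tables (per-subject rows + Mean/STD footer) and paired
    statistics per measure."""

    characteristic_frequencies: pd.DataFrame
    erd_means: pd.DataFrame
    recognition_rates: pd.DataFrame
    statistics: dict = field(default_factory=dict)

    def to_dir(self, outdir) -> list:
        """Write the three tables as TSV plus the statistics as JSON."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in [
            ("characteristic_frequencies", self.characteristic_frequencies),
            ("erd_means", self.erd_means),
            ("recognition_rates", self.recognition_rates),
        ]:
            path = outdir / f"{name}.tsv"
            table.to_csv(path, sep="\t")
            written.append(path)
        path = outdir / "statistics.json"
        path.write_text(json.dumps(self.statistics, indent=2))
        written.append(path)
        return written


def _footered(table: pd.DataFrame) -> pd.DataFrame:
    means, stds = {}, {}
    for col in table.columns:
        means[col], stds[col] = describe(table[col].to_numpy())
    footer = pd.DataFrame([means, stds], index=["Mean", "STD"])
    return pd.concat([table, footer])


def _paired_block(a: np.ndarray, b: np.ndarray, labels: tuple[str, str]) -> dict:
    sample = PairedSample(a, b, labels)
    t_res = paired_t(sample)
    r_res = pearson_r(sample)
    return {
        "t": t_res.t,
        "p": t_res.p,
        "dof": t_res.dof,
        "r": r_res.r,
        "r_p": r_res.p,
        "degenerate": bool(t_res.degenerate or r_res.degenerate),
        "n": int(len(sample.values_a)),
    }


def build_report(cohort_results: list[dict]) -> StatsReport:
    """Assemble cohort tables from per-subject result records.

    Parameters
    ----------
    cohort_results : list of dict
        One record per subject with keys ``subject_id``,
        ``characteristic_frequency[band][condition]`` (Hz),
        ``erd[band][condition]`` (dB) and ``recognition[condition]``
        (accuracy in [0, 1]). All records must cover the same conditions
        and bands.

    Returns
    -------
    StatsReport
        Three per-subject tables with Mean/STD footer rows, plus paired
        t / Pearson r blocks comparing the two conditions per band
        (and for the recognition rates).
    """
    if len(cohort_results) < 3:
        raise ValueError("need at least 3 subjects to build a report")
    subjects = [rec["subject_id"] for rec in cohort_results]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids in cohort results")

    first = cohort_results[0]
    bands = sorted(first["characteristic_frequency"])
    conditions = sorted(first["characteristic_frequency"][bands[0]])
    for rec in cohort_results:
        if sorted(rec["characteristic_frequency"]) != bands or sorted(
            rec["recognition"]
        ) != conditions:
            raise ValueError("mixed band/condition sets across subjects")

    def collect(getter) -> pd.DataFrame:
        cols = {}
        for band in bands:
            for cond in conditions:
                cols[f"{cond}_{band}"] = [
                    getter(rec, band, cond) for rec in cohort_results
                ]
        return pd.DataFrame(cols, index=pd.Index(subjects, name="subject"))

    cf = collect(lambda rec, band, cond: rec["characteristic_frequency"][band][cond])
    erd = collect(lambda rec, band, cond: rec["erd"][band][cond])
    recog = pd.DataFrame(
        {cond: [rec["recognition"][cond] for rec in cohort_results]
         for cond in conditions},
        index=pd.Index(subjects, name="subject"),
    )

    statistics: dict = {}
    if len(conditions) == 2:
        a, b = conditions
        for band in bands:
            statistics[f"erd_{band}"] = _paired_block(
                erd[f"{a}_{band}"].to_numpy(), erd[f"{b}_{band}"].to_numpy(), (a, b)
            )
            statistics[f"characteristic_frequency_{band}"] = _paired_block(
                cf[f"{a}_{band}"].to_numpy(), cf[f"{b}_{band}"].to_numpy(), (a, b)
            )
        statistics["recognition"] = _paired_block(
            recog[a].to_numpy(), recog[b].to_numpy(), (a, b)
        )

    return StatsReport(
        characteristic_frequencies=_footered(cf),
        erd_means=_footered(erd),
        recognition_rates=_footered(recog),
        statistics=statistics,
    )
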