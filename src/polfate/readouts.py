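"""Population-level quantifications: flow-cytometry Pol II levels,
cycloheximide time courses, DDB2 stratification, Ser2 fractionation, EU
transcription recovery, clonogenic survival and the co-culture fold change.

Conventions follow the assays these statistics quantify: every readout is
normalized to its mock/untreated reference (set to 1, or 100 for the Ser2
signal), background correction of flow samples uses the paired
non-fluorescent blank population, and SEMs of ratio statistics are
propagated with the delta method.  No hypothesis tests are performed here;
estimates and SEMs are reported and testing is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay_sim import CocultureSeries, EUSample, FlowSample, FractionationMeasurement

__all__ = [
    "RelativeLevel",
    "relative_pol2_level",
    "chx_timecourse",
    "ddb2_stratified_level",
    "quantify_ser2",
    "transcription_recovery",
    "clonogenic_survival",
    "coculture_fold_change",
]


@dataclass
class RelativeLevel:
    """A mock-normalized level (reference = 1 or 100) with its SEM."""

    value: float
    sem: float
    n: int
    reference: str
    genotype: str = ""
    treatment: str = ""


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(np.mean(x)), sem


def relative_pol2_level(
    treated: FlowSample, mock: FlowSample, blank: FlowSample | None = None
) -> RelativeLevel:
    """Blank-corrected, mock-normalized mean Pol II fluorescence.

    value = (mean_treated - mean_blank) / (mean_mock - mean_blank); the SEM
    combines the three sample SEMs by the delta method (the blank enters
    both numerator and denominator).
    """
    blank_values = blank.values if blank is not None else treated.blank
    mt, st = _mean_sem(treated.values)
    mm, sm = _mean_sem(mock.values)
    mb, sb = _mean_sem(blank_values)
    denom = mm - mb
    if denom <= 0:
        raise ValueError("mock mean must exceed blank mean")
    value = (mt - mb) / denom
    d_t = 1.0 / denom
    d_m = -(mt - mb) / denom**2
    d_b = (mt - mm) / denom**2
    sem = float(np.sqrt((d_t * st) ** 2 + (d_m * sm) ** 2 + (d_b * sb) ** 2))
    return RelativeLevel(value=value, sem=sem, n=len(treated.values),
                         reference="mock=1", genotype=treated.genotype,
                         treatment=treated.treatment)


def chx_timecourse(
    treated: pd.Series, mock: pd.Series, reference_time: float
) -> pd.Series:
    """Mock-corrected degradation time course under cycloheximide.

    ``treated`` and ``mock`` are level series indexed by time; the result is
    (treated_t / mock_t) normalized to the same ratio at ``reference_time``
    (which therefore reads exactly 1).
    """
    treated = pd.Series(treated).sort_index()
    mock = pd.Series(mock).sort_index()
    missing = [t for t in treated.index if t not in mock.index]
    if missing:
        raise ValueError(f"no mock pairing at time points {missing}")
    if reference_time not in treated.index:
        raise ValueError(f"reference time {reference_time} not in the series")
    ratio = treated / mock.loc[treated.index]
    return ratio / ratio.loc[reference_time]


def ddb2_stratified_level(
    treated: FlowSample,
    mock: FlowSample,
    threshold: float | None = None,
) -> tuple[RelativeLevel, RelativeLevel]:
    """Split cells into DDB2-expressing / non-expressing strata on the
    mCherry channel and normalize each stratum to its own mock stratum.

    The default threshold is the 99th percentile of the blank sample's
    mCherry channel.  Returns (expressing, non_expressing).
    """
    for s in (treated, mock):
        if s.channel2 is None:
            raise ValueError("second (mCherry) channel missing")
    if threshold is None:
        ref = treated.blank_channel2
        if ref is None:
            raise ValueError("no blank mCherry channel to derive the threshold")
        threshold = float(np.percentile(ref, 99.0))

    def split(s: FlowSample) -> tuple[FlowSample, FlowSample]:
        hi = s.channel2 >= threshold
        return (
            FlowSample(values=s.values[hi], blank=s.blank, genotype=s.genotype,
                       treatment=s.treatment),
            FlowSample(values=s.values[~hi], blank=s.blank, genotype=s.genotype,
                       treatment=s.treatment),
        )

    t_hi, t_lo = split(treated)
    m_hi, m_lo = split(mock)
    for part, name in ((t_hi, "treated expressing"), (t_lo, "treated non-expressing"),
                       (m_hi, "mock expressing"), (m_lo, "mock non-expressing")):
        if len(part.values) == 0:
            raise ValueError(f"empty stratum: {name}")
    expressing = relative_pol2_level(t_hi, m_hi)
    non_expressing = relative_pol2_level(t_lo, m_lo)
    expressing.treatment = (treated.treatment + "|DDB2+").lstrip("|")
    non_expressing.treatment = (treated.treatment + "|DDB2-").lstrip("|")
    return expressing, non_expressing


def quantify_ser2(
    treated: FractionationMeasurement, mock: FractionationMeasurement
) -> RelativeLevel:
    """Loading-control- and mock-normalized chromatin Ser2 signal (mock=100)."""
    if treated.loading_signal <= 0 or mock.loading_signal <= 0:
        raise ValueError("loading-control signal must be > 0")
    value = 100.0 * (treated.ser2_signal / treated.loading_signal) / (
        mock.ser2_signal / mock.loading_signal)
    return RelativeLevel(value=value, sem=0.0, n=1, reference="mock=100",
                         genotype=treated.genotype, treatment=treated.treatment)


def transcription_recovery(
    treated: EUSample, mock: EUSample
) -> tuple[np.ndarray, RelativeLevel]:
    """Per-cell EU intensities divided by the mock mean, plus the summary."""
    if len(mock.values) == 0:
        raise ValueError("mock sample is empty")
    mock_mean = float(np.mean(mock.values))
    if mock_mean <= 0:
        raise ValueError("mock mean must be > 0")
    per_cell = np.asarray(treated.values, dtype=float) / mock_mean
    mean, sem = _mean_sem(per_cell)
    return per_cell, RelativeLevel(value=mean, sem=sem, n=len(per_cell),
                                   reference="mock=1", genotype=treated.genotype,
                                   treatment=treated.treatment)


def clonogenic_survival(table: pd.DataFrame) -> pd.DataFrame:
    """Per-dose relative survival curves from a colony table.

    For each genotype, the per-dose mean colony count is divided by the
    dose-0 mean (so survival at dose 0 is exactly 1); the SEM is taken
    across replicates on the same scale.
    """
    required = {"genotype", "dose", "replicate", "seeded", "colonies"}
    if not required.issubset(table.columns):
        raise ValueError(f"colony table needs columns {sorted(required)}")
    if (table["colonies"] > table["seeded"]).any():
        raise ValueError("colony count exceeds seeded count")
    rows = []
    for geno, g in table.groupby("genotype", sort=False):
        zero = g.loc[g["dose"] == 0, "colonies"]
        if zero.empty:
            raise ValueError(f"genotype {geno}: missing dose-0 rows")
        ref = zero.mean()
        if ref <= 0:
            raise ValueError(f"genotype {geno}: zero dose-0 colony mean")
        for dose, gd in g.groupby("dose", sort=True):
            rel = gd["colonies"].to_numpy(float) / ref
            mean, sem = _mean_sem(rel)
            rows.append({"genotype": geno, "dose": dose,
                         "survival": mean, "sem": sem, "n": len(rel)})
    return pd.DataFrame(rows)


def coculture_fold_change(series: CocultureSeries) -> pd.DataFrame:
    """Per-day fold change of the GFP-positive share, UV relative to mock.

    fold_change(d) = [GFP+/GFP-]_UV(d) / [GFP+/GFP-]_mock(d); the mock arm
    corrects for intrinsic growth-rate differences between the two
    genotypes.
    """
    t = series.table
    rows = []
    for day, g in t.groupby("day", sort=True):
        arms = {arm: a.iloc[0] for arm, a in g.groupby("arm")}
        if "mock" not in arms or "UV" not in arms:
            raise ValueError(f"day {day}: both arms required")
        for arm in ("mock", "UV"):
            if arms[arm]["gfp_neg"] == 0:
                raise ValueError(f"day {day}, {arm} arm: zero GFP-negative count")
        ratio_uv = arms["UV"]["gfp_pos"] / arms["UV"]["gfp_neg"]
        ratio_mock = arms["mock"]["gfp_pos"] / arms["mock"]["gfp_neg"]
        rows.append({"day": day, "fold_change": ratio_uv / ratio_mock})
    return pd.DataFrame(rows)
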