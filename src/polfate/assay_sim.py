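"""Synthetic single-cell assay generators driven by the kinetic model.

Each generator turns a kinetics run (a mean-field :class:`StateTrajectory`
or a stochastic :class:`MoleculeHistory`) into measurements with the
statistical structure the corresponding analysis stage assumes:

* strip-FRAP traces (GFP-RPB1 or CSB-mScarletI protocols),
* flow-cytometry Pol II levels with a paired non-fluorescent blank,
* chromatin-fractionation Ser2/total signals with the ubiquitylated
  slow-migrating band,
* EU nascent-transcription intensities,
* clonogenic colony tables and competitive co-culture count series.

Every generator is a pure function of its inputs and an explicit seed.
Fluorescence units are arbitrary; only mock-normalized ratios are meaningful
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    GENOTYPES,
    LESION_CLASSES,
    S_DEGRADED,
    S_ELONGATING,
    S_FREE,
    S_PROMOTER,
    S_QUEUED,
    S_STALLED,
    S_UNBORN,
    Event,
    MoleculeHistory,
    PerturbationSchedule,
    RateSet,
    StateTrajectory,
    build_rate_set,
    default_rates,
    propagate_mean_field,
    simulate_molecules,
)

__all__ = [
    "FRAPProtocol",
    "GFP_RPB1",
    "CSB_MSCARLETI",
    "RawFRAPTrace",
    "FlowSample",
    "FractionationMeasurement",
    "EUSample",
    "CocultureSeries",
    "simulate_frap_trace",
    "derive_csb_history",
    "generate_frap_experiment",
    "simulate_flow_sample",
    "simulate_ddb2_mixture",
    "simulate_fractionation",
    "simulate_eu_sample",
    "unresolved_burden",
    "simulate_colony_table",
    "simulate_coculture",
    "TRACE_COLUMNS",
]

_BOUND_CODES = (S_PROMOTER, S_ELONGATING, S_QUEUED, S_STALLED)

# observable-model constants (arbitrary units; ratios are what matters)
MOLECULE_INTENSITY = 0.02     # a.u. per unbleached Pol II in the FRAP strip model
FRAP_BACKGROUND = 8.0         # outside-nucleus strip background, a.u.
FLOW_GAIN = 0.01              # a.u. per undegraded Pol II molecule
AUTOFLUOR_MEAN = 30.0         # flow autofluorescence offset, a.u.
AUTOFLUOR_CV = 0.30
MCHERRY_EXPRESSING_MEAN = 500.0
MCHERRY_BACKGROUND_MEAN = 5.0
EU_GAIN = 0.005               # a.u. per (molecule x min) of elongation
SER2_GAIN = 1.0e-3
LOADING_SIGNAL = 50.0
SLOW_BAND_COEF = 0.9          # ubiquitylated share of lesion-bound Ser2 signal
PLATING_EFFICIENCY = 0.35
SURVIVAL_COEF = 6.0e-4        # /lesion-day in exp(-c x burden); WT ~0.5 at 8 J/m2
COCULTURE_GROWTH_COEF = 3.0e-5  # gentler daily growth link for chronic low dosing
STALL_TOXICITY_WEIGHT = 0.25  # extra burden weight per lesion-stalled Pol II
DOUBLING_PER_DAY = 1.0        # log2 growth of the co-culture per day, undamaged


@dataclass(frozen=True)
class FRAPProtocol:
    """Acquisition protocol of a strip-FRAP experiment."""

    tag: str
    n_pre: int
    n_post: int
    interval_s: float = 0.4
    bleach_depth: float = 0.05     # residual fluorescence fraction in the strip
    strip_fraction: float = 0.1    # fraction of nuclear content inside the strip

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must lie in [0, 1)")
        if not 0.0 < self.strip_fraction < 1.0:
            raise ValueError("strip_fraction must lie in (0, 1)")
        if self.n_pre < 1 or self.n_post < 1 or self.interval_s <= 0:
            raise ValueError("invalid frame counts or interval")

    @property
    def n_frames(self) -> int:
        return self.n_pre + self.n_post

    @property
    def bleach_frame(self) -> int:
        """1-based index of the first post-bleach frame."""
        return self.n_pre + 1

    def frame_offsets_min(self) -> np.ndarray:
        """Frame times in minutes relative to the first frame."""
        return np.arange(self.n_frames) * self.interval_s / 60.0


GFP_RPB1 = FRAPProtocol(tag="GFP-RPB1", n_pre=25, n_post=450)
CSB_MSCARLETI = FRAPProtocol(tag="CSB-mScarletI", n_pre=5, n_post=40)


@dataclass
class RawFRAPTrace:
    """One cell's strip-FRAP measurement (plus its background channel)."""

    cell_id: str
    genotype: str
    treatment: str
    tag: str
    time_s: np.ndarray
    strip_intensity: np.ndarray
    background_intensity: np.ndarray
    bleach_frame: int          # 1-based; equals n_pre + 1
    n_pre: int
    seed: int = 0
    clamped_frames: int = 0    # frames clamped to 0 by background correction

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if len(self.strip_intensity) != n or len(self.background_intensity) != n:
            raise ValueError("channel lengths differ")
        if self.bleach_frame != self.n_pre + 1:
            raise ValueError("bleach frame must be n_pre + 1 (1-based)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_id,
            "genotype": self.genotype,
            "treatment": self.treatment,
            "tag": self.tag,
            "frame": np.arange(1, len(self.time_s) + 1),
            "time_s": self.time_s,
            "strip_intensity": self.strip_intensity,
            "background_intensity": self.background_intensity,
            "bleach_frame": self.bleach_frame,
        })


TRACE_COLUMNS = [
    "cell_id", "genotype", "treatment", "tag", "frame", "time_s",
    "strip_intensity", "background_intensity", "bleach_frame",
]


def simulate_frap_trace(
    history: MoleculeHistory,
    protocol: FRAPProtocol,
    noise_cv: float = 0.03,
    seed: int = 0,
    tau_mix_s: float | None = None,
    cell_id: str = "cell",
    treatment: str = "",
) -> RawFRAPTrace:
    """Turn a per-molecule history into one strip-FRAP trace.

    The last ``n_pre + n_post`` recorded times of ``history`` are taken as
    the acquisition frames.  Chromatin-bound molecules occupy a fixed
    position (inside the strip with probability ``strip_fraction``); the
    free pool re-equilibrates exponentially with timescale ``tau_mix_s``,
    tracked as a per-molecule in-strip probability weight.  The bleach is
    instantaneous at the timestamp of the first post-bleach frame and is
    applied in expectation: each molecule keeps a brightness factor equal to
    its survival probability, so the first post-bleach sample reads the
    bleach depth.  Post-bleach frames are normalized by the expected
    surviving fluorescence fraction (double normalization), so a fully
    mobile pool recovers exactly to its pre-bleach level after mixing.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    nf = protocol.n_frames
    if history.states.shape[0] < nf:
        raise ValueError("history shorter than the acquisition window")
    states = history.states[-nf:]
    times_min = history.times[-nf:]
    tau = (tau_mix_s if tau_mix_s is not None else default_rates().tau_mix)
    rng = np.random.default_rng(seed)
    sf = protocol.strip_fraction
    beta = protocol.bleach_depth
    n_slots = states.shape[1]

    bound = np.isin(states, _BOUND_CODES)
    alive = (states != S_DEGRADED) & (states != S_UNBORN)

    # per-molecule in-strip weight: realized 0/1 while bound, fractional
    # (relaxing toward strip_fraction) while free; u is the unbleached
    # brightness carried in expectation after the bleach
    w = np.where(bound[0], (rng.random(n_slots) < sf).astype(float), sf)
    u = np.ones(n_slots)
    signal = np.empty(nf)
    decay = math.exp(-protocol.interval_s / tau)
    bleach_i = protocol.n_pre  # 0-based frame index of the bleach
    m_surv = 1.0 - sf * (1.0 - beta)  # expected surviving fluorescence fraction

    for f in range(nf):
        if f > 0:
            newly_bound = bound[f] & ~bound[f - 1]
            if newly_bound.any():
                idx = np.flatnonzero(newly_bound)
                w[idx] = (rng.random(len(idx)) < w[idx]).astype(float)
            free_now = alive[f] & ~bound[f]
            w[free_now] = sf + (w[free_now] - sf) * decay
        if f == bleach_i:
            in_bleach = alive[f]
            surv = 1.0 - w * (1.0 - beta)
            w = np.where(in_bleach & (surv > 0), w * beta / np.maximum(surv, 1e-300), w)
            u = np.where(in_bleach, u * surv, u)
        sig = float((u * w)[alive[f]].sum())
        signal[f] = sig / m_surv if f >= bleach_i else sig

    strip = signal * MOLECULE_INTENSITY + FRAP_BACKGROUND
    if noise_cv > 0:
        strip = strip * (1.0 + noise_cv * rng.standard_normal(nf))
    strip = np.clip(strip, 0.0, None)
    background = FRAP_BACKGROUND * (1.0 + noise_cv * rng.standard_normal(nf))
    background = np.clip(background, 0.0, None)

    return RawFRAPTrace(
        cell_id=cell_id,
        genotype=history.genotype,
        treatment=treatment,
        tag=protocol.tag,
        time_s=(times_min - times_min[0]) * 60.0,
        strip_intensity=strip,
        background_intensity=background,
        bleach_frame=protocol.bleach_frame,
        n_pre=protocol.n_pre,
        seed=seed,
    )


def derive_csb_history(history: MoleculeHistory) -> MoleculeHistory:
    """CSB-mScarletI observable derived from a Pol II molecule history.

    CSB binds lesion-stalled Pol II stably, so a CSB molecule is chromatin
    (strip-)immobile exactly while its Pol II partner is stalled; all other
    CSB is treated as freely mixing.  CSB immobilization thereby reads out
    the lesion-stalled Pol II fraction.
    """
    states = np.where(history.states == S_STALLED, S_STALLED, S_FREE).astype(np.int8)
    states[history.states == S_UNBORN] = S_UNBORN  # unused synthesis capacity
    return MoleculeHistory(times=history.times, states=states,
                           n_molecules=history.n_molecules,
                           seed=history.seed, genotype=history.genotype)


def _child_seed(master_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(master_seed), *key]).generate_state(1)[0]
               % (2**31 - 1))


def generate_frap_experiment(
    genotypes: Sequence[str],
    n_cells: int,
    protocol: FRAPProtocol = GFP_RPB1,
    master_seed: int = 0,
    uv_dose: float = 4.0,
    thz1: bool = True,
    uv_time_min: float = 0.0,
    thz1_time_min: float = 30.0,
    t_frap_min: float = 120.0,
    n_molecules: int = 50_000,
    noise_cv: float = 0.03,
    base: RateSet | None = None,
    scenario_step: float = 0.2,
    arms: Sequence[str] = ("mock", "UV"),
) -> pd.DataFrame:
    """Generate a grid of per-cell FRAP traces (mock arms always included).

    Each cell is an independent seeded molecule simulation of the scenario up
    to ``t_frap_min`` followed by acquisition at the protocol's frame rate.
    Returns a tidy table in the trace CSV dialect (one row per cell-frame).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not genotypes:
        raise ValueError("empty genotype grid")
    arms = tuple(arms)
    if "mock" not in arms:
        arms = ("mock",) + arms
    frames = []
    offsets = protocol.frame_offsets_min()
    for gi, genotype in enumerate(genotypes):
        for ai, arm in enumerate(arms):
            events = []
            if arm == "UV":
                events.append(Event(uv_time_min, "UV_DOSE", uv_dose))
            if thz1:
                events.append(Event(thz1_time_min, "THZ1_ON"))
            schedule = PerturbationSchedule(tuple(events))
            rates = build_rate_set(genotype, schedule, base=base)
            treatment = arm + ("+THZ1" if thz1 else "")
            record = t_frap_min + offsets
            for ci in range(n_cells):
                seed = _child_seed(master_seed, gi, ai, ci)
                hist = simulate_molecules(
                    rates, schedule, n_molecules=n_molecules, seed=seed,
                    record_times=record, step=scenario_step,
                )
                if protocol.tag == "CSB-mScarletI":
                    hist = derive_csb_history(hist)
                trace = simulate_frap_trace(
                    hist, protocol, noise_cv=noise_cv, seed=_child_seed(seed, 1),
                    tau_mix_s=(base or default_rates()).tau_mix,
                    cell_id=f"{genotype}_{treatment}_c{ci:03d}",
                    treatment=treatment,
                )
                frames.append(trace.to_frame())
    return pd.concat(frames, ignore_index=True)[TRACE_COLUMNS]


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass
class FlowSample:
    """Per-cell total-fluorescence sample with its paired blank population."""

    values: np.ndarray
    blank: np.ndarray
    genotype: str = ""
    treatment: str = ""
    channel2: np.ndarray | None = None        # e.g. DDB2-mCherry
    blank_channel2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0) or np.any(np.asarray(self.blank) < 0):
            raise ValueError("flow intensities must be >= 0")


def _lognormal_factor(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean lognormal scatter with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def _autofluor(rng: np.random.Generator, n: int) -> np.ndarray:
    return AUTOFLUOR_MEAN * _lognormal_factor(rng, n, AUTOFLUOR_CV)


def simulate_flow_sample(
    trajectory: StateTrajectory,
    t_min: float,
    n_cells: int = 15_000,
    size_cv: float = 0.25,
    seed: int = 0,
    cell_range: tuple[int, int] = (10_000, 20_000),
    treatment: str = "",
) -> FlowSample:
    """Per-cell GFP-RPB1 intensities at one trajectory time point.

    intensity = undegraded count x gain x lognormal cell-size factor +
    autofluorescence; the paired blank sample is autofluorescence only.
    """
    if not cell_range[0] <= n_cells <= cell_range[1]:
        raise ValueError(f"n_cells must lie within {cell_range}")
    count = trajectory.undegraded(t_min)
    rng = np.random.default_rng(seed)
    values = count * FLOW_GAIN * _lognormal_factor(rng, n_cells, size_cv) \
        + _autofluor(rng, n_cells)
    blank = _autofluor(rng, n_cells)
    return FlowSample(values=values, blank=blank, genotype=trajectory.genotype,
                      treatment=treatment)


def simulate_ddb2_mixture(
    traj_expressing: StateTrajectory,
    traj_control: StateTrajectory,
    t_min: float,
    n_cells: int = 15_000,
    frac_expressing: float = 0.4,
    size_cv: float = 0.25,
    seed: int = 0,
    treatment: str = "",
) -> FlowSample:
    """A transiently DDB2-mCherry-transfected sample: a mixture of expressing
    cells (following ``traj_expressing``) and non-expressing cells
    (``traj_control``), with the mCherry level as second channel."""
    rng = np.random.default_rng(seed)
    expressing = rng.random(n_cells) < frac_expressing
    counts = np.where(expressing,
                      traj_expressing.undegraded(t_min),
                      traj_control.undegraded(t_min))
    values = counts * FLOW_GAIN * _lognormal_factor(rng, n_cells, size_cv) \
        + _autofluor(rng, n_cells)
    ch2 = np.where(
        expressing,
        MCHERRY_EXPRESSING_MEAN * _lognormal_factor(rng, n_cells, 0.6),
        MCHERRY_BACKGROUND_MEAN * _lognormal_factor(rng, n_cells, 0.4),
    )
    blank = _autofluor(rng, n_cells)
    blank_ch2 = MCHERRY_BACKGROUND_MEAN * _lognormal_factor(rng, n_cells, 0.4)
    return FlowSample(values=values, blank=blank,
                      genotype=traj_control.genotype, treatment=treatment,
                      channel2=ch2, blank_channel2=blank_ch2)


# ---------------------------------------------------------------------------
# fractionation / EU


@dataclass
class FractionationMeasurement:
    """Chromatin-fraction western quantification for one condition."""

    genotype: str
    treatment: str
    ser2_signal: float
    total_rpb1_signal: float
    loading_signal: float
    slow_band_fraction: float

    def __post_init__(self) -> None:
        if min(self.ser2_signal, self.total_rpb1_signal, self.loading_signal) < 0:
            raise ValueError("signals must be >= 0")
        if not 0.0 <= self.slow_band_fraction <= 1.0:
            raise ValueError("slow-band fraction must lie in [0, 1]")


def simulate_fractionation(
    trajectory: StateTrajectory,
    t_min: float,
    noise_cv: float = 0.05,
    seed: int = 0,
    treatment: str = "",
) -> FractionationMeasurement:
    """Chromatin Ser2 / total RPB1 / loading-control signals at one time.

    The Ser2 (elongation-mark) signal follows elongating + queued + stalled
    Pol II; the slow-migrating (ubiquitylated) Ser2 band appears only when
    the genotype's CRL4^CSA ligase can modify lesion-stalled Pol II.
    """
    i = trajectory.index_of(t_min)
    c = trajectory.counts
    rng = np.random.default_rng(seed)
    noise = lambda: 1.0 + noise_cv * rng.standard_normal()  # noqa: E731
    elongating_like = c["elongating"][i] + c["queued"][i] + c["stalled"][i]
    total = c["promoter"][i] + elongating_like
    crl4 = GENOTYPES.get(trajectory.genotype, {"crl4_active": True})["crl4_active"]
    if crl4 and elongating_like > 0:
        lesion_bound = c["queued"][i] + c["stalled"][i]
        slow = SLOW_BAND_COEF * lesion_bound / elongating_like
    else:
        slow = 0.0
    return FractionationMeasurement(
        genotype=trajectory.genotype,
        treatment=treatment,
        ser2_signal=max(SER2_GAIN * elongating_like * noise(), 0.0),
        total_rpb1_signal=max(SER2_GAIN * total * noise(), 0.0),
        loading_signal=max(LOADING_SIGNAL * noise(), 0.0),
        slow_band_fraction=float(np.clip(slow, 0.0, 1.0)),
    )


@dataclass
class EUSample:
    """Per-cell integrated EU (nascent RNA) intensities for one condition."""

    values: np.ndarray
    genotype: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("EU intensities must be >= 0")


def simulate_eu_sample(
    trajectory: StateTrajectory,
    window_min: tuple[float, float],
    n_cells: int = 300,
    noise_cv: float = 0.25,
    seed: int = 0,
    treatment: str = "",
) -> EUSample:
    """Integrated EU incorporation over a labelling window.

    Per-cell intensity is proportional to the time integral of the actively
    elongating Pol II count (queued and stalled polymerases do not
    synthesize RNA), times a lognormal cell factor.
    """
    t0, t1 = window_min
    i0, i1 = trajectory.index_of(t0), trajectory.index_of(t1)
    if i1 <= i0:
        raise ValueError("invalid EU window")
    integral = float(np.trapezoid(trajectory.counts["elongating"][i0:i1 + 1],
                                  trajectory.times[i0:i1 + 1]))
    rng = np.random.default_rng(seed)
    values = EU_GAIN * integral * _lognormal_factor(rng, n_cells, noise_cv)
    return EUSample(values=np.clip(values, 0.0, None),
                    genotype=trajectory.genotype, treatment=treatment)


# ---------------------------------------------------------------------------
# survival and competitive growth


@lru_cache(maxsize=128)
def unresolved_burden(
    genotype: str,
    dose: float,
    base: RateSet | None = None,
    horizon_min: float = 1440.0,
    step: float = 0.2,
    damage: str = "UV",
    illudin_duration_min: float = 1440.0,
) -> float:
    """Time-integrated toxic exposure over a fixed horizon after one damage
    challenge (units: lesion-days).

    burden = integral over the horizon of [unrepaired lesions + an extra
    weight per lesion-stalled Pol II complex] / one day.  The stalled
    complex both blocks its gene and shields the lesion, so it carries extra
    weight; a genotype that clears damage quickly accumulates little
    exposure even though the initial lesion load is identical.  Bridges the
    kinetics into the clonogenic-survival and co-culture growth links.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    if damage == "UV":
        schedule = PerturbationSchedule((Event(0.0, "UV_DOSE", dose),))
    elif damage == "illudin":
        schedule = PerturbationSchedule(
            (Event(0.0, "ILLUDIN", dose, duration=illudin_duration_min),))
    else:
        raise ValueError(f"unknown damage kind {damage!r}")
    tr = propagate_mean_field(build_rate_set(genotype, schedule, base=base),
                              n0=50_000, horizon=horizon_min, step=step)
    lesions = sum(tr.lesions_unoccupied[c] for c in LESION_CLASSES)
    toxic = lesions + (1.0 + STALL_TOXICITY_WEIGHT) * tr.counts["stalled"]
    return float(np.trapezoid(toxic, tr.times) / 1440.0)


def simulate_colony_table(
    genotype: str,
    doses: Sequence[float],
    n_seeded: int = 400,
    replicates: int = 3,
    seed: int = 0,
    base: RateSet | None = None,
    damage: str = "UV",
) -> pd.DataFrame:
    """Clonogenic-survival colony counts: one row per dose x replicate.

    Colony count ~ Binomial(n_seeded, plating_efficiency x
    exp(-c x burden(dose))).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(d < 0 for d in doses):
        raise ValueError("negative dose")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        burden = unresolved_burden(genotype, dose, base=base, damage=damage)
        p = PLATING_EFFICIENCY * math.exp(-SURVIVAL_COEF * burden)
        for rep in range(replicates):
            rows.append({
                "genotype": genotype, "dose": dose, "replicate": rep,
                "seeded": n_seeded,
                "colonies": int(rng.binomial(n_seeded, min(max(p, 0.0), 1.0))),
            })
    return pd.DataFrame(rows)


@dataclass
class CocultureSeries:
    """GFP-positive / GFP-negative counts per sampling day, mock and UV arms."""

    table: pd.DataFrame  # columns: day, arm, gfp_pos, gfp_neg
    genotype_gfp_pos: str = ""
    genotype_gfp_neg: str = ""


def simulate_coculture(
    genotype_gfp_pos: str,
    genotype_gfp_neg: str,
    daily_dose: float = 2.0,
    days: int = 10,
    n0: int = 20_000,
    seed: int = 0,
    base: RateSet | None = None,
    sample_every: int = 2,
) -> CocultureSeries:
    """Competitive co-culture under daily UV dosing.

    Each population doubles daily, scaled by its per-day damage survival
    exp(-c x burden(daily dose)); the mock arm grows undamaged.  Counts are
    Poisson-sampled around the expectations on days 0, 2, ..., ``days``.
    """
    if days < 2 or days % sample_every:
        raise ValueError("days must be >= 2 and a multiple of the sampling stride")
    if daily_dose < 0:
        raise ValueError("negative dose")
    rng = np.random.default_rng(seed)
    surv = {
        g: math.exp(-COCULTURE_GROWTH_COEF * unresolved_burden(g, daily_dose, base=base))
        for g in {genotype_gfp_pos, genotype_gfp_neg}
    }
    growth = 2.0 ** DOUBLING_PER_DAY
    rows = []
    for day in range(0, days + 1, sample_every):
        for arm in ("mock", "UV"):
            fac_pos = growth * (surv[genotype_gfp_pos] if arm == "UV" else 1.0)
            fac_neg = growth * (surv[genotype_gfp_neg] if arm == "UV" else 1.0)
            rows.append({
                "day": day, "arm": arm,
                "gfp_pos": int(rng.poisson(n0 * fac_pos ** day)),
                "gfp_neg": int(rng.poisson(n0 * fac_neg ** day)),
            })
    return CocultureSeries(table=pd.DataFrame(rows),
                           genotype_gfp_pos=genotype_gfp_pos,
                           genotype_gfp_neg=genotype_gfp_neg)
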