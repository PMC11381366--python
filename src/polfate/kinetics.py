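"""Multi-state kinetic model of RNA polymerase II chromatin engagement at
transcription-blocking DNA lesions (TBLs).

The model tracks a well-mixed pool of Pol II molecules cycling through
chromatin states::

    free -> promoter -> elongating -> (stalled | queued) -> ...

UV (or Illudin S) creates a pool of lesions on transcribed strands.  An
elongating polymerase that encounters an unoccupied lesion becomes *stalled*;
one that runs into an already occupied lesion joins the trailing *queue*
("traffic jam").  What happens next depends on genotype:

* TC-NER proficient cells (WT, XPC KO, CSA-rescue): the stalled polymerase is
  resolved by repair (``k_repair``), the lesion is removed and trailing
  polymerases resume elongation.
* Cockayne-syndrome genotypes (CSB KO, CSA KO, CSA A160T/W194C, CSA+UVSSA
  DKO): neither repair nor CRL4^CSA-mediated degradation is available; the
  stalled complex persists and shields the lesion from GG-NER.
* UV^S^S genotypes (UVSSA KO, CSA W361C): no repair, but CRL4^CSA is active,
  so the stalled polymerase is ubiquitylated, extracted by VCP and degraded
  (``k_degrade_stalled``), freeing the lesion for GG-NER.
* XPA KO: no repair and no GG-NER, but the stalled polymerase is released
  back to the free pool without degradation (``k_release_stalled``).

Promoter-bound Pol II is additionally degraded after UV in a TC-NER
independent manner (``k_pdeg_uv``).  Lesions come in classes CPD (slowly
removed by GG-NER), 6-4PP (quickly removed) and TC-only (Illudin S adducts,
never removed by GG-NER).

Both a deterministic mean-field propagator and a seeded per-molecule
stochastic engine are provided; they share the same aggregate queue closure
so that their occupancies agree for large molecule numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "STATE_NAMES",
    "LESION_CLASSES",
    "RateSet",
    "Event",
    "PerturbationSchedule",
    "TimedRates",
    "StateTrajectory",
    "MoleculeHistory",
    "default_rates",
    "build_rate_set",
    "basal_fractions",
    "propagate_mean_field",
    "simulate_molecules",
    "mean_residence_time",
    "stalled_fraction",
]

# ---------------------------------------------------------------------------
# domain types

STATE_NAMES = ("free", "promoter", "elongating", "queued", "stalled")
LESION_CLASSES = ("cpd", "pp64", "tc_only")

#: integer state codes used by the stochastic engine
S_FREE, S_PROMOTER, S_ELONGATING, S_QUEUED, S_STALLED, S_DEGRADED = range(6)
S_UNBORN = -1  # synthesis slot not yet activated

EVENT_KINDS = (
    "UV_DOSE",
    "ILLUDIN",
    "THZ1_ON",
    "CHX_ON",
    "PROTEASOME_INH_ON",
    "VCP_INH_ON",
    "DDB2_OE",
)


@dataclass(frozen=True)
class RateSet:
    """Kinetic rate constants for the Pol II state graph.

    All first-order rates are per minute; ``tau_elong`` and ``tau_mix`` are
    timescales (min and s respectively).  ``k_stall`` is per minute per
    lesion (a molecule-level encounter rate proportional to the current
    number of unrepaired lesions).  ``k_pdeg_uv`` is the post-UV value; it is
    held at zero until a UV event activates it.
    """

    k_init: float = 0.5            # free -> promoter, /min
    k_escape: float = 0.2          # promoter -> elongating, /min
    k_pre_release: float = 1.8     # promoter -> free, /min
    k_pdeg_uv: float = 0.0065      # promoter -> degraded post-UV, /min
    tau_elong: float = 25.0        # mean undamaged elongating residence, min
    k_stall: float = 7.0e-7        # elongating -> stalled/queued, /min/lesion
    k_repair: float = 0.07         # stalled -> elongating via TC-NER, /min
    k_degrade_stalled: float = 0.008   # stalled -> degraded (CRL4^CSA route), /min
    k_release_stalled: float = 0.0     # stalled -> free (XPA-type route), /min
    k_ggner_cpd: float = 0.00039   # CPD removal by GG-NER, /min (t1/2 ~ 30 h)
    k_ggner_pp64: float = 0.0116   # 6-4PP removal by GG-NER, /min (t1/2 ~ 1 h)
    k_syn: float = 24.0            # Pol II synthesis, molecules/min
    tau_mix: float = 1.5           # free-pool strip re-equilibration, s
    lesions_per_dose: float = 2600.0   # lesions created per J/m2 of UV-C
    cpd_fraction: float = 0.75     # CPD share of UV lesions (rest 6-4PP)
    illudin_lesions_per_ngml_min: float = 0.02  # TC-only lesion production
    repair_release: str = "elongating"  # where repair puts Pol II: "elongating"|"free"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "repair_release":
                if v not in ("elongating", "free"):
                    raise ValueError(f"repair_release must be 'elongating' or 'free', got {v!r}")
                continue
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {f.name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.cpd_fraction <= 1.0:
            raise ValueError("cpd_fraction must lie in [0, 1]")

    def ggner(self, lesion_class: str) -> float:
        if lesion_class == "cpd":
            return self.k_ggner_cpd
        if lesion_class == "pp64":
            return self.k_ggner_pp64
        if lesion_class == "tc_only":
            return 0.0
        raise ValueError(f"unknown lesion class {lesion_class!r}")


def default_rates(**overrides: float) -> RateSet:
    """The default (WT-calibrated) rate set, with optional field overrides."""
    return replace(RateSet(), **overrides) if overrides else RateSet()


# Genotype -> rate-modifier profile.  ``crl4_active`` flags whether the
# CRL4^CSA ubiquitin ligase can still modify lesion-stalled Pol II (controls
# the ubiquitylated slow-migrating Ser2 band in fractionation simulations).
_K_DEG_UVSS = 0.024  # stalled degradation in UV^S^S genotypes, /min

GENOTYPES: dict[str, dict] = {
    "WT": {"overrides": {}, "crl4_active": True},
    "XPC_KO": {"overrides": {"k_ggner_cpd": 0.0, "k_ggner_pp64": 0.0}, "crl4_active": True},
    "CSB_KO": {"overrides": {"k_repair": 0.0, "k_degrade_stalled": 0.0}, "crl4_active": False},
    "CSA_KO": {"overrides": {"k_repair": 0.0, "k_degrade_stalled": 0.0}, "crl4_active": False},
    "UVSSA_KO": {"overrides": {"k_repair": 0.0, "k_degrade_stalled": _K_DEG_UVSS}, "crl4_active": True},
    "XPA_KO": {
        "overrides": {
            "k_repair": 0.0,
            "k_degrade_stalled": 0.0,
            "k_release_stalled": 0.024,
            "k_ggner_cpd": 0.0,
            "k_ggner_pp64": 0.0,
        },
        "crl4_active": True,
    },
    "CSA_UVSSA_DKO": {"overrides": {"k_repair": 0.0, "k_degrade_stalled": 0.0}, "crl4_active": False},
    "UVSSA_XPC_DKO": {
        "overrides": {"k_repair": 0.0, "k_degrade_stalled": _K_DEG_UVSS,
                      "k_ggner_cpd": 0.0, "k_ggner_pp64": 0.0},
        "crl4_active": True,
    },
    "CSA_rescue_WT": {"overrides": {}, "crl4_active": True},
    "CSA_A160T": {"overrides": {"k_repair": 0.0, "k_degrade_stalled": 0.0}, "crl4_active": False},
    "CSA_W194C": {"overrides": {"k_repair": 0.0, "k_degrade_stalled": 0.0}, "crl4_active": False},
    "CSA_W361C": {"overrides": {"k_repair": 0.0, "k_degrade_stalled": _K_DEG_UVSS}, "crl4_active": True},
}


@dataclass(frozen=True)
class Event:
    """One timed perturbation.

    ``magnitude`` carries the UV dose (J/m2), the Illudin S concentration
    (ng/ml) or the DDB2 overexpression factor; it is ignored for the on/off
    inhibitor kinds.  ``duration`` (min) applies to ILLUDIN exposure windows.
    """

    t_min: float
    kind: str
    magnitude: float = 0.0
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not np.isfinite(self.t_min):
            raise ValueError("event time must be finite")
        if self.magnitude < 0:
            raise ValueError("event magnitude must be >= 0")
        if self.kind == "DDB2_OE" and self.magnitude <= 1.0:
            raise ValueError("DDB2_OE factor must be > 1")
        if self.kind == "ILLUDIN" and (self.duration is None or self.duration <= 0):
            raise ValueError("ILLUDIN events need a positive exposure duration")


@dataclass(frozen=True)
class PerturbationSchedule:
    """Ordered list of timed perturbations applied to one scenario."""

    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        evs = tuple(sorted(self.events, key=lambda e: e.t_min))
        object.__setattr__(self, "events", evs)
        n_uv = sum(1 for e in evs if e.kind == "UV_DOSE")
        if n_uv > 1:
            raise ValueError("at most one UV event per scenario")

    @classmethod
    def from_dicts(cls, items: Iterable[dict]) -> "PerturbationSchedule":
        return cls(tuple(Event(**d) for d in items))

    def of_kind(self, kind: str) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.kind == kind)


@dataclass(frozen=True)
class TimedRates:
    """Piecewise-constant rates: genotype modifiers plus scheduled switches.

    ``breakpoints`` are the segment start times; segment ``i`` applies on
    ``[breakpoints[i], breakpoints[i + 1])`` (the last one is open-ended).
    """

    genotype: str
    crl4_active: bool
    breakpoints: tuple[float, ...]
    segments: tuple[RateSet, ...]
    schedule: PerturbationSchedule

    def at(self, t: float) -> RateSet:
        idx = int(np.searchsorted(np.asarray(self.breakpoints), t, side="right") - 1)
        return self.segments[max(idx, 0)]


def build_rate_set(
    genotype: str,
    schedule: PerturbationSchedule,
    base: RateSet | None = None,
) -> TimedRates:
    """Map a genotype plus a perturbation schedule to piecewise rates.

    Genotype modifiers are applied first; events then switch individual rates
    on or off from their scheduled time onward.  The promoter-degradation
    rate ``k_pdeg_uv`` is held at zero until the UV event and is suppressed
    entirely by proteasome or VCP inhibition, as is ``k_degrade_stalled``.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype label {genotype!r}")
    base = base or default_rates()
    profile = GENOTYPES[genotype]
    geno = replace(base, **profile["overrides"])

    # sweep events in time order, maintaining switch flags
    times = sorted({0.0} | {e.t_min for e in schedule.events})
    uv_seen_at = next((e.t_min for e in schedule.events if e.kind == "UV_DOSE"), None)
    breakpoints: list[float] = []
    segments: list[RateSet] = []
    thz1 = chx = pi = False
    ddb2_factor = 1.0
    for t in times:
        for e in schedule.events:
            if e.t_min == t:
                if e.kind == "THZ1_ON":
                    thz1 = True
                elif e.kind == "CHX_ON":
                    chx = True
                elif e.kind in ("PROTEASOME_INH_ON", "VCP_INH_ON"):
                    pi = True
                elif e.kind == "DDB2_OE":
                    ddb2_factor = e.magnitude
        uv_active = uv_seen_at is not None and t >= uv_seen_at
        seg = replace(
            geno,
            k_init=0.0 if thz1 else geno.k_init,
            k_syn=0.0 if chx else geno.k_syn,
            k_degrade_stalled=0.0 if pi else geno.k_degrade_stalled,
            k_pdeg_uv=geno.k_pdeg_uv if (uv_active and not pi) else 0.0,
            k_ggner_cpd=geno.k_ggner_cpd * ddb2_factor,
        )
        breakpoints.append(t)
        segments.append(seg)
    return TimedRates(
        genotype=genotype,
        crl4_active=bool(profile["crl4_active"]),
        breakpoints=tuple(breakpoints),
        segments=tuple(segments),
        schedule=schedule,
    )


@dataclass
class StateTrajectory:
    """Time-resolved expected occupancy of each Pol II state and lesion pool.

    ``counts`` maps state name -> array over ``times``; lesion pools are per
    lesion class.  ``degraded`` and ``synthesized`` are cumulative.
    """

    times: np.ndarray
    counts: dict[str, np.ndarray]
    lesions_unoccupied: dict[str, np.ndarray]
    lesions_removed: dict[str, np.ndarray]
    n0: float
    genotype: str
    scenario_id: str = ""

    def index_of(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6 + 1e-9 * abs(t):
            raise ValueError(f"time {t} min is not on the trajectory grid")
        return i

    def undegraded(self, t: float | None = None) -> np.ndarray | float:
        tot = sum(self.counts[s] for s in STATE_NAMES)
        if t is None:
            return tot
        return float(tot[self.index_of(t)])

    def mass_residual(self) -> np.ndarray:
        """free+promoter+elongating+queued+stalled - (n0 + synthesized - degraded)."""
        return (
            self.undegraded()
            - (self.n0 + self.counts["synthesized"] - self.counts["degraded"])
        )

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.counts.items():
            rows.append(pd.DataFrame({
                "time_min": self.times, "state": name, "count": arr,
                "scenario_id": self.scenario_id,
            }))
        for cls in LESION_CLASSES:
            rows.append(pd.DataFrame({
                "time_min": self.times, "state": f"lesion_unoccupied_{cls}",
                "count": self.lesions_unoccupied[cls], "scenario_id": self.scenario_id,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class MoleculeHistory:
    """Per-molecule state labels over time from the stochastic engine.

    ``states`` is an (n_times, n_slots) int8 array of state codes; slots with
    code ``S_UNBORN`` are synthesis capacity not yet used at that time.  FRAP
    strip membership and bleach flags are attached later by the assay layer.
    """

    times: np.ndarray
    states: np.ndarray
    n_molecules: int
    seed: int
    genotype: str = ""

    def state_counts(self) -> dict[str, np.ndarray]:
        out = {}
        codes = {
            "free": S_FREE, "promoter": S_PROMOTER, "elongating": S_ELONGATING,
            "queued": S_QUEUED, "stalled": S_STALLED, "degraded": S_DEGRADED,
        }
        for name, code in codes.items():
            out[name] = (self.states == code).sum(axis=1)
        return out


# ---------------------------------------------------------------------------
# analytic helpers


def basal_fractions(rates: RateSet) -> dict[str, float]:
    """Steady-state fractions of the undamaged free/promoter/elongating cycle.

    Degenerate rate sets (a stage with zero throughput) park all molecules in
    the free pool.
    """
    if rates.k_init <= 0 or rates.k_escape <= 0 or rates.tau_elong <= 0:
        return {"free": 1.0, "promoter": 0.0, "elongating": 0.0}
    p = 1.0
    f = (rates.k_escape + rates.k_pre_release) / rates.k_init
    e = rates.k_escape * rates.tau_elong
    tot = f + p + e
    return {"free": f / tot, "promoter": p / tot, "elongating": e / tot}


def mean_residence_time(rates: RateSet, state: str) -> float:
    """Mean chromatin residence time (min) of a promoter- or elongating-class
    Pol II, computed analytically from the rate set.

    A zero total exit rate yields ``inf`` (flagged, not raised).
    """
    if state == "promoter":
        exit_rate = rates.k_escape + rates.k_pre_release + rates.k_pdeg_uv
        return 1.0 / exit_rate if exit_rate > 0 else math.inf
    if state == "elongating":
        return rates.tau_elong if rates.tau_elong > 0 else math.inf
    raise ValueError(f"unsupported state {state!r}; use 'promoter' or 'elongating'")


def stalled_fraction(
    trajectory: StateTrajectory, t: float, include_queued: bool = False
) -> float:
    """Fraction of undegraded Pol II molecules stalled at a lesion at time t.

    With ``include_queued`` the trailing (queued) polymerases count as part
    of the lesion-bound pool, matching what strip-FRAP immobility reports.
    """
    i = trajectory.index_of(t)
    num = trajectory.counts["stalled"][i]
    if include_queued:
        num += trajectory.counts["queued"][i]
    denom = float(sum(trajectory.counts[s][i] for s in STATE_NAMES))
    if denom <= 0:
        return 0.0
    return float(num) / denom


# ---------------------------------------------------------------------------
# mean-field propagation


def _lesion_injections(schedule: PerturbationSchedule, rates: TimedRates):
    """(instant injections [(t, class, amount)], production windows
    [(t0, t1, class, rate/min)]) implied by the schedule."""
    inject: list[tuple[float, str, float]] = []
    windows: list[tuple[float, float, str, float]] = []
    for e in schedule.events:
        base = rates.segments[0]
        if e.kind == "UV_DOSE":
            n = e.magnitude * base.lesions_per_dose
            inject.append((e.t_min, "cpd", n * base.cpd_fraction))
            inject.append((e.t_min, "pp64", n * (1.0 - base.cpd_fraction)))
        elif e.kind == "ILLUDIN":
            rate = e.magnitude * base.illudin_lesions_per_ngml_min
            windows.append((e.t_min, e.t_min + e.duration, "tc_only", rate))
    return inject, windows


def _decay_split(x: float, rates_out: Sequence[float], dt: float) -> list[float]:
    """Exact competing-risk outflow of a pool over one step, split per route."""
    tot = float(sum(rates_out))
    if tot <= 0 or x <= 0:
        return [0.0] * len(rates_out)
    out = x * (1.0 - math.exp(-tot * dt))
    return [out * r / tot for r in rates_out]


def propagate_mean_field(
    rates: TimedRates,
    schedule: PerturbationSchedule | None = None,
    n0: float = 50_000,
    horizon: float = 120.0,
    step: float = 0.05,
    scenario_id: str = "",
) -> StateTrajectory:
    """Deterministic (expected-occupancy) propagation of the state graph.

    Uses a fixed-step scheme with exact exponential competing-risk outflows
    per pool and piecewise-frozen coupling terms.  Schedule event times are
    snapped to the step grid.  Mass conservation holds to floating-point
    accuracy by construction.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    if horizon < step:
        raise ValueError("horizon must be >= step")
    schedule = schedule if schedule is not None else rates.schedule
    for e in schedule.events:
        if not (0.0 <= e.t_min <= horizon):
            raise ValueError(f"schedule event at t={e.t_min} outside [0, {horizon}]")

    n_steps = int(round(horizon / step))
    times = np.arange(n_steps + 1) * step
    inject, windows = _lesion_injections(schedule, rates)
    inject_idx = {}
    for (t, cls, amt) in inject:
        inject_idx.setdefault(int(round(t / step)), []).append((cls, amt))

    r0 = rates.at(0.0)
    frac = basal_fractions(r0)
    F, P, E = n0 * frac["free"], n0 * frac["promoter"], n0 * frac["elongating"]
    S = {c: 0.0 for c in LESION_CLASSES}
    Q = {c: 0.0 for c in LESION_CLASSES}
    Lu = {c: 0.0 for c in LESION_CLASSES}
    Rm = {c: 0.0 for c in LESION_CLASSES}
    D = 0.0
    syn = 0.0

    rec = {name: np.zeros(n_steps + 1) for name in
           ("free", "promoter", "elongating", "queued", "stalled", "degraded", "synthesized")}
    rec_lu = {c: np.zeros(n_steps + 1) for c in LESION_CLASSES}
    rec_rm = {c: np.zeros(n_steps + 1) for c in LESION_CLASSES}

    def record(i: int) -> None:
        rec["free"][i], rec["promoter"][i], rec["elongating"][i] = F, P, E
        rec["queued"][i] = sum(Q.values())
        rec["stalled"][i] = sum(S.values())
        rec["degraded"][i], rec["synthesized"][i] = D, syn
        for c in LESION_CLASSES:
            rec_lu[c][i], rec_rm[c][i] = Lu[c], Rm[c]

    if 0 in inject_idx:
        for cls, amt in inject_idx[0]:
            Lu[cls] += amt
    record(0)

    for i in range(n_steps):
        t = times[i]
        r = rates.at(t + 0.5 * step)
        prod = {c: 0.0 for c in LESION_CLASSES}
        for (t0, t1, cls, rate) in windows:
            overlap = max(0.0, min(t + step, t1) - max(t, t0))
            prod[cls] += rate * overlap

        avail = {c: Lu[c] + S[c] for c in LESION_CLASSES}
        k_enc = r.k_stall * sum(avail.values())
        k_term = 1.0 / r.tau_elong if r.tau_elong > 0 else 0.0

        # outflows computed from start-of-step pools (piecewise frozen)
        dF_init, = _decay_split(F, [r.k_init], step)
        dP_esc, dP_rel, dP_deg = _decay_split(
            P, [r.k_escape, r.k_pre_release, r.k_pdeg_uv], step)
        dE_term, dE_enc = _decay_split(E, [k_term, k_enc], step)

        # partition lesion encounters by class and occupancy
        tot_avail = sum(avail.values())
        new_stall = {c: 0.0 for c in LESION_CLASSES}
        new_queue = {c: 0.0 for c in LESION_CLASSES}
        if tot_avail > 0:
            for c in LESION_CLASSES:
                enc_c = dE_enc * avail[c] / tot_avail
                hit_unocc = enc_c * (Lu[c] / avail[c]) if avail[c] > 0 else 0.0
                hit_unocc = min(hit_unocc, Lu[c])
                new_stall[c] = hit_unocc
                new_queue[c] = enc_c - hit_unocc

        # stalled-pool processing per lesion class
        to_E_from_S = to_F_from_S = 0.0
        dD_stall = 0.0
        for c in LESION_CLASSES:
            a_rep, a_deg, a_rel = _decay_split(
                S[c], [r.k_repair, r.k_degrade_stalled, r.k_release_stalled], step)
            q = Q[c] / S[c] if S[c] > 0 else 0.0
            p_empty = 1.0 / (1.0 + q)
            # repair: lesion removed, stalled molecule resumes (or frees),
            # trailing queue resumes elongation
            q_released = min(Q[c], Q[c] * (1.0 - math.exp(-r.k_repair * step)))
            if r.repair_release == "elongating":
                to_E_from_S += a_rep
            else:
                to_F_from_S += a_rep
            # degradation / XPA-type release without lesion removal: the
            # oldest queued molecule is promoted into the stalled position
            # when a queue is present, otherwise the lesion is re-exposed
            promoted = min(Q[c] - q_released, (a_deg + a_rel) * (1.0 - p_empty))
            promoted = max(promoted, 0.0)
            freed = (a_deg + a_rel) - promoted
            dD_stall += a_deg
            to_F_from_S += a_rel
            # GG-NER removal of unoccupied lesions (shielded while occupied)
            gg, = _decay_split(Lu[c], [r.ggner(c)], step)
            S[c] += new_stall[c] - a_rep - freed
            Q[c] += new_queue[c] - q_released - promoted
            Lu[c] += prod[c] - new_stall[c] + freed - gg
            Rm[c] += gg + a_rep
            to_E_from_S += q_released
            S[c] = max(S[c], 0.0)
            Q[c] = max(Q[c], 0.0)
            Lu[c] = max(Lu[c], 0.0)

        dSyn = r.k_syn * step
        F += dSyn - dF_init + dP_rel + dE_term + to_F_from_S
        P += dF_init - dP_esc - dP_rel - dP_deg
        E += dP_esc - dE_term - dE_enc + to_E_from_S
        D += dP_deg + dD_stall
        syn += dSyn

        if (i + 1) in inject_idx:
            for cls, amt in inject_idx[i + 1]:
                Lu[cls] += amt
        record(i + 1)

    return StateTrajectory(
        times=times,
        counts=rec,
        lesions_unoccupied=rec_lu,
        lesions_removed=rec_rm,
        n0=float(n0),
        genotype=rates.genotype,
        scenario_id=scenario_id,
    )


# ---------------------------------------------------------------------------
# stochastic per-molecule engine


def simulate_molecules(
    rates: TimedRates,
    schedule: PerturbationSchedule | None = None,
    n_molecules: int = 50_000,
    seed: int = 0,
    record_times: Sequence[float] | None = None,
    horizon: float | None = None,
    step: float = 0.1,
    initial_counts: dict[str, int] | None = None,
) -> MoleculeHistory:
    """Seeded per-molecule realization of the state graph.

    Molecules carry exponential (per-step competing-risk) transition draws;
    lesion contention is resolved by uniform random assignment of encounters
    to unoccupied versus occupied lesions each step, and queue promotion on
    degradation/release uses the same geometric queue closure as the
    mean-field propagator.  ``record_times`` defaults to the step grid up to
    ``horizon``.  ``initial_counts`` (state name -> count) overrides the
    basal steady-state initialization; initially stalled molecules occupy
    CPD-class lesions.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    schedule = schedule if schedule is not None else rates.schedule
    if record_times is None:
        if horizon is None:
            raise ValueError("give record_times or horizon")
        record_times = np.arange(0.0, horizon + step / 2, step)
    record_times = np.asarray(record_times, dtype=float)
    if record_times.ndim != 1 or len(record_times) == 0 or np.any(np.diff(record_times) <= 0):
        raise ValueError("record_times must be strictly increasing and non-empty")
    t_end = float(record_times[-1])

    rng = np.random.default_rng(seed)
    r0 = rates.at(0.0)

    # capacity for synthesized molecules (generous Poisson upper bound)
    max_syn_rate = max(seg.k_syn for seg in rates.segments)
    cap_syn = int(max_syn_rate * t_end + 6.0 * math.sqrt(max_syn_rate * t_end + 1.0)) + 8
    n_slots = n_molecules + cap_syn
    state = np.full(n_slots, S_UNBORN, dtype=np.int8)
    lesion_cls = np.full(n_slots, -1, dtype=np.int8)   # class index while stalled/queued
    queue_rank = np.full(n_slots, -1, dtype=np.int64)  # FIFO order stamp for queued
    rank_counter = 0

    if n_molecules > 0:
        if initial_counts is None:
            frac = basal_fractions(r0)
            counts = rng.multinomial(
                n_molecules, [frac["free"], frac["promoter"], frac["elongating"]])
            init = {"free": counts[0], "promoter": counts[1], "elongating": counts[2]}
        else:
            init = dict(initial_counts)
            if sum(init.values()) != n_molecules:
                raise ValueError("initial_counts must sum to n_molecules")
        pos = 0
        code_of = {"free": S_FREE, "promoter": S_PROMOTER, "elongating": S_ELONGATING,
                   "queued": S_QUEUED, "stalled": S_STALLED}
        for name, cnt in init.items():
            state[pos:pos + cnt] = code_of[name]
            if name in ("stalled", "queued"):
                lesion_cls[pos:pos + cnt] = 0  # cpd
                if name == "queued":
                    queue_rank[pos:pos + cnt] = np.arange(rank_counter, rank_counter + cnt)
                    rank_counter += cnt
            pos += cnt
        state[pos:n_molecules] = S_FREE  # safety: unassigned remainder

    Lu = np.zeros(3, dtype=np.int64)
    inject, windows = _lesion_injections(schedule, rates)
    cls_index = {c: k for k, c in enumerate(LESION_CLASSES)}
    # initially stalled molecules occupy cpd lesions implicitly (S counts them)

    out = np.empty((len(record_times), n_slots), dtype=np.int8)
    rec_i = 0
    if record_times[0] == 0.0:
        out[0] = state
        rec_i = 1
    next_syn = n_molecules  # next free slot for a synthesized molecule

    # incremental per-class stalled/queued counters
    S_cnt = np.zeros(3, dtype=np.int64)
    Q_cnt = np.zeros(3, dtype=np.int64)
    for k in range(3):
        S_cnt[k] = int(np.count_nonzero((state == S_STALLED) & (lesion_cls == k)))
        Q_cnt[k] = int(np.count_nonzero((state == S_QUEUED) & (lesion_cls == k)))

    pending_inject = sorted(inject)
    t = 0.0
    for t0, cls, amt in list(pending_inject):
        if t0 <= 0.0:
            Lu[cls_index[cls]] += int(round(amt))
            pending_inject.remove((t0, cls, amt))

    # per-molecule leave probability per state code, refreshed when the rate
    # segment, the step size or the lesion availability changes
    leave_p = np.zeros(8)  # indexed by state + 2 (S_UNBORN=-1, spare -2)
    cached = (None, None, None)

    while rec_i < len(record_times):
        t_target = record_times[rec_i]
        while t < t_target - 1e-12:
            dt = min(step, t_target - t)
            r = rates.at(t + 0.5 * dt)
            avail = Lu + S_cnt
            k_enc = r.k_stall * float(avail.sum())
            k_term = 1.0 / r.tau_elong if r.tau_elong > 0 else 0.0
            k_stalled_out = r.k_repair + r.k_degrade_stalled + r.k_release_stalled
            key = (id(r), dt, float(k_enc))
            if key != cached:
                leave_p[:] = 0.0
                leave_p[S_FREE + 2] = -math.expm1(-r.k_init * dt)
                leave_p[S_PROMOTER + 2] = -math.expm1(
                    -(r.k_escape + r.k_pre_release + r.k_pdeg_uv) * dt)
                leave_p[S_ELONGATING + 2] = -math.expm1(-(k_term + k_enc) * dt)
                leave_p[S_STALLED + 2] = -math.expm1(-k_stalled_out * dt)
                cached = key

            # synthesis -> new free molecules
            if r.k_syn > 0:
                n_new = rng.poisson(r.k_syn * dt)
                n_new = min(n_new, n_slots - next_syn)
                if n_new:
                    state[next_syn:next_syn + n_new] = S_FREE
                    next_syn += n_new

            movers = np.flatnonzero(rng.random(n_slots) < leave_p[state + 2])
            mstate = state[movers]

            # free -> promoter
            state[movers[mstate == S_FREE]] = S_PROMOTER

            # promoter exits
            prom = movers[mstate == S_PROMOTER]
            ktot = r.k_escape + r.k_pre_release + r.k_pdeg_uv
            if len(prom):
                u = rng.random(len(prom))
                p1 = r.k_escape / ktot
                p2 = (r.k_escape + r.k_pre_release) / ktot
                state[prom[u < p1]] = S_ELONGATING
                state[prom[(u >= p1) & (u < p2)]] = S_FREE
                state[prom[u >= p2]] = S_DEGRADED

            # elongating: termination or lesion encounter
            elo = movers[mstate == S_ELONGATING]
            if len(elo):
                enc_mask = rng.random(len(elo)) < (k_enc / (k_term + k_enc))
                state[elo[~enc_mask]] = S_FREE
                enc = elo[enc_mask]
                if len(enc) and avail.sum() > 0:
                    enc = rng.permutation(enc)
                    cls_draw = rng.choice(3, size=len(enc), p=avail / avail.sum())
                    for k in range(3):
                        mols = enc[cls_draw == k]
                        a = int(avail[k])
                        if not len(mols) or a <= 0:
                            continue
                        hit_unocc = rng.random(len(mols)) < (Lu[k] / a)
                        n_stall = min(int(hit_unocc.sum()), int(Lu[k]))
                        stallers = mols[np.flatnonzero(hit_unocc)[:n_stall]]
                        queuers = np.setdiff1d(mols, stallers, assume_unique=True)
                        state[stallers] = S_STALLED
                        lesion_cls[stallers] = k
                        Lu[k] -= n_stall
                        S_cnt[k] += n_stall
                        if S_cnt[k] > 0 and len(queuers):
                            state[queuers] = S_QUEUED
                            lesion_cls[queuers] = k
                            queue_rank[queuers] = np.arange(
                                rank_counter, rank_counter + len(queuers))
                            rank_counter += len(queuers)
                            Q_cnt[k] += len(queuers)

            # stalled exits per class
            stl = movers[mstate == S_STALLED]
            if len(stl) and k_stalled_out > 0:
                for k in range(3):
                    leave = stl[lesion_cls[stl] == k]
                    if not len(leave):
                        continue
                    u = rng.random(len(leave))
                    p1 = r.k_repair / k_stalled_out
                    p2 = (r.k_repair + r.k_degrade_stalled) / k_stalled_out
                    rep = leave[u < p1]
                    deg = leave[(u >= p1) & (u < p2)]
                    rel = leave[u >= p2]
                    qbar = Q_cnt[k] / S_cnt[k] if S_cnt[k] > 0 else 0.0
                    q_idx = (np.flatnonzero((state == S_QUEUED) & (lesion_cls == k))
                             if Q_cnt[k] > 0 and (len(rep) or len(deg) or len(rel))
                             else np.empty(0, dtype=np.int64))
                    # repair: lesion removed; the expected whole queue at that
                    # lesion resumes elongation (oldest first)
                    if len(rep):
                        state[rep] = (S_ELONGATING if r.repair_release == "elongating"
                                      else S_FREE)
                        lesion_cls[rep] = -1
                        S_cnt[k] -= len(rep)
                        n_rel_q = min(len(q_idx), rng.poisson(qbar * len(rep)))
                        if n_rel_q:
                            order = q_idx[np.argsort(queue_rank[q_idx])][:n_rel_q]
                            state[order] = S_ELONGATING
                            lesion_cls[order] = -1
                            queue_rank[order] = -1
                            Q_cnt[k] -= n_rel_q
                            q_idx = np.setdiff1d(q_idx, order, assume_unique=True)
                    # degradation / release without lesion removal:
                    # first-in-first-promoted trailing queue
                    for mols, new_code in ((deg, S_DEGRADED), (rel, S_FREE)):
                        if not len(mols):
                            continue
                        state[mols] = new_code
                        lesion_cls[mols] = -1
                        S_cnt[k] -= len(mols)
                        p_promote = 1.0 - 1.0 / (1.0 + qbar)
                        n_prom = min(len(q_idx),
                                     int(rng.binomial(len(mols), p_promote)))
                        if n_prom:
                            order = q_idx[np.argsort(queue_rank[q_idx])][:n_prom]
                            state[order] = S_STALLED
                            queue_rank[order] = -1
                            Q_cnt[k] -= n_prom
                            S_cnt[k] += n_prom
                            q_idx = np.setdiff1d(q_idx, order, assume_unique=True)
                        Lu[k] += len(mols) - n_prom  # lesions left unoccupied

            # GG-NER removal of unoccupied lesions + Illudin production
            for k, cls in enumerate(LESION_CLASSES):
                kg = r.ggner(cls)
                if kg > 0 and Lu[k] > 0:
                    Lu[k] -= rng.binomial(int(Lu[k]), -math.expm1(-kg * dt))
            for (w0, w1, cls, rate) in windows:
                overlap = max(0.0, min(t + dt, w1) - max(t, w0))
                if overlap > 0:
                    Lu[cls_index[cls]] += rng.poisson(rate * overlap)

            t += dt
            # instantaneous UV lesion injection at event time
            for item in list(pending_inject):
                t0, cls, amt = item
                if t0 <= t + 1e-12:
                    Lu[cls_index[cls]] += int(round(amt))
                    pending_inject.remove(item)

        out[rec_i] = state
        rec_i += 1

    return MoleculeHistory(
        times=record_times, states=out, n_molecules=n_molecules, seed=seed,
        genotype=rates.genotype,
    )
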