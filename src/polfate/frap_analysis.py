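"""Strip-FRAP quantification: background correction, RFI normalization and
the immobile-fraction statistic.

The pipeline per cell is

1. subtract the pre-bleach mean of the outside-nucleus background channel
   from every frame of the strip signal (``background_correct``);
2. rescale so the pre-bleach average reads 100 exactly (``compute_rfi``);
3. compare each treated cell to the matched untreated control group through

   ``F_imm = 1 - (I_recovery,UV - I_bleach,UV) /
                 (<I_recovery,untreated> - I_bleach,UV)``

   where ``I_bleach`` is the RFI at the first post-bleach frame and
   ``I_recovery`` the mean RFI over a tag-specific late recovery window:
   post-bleach frames 250-450 for GFP-RPB1, 24-33 for CSB-mScarletI (closed,
   1-based within the post-bleach segment).

Cells are never dropped silently: any rejection carries a reason code.
Controls are matched within genotype, never pooled across genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assay_sim import RawFRAPTrace, TRACE_COLUMNS

__all__ = [
    "FRAPWindows",
    "WINDOWS_BY_TAG",
    "RFICurve",
    "ImmobileFractionResult",
    "RejectedCell",
    "background_correct",
    "compute_rfi",
    "immobile_fraction",
    "summarize_condition",
    "analyze_experiment",
    "traces_from_frame",
]


@dataclass(frozen=True)
class FRAPWindows:
    """Tag-specific frame windows (1-based, closed) used by the statistic."""

    tag: str
    recovery_start: int   # first post-bleach frame of the recovery window
    recovery_end: int     # last post-bleach frame (inclusive)

    def recovery_slice(self, n_pre: int, n_frames: int) -> slice:
        """0-based absolute-frame slice for the recovery window."""
        a = n_pre + self.recovery_start - 1
        b = n_pre + self.recovery_end
        if b > n_frames:
            raise ValueError("recovery window extends past the acquisition")
        return slice(a, b)


WINDOWS_BY_TAG = {
    "GFP-RPB1": FRAPWindows("GFP-RPB1", 250, 450),
    "CSB-mScarletI": FRAPWindows("CSB-mScarletI", 24, 33),
}


@dataclass
class RFICurve:
    """Per-frame relative fluorescence intensity; pre-bleach mean is 100."""

    cell_id: str
    genotype: str
    treatment: str
    tag: str
    values: np.ndarray
    n_pre: int
    bleach_frame: int  # 1-based = n_pre + 1


@dataclass
class ImmobileFractionResult:
    """F_imm for one treated cell, with its constituent intensities."""

    cell_id: str
    genotype: str
    treatment: str
    f_imm: float
    i_bleach_uv: float
    i_recovery_uv: float
    mean_i_recovery_untreated: float
    n_untreated: int


@dataclass
class RejectedCell:
    cell_id: str
    reason: str


def background_correct(raw: RawFRAPTrace) -> RawFRAPTrace:
    """Subtract the pre-bleach mean of the background channel from all frames.

    Negative corrected intensities are clamped to zero and counted in
    ``clamped_frames``.
    """
    if raw.background_intensity is None or len(raw.background_intensity) == 0:
        raise ValueError("missing background channel")
    if raw.n_pre < 1:
        raise ValueError("need at least one pre-bleach frame")
    bg = float(np.mean(raw.background_intensity[: raw.n_pre]))
    corrected = raw.strip_intensity - bg
    clamped = int(np.count_nonzero(corrected < 0))
    corrected = np.clip(corrected, 0.0, None)
    return RawFRAPTrace(
        cell_id=raw.cell_id,
        genotype=raw.genotype,
        treatment=raw.treatment,
        tag=raw.tag,
        time_s=raw.time_s,
        strip_intensity=corrected,
        background_intensity=np.zeros_like(raw.background_intensity),
        bleach_frame=raw.bleach_frame,
        n_pre=raw.n_pre,
        seed=raw.seed,
        clamped_frames=clamped,
    )


def compute_rfi(corrected: RawFRAPTrace) -> RFICurve:
    """Normalize so the mean pre-bleach intensity reads exactly 100.

    Raises on a non-positive pre-bleach mean; callers report such cells as
    rejected rather than dropping them silently.
    """
    pre_mean = float(np.mean(corrected.strip_intensity[: corrected.n_pre]))
    if pre_mean <= 0:
        raise ValueError(f"cell {corrected.cell_id}: non-positive pre-bleach mean")
    return RFICurve(
        cell_id=corrected.cell_id,
        genotype=corrected.genotype,
        treatment=corrected.treatment,
        tag=corrected.tag,
        values=100.0 * corrected.strip_intensity / pre_mean,
        n_pre=corrected.n_pre,
        bleach_frame=corrected.bleach_frame,
    )


def _recovery_mean(curve: RFICurve, windows: FRAPWindows) -> float:
    sl = windows.recovery_slice(curve.n_pre, len(curve.values))
    return float(np.mean(curve.values[sl]))


def immobile_fraction(
    rfi_treated: RFICurve,
    controls: Sequence[RFICurve],
    windows: FRAPWindows | None = None,
) -> ImmobileFractionResult:
    """The immobile-fraction statistic of one treated cell versus controls.

    The control term is the mean over control cells of their own
    recovery-window means (mean of means, not a pooled frame average).
    ``F_imm`` is not clipped; values outside [0, 1] are legitimate noise.
    A non-positive denominator raises, and callers record the cell as
    excluded with a diagnostic.
    """
    if not controls:
        raise ValueError("controls must be non-empty")
    windows = windows or WINDOWS_BY_TAG[rfi_treated.tag]
    i_bleach = float(rfi_treated.values[rfi_treated.bleach_frame - 1])
    i_rec = _recovery_mean(rfi_treated, windows)
    ctrl = float(np.mean([_recovery_mean(c, windows) for c in controls]))
    denom = ctrl - i_bleach
    if denom <= 0:
        raise ValueError(
            f"cell {rfi_treated.cell_id}: non-positive F_imm denominator ({denom:.3g})")
    f_imm = 1.0 - (i_rec - i_bleach) / denom
    return ImmobileFractionResult(
        cell_id=rfi_treated.cell_id,
        genotype=rfi_treated.genotype,
        treatment=rfi_treated.treatment,
        f_imm=f_imm,
        i_bleach_uv=i_bleach,
        i_recovery_uv=i_rec,
        mean_i_recovery_untreated=ctrl,
        n_untreated=len(controls),
    )


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def summarize_condition(
    curves: Sequence[RFICurve],
    f_imm_results: Sequence[ImmobileFractionResult] = (),
    clip_f_imm: bool = False,
) -> dict:
    """Per-condition summary: per-frame mean RFI +- SEM and mean F_imm +- SEM.

    SEM entries are NaN when only one cell is present.  ``clip_f_imm``
    optionally clips F_imm into [0, 1] for reporting (default off).
    """
    if not curves:
        raise ValueError("empty condition")
    mat = np.vstack([c.values for c in curves])
    n = mat.shape[0]
    out = {
        "genotype": curves[0].genotype,
        "treatment": curves[0].treatment,
        "tag": curves[0].tag,
        "n_cells": n,
        "mean_rfi": mat.mean(axis=0),
        "sem_rfi": (mat.std(axis=0, ddof=1) / np.sqrt(n)
                    if n > 1 else np.full(mat.shape[1], np.nan)),
    }
    if f_imm_results:
        vals = np.array([r.f_imm for r in f_imm_results], dtype=float)
        if clip_f_imm:
            vals = np.clip(vals, 0.0, 1.0)
        out["mean_f_imm"] = float(vals.mean())
        out["sem_f_imm"] = _sem(vals)
        out["n_f_imm"] = len(vals)
    return out


def traces_from_frame(df: pd.DataFrame) -> list[RawFRAPTrace]:
    """Parse the tidy trace CSV dialect into per-cell trace objects."""
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    traces = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("frame")
        bleach_frame = int(g["bleach_frame"].iloc[0])
        traces.append(RawFRAPTrace(
            cell_id=str(cell_id),
            genotype=str(g["genotype"].iloc[0]),
            treatment=str(g["treatment"].iloc[0]),
            tag=str(g["tag"].iloc[0]),
            time_s=g["time_s"].to_numpy(float),
            strip_intensity=g["strip_intensity"].to_numpy(float),
            background_intensity=g["background_intensity"].to_numpy(float),
            bleach_frame=bleach_frame,
            n_pre=bleach_frame - 1,
        ))
    return traces


def analyze_experiment(
    traces: pd.DataFrame | Iterable[RawFRAPTrace],
    control_treatment: str = "mock+THZ1",
    windows: FRAPWindows | None = None,
    clip_f_imm: bool = False,
) -> dict:
    """Full FRAP analysis of a trace table.

    Groups cells by genotype, computes RFI curves, and evaluates F_imm of
    every non-control cell against its genotype-matched control group.

    Returns ``{"rfi": [...], "f_imm": [...], "summaries": [...],
    "rejected": [...]}`` where summaries is a per-(genotype, treatment)
    list of :func:`summarize_condition` dicts.
    """
    if isinstance(traces, pd.DataFrame):
        traces = traces_from_frame(traces)
    rejected: list[RejectedCell] = []
    curves: list[RFICurve] = []
    for raw in traces:
        try:
            curves.append(compute_rfi(background_correct(raw)))
        except ValueError as e:
            rejected.append(RejectedCell(raw.cell_id, f"rfi: {e}"))
    by_geno: dict[str, list[RFICurve]] = {}
    for c in curves:
        by_geno.setdefault(c.genotype, []).append(c)

    results: list[ImmobileFractionResult] = []
    summaries = []
    for geno, group in by_geno.items():
        controls = [c for c in group if c.treatment == control_treatment]
        treated_by_cond: dict[str, list[RFICurve]] = {}
        for c in group:
            if c.treatment != control_treatment:
                treated_by_cond.setdefault(c.treatment, []).append(c)
        if treated_by_cond and not controls:
            raise ValueError(f"genotype {geno}: no matched control condition "
                             f"{control_treatment!r}")
        summaries.append(summarize_condition(controls) if controls else None)
        if controls:
            summaries[-1]["is_control"] = True
        for cond, cells in treated_by_cond.items():
            cond_results = []
            for c in cells:
                try:
                    cond_results.append(immobile_fraction(c, controls, windows))
                except ValueError as e:
                    rejected.append(RejectedCell(c.cell_id, f"f_imm: {e}"))
            results.extend(cond_results)
            s = summarize_condition(cells, cond_results, clip_f_imm=clip_f_imm)
            s["is_control"] = False
            summaries.append(s)
    summaries = [s for s in summaries if s is not None]
    return {"rfi": curves, "f_imm": results, "summaries": summaries,
            "rejected": rejected}
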