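# Methods

## The kinetic model

`polfate` models a well-mixed nuclear pool of Pol II molecules (default
N₀ = 50,000 per cell) on the state graph

```
free --k_init--> promoter --k_escape--> elongating --(k_stall x lesions)--> stalled/queued
         <--k_pre_release--        <--1/tau_elong-- (termination)
```

Lesions are a well-mixed pool with three classes: CPD and 6-4PP (from UV,
split 75/25) and TC-only (Illudin S adducts, produced at a constant rate
during the exposure window and invisible to GG-NER). A lesion is *occupied*
exactly when a stalled polymerase sits on it; polymerases that encounter an
occupied lesion join its trailing queue. Sequence, strand and genomic
position are deliberately not represented — the assays being modelled
(strip-FRAP, flow cytometry, fractionation) integrate over the nucleus, so
only pool sizes matter.

Fate of a stalled polymerase, per genotype profile:

| route | rate | active in |
|---|---|---|
| repair (lesion removed, Pol II resumes) | `k_repair` | WT, XPC KO, CSA-rescue |
| CRL4^CSA/VCP/proteasome degradation | `k_degrade_stalled` | UVSSA KO, CSA W361C (and weakly WT) |
| release to the free pool, lesion left | `k_release_stalled` | XPA KO |
| none (persistent block) | — | CSB/CSA KO, CSA A160T/W194C, CSA+UVSSA DKO |

On repair the whole trailing queue resumes elongation; on degradation or
release the oldest queued polymerase is promoted into the stalled position
(serial, first-in-first-processed), otherwise the lesion returns to the
GG-NER-accessible pool. GG-NER acts only on unoccupied lesions — a stalled
polymerase shields its lesion — which is what makes DDB2 overexpression
(a multiplier on the CPD removal rate) effective only in genotypes that
clear Pol II from the damage. Whether repair returns Pol II to elongation
or to the free pool is genuinely unknown; the default is return to
elongation and the alternative is switchable (`repair_release="free"`).

Promoter-bound Pol II is additionally degraded after UV in a TC-NER
independent manner (`k_pdeg_uv`); the rate is zero before the UV event,
constant afterwards, genotype-independent, and suppressed (along with the
stalled route) by proteasome or VCP inhibition.

## Default rates and their calibration

All defaults live in `RateSet` (units per minute unless noted) and are
overridable everywhere.

| parameter | default | why |
|---|---|---|
| `k_init` | 0.5 | with `k_escape`/`k_pre_release`, gives a basal partition of ~40% free / 10% promoter / 50% elongating |
| `k_escape`, `k_pre_release` | 0.2, 1.8 | promoter residence 1/(2.0065) ≈ 0.5 min (< 1 min) |
| `tau_elong` | 25 min | elongating class chromatin-bound > 20 min on average |
| `lesions_per_dose` | 2,600 /(J/m²) | with `k_stall`, calibrated so the CS-genotype scenario (4 J/m², THZ1 at 30 min) holds ~5,400 stalled + ~2,500 queued polymerases (≈ 15% of the pool) at 2 h |
| `k_stall` | 7.0e-7 /min/lesion | see above |
| `k_repair` | 0.07 | stalled Pol II resolved in ~15 min in repair-proficient cells; drives WT F_imm to ≈ 0 at 2 h |
| `k_degrade_stalled` | 0.008 (WT), 0.024 (UVSS-type) | WT retains a weak CRL4^CSA route; the UVSS value clears most lesion-stalled Pol II within the 2 h window and sets the ~10–12-point CSA−UVSSA flow difference |
| `k_release_stalled` | 0.024 (XPA KO) | release kinetics taken equal to the UVSS clearance timescale |
| `k_ggner_cpd`, `k_ggner_pp64` | 3.9e-4, 1.16e-2 | CPD half-life ~30 h, 6-4PP ~1 h |
| `k_pdeg_uv` | 0.0065 | with `k_syn`, calibrated so WT loses ≈ 50% of total Pol II relative to mock over 24 h after 8 J/m² with synthesis active |
| `k_syn` | 24 molecules/min | replaces ~70% of the pool per day; mock arms grow identically |
| `tau_mix` | 1.5 s | free-pool strip re-equilibration; fast relative to the 0.4 s sampling, only its timescale matters |

A stated design anchor — transcription-initiation block emptying ≥ 95% of
the elongating pool in 45 min — is arithmetically incompatible with an
elongating residence ≥ 20 min (exp(−45/20) ≈ 0.11). The package follows
the residence-time constraint: after 45 min of THZ1 about 83% of the
elongating pool has terminated, and because that pool is half of all Pol II
the chromatin-bound fraction of total Pol II falls to ~8%, i.e. an almost
complete mobilization of Pol II, which is the observable the anchor
describes.

## Numerics

The mean-field propagator uses a fixed step (default 0.05 min; 0.1–0.2 min
for day-long horizons) with exact exponential competing-risk outflows per
pool and coupling terms frozen within a step; mass conservation
(free + promoter + elongating + queued + stalled = N₀ + synthesized −
degraded) holds to floating-point accuracy by construction and a
step-halving check in the test suite bounds the discretization error at
< 1% on the calibration statistic. Schedule event times snap to the step
grid. Queue bookkeeping uses an aggregate closure: the probability that a
stalled polymerase has no trailing queue is 1/(1+q) with q = queued/stalled
(geometric queue-length assumption). The stochastic engine draws per-step
competing-risk transitions per molecule with the same piecewise-constant
rates and the same queue closure, resolves lesion contention by uniform
random assignment per step, and is a pure function of its integer seed; its
occupancies agree with the mean field within sampling error (4 SE at ten
checkpoints for 2×10⁴ molecules in the test suite).

## The synthetic assays

Observable scales are arbitrary units; every analysis stage consumes only
mock-normalized ratios.

**Strip-FRAP.** A scalar `strip_fraction` (0.1) replaces the strip
geometry. Bound molecules hold a fixed in-strip position; free molecules
carry an in-strip probability weight relaxing toward `strip_fraction` with
timescale `tau_mix`. The bleach is instantaneous at the timestamp of the
first post-bleach frame (so that sample reads the bleach depth, 0.05
default) and is applied in expectation: each molecule keeps a brightness
factor equal to its bleach-survival probability. Post-bleach frames are
divided by the expected surviving fluorescence fraction
m = 1 − strip_fraction × (1 − bleach_depth) (double normalization). Under
these conventions two exact identities hold, which the tests assert: a
fully mobile pool returns exactly to its pre-bleach level, and the F_imm
estimator recovers an injected immobile fraction with no systematic bias
(the ±0.03 parameter-recovery check). The price is that a fully immobile
pool plateaus at bleach_depth/m (≈ 0.055) rather than exactly at the
bleach depth — the two conventions cannot both be exact in a closed
nucleus, and the mobile-pool identity is the one the estimator's
calibration rests on. The CSB-mScarletI protocol reads a derived
observable: a CSB molecule is immobile exactly while its Pol II partner is
stalled, so CSB FRAP reports the lesion-stalled fraction. Measurement
noise is multiplicative Gaussian (CV 0.03) on strip and background
channels; the background channel is a constant offset. Both acquisition
protocols are presets: GFP-RPB1 (25 pre + 450 post frames at 0.4 s) and
CSB-mScarletI (5 + 40).

**Flow cytometry.** Per-cell intensity = undegraded count × gain ×
unit-mean lognormal cell-size factor (CV 0.25) + lognormal autofluorescence;
a paired blank population carries autofluorescence only. Samples are
assumed pre-gated (no doublet/scatter simulation). The DDB2 assay is a
mixture sample (40% transfected) with an mCherry second channel;
stratification thresholds default to the blank's 99th percentile.

**Fractionation.** Ser2 signal ∝ elongating + queued + stalled; total
RPB1 adds the promoter pool; the slow-migrating (ubiquitylated) Ser2 band
is proportional to the lesion-bound share and present only when the
genotype's CRL4^CSA is active.

**EU transcription recovery.** Per-cell intensity ∝ the trapezoidal time
integral of the actively elongating count over the labelling window
(queued and stalled polymerases do not synthesize RNA).

**Survival and co-culture.** An invented but documented bridge links
kinetics to viability: burden = time integral over 24 h of (unrepaired
lesions + 1.25 × stalled complexes), in lesion-days; colony counts are
Binomial(seeded, plating_efficiency × exp(−c × burden)) with c set so WT
survival at 8 J/m² is ≈ 0.5 (a package calibration constant). The
co-culture uses the same burden with a gentler daily-growth coefficient so
that chronic 2 J/m² dosing separates the UVSS and CS genotypes gradually
over ten days instead of collapsing either population.

## What the generators do and do not emulate

The generators reproduce the statistical structure the estimators assume:
per-cell seeds, mock arms for every treated arm, cell-size scatter, blank
populations, background channels, lesion-dose scaling. They do not emulate
image formation (no pixels, segmentation or bleach-spot geometry),
cell-cycle structure, gating artifacts, antibody or extraction biases, or
absolute fluorescence units. Passing round-trip tests therefore shows the
estimators are correct and calibrated *for data with this structure*; it
does not certify performance on microscopy artifacts the model excludes.

## Analysis conventions

Background correction subtracts the pre-bleach mean of the outside-nucleus
background channel from all frames (not per-frame subtraction); negative
results clamp to zero and are flagged. RFI sets the pre-bleach mean to 100
exactly. Post-bleach frames are numbered 1..n_post with closed recovery
windows [250, 450] (GFP-RPB1) and [24, 33] (CSB-mScarletI); I_bleach is
post-bleach frame 1. The control term of F_imm is the mean over control
cells of their own recovery-window means, controls matched within genotype
and never pooled across genotypes. F_imm is not clipped; clipping to [0,1]
is a reporting option, off by default. Rejected cells (non-positive
pre-bleach mean, non-positive F_imm denominator) carry reason codes and are
excluded from summary n. Flow summaries use arithmetic means; ratio SEMs
use the delta method; the cycloheximide series is
(treated/mock) normalized to the reference time point. No hypothesis tests
are computed anywhere — estimates ± SEM only.

## Problem sizes

Default study sizes are the modelled conditions: 50,000 Pol II molecules
per cell, 10,000–20,000 flow events, 30 FRAP cells per arm for headline
statistics, 300–500 seeded cells per survival replicate. The test suite
and the reproduction script run smaller grids (2–8 FRAP cells, 2×10⁴
molecules for agreement checks) chosen so each check is statistically
decisive at its stated tolerance.

## Known limitations

* Lesions and genes are a mean-field pool; no per-gene queue geometry, so
  queue statistics beyond the mean rest on the geometric closure.
* The promoter-degradation rate is constant after UV rather than tracking
  the damage response, which overstates late promoter turnover in
  long (24 h) scenarios; the mock-corrected readouts the package reports
  are insensitive to this except through the calibrated WT loss anchor.
* The survival/co-culture link functions are phenomenological bridges, not
  mechanistic claims; only their orderings and calibrated anchors are
  meaningful.
* Illudin S lesion chemistry is reduced to a constant TC-only production
  rate during exposure.
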