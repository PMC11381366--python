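# polfate

Kinetic simulation and quantification of RNA polymerase II fate at
transcription-blocking DNA lesions (TBLs).

## The problem

When elongating Pol II runs into a bulky DNA lesion (a UV photoproduct, an
Illudin S adduct), transcription-coupled nucleotide excision repair (TC-NER)
normally removes the damage and transcription resumes. Cells lacking
different TC-NER factors are equally repair-deficient yet clinically very
different: loss of CSA or CSB causes severe Cockayne syndrome, while loss of
UVSSA causes mild UV-sensitive syndrome. The mechanistic difference is what
happens to the *stalled polymerase itself*: in CS-type cells it stays
chromatin-bound on the lesion, in UVSS-type cells the CRL4^CSA ubiquitin
ligase marks it for VCP extraction and proteasomal degradation, freeing the
lesion for global-genome NER, and in XPA-deficient cells it is released
without degradation.

`polfate` implements this genotype-resolved fate model as a quantitative,
testable package for people who analyze live-cell Pol II mobility and
abundance data: a multi-state kinetic model, synthetic single-cell assay
generators with realistic statistical structure, and the exact analysis
stages used on such data (strip-FRAP immobile fractions, flow-cytometry
level normalization, fractionation, EU transcription recovery, clonogenic
survival, competitive co-culture). Every analysis stage can therefore be
validated by round-trip against a generator whose ground truth is known.

## The model in brief

Pol II molecules move through chromatin states

```
free <-> promoter -> elongating -> stalled (at a lesion) / queued (behind one)
```

with first-order rates per minute. Promoter residence is
`1/(k_escape + k_pre_release + k_pdeg_uv)` (< 1 min by default), elongating
residence is `tau_elong` (25 min). UV creates a lesion pool (75% CPD / 25%
6-4PP); elongating Pol II encounters lesions at rate `k_stall` per lesion.
Genotype decides the stalled branch: repair (`k_repair`, TC-NER proficient),
degradation (`k_degrade_stalled`, UVSS-type), release (`k_release_stalled`,
XPA-type) or nothing (CS-type). GG-NER (`k_ggner`, slow for CPDs, fast for
6-4PPs) removes only lesions not shielded by a stalled polymerase. Timed
perturbations (UV, Illudin S, THZ1, cycloheximide, proteasome/VCP
inhibitors, DDB2 overexpression) switch rates piecewise.

The central FRAP statistic is the immobile fraction

```
F_imm = 1 - (I_recovery,UV - I_bleach,UV) / (<I_recovery,untreated> - I_bleach,UV)
```

computed on relative fluorescence intensity (RFI, pre-bleach mean = 100),
with recovery windows of post-bleach frames 250–450 (GFP-RPB1 protocol:
25 + 450 frames at 0.4 s) or 24–33 (CSB-mScarletI: 5 + 40 frames).

## Worked example

The residence-time experiment: UV (4 J/m²) at t = 0, block of *de novo*
initiation (THZ1) at 30 min, strip-FRAP at 2 h — first deterministic, then
as a synthetic per-cell experiment pushed through the analysis pipeline.

```python
from polfate import assay_sim, frap_analysis
from polfate.kinetics import (Event, PerturbationSchedule, build_rate_set,
                              propagate_mean_field, stalled_fraction)

uv_thz1 = PerturbationSchedule((Event(0.0, "UV_DOSE", 4.0),
                                Event(30.0, "THZ1_ON")))
traj = propagate_mean_field(build_rate_set("CSA_KO", uv_thz1),
                            n0=50_000, horizon=120.0)
print(f"stalled Pol II at 2 h: {traj.counts['stalled'][-1]:.0f} of 50,000 "
      f"({100*stalled_fraction(traj, 120.0, include_queued=True):.1f}% immobile)")

traces = assay_sim.generate_frap_experiment(["CSA_KO", "WT"], n_cells=8,
                                            master_seed=1)
result = frap_analysis.analyze_experiment(traces)
for s in result["summaries"]:
    if not s.get("is_control"):
        print(f"{s['genotype']:7s} {s['treatment']}: F_imm = "
              f"{s['mean_f_imm']:.3f} +/- {s['sem_f_imm']:.3f} (n = {s['n_f_imm']})")
```

prints

```
stalled Pol II at 2 h: 5383 of 50,000 (15.2% immobile incl. queued)
CSA_KO  UV+THZ1: F_imm = 0.153 +/- 0.003 (n = 8)
WT      UV+THZ1: F_imm = 0.009 +/- 0.003 (n = 8)
```

In the CS genotype ~5,400 of 50,000 polymerases are still lesion-bound two
hours after damage and the FRAP estimator reads the 15% immobile fraction
back out; in wild type the stalled pool has been resolved by repair and
F_imm is indistinguishable from zero.

The same workflows are scriptable from the shell:

```bash
polfate preset residence-time --seed 1 --out out/residence
polfate frap analyze --traces out/residence/frap_traces.csv \
    --tag gfp-rpb1 --controls mock+THZ1 --out out/frap
polfate fixtures --size small --out fixtures/
```

## Layout

```
src/polfate/kinetics.py       state-graph model, mean-field + stochastic engines
src/polfate/assay_sim.py      synthetic FRAP / flow / fractionation / EU /
                              survival / co-culture generators
src/polfate/frap_analysis.py  background correction, RFI, F_imm, summaries
src/polfate/readouts.py       population-level normalizations and statistics
src/polfate/cli.py            scenario configs, presets, fixtures, CLI
docs/methods.md               model assumptions, calibration and limitations
```
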