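# motionerp

**Visuomotor reaction ERP analysis with a ground-truth synthetic recording
generator.**

When an athlete reacts to the onset of visual motion, the button press
arrives some 230–260 ms after the stimulus — and most of that time is
neural, not muscular. This package implements the full analysis chain used
to decompose that interval in motion-onset visual evoked potential (VEP)
experiments: from continuous 63-channel EEG + EOG + EMG recordings at
1000 Hz to

- **cortical component latencies/amplitudes** — N1 and N2 over the visual
  motion-sensitive area MT (electrode pool PO7, P7, P5, PO8, P8, P6), the
  response-locked N2-r (most negative peak within ±50 ms of EMG onset), and
  the BA6 positivity/negativity over the pre-/supplementary motor cortex
  (FC1/FCz/FC2 plus probability-weighted neighbors);
- **behavioral measures** — EMG onset (rectified, 50 Hz low-passed, 25 ms
  moving-averaged signal crossing baseline mean + 3 SD), visuomotor
  reaction time (VMRT = button press − stimulus onset) and motor time
  (VMRT − EMG onset);
- **group statistics** — paired t-tests with Cohen's d (= t/√n) and
  Benjamini–Hochberg FDR, Pearson screening, collinearity checks
  (tolerance < 0.4 ⇔ VIF > 2.5), stepwise forward regression with
  Breusch–Pagan / Durbin–Watson / Lilliefors-KS diagnostics, and adjusted
  R² = 1 − (1−R²)(n−1)/(n−k−1).

Preprocessing covers 0.3–35 Hz zero-phase filtering, −500..1000 ms
epoching with −500..0 ms baseline, blink flagging (EOG, −500..200 ms),
artifact rejection (steps > 50 µV/ms or |amplitude| > 150 µV in
−500..500 ms), bad-channel spherical-spline interpolation, and a
spherical-spline current source density transform (m = 4, 10 Legendre
terms, λ = 1e−5) with closed-form behavior on spherical harmonics.

Because raw recordings from such studies are rarely shareable, the package
ships a first-class synthetic generator (`motionerp.synth`) that emulates
the protocol — 80 trials per motion-velocity condition, ISIs uniform on
2–6 s, raised-cosine ERP templates on realistic scalp patterns, an EMG
burst model, blink/artifact injection, and a cohort-level linear coupling
between N2/N2-r latencies and EMG onset — while recording exact ground
truth for every drawn value. Every pipeline stage is verified against that
truth. See `docs/methods.md` for the model details and their limits.

## Worked example

```python
from motionerp import (CohortSpec, PipelineConfig, generate_cohort,
                       run_subject, run_cohort)

cohort = generate_cohort(CohortSpec(n_subjects=10, master_seed=5))
cfg = PipelineConfig()
cfg.csd.bypass = True          # sensor-space run (truth is sensor-level)

results = []
for i, (recording, truth) in enumerate(cohort.iter_recordings()):
    res = run_subject(recording, cfg)
    res.subject_id = cohort.subjects[i].subject_id
    results.append(res)

stats = run_cohort(results, cfg)
print(stats.paired_tests[["parameter", "t", "p_fdr", "d"]].head(3))
reg = stats.regressions[("emg_onset", "slow")]
print(reg.predictors, round(reg.r2_adjusted, 3))
```

which prints

```
    parameter         t     p_fdr         d
0   emg_onset -6.751965  0.000362 -2.135159
1        vmrt -7.396665  0.000362 -2.339031
2  motor_time  0.079233  0.938581  0.025056
['N2r_latency'] 0.482
```

Read: with 10 synthetic subjects, EMG onset and VMRT are significantly
earlier in the fast motion condition (negative t, FDR-adjusted p < 0.001,
large effects d ≈ −2) while motor time does not differ — the speed-up is
perceptual/cortical, not muscular. In the regression, only the stronger
predictor (the response-locked N2-r latency) survives Pearson screening at
this small n and alone explains ~48 % of the between-subject variance in
EMG onset; at the protocol's full n = 37 the stepwise model recovers both
N2 and N2-r (see the acceptance run below).

The same pipeline is scriptable from the shell:

```bash
motionerp simulate --seed 4 --subjects 3 --outdir sim/
motionerp run-subject sim/S01.vhdr --csd-bypass --outdir out/S01
motionerp run-cohort sim/S0*.vhdr --csd-bypass --outdir out/group
motionerp report out/group/stats.json
```

Recordings are written/read as BrainVision triplets (.vhdr/.eeg/.vmrk,
multiplexed IEEE float32); trial tables, component tables, and rejection
reports as TSV; group stats as JSON.

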