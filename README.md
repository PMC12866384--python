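# pyp-dynaquant

Quantitative analysis of dynamic [99mTc]Tc-pyrophosphate (99mTc-PYP)
SPECT/CT for transthyretin amyloid cardiomyopathy (ATTR-CM), driven by a
synthetic 4-D thorax-phantom cohort generator.

99mTc-PYP is a bone-avid tracer that accumulates in amyloid-infiltrated
myocardium. Clinical protocols image 2-3 h after injection so that blood
pool clears and bone uptake stabilizes for visual grading — but myocardial
uptake actually peaks within minutes. This package implements the
quantitative machinery needed to study early imaging: absolute calibration
of count-rate images, VOI statistics over myocardium (LV_myo), left-atrial
blood pool (LA_bp) and lower thoracic spine (LS), standardized uptake values
and percent injected dose per milliliter, time-activity curves, synthetic
static images time-averaged from dynamic frames, blood-pool subtraction,
and rule-based classification. Because no patient images are public, a
first-class synthetic-data module generates cohorts (8 ATTR-CM + 11
non-ATTR-CM by default) whose group kinetics match published group-mean
SUVs, with log-normal inter-subject variability matched to the published
SDs, Poisson count noise, and optional Gaussian resolution blur.

Core quantities, for a VOI with decay-corrected activity concentration C
(Bq/mL), net injected activity ID (Bq, residual-corrected and referenced to
the assay time), and body weight W (kg):

    SUV      = C x (1000 W) / ID                      [g/mL]
    %ID/mL   = 100 x SUVmean(LV_myo) / (1000 W)       [percent per mL]
    ratios   = SUVmean(LV_myo)/SUVmean(LS),  SUVmean(LV_myo)/SUVmean(LA_bp)
    C_corr   = C x 2^((t - t_ref)/T_half),  T_half(99mTc) = 360.4 min

Classification rules: *blood-pool grade* — positive iff myocardial SUVmean
is greater than or equal to blood-pool SUVmean on the same image; *%ID/mL
rule* — positive iff myocardial %ID/mL >= 0.003%.

See `docs/methods.md` for the model, its assumptions, and its limits.

## Worked example

```python
import pyp_dynaquant as pq

report = pq.run_pipeline(pq.RunConfig(seed=0))   # 8 ATTR + 11 non-ATTR
s = report.group_summary
print(s[(s.metric == "suv_mean") & (s.window == "10-25min")]
      [["group", "voi", "n", "mean", "sd"]].round(2).to_string(index=False))
```

prints the group-mean SUVmean over the earliest (10-25 min) window:

```
   group    voi  n  mean   sd
    ATTR  LA_bp  8  2.97 0.33
    ATTR     LS  8  1.83 0.13
    ATTR LV_myo  8  3.86 0.53
non-ATTR  LA_bp 11  2.99 0.60
non-ATTR     LS 11  1.97 0.61
non-ATTR LV_myo 11  1.26 0.42
```

Already at 10-25 min, simulated ATTR-CM myocardium (3.86 g/mL) runs above
its blood pool (2.97) while non-ATTR myocardium (1.26) sits well below its
blood pool (2.99) — the early-imaging separation the quantitation is built
to measure. Classifying every subject with the blood-pool grade at this
window and scoring against the generator's group labels:

```python
perf = report.performance
print(perf[perf.rule == "blood_pool_grade"]
      [["window", "sensitivity", "specificity", "accuracy"]]
      .to_string(index=False))
```

```
    window  sensitivity  specificity  accuracy
  10-25min        100.0        100.0     100.0
  30-45min        100.0        100.0     100.0
  45-60min        100.0        100.0     100.0
 90-105min        100.0        100.0     100.0
150-165min        100.0        100.0     100.0
```

The %ID/mL metric separates the groups without overlap at the same window
(ATTR range 0.0037-0.0092%, non-ATTR 0.0008-0.0028%, threshold 0.003%).
With an output directory configured (`RunConfig(output_dir=...)` or the
`pyp-dynaquant run --out DIR` CLI), the pipeline writes tidy CSV tables
(quantitation, group summaries, diagnoses, performance, TACs), the
calibration factor, and figures regenerated from the tables.

## Command line

```sh
pyp-dynaquant run --config run.yaml --seed 0 --out results/
pyp-dynaquant simulate --seed 0 --out cohort/          # NIfTI + sidecars
pyp-dynaquant calibrate --activity-mbq 100 --volume-ml 5000 --out cf.json
pyp-dynaquant segment|quantify|diagnose ...            # file-based stages
```

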