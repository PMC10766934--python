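# volumetrix

Threshold-based thyroid volumetry on quantitative SPECT/CT, rebuilt as a
digital experiment.

Radioiodine dosimetry for Graves' hyperthyroidism (GH) needs an accurate
thyroid volume. Planar scintigraphy estimates it with the Allen formula
`V = S·L·K` (frontal projected area S, mean lobe length L, K ≈ 0.32) and is
known to overestimate; quantitative SPECT/CT instead delineates an
iso-contour VOI — every voxel at least a fraction *f* of the maximum uptake —
whose volume depends strongly on *f* through the partial volume effect.
`volumetrix` reproduces the phantom-and-cohort study that asks which *f*
recovers the true volume: it builds a voxelized butterfly phantom (two
Pappus-calibrated 45° torus-sector lobes, 53 mL bilateral, in a 10,122 mL
tank), emulates planar and tomographic acquisitions (Gaussian PSF + Poisson
counting noise in place of projection/OSEM), sweeps thresholds
20–60% at target-to-background ratios 200/600/1000, and compares ultrasound
(`V = π/6·(L1·W1·T1 + L2·W2·T2)`), planar and SPECT volumetry on a synthetic
40-patient GH cohort with ANOVA/LSD, Pearson/regression and Bland–Altman
statistics.

Intended users: nuclear-medicine physicists and methods researchers who want
a controllable, fully seeded testbed for threshold-segmentation behavior —
not a clinical tool.

## Worked example

```python
from volumetrix import ExperimentConfig, run_phantom_experiment

result = run_phantom_experiment(ExperimentConfig(seed=1))
print(result.planar_table[["tb_ratio", "replicate", "S_cm2", "L_cm", "V_ml"]].head(3))
print(result.volume_summary.pivot(index="tb_ratio", columns="threshold",
                                  values="volume_mean").round(2))
print("optimal threshold:", result.optimal_threshold)
```

prints (seed 1):

```
   tb_ratio  replicate  S_cm2  L_cm   V_ml
0     200.0          0  32.20  6.15  63.37
1     200.0          1  32.67  6.15  64.29
2     200.0          2  32.56  6.10  63.56

threshold   0.20   0.25   0.30   0.40  0.50  0.60
tb_ratio
200.0      47.46  36.36  24.64  10.39  3.39  0.10
600.0      47.20  33.22  24.46  11.72  3.28  0.17
1000.0     47.24  36.25  24.54  10.34  4.69  0.14

optimal threshold: 0.2
```

Reading this: every planar Allen volume (`V_ml`) exceeds the true 53 mL —
the overestimation planar scintigraphy is known for — while the measured
lobe length L ≈ 6.1 cm matches what operators measure on the physical part.
The tomographic VOI volume falls monotonically with the threshold fraction
and is nearly identical across the three rows (T/B has no effect); with
counting noise the volume-matching threshold lands in the low-fraction band
(here 20%, with 25–30% close behind), the regime in which the physical study
identified 25% as optimal. A noiseless run
(`ExperimentConfig(noisy=False)`) shifts the optimum up to ~40%, isolating
the noisy-maximum order-statistic bias as the mechanism.

The cohort arm:

```python
from volumetrix import run_cohort_experiment
res = run_cohort_experiment(ExperimentConfig(seed=1))
print(res.correlation_table.round(3))
```

```
    method   reference      r      b
0  spect25  ultrasound  0.960  0.968
1   planar  ultrasound  0.669  1.248
```

— the iso-contour SPECT channel tracks ultrasound far more tightly than the
noisy, biased planar channel, matching the published agreement ordering.

There is also a CLI: `volumetrix phantom run`, `volumetrix cohort run`,
`volumetrix tomo-sweep --image vol.nii.gz --true-volume 53`, and
`volumetrix verify-paper`, which recomputes every closed-form quantity of
the study (dilution arithmetic, volume errors, mean errors, formula
examples) and checks them against their printed values.

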