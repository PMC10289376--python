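# neurocurve

Curvature morphometry of traced 3D neuron skeletons, with case-control
cohort statistics and a fully synthetic cohort generator.

## The problem

Post-mortem nano-tomography of Golgi-stained cortical tissue yields 3D
images of single neurons that are hand-traced into skeleton models:
ordered chains of nodes, each with a coordinate (μm) and a local
half-thickness (radius, μm), grouped into unbranched neurite segments.
The scientific questions asked of such data are distributional: how
tortuous are the neurites of each subject, how does the spread of
tortuosity change with age, does a disease group differ from controls,
and does tissue structure track symptom severity?

`neurocurve` implements that analysis chain for anyone with traced
skeletons (or nobody's data at all — see the simulator):

1. **I/O** — a fixed-column PDB-dialect coordinate format (one chain per
   trace, radius in the occupancy column, coordinates read directly as
   μm) and standard SWC, with strict validation and lossless
   round-trips.
2. **Geometry** — discrete curvature along each neurite. Curvature is
   the reciprocal of the local curve radius, estimated by the Menger
   construction: for consecutive resampled points *p₁p₂p₃*,

   κ = 1/R = 4·Area(p₁p₂p₃) / (|p₁p₂|·|p₂p₃|·|p₃p₁|),

   after resampling each trace to a uniform 1 μm arc-length step. The
   per-neurite summary is the arc-length-weighted mean of the point
   curvatures (units μm⁻¹); the per-neurite radius is the weighted mean
   node radius.
3. **Cohort statistics** — per-case aggregation (mean, SD, median, max
   of per-neurite curvature; mean radius), two-sided Welch *t*-tests
   between groups at the case level, Shapiro–Wilk normality checks,
   Pearson/OLS regressions (curvature SD vs age in controls, mean
   curvature vs hallucination score, mean curvature vs antipsychotic
   dose), and relative-frequency curvature histograms in 0.1 μm⁻¹ bins
   with the mass beyond 0.8 μm⁻¹ reported separately.
4. **Synthetic cohorts** — neurites simulated as worm-like chains whose
   persistence length is set from a target curvature via
   E[κ] = √(π / (2·h·Lp)), with an age-declining curvature SD in
   controls, multiplicative disease effects on curvature and radius, a
   long-tail mixture component, and a noisy monotone symptom link.

## Worked example

```
$ neurocurve simulate --seed 11 --out democohort
INFO neurocurve: wrote 16 model files to democohort/models
$ neurocurve measure --models democohort/models --out democohort/morphometry.csv
INFO neurocurve: measured 3200 neurites (0 excluded) from 16 datasets
$ neurocurve analyze --morphometry democohort/morphometry.csv \
      --cohort democohort/cohort.csv --out democohort/report
INFO neurocurve: report written to democohort/report (8 statistical tests)
```

The morphometry table has one row per neurite:

```
dataset_id trace_id  trace_length_um  neurite_curvature_um-1  neurite_radius_um  n_points  excluded_flag
       N1A    T0000        27.998703                0.396016           0.640015        30          False
       N1A    T0001        58.997291                0.330731           0.613482        61          False
```

and `report/summary.json` holds the cohort-level results. For this seed:
group case-mean curvature 0.530 μm⁻¹ (schizophrenia) vs 0.365 μm⁻¹
(control), Welch *t* = 8.02, df = 8.6, *p* = 2.9 × 10⁻⁵; curvature SD
vs age in controls *r* = −0.81, *p* = 0.015; mean curvature vs
hallucination score *r* = 0.81, *p* = 1.7 × 10⁻⁴. The disease group's
higher, broader, longer-tailed curvature distribution and the aging and
symptom correlations are exactly the structure the generator builds in,
so the numbers demonstrate that the measurement + statistics chain
recovers them at realistic cohort sizes (8 cases per group).

The same `measure`/`analyze` stages run unchanged on real traced
skeletons; `measure` never reads clinical metadata, so model
measurement stays blind to case identity.

As a library:

```python
from neurocurve import (SyntheticCohortSpec, generate_cohort,
                        model_morphometry, morphometry_frame,
                        run_cohort_analysis)

spec = SyntheticCohortSpec(seed=11)
models, records, truth = generate_cohort(spec)
frame = morphometry_frame([model_morphometry(m) for m in models])
report = run_cohort_analysis(frame, records)
print(report.group_means["schizophrenia"]["mean_curvature_case_mean"])
```

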