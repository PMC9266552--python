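# axondd — axon diameter distribution analysis

`axondd` analyzes the distribution of axon calibers (the **ADD**, axon
diameter distribution) within a white-matter tract, as measured by
fluorescence or electron-microscopy morphometry. It was built for studies of
traumatic axonal injury in the mouse corticospinal tract — where injury first
removes ~30% of axons with a bias towards large calibers, and later remodels
the surviving population — but applies to any per-axon diameter table with
animal and group annotations.

Axon calibers are strongly right-skewed and well described by a lognormal
law, `ln d ~ N(μ, σ²)`. The package's core quantities are the lognormal
shape features

- geometric mean `GM = e^μ` (equals the median diameter),
- geometric standard deviation `GSD = e^σ`,
- skewness `(ω + 2)·√(ω − 1)` with `ω = e^{σ²}`,
- mode `e^{μ − σ²}` and percentiles `e^{μ + σ·z_p}`,

together with the analyses built on them:

- **Fitting** — maximum likelihood on raw diameters, or least squares on
  0.1 μm-binned relative frequencies; lognormal-vs-normal likelihood ratio.
- **Inference** — leave-one-animal-out jackknife CIs; permutation
  distributions of the one-way F, pooled t and two-way (Freedman–Lane) F;
  Spearman rank correlation.
- **Remodeling** — survival-adjusted frequency curves (curve area = total
  axon survival), per-bin surviving fractions against a sham reference, and
  rank (percentile) frequency curves that separate redistribution from
  overall shrinkage.
- **Discrimination** — ROC/AUC of per-animal GM/GSD (Mann–Whitney AUC,
  DeLong CI, permutation p) and the MR effective axon radius
  `r_eff = (⟨r⁶⟩/⟨r²⟩)^{1/4} = exp(μ_r + 4σ²)`.
- **Morphometry** — maximum Feret (caliper) diameter of labeled 2-D profiles
  via convex hull + rotating calipers, plus a synthetic ellipse mask
  generator.
- **Synthetic cohorts** — a hierarchical lognormal generator with calibrated
  thinning-and-atrophy injury presets, so every stage is testable without
  microscopy data.

## Worked example

Simulate a study at the default conditions (sham GM 0.69 μm / GSD 2.10,
n = 7; day 7 GM 0.65 / 2.03, n = 7; day 21 GM 0.51 / 1.97, n = 6; 30% axon
loss after injury) and run the full pipeline:

```python
from axondd import simulate_study, run_pipeline, RunConfig

cohort = simulate_study(seed=1)                     # animal_id, group, apnea, diameter_um
report = run_pipeline(cohort, RunConfig(n_perms=2000, seed=1))

for g in report["group_order"]:
    f = report["groups"][g]["features"]
    jk = report["groups"][g]["jackknife"]["gm"]
    print(f"{g:6s} GM {f['gm']:.2f} ({jk['ci_lo']:.2f}-{jk['ci_hi']:.2f})  "
          f"GSD {f['gsd']:.2f}  skew {f['skewness']:.2f}  P90 {f['p90']:.2f}")
```

```
sham   GM 0.68 (0.61-0.76)  GSD 2.14  skew 3.33  P90 1.80
day7   GM 0.70 (0.63-0.78)  GSD 2.07  skew 3.08  P90 1.78
day21  GM 0.49 (0.44-0.55)  GSD 1.99  skew 2.81  P90 1.18
```

Each line is a group's pooled lognormal fit: the point GM with its jackknife
95% CI, the spread (GSD), and the derived tail features. The same report
carries the comparative statistics — for this cohort the permutation ANOVA
on per-animal GM gives F = 10.7, p = 0.002; sham vs day 21 t = 4.1,
p = 0.003; the day-21 AUC is 0.98 for GM; and the effective-radius
projection falls by 52% — i.e. the late-injury signature (smaller, less
dispersed calibers that nonetheless preserve their rank structure, with peak
rank frequencies at the ~22nd–25th percentile) is recovered from synthetic
data end to end.

The same pipeline runs from the shell:

```sh
axondd simulate --preset fitted --seed 1 --out cohort.csv
axondd report --cohort cohort.csv --seed 1 --out results/
```

writing `report.json`, per-group CSV curves and PNG figures. Masks can be
measured with `axondd measure --mask mask.tif --pixel-size 0.05 --out feret.csv`.

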