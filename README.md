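# occlureg

Simulated accuracy evaluation of reference-point registration for the 3D
reconstruction of the intercuspal jaw relation of dental models.

## The problem

Digital workflows need the maxillary and mandibular casts expressed in one
coordinate frame that reproduces their occlusal (intercuspal) relation. One
way to recover that relation from separate optical scans is a pair of
articulator mounting plates carrying machined hemispherical concaves: the
best-fit center of each concave is a labelled landmark, a contact coordinate
measuring arm provides reference ("standard") landmark positions in the
articulator frame, and each jaw's scan is rigidly registered onto the
standard using a subset of the landmarks. The open design question is which
subset: how many reference points, and where on the plate, give the most
accurate reconstruction?

`occlureg` answers this in silico. It simulates the whole measurement chain —
plate geometry, contact probing with repeat averaging, optical scanning of
each concave surface in an arbitrary scanner pose, least-squares sphere
fitting, equal-weight rigid (Kabsch) alignment per reference-point group —
and scores each of seven candidate groups by the trueness and precision of
the *held-out* inter-jaw pair distances, with ANOVA/Tukey comparisons across
groups and intraclass-correlation reliability across two simulated operators.

## The model in brief

* 9 + 9 concaves (6 mm diameter) on paired plates, named with FDI-style
  tokens; nine vertical pairs `11–41, 12–42, …, 24–34`.
* Contact probe: landmark = mean of 3 draws of N(c, σ_c² I), σ_c = 0.024 mm.
* Scan: per concave, 300 surface samples on a 75° spherical cap with
  N(0, σ_s² I) noise, σ_s = 0.059 mm, in a random rigid pose per
  (jaw, operator, repetition); sphere center fitted by algebraic
  initialization + Levenberg–Marquardt refinement of Σ(‖pᵢ−c‖−r)², with
  3 replicate fits averaged.
* Registration: for group g with reference ids I, the Kabsch solution of
  argmin_{R,t} Σ_{i∈I} ‖R sᵢ + t − stdᵢ‖², per jaw, det(R)=+1 enforced.
* Accuracy, following ISO 5725-1: per unit, trueness RMSE
  √(mean over held-out pairs of (D_M − D_R)²); per (operator, group),
  per-repetition precision RMSE about the per-pair repetition means.
* Design: 7 groups × 15 repetitions × 2 operators = 210 units.

## Worked example

```python
from occlureg import SimulationConfig, run_experiment

report = run_experiment(SimulationConfig(seed=1))
for g, a in sorted(report.accuracy.items()):
    print(f"group {g}: trueness {a.trueness_mean:.3f} ± {a.trueness_sd:.3f} mm, "
          f"precision {a.precision_mean:.3f} ± {a.precision_sd:.3f} mm")
s = report.stats
print(f"trueness ANOVA: F({s.anova_trueness.df_between},{s.anova_trueness.df_within})"
      f" = {s.anova_trueness.F:.1f}, p = {s.anova_trueness.p:.3g}")
print(f"Tukey p (group 4 vs 7): {s.tukey_trueness.p(4, 7):.3g}")
```

prints

```
group 1: trueness 0.017 ± 0.003 mm, precision 0.008 ± 0.002 mm
group 2: trueness 0.015 ± 0.003 mm, precision 0.009 ± 0.002 mm
group 3: trueness 0.029 ± 0.011 mm, precision 0.018 ± 0.009 mm
group 4: trueness 0.012 ± 0.003 mm, precision 0.008 ± 0.003 mm
group 5: trueness 0.018 ± 0.003 mm, precision 0.007 ± 0.002 mm
group 6: trueness 0.016 ± 0.004 mm, precision 0.009 ± 0.003 mm
group 7: trueness 0.026 ± 0.011 mm, precision 0.016 ± 0.011 mm
trueness ANOVA: F(6,203) = 27.7, p = 4.48e-24
Tukey p (group 4 vs 7): 1.07e-13
```

Lower RMSE is better. The widely spread four-pair group 4 reconstructs the
jaw relation most truly, while the front-concentrated groups 3 and 7 are the
worst of their size classes — registration error at landmarks far from the
reference cluster is amplified by leverage, so accuracy increases with the
homogeneity of the reference-point distribution. The same pipeline is
available from the shell:

```
occlureg run --seed 1 --out results/
```

which writes `records.csv`, `summary.csv`, `anova.csv`, `tukey.csv`,
`icc_intra.csv`, `icc_inter.csv` and a provenance `report.json`.

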