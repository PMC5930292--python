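# folscan

**Which follicle sizes on the day of trigger yield mature oocytes?**

In IVF, ovarian stimulation is stopped by a "trigger" injection (hCG,
GnRH agonist, or kisspeptin) once two to three lead follicles reach
17–18 mm. Follicles that are too small on that morning are unlikely to
release a mature (MII) oocyte at retrieval; follicles that are too large
tend to contain post-mature oocytes. `folscan` is a reusable pipeline
for discovering, from per-patient trigger-day follicle diameter profiles
and outcome counts, the diameter window that contributes most to the
number of oocytes and mature oocytes retrieved — the analysis behind the
clinical recommendation to report *oocyte yield* with a 12–19 mm
denominator.

It is written for reproductive-medicine statisticians and methodologists
who want the full analysis chain as tested, seedable code, together with
a synthetic cohort generator with known ground truth for validating each
stage.

## The analysis

A patient's trigger-day scan is summarised as counts $c_d$ of follicles
per integer diameter bin $d \in \{8,\dots,25\}$ mm (below 8 mm is not
aspirated; above 25 mm is pooled). For an outcome count $y$ (oocytes,
mature oocytes, zygotes, embryos, grade-1 embryos) the pipeline runs:

1. **Window scan** — for every contiguous window $[lo, hi]$ (171 in
   all), simple least squares of $y$ on the window count
   $\sum_{d=lo}^{hi} c_d$; report the window maximising the coefficient
   of determination $r^2$.
2. **Per-diameter regression** — one multi-predictor model
   $\mathbb{E}[y] = \beta_0 + \sum_d \beta_d c_d$ (Gaussian identity by
   default, Poisson log optional), which avoids the overlap
   autocorrelation of single-window fits and gives per-diameter
   significance (starred like the clinical tables: \* p<0.05,
   \*\* p<0.01, \*\*\* p<0.0001).
3. **Regression forest** — a from-scratch CART bootstrap forest
   (default 5,000 trees, `mtry` 6, minimum leaf 5) whose per-diameter
   *model importance factor* is the total SSE decrease from splits on
   that diameter averaged over trees; out-of-bag permutation importance
   is the built-in cross-check.
4. **Proportion contrasts** — median/tertile splits on the proportion
   of a patient's follicles inside the window, compared with
   Kruskal–Wallis and Dunn's post hoc test, plus a confounder check on
   total follicle number.
5. **Counterfactual simulation** — predicted oocyte counts for
   simulated patients with 20 follicles entirely inside vs entirely
   outside the window, isolating the effect of the size *profile* from
   the effect of follicle *number*.

The synthetic generator emulates the clinical conditioning: per-patient
diameters are drawn from a skew-normal with patient-specific spread and
rigidly shifted so the n-th largest follicle sits at the lead threshold
("the scan taken the morning the trigger rule fired"), and outcomes
follow a known diameter-dependent yield curve with nested Bernoulli
thinning (oocyte → mature → zygote → embryo → grade 1).

## Worked example

```python
import folscan as fs

cfg = fs.preset("hcg_like", n_patients=400, seed=7,
                yield_curve=fs.YieldCurve("step", 12, 19, 0.8, 0.1))
cohort, truth = fs.generate_cohort(cfg)

scan = fs.scan_windows(cohort, "mature")
print(f"best window: {scan.best_window} (r2={scan.best_fit.r2:.3f}, "
      f"p={scan.best_fit.p_slope:.1e})")

glm = fs.fit_diameter_glm(cohort, "mature")
print(f"GLM r2={glm.r2_model:.3f}; significant diameters: {glm.significant()}")

forest = fs.fit_forest_cohort(cohort, "mature", n_trees=200, seed=7)
imp = fs.importance(forest)
print("top importance factors:",
      ", ".join(f"{d} mm ({v:.0f})" for d, v in imp.ranked()[:4]))

con = fs.contrast_report(cohort, fs.Window(12, 19), k=3)
print(f"tertile delta (mature): {con.delta_top_bottom['mature']:+.2f}, "
      f"KW p={con.kw['mature'][2]:.1e}")

comp = fs.compare_scenarios(
    forest,
    fs.ScenarioSpec("all_in_window", fs.Window(12, 19), 1000, 20, seed=8),
    fs.ScenarioSpec("all_out_window", fs.Window(12, 19), 1000, 20, seed=9),
)
print(f"simulated 20-follicle patients: all-in {comp.a.mean_pred:.1f} "
      f"(95% limits {comp.a.pred_limits[0]:.1f}-{comp.a.pred_limits[1]:.1f}) vs "
      f"all-out {comp.b.mean_pred:.1f} "
      f"(95% limits {comp.b.pred_limits[0]:.1f}-{comp.b.pred_limits[1]:.1f}), "
      f"p={comp.p:.1e}")
```

prints:

```
best window: 12-20 (r2=0.670, p=6.1e-98)
GLM r2=0.680; significant diameters: [12, 13, 14, 15, 16, 17, 18, 19]
top importance factors: 15 mm (652), 16 mm (583), 14 mm (356), 17 mm (223)
tertile delta (mature): +1.15, KW p=3.1e-05
simulated 20-follicle patients: all-in 8.9 (95% limits 7.1-10.5) vs all-out 4.0 (95% limits 3.7-4.2), p=0.0e+00
```

The generator planted a step yield curve on 12–19 mm (80% per-follicle
oocyte probability inside, 10% outside). Every stage points back at it:
the scan's best window covers it (one bin of slack at the upper edge is
common — bins 20–21 are rare, so adding them costs little variance),
the multi-predictor regression flags exactly 12–19 mm, the forest puts
its largest importance factors inside the window, the top tertile of
patients by proportion-in-window retrieves about one more mature oocyte
than the bottom tertile, and simulated patients whose 20 follicles all
sit in-window are predicted more than twice the oocytes of patients
with none in-window.

## Command line

```bash
folscan generate --preset hcg_like --n-patients 400 --seed 7 --out cohort.csv
folscan scan --cohort cohort.csv --outcome mature
folscan glm --cohort cohort.csv --outcome mature
folscan forest --cohort cohort.csv --outcome mature --n-trees 5000 --seed 7 --model-out forest.json
folscan contrast --cohort cohort.csv --window 12:19 --k 3
folscan counterfactual --forest forest.json --window 12:19 --seed 7
folscan run --config pipeline.yaml     # all stages + JSON/Markdown report
```

Cohorts are plain CSV (`patient_id,trigger,d8,...,d25,n_oocytes,
n_mature,n_zygotes,n_embryos,n_grade1`, one row per cycle); a long
layout (`patient_id,diameter_mm`) of raw diameters is also accepted.

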