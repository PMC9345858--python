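# tcellprox

Spatial tumour cell / T cell co-localisation scoring for tissue-microarray
single-cell data, with survival analysis.

High T cell density in a tumour is a well-established favourable prognostic
factor in colorectal and other solid cancers, but density alone ignores
*where* the T cells sit relative to the tumour cells.  `tcellprox`
implements a spatial point-pattern alternative: for each TMA core it
estimates the cross-type nearest-neighbour distance distribution

```
G_tumour:T cell(r) = P(a typical tumour cell has ≥ 1 T cell within radius r)
```

from the per-tumour-cell distances to the nearest T cell centroid, using
the Kaplan–Meier product-limit estimator on distances right-censored at
the observation-window boundary (the standard edge correction).  The
value at r = 20 µm — T cells close enough for direct cell–cell
interaction — is computed for the four components CD3/CD8 × tumour
centre/invasive margin, converted to cohort percentiles, and averaged
into a **T cell proximity score** (0–100), categorised low (0–25],
intermediate (25–70] or high (70–100].  The analogous **T cell density
score** built from cell densities (cells/mm², Immunoscore-style) is
computed alongside.  A survival module quantifies the association of
scores and categories with cancer-specific and overall survival
(Kaplan–Meier/log-rank, Cox models with ordinal trend tests, subgroup and
interaction analyses), and a synthetic-data module generates TMA-like
cohorts with known co-localisation ground truth so every stage is
verifiable without access to patient data.

Intended users: computational pathology and tumour-immunology groups
working with classified single-cell coordinate tables (e.g. QuPath
detection exports).

## Worked example

Generate a synthetic 40-patient cohort whose cancer-death hazard falls by
a factor 0.6 per true co-localisation category, then run the full
pipeline:

```bash
tcellprox generate -o fixture -n 40 --seed 11 --beta -0.51
tcellprox run -i fixture -o run
tcellprox report --scores run/patient_scores.csv
```

The report prints (this exact output for this seed):

```
Patients scored: 40

proximity category:
  LOW               9 ( 22.5%)
  INTERMEDIATE     20 ( 50.0%)
  HIGH             11 ( 27.5%)
...
```

i.e. the percentile thresholds (25/70) split the cohort into roughly
25/45/30% low/intermediate/high, as they must by construction.  The
univariable Cox model in `run/survival_css.csv` shows the generated
protective gradient across proximity categories:

```
variable             level         n  events  hr     ci_low  ci_high
proximity_category   LOW           9  4       1.000
proximity_category   INTERMEDIATE  20 5       0.453  0.121   1.697
proximity_category   HIGH          11 2       0.265  0.048   1.456
```

Hazard ratios below 1 for higher categories reproduce the simulated
effect (HR 0.6 per category step); at n = 40 the confidence intervals are
wide — the test suite repeats this experiment at n = 1000 and requires
the fitted trend coefficient to land within 3 standard errors of the
truth.

The `run/` directory also contains per-core G-curves (`gcurves.csv`),
the per-patient score table with component values, percentiles,
categories, quartiles and combined subgroups (`patient_scores.csv`), the
stored percentile reference distributions for scoring external cohorts
(`reference_*.csv`), the QC exclusion report, Kaplan–Meier curve
coordinates, and the resolved configuration.

Library use mirrors the CLI:

```python
import tcellprox as tp

core = tp.simulate_core(tp.SyntheticCoreParams(seed=1, rho=0.5))
curve = tp.gcross(core, "KM")          # edge-corrected G estimate
curve(20.0)                            # 0.712 for this seed
```

## Layout

```
src/tcellprox/
  cell_io.py         input dialects, windows, QC filtering
  spatial_stats.py   densities, nearest-neighbour distances, G-cross (RAW/KM)
  scoring.py         components, percentiles, scores, categories, quartiles
  survival.py        KM/log-rank, Cox models, trend and interaction tests
  synthetic_data.py  cluster/attachment point processes, linked outcomes
  pipeline.py, cli.py  orchestration and the `tcellprox` command
docs/methods.md      model, assumptions, parameter choices, limitations
```
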