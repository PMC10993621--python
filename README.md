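# microdyn

Quantification of longitudinal microglial dynamics from chronic in vivo
two-photon imaging.

Microglia — the resident immune cells of the brain — tile the cortex in
evenly spaced territories and continuously extend and retract their processes
to survey the parenchyma. Chronic imaging studies follow the same cortical
field in the same animal over weeks (e.g. before and after an insult such as
cranial irradiation) and ask: are cells lost or gained, do the survivors
redistribute or migrate, and do their process dynamics and morphology change?
`microdyn` implements the full measurement pipeline for such studies,
operating on binarized image stacks, plus a synthetic-cohort simulator with
recorded ground truth so that every stage is validated by parameter recovery
rather than by eye.

## What it computes

**Soma distribution and displacement** (wide-field population images, one per
animal per session):

- cell counts and percent change vs. baseline, `100·(N_t/N_0 − 1)`;
- per-soma nearest-neighbor distances (NND) within each timepoint, the cell
  density `ρ = N/A`, and the **spacing index** `(mean NND)²·ρ` — a
  dimensionless regularity measure that equals 1 for grid-like tiling;
- NND and displacement histograms over the bins <10, 10–20, 20–30, 30–40,
  40–50, >50 µm;
- percent of cells **lost and gained** via one-to-one greedy
  nearest-neighbor matching of somas between sessions;
- soma **displacement** as the unconstrained cross-session nearest-neighbor
  distance (a population-level lower bound on movement), with the stable
  fraction (<10 µm).

**Process dynamics** (12-frame hour-long binary time-lapses, 5-min
intervals): per consecutive frame pair, positive pixels are classified as
stable / extension / retraction, giving

- **motility index** = (extended + retracted)/stable, averaged over pairs;
- **coverage** = percent of the field positive at T0;
- **surveillance** = percent positive in the maximum T-projection;
- the ratios motility/coverage and motility/surveillance.

**Single-cell morphology**: soma/process partition, sizes, ImageJ-convention
shape descriptors (circularity `4πA/P²`, aspect ratio, roundness
`4A/(π·major²)`, solidity), and **Sholl analysis** (intersections of the cell
mask with concentric circles around the soma; max, mean, AUC).

**Longitudinal assembly**: everything lands in a tidy long-format cohort
table (animal × group × session × metric) with within-animal percent change
vs. baseline, group mean ± SEM summaries (the animal is the unit of
replication), PCA, Pearson correlation matrices and simple regression.

## Worked example

Simulate a two-group study (6 control + 6 "irradiated" animals, 7 sessions
from Baseline to Week 4; the insult group is programmed to lose 30% of its
cells, drop to 80% coverage, and double its process turnover by Week 4), run
the full analysis, and compare the recovered group effects with the
programmed ground truth:

```python
from microdyn import (default_cohort_groups, simulate_cohort,
                      analyze_cohort, recovery_report)

groups = default_cohort_groups(n_per_group=6, seed=0)
manifest, truth = simulate_cohort("cohort_out", groups)
analysis = analyze_cohort("cohort_out/manifest.csv")
print(recovery_report(analysis, truth, "Week4"))
```

```
                  effect    measured  programmed
0  cell_count_pct_change  -30.000000  -30.000000
1    coverage_pct_change  -19.168991  -19.168991
2    motility_pct_change  110.792481  111.520127
```

Reading: at Week 4 the irradiated group's cell count is down 30% vs. its own
baseline (recovered exactly — simulated somas are well separated, so soma
extraction is exact); measured coverage change matches the rendered target
(the nominal −20% programmed effect lands at −19.2% after accounting for
overlap between neighboring cells' processes); and the measured motility
index rose ~111% against a closed-form target of ~112% (turnover probability
doubled; the motility index is slightly super-linear in turnover because the
stable-pixel denominator shrinks).

The same pipeline runs from the shell:

```bash
microdyn simulate --out cohort_out --seed 0
microdyn cohort --manifest cohort_out/manifest.csv --out table.csv
microdyn report --table table.csv --out figures/
```

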