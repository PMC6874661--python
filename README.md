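# fullcycle

Full annual-cycle, full life-cycle survival analysis for tracked
migratory birds.

Satellite/GPS tracking of long-lived migrants yields *known-fate* data:
for each tagged bird we observe the tagging date, the age at tagging, and
either a death date and location or a censoring date (transmitter failure
or study end).  This package estimates how daily mortality varies across
the four stages of the annual cycle (breeding, southward migration,
African wintering, northward migration) and across four life-cycle
classes (juvenile, young adult, prime, senescent), and propagates those
estimates into an age-structured population model — the workflow of a
full-annual-cycle demographic study of a trans-Saharan raptor.  It is
aimed at movement ecologists and quantitative conservation biologists
working with tracking datasets of tens to a few hundred individuals.

## The method

Each tracking history is decomposed into exposure segments within one
(age class *j*, stage *k*): a bird leaving a stage alive re-enters the
next as a new individual.  Within a combination, every death day closes a
Kaplan–Meier risk interval

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>j,k,t</sub> = (r<sub>j,k,t</sub> − n) / r<sub>j,k,t</sub>,

with `r` the birds at risk and `n` the deaths (intervals with ≤ 5 at risk
are excluded).  Interval survivals are rescaled to daily survivals
dS<sub>t</sub> = S<sub>t</sub><sup>1/Δt</sup>, combined by a geometric
mean (duration-weighted by default; see `docs/methods.md`) with δ-method
variances, and exponentiated to the stage survival
φ<sub>j,k</sub> = dS<sup>l</sup> over the stage duration *l*.
Zero-death combinations are assigned φ = 1 and flagged.

Downstream: annual survival σ<sub>j</sub> = ∏<sub>k</sub> φ<sub>j,k</sub>
enters a pre-breeding-census Leslie matrix over ages 1–28, whose dominant
eigenvalue λ, stable age structure and stage-level sensitivities
∂λ/∂φ<sub>j,k</sub> (and, on the figure-facing scale, sensitivity to
daily mortality) come with bootstrap SEs from 1,000 replicate matrices.
Significance of stage × age effects on death placement is tested by a
control-resampling binomial GLM (one simulated death day per never-dead
bird, likelihood-ratio tests), plus pooled-age χ² frequency tests and
ANOVAs of age- and latitude-at-death.  Death-site clustering per stage is
tested with the Average Nearest Neighbor z-test.  A seeded synthetic
generator produces datasets with exactly this structure, so the whole
chain is testable without any field data.

## Worked example

The analysis is organised as numbered drivers over the `fullcycle`
library; each reads/writes `results/`:

```
python analysis/01_simulate_tracking.py --seed 1
python analysis/02_survival_estimates.py --seed 1
python analysis/03_death_patterns.py    --seed 1
python analysis/04_population_model.py  --seed 1
python analysis/05_spatial_clustering.py --seed 1
```

With seed 1 this prints, among other output:

```
tagged 108 birds: 48 died, 60 censored (failure or study end)

daily mortality x10 (per age class, highest first):
  juvenile: breeding=0.054, southward_migration=0.034, wintering=0.012
  young_adult: southward_migration=0.029, northward_migration=0.009, breeding=0.005, wintering=0.002
  prime: southward_migration=0.021, breeding=0.003, wintering=0.003, northward_migration=0.000
  senescent: southward_migration=0.040, northward_migration=0.022, wintering=0.006, breeding=0.004

  GLM stage: LRT=17.87, df=3, p=0.0005
  chi-square age x stage: chi2=0.82, df=3, p=0.8445

lambda = 0.9536 (elasticity check: 1.000000)
annual survival by class: {'juvenile': 0.281, 'young_adult': 0.827,
                           'prime': 0.862, 'senescent': 0.762}
```

Reading it: about half the synthetic birds die, as in a typical long-term
tagging study of this scale.  Daily mortality (×10 for readability) is
highest on migration in the adult classes — the short journeys are the
riskiest days of the year — while the χ²/GLM outputs test whether death
placement shifts with age.  λ < 1 with these survival draws and the
placeholder natality table indicates decline; the elasticity check
confirms the eigen-analysis.  The sensitivity table written by script 04
shows that per *stage* (duration × per-day impact) the long, safe stages
matter as much for λ as the short, dangerous ones.

Estimates at n = 108 are noisy by design — that is the point of the
synthetic study: rerunning with another seed shows which conclusions are
stable at tracking-study sample sizes.

Library use mirrors the scripts:

```python
import fullcycle as fc
cfg = fc.default_run_config(seed=1)
bundle = fc.run_full(cfg, "results")      # all artifacts + run log
```

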