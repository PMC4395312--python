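# motorpool

Quantification of spinal motor-pool topography from serial-section traces:
serial alignment, cervical-enlargement correction, a covariance-ellipse
**scatter index**, and the cohort statistics of a genotype × housing study —
plus a synthetic-cohort generator so the whole pipeline is testable without
animal data.

## The problem

Motor neurons innervating one muscle group cluster into a *motor pool* in the
ventral horn of the spinal cord. After retrograde labeling (e.g. CTB injected
into dorsal vs ventral forelimb muscles), each animal yields a stack of
coronal sections with traced neuron positions. Two obstacles stand between the
raw traces and a comparable per-animal statistic:

1. sections are mounted with arbitrary rigid offsets, and
2. section diameter varies physiologically along the cervical enlargement.

The pipeline registers every section to the first one by the least-squares
rigid transform on four optical reference points, then measures each
section's hemicord radius as the distance from the central canal to the
intercept of a reference curve (a cubic spline through five lateral-edge
landmarks) with the perpendicular to the mid-sagittal axis through the canal.
The intercept distances are spline-smoothed along the series and each section
is rescaled isotropically about its canal so the smoothed profile is
constant. All neurons of a pool are then projected along the
anterior–posterior axis into one 2-D point cloud.

## The scatter index

For a pooled cloud with sample covariance Σ of the medio-lateral (x) and
dorso-ventral (y) coordinates, with eigenvalues λ₁ ≥ λ₂,

    SI = π · λ₁ · λ₂

the area of the covariance ellipse (eigen*values*, i.e. variances, enter the
product). Directional scattering is reported as sd_ml = √Σ₁₁ and
sd_dv = √Σ₂₂. For an axis-aligned Gaussian pool, E[SI] ≈ π σ_ml² σ_dv².

The statistics layer mirrors a standard cohort report: Shapiro–Wilk-gated
choice between Student's t and Mann–Whitney U (exact for small tie-free
samples), two-way repeated-measures ANOVA with the genotype × time
interaction for longitudinal behavior, OLS for the SI-vs-performance
relation, one-way ANOVA on per-animal perineuronal-net category fractions,
and pairwise t-tests on per-animal mean synapse counts.

## Worked example

```python
import numpy as np
from motorpool import (SimConfig, gen_series, rigid_align,
                       normalize_sections, project_pool, scatter_index)

cfg = SimConfig(seed=0, n_sections=30, neurons_per_pool=60)   # 30% enlargement, rigid jitter
series = gen_series(cfg, animal_seed=42)
pool = project_pool(normalize_sections(rigid_align(series)), "ventral")
res = scatter_index(pool)
truth = series.meta["true_sigma"]["ventral"]
print(f"sd_ml = {res.sd_ml:.4f}  sd_dv = {res.sd_dv:.4f}  SI = {res.si:.6f}")
print(f"true sigma = {truth}")
```

prints

```
sd_ml = 0.1188  sd_dv = 0.1222  SI = 0.000662
true sigma = (0.11, 0.13)
```

i.e. despite a 30% mid-series diameter bump and per-section rigid jitter, the
pipeline recovers the generating directional SDs (0.11, 0.13) up to the
sampling error of a 60-neuron pool (SE ≈ σ/√(2n) ≈ 0.01); the SI lands near
its closed form π·0.11²·0.13² ≈ 6.4·10⁻⁴. The pipeline's own contribution to
the error is far smaller (median < 0.5% over replicate series).

A full run — simulate a two-genotype cohort, align, measure, analyze,
report — is available from the shell:

```bash
motorpool run --seed 1 --out demo_run
cat demo_run/report.txt
```

## Layout

- `motorpool.synth` — synthetic series/cohort generator with published group presets
- `motorpool.geometry` — rigid alignment, reference curve, diameter normalization, A–P projection
- `motorpool.morphometry` — covariance ellipse, SI, directional scatter
- `motorpool.stats` — group comparisons, RM-ANOVA interaction, regression, count/category tests
- `motorpool.io` — trace CSV dialect, cohort tables, pipeline and manifests
- `motorpool.cli` — `motorpool simulate|align|scatter|analyze|run|report`

See `docs/methods.md` for the model, parameter choices and limitations.
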