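# phenodrought

Statistical workflow for selecting informative traits from image-based
plant-phenotyping time series under drought.

## The problem

Conveyor greenhouse platforms image every plant of a genotype panel daily
under two watering regimes (well-watered control vs. drought), and the
image-analysis pipeline emits hundreds of traits — projected area, convex
hull geometry, color histograms, texture statistics — most of them highly
redundant. For a quantitative geneticist the question is which of those
traits carry repeatable, genetically structured signal about the drought
response, and which ones track the yield components scored after harvest.
This package implements a complete, reusable pipeline for that question,
aimed at experiments with the layout *genotypes × {control, drought} ×
replicate carriers × plants × imaging days*.

## The method

1. **Preprocessing** — iterative two-sided Grubbs outlier removal within
   each (genotype, treatment, day, trait) cell; averaging of plants
   within carriers; a repeatability filter that accepts a trait only if
   the Pearson correlation between the two carriers' pooled
   (genotype, day) time courses exceeds 0.2 in *both* conditions.
2. **Per-day G×E mixed model** — for each trait and day, carrier means
   follow `y_gtc = μ_t + u_gt + ε_gtc` with `(u_gC, u_gD) ~ N(0, G)`
   unstructured (2×2) and heterogeneous residuals; REML estimation with
   the G diagonal deliberately unconstrained in sign. Derived per fit:
   the Wald χ²(1) test of the mean drought effect, the genetic
   correlation between conditions `r_g = g_CD /√(g_CC g_DD)` (undefined
   for non-positive diagonals), and `log2(g_DD/g_CC)`.
3. **Relative drought effects** — per genotype and day,
   `RDE = 100·(mean_drought − mean_control)/mean_control` (percent).
4. **Profile clustering** — minimum within-group-sum-of-squares
   clustering (best-of-100-restarts Lloyd, k = 1…10) of the mean-RDE and
   genetic-correlation time profiles, with the number of groups chosen
   from the WSS scree; simultaneous classification crosses the two
   labelings.
5. **Linkage and selection** — per-day Pearson correlation between each
   image trait's RDE and each post-harvest trait's RDE across genotypes;
   "days with correlation" counts significant days (P < 0.001) split by
   sign; within each joint profile category the trait with the maximal
   count is selected iff that count exceeds the upper quartile of all
   counts.
6. **PLS prediction** — NIPALS partial least squares of post-harvest RDE
   on image-trait RDE, day by day, with two-group cross-validated PRESS
   comparing the selected subset against all accepted traits.

A synthetic-data generator (`phenodrought.simulate`) produces experiments
with this exact structure plus ground truth — planted RDE profiles,
per-genotype deviations, planted G trajectories and post-harvest linkage
weights — so every stage is testable end to end.

## Worked example

```
$ phenodrought run-all --seed 1 --outdir out/
{
  "accepted": 24,
  "k_effects": 6,
  "k_gcorr": 2,
  "combined_clusters": 6,
  "selected": {
    "spike": ["img01", "img02", "img03", "img04", "img05"],
    "TGW": ["img01", "img03", "img05"],
    "overlap": ["img01", "img03", "img05"]
  }
}
```

This simulates the bundled demonstration experiment (97 genotypes × 2
conditions × 2 carriers × 2 plants × 20 days, drought on days 5–14,
24 image traits in six profile families) and runs the full workflow. All
24 traits pass the repeatability filter; the mean-RDE profiles cluster
into 6 shape groups and the genetic-correlation profiles into 2, giving 6
occupied joint categories; the selection rule then returns exactly the
five traits whose planted per-genotype deviations drive the post-harvest
spike complex (`spike`) and thousand grain weight (`TGW`), with the three
TGW-linked ones in the overlap. `out/` holds every stage's CSV (per-day
REML components, RDE stack, cluster labels, correlation-day counts, PRESS
profiles) plus a `manifest.json` that makes the run exactly
reproducible.

The same stages are available programmatically:

```python
from phenodrought import (demo_scenario, demo_design, simulate_experiment,
                          run_pipeline, PipelineConfig)
obs, ph, truth = simulate_experiment(demo_scenario(seed=1))
result = run_pipeline(obs, ph, demo_design(), PipelineConfig())
result.selections["spike"].selected   # ['img01', ..., 'img05']
```

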