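# nitflow

Nitrogen mass-balance and community-succession analytics for autotrophic
nitrogen-removal bioreactors.

In reactors that remove ammonium autotrophically, two guilds do the
work: nitrifiers oxidize NH₄⁺ through NO₂⁻ to NO₃⁻, and anammox
bacteria convert NH₄⁺ + NO₂⁻ to N₂ gas with a small nitrate by-product
(0.26 mol NO₃⁻ per 1.02 mol N₂). Because N₂ escapes, it cannot be
measured in the effluent — but it can be inferred from the nitrogen
deficit, and measured nitrate can be split by stoichiometry into an
anammox-derived pool (apNO₃⁻ = N₂-N × 0.26/2.04) and a
nitrification-derived pool (npNO₃⁻). The ratio **N₂/npNO₃⁻** is the
system-performance index this package is built around: high when the
feed leaves as harmless gas, low when it accumulates as nitrate.

`nitflow` is for microbial ecologists and environmental engineers who
ask how much of a reactor's performance variation is explained by the
succession of its microbial community, beyond what operating conditions
explain. It provides:

* a mechanistic CSTR guild simulator (Monod kinetics, oxygen-inhibited
  anammox, biofilm/suspended biomass pools, a biofilm-homogenizing
  disturbance, Dirichlet-multinomial 16S count emission) whose packaged
  `paper_default` scenario plants a three-stage post-disturbance
  succession over 56 daily samples;
* the nitrogen partition and HRT-window smoothing of the index;
* community analytics: rarefied richness/Shannon/Pielou, Bray–Curtis,
  NMDS, Ward+elbow successional staging, point-biserial indicator taxa
  with permutation p-values, dissimilarity-vs-time-gap structure;
* Mann–Kendall trend tests (tie-corrected, continuity-corrected, exact
  at small n) and Sen's slope, per successional stage;
* standardized best-subset AIC regression of the index on
  environmental (temperature, pH, DO), diversity, and community (NMDS
  axes or genus abundances) predictor groups, plus db-RDA of community
  composition on the operating variables.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the full analysis on the packaged disturbance scenario:

```python
from nitflow import PipelineConfig, run_full_pipeline

cfg = PipelineConfig(scenario="paper_default", seed=1, outdir="demo_out")
res = run_full_pipeline(cfg)
print(res["stages"].k)                 # 3
print(res["trends"].round(4))
```

or from the shell: `nitflow --seed 1 --outdir demo_out run-all`.

With seed 1 the Ward+elbow staging recovers the three planted
successional stages exactly (days 1–13, 14–34, 35–56), and the
per-stage Mann–Kendall table reads:

```
  stage  n   S      var_S       Z  p_value  sen_slope
    all 56 648 20020.0000  4.5727   0.0000     0.0072
stage_1 13 -74   268.6667 -4.4536   0.0000    -0.0433
stage_2 21 106  1096.6667  3.1707   0.0015     0.0058
stage_3 22 219  1257.6667  6.1471   0.0000     0.0310
```

The index falls significantly during the early stage (Sen's slope
−0.043/day, p < 10⁻⁴: anammox is suppressed after the disturbance and
nitrate accumulates), then recovers through the middle and late stages.
The model-comparison table (adjusted R² of the best-AIC model per
predictor pool) shows community structure carrying far more information
about performance than the operating variables:

```
      model  adjusted_r2
   Only ENV        0.005
   Only DIV        0.346
   Only COM        0.627
    ENV+DIV        0.346
    ENV+COM        0.678
    DIV+COM        0.662
ENV+DIV+COM        0.694
```

That ordering is the expected signature of this scenario: performance is
driven by the simulated guild dynamics (which the NMDS axes trace),
while temperature, pH and DO only fluctuate around their setpoints
(db-RDA: the operating variables explain ~4% of compositional variance
here). Among indicator taxa, *Sideroxydans* marks the early stage
(r_pb = 0.93, p = 0.001) — an early-bloom taxon washed out as the
community matures.

Outputs written to `outdir`: the simulated chemistry/counts/taxonomy,
`partition.csv` (N₂, apNO₃⁻, npNO₃⁻, raw and smoothed ratio),
`diversity.csv`, `dissimilarity.csv` and `dissimilarity_by_gap.csv`,
`ordination.csv`, `stages.csv`, `indicators.csv` (with functional-guild
annotations), `trends.csv`, `models_table1.csv`, `models_table2.csv`,
`dbrda.csv`, and a `run_log.json` with all derived sub-seeds. Identical
config + seed ⇒ byte-identical outputs.

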