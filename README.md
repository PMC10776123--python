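# metaboaging

Analysis toolkit for time-course metabolomics and cohort demography in
short-lived vertebrate aging models (built around a three-timepoint
killifish skeletal-muscle study design: early-life, aged and extremely
old animals).

It is written for researchers who have an LC–MS metabolite intensity
table across ordered age groups (or treatment arms), weekly survival
records for the same population, and optionally muscle-fiber
cross-sectional areas — and who want the standard chain of analyses for
asking whether late-life physiology *reverts* toward an early-life
state:

1. **Trend typing.** Each metabolite's log2 abundance profile over the
   three ordered groups (A, B, C) is tested by one-way ANOVA with Tukey
   HSD (Tukey–Kramer for unequal n) and assigned one of **17 trend
   types in 5 groups**: no-change; up; down; bell-shaped inversion
   (mean_B > mean_A, mean_B > mean_C); U-shaped inversion. Within each
   direction the subtype records which pairwise comparisons reach
   significance (A–B, B–C, both, or only A–C).
2. **Co-abundance network.** Edges connect metabolite pairs with
   Pearson *r* > 0.7 and Benjamini–Hochberg adjusted *p* < 0.01 across
   all samples; modules come from a from-scratch **Markov Clustering
   (MCL)** implementation (expansion 2, inflation 2.0).
3. **Influence ranking.** Six centralities — degree, ClusterRank,
   neighborhood connectivity, local H-index, betweenness, collective
   influence at radius 3 — are range-normalized to [1, 100] and
   combined into the **Integrated Value of Influence**:
   `IVI = norm[(DC' + LH') × (NC' + CR') × (BC' + CI')]`,
   ranking metabolites by their topological importance.
4. **Mortality deceleration.** Cumulative mortality M(t) =
   deaths(≤t)/N is log10-transformed and searched for inflection
   points with the **extremum surface estimator (ESE)** — the midpoint
   of the extrema of the signed areas between the data polyline and its
   chords — delimiting early-life, exponential (Gompertzian) aging, and
   late-life plateau phases.
5. **Lipid bookkeeping.** Shorthand names (`TG(52:2)`, `CAR(4:0)`, …)
   are parsed into classes; per-class totals sum raw peak intensities
   of significantly altered species; acylcarnitines are binned into
   short (C2–C6), medium (C7–C12) and long (C13–C22) chains.
6. **Fiber morphometry.** Cross-sectional areas are categorized as
   small (<1000 μm²), medium (1000–2600 μm², inclusive) or large
   (>2600 μm²), with a seeded per-category sampler.

A synthetic-data module generates abundance tables with planted trend
types and correlated latent-factor modules, Gompertz-plateau survival
cohorts, and lognormal fiber areas, so the entire pipeline is testable
against known ground truth without any external download.

## Worked example

```bash
metaboaging run-all --seed 1 --out-dir results
```

or equivalently in Python:

```python
from metaboaging import pipeline
bundle = pipeline.run_all(pipeline.PipelineConfig(seed=1, out_dir="results"))
print(bundle["trend_summary"])
```

With the default demo configuration (500 synthetic metabolites, 3 age
groups × 7 samples, a 10,000-animal survival cohort) this prints:

```
{'no_change': 0.684, 'up': 0.058, 'down': 0.054, 'bell': 0.14, 'u_shape': 0.064}
```

The generator plants 72.1 % no-change and 12.8 % bell-shaped
metabolites; the observed no-change fraction (68.4 %) is the planted
fraction eroded by the ~5 % per-metabolite false-positive rate at
α = 0.05, and the bell fraction (14.0 %) is the planted 12.8 % plus
false calls — i.e. the classifier behaves as its error rates predict.
Of the top-15 metabolites by IVI, 14 carry a bell-shaped trend: the
bell metabolites co-trend, therefore co-correlate, and form the densest
most central region of the co-abundance network — the same phenomenon
that makes bell-shaped metabolites the influential core in real aging
metabolomes. `results/inflections.json`, `results/class_totals.tsv`
and `results/fiber_counts.tsv` hold the mortality, lipid and fiber
summaries.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on the synthetic demo under the
given seed (all randomness flows from `--seed`) and writes the JSON
summary; per-stage artifacts land next to it under
`results/pipeline_outputs/`.

## Layout

| module | contents |
| --- | --- |
| `metaboaging.io` | CSV/TSV readers and writers, GraphML/edge-list networks, survival tables |
| `metaboaging.preprocess` | deduplication by identification confidence, log2/log10 transforms |
| `metaboaging.trends` | ANOVA + Tukey HSD, the 17-type taxonomy, fast studentized-range SF |
| `metaboaging.network` | correlation edge selection, Markov Clustering |
| `metaboaging.influence` | six centralities, IVI, top-k ranking |
| `metaboaging.mortality` | cumulative mortality, ESE inflections, life-history phases |
| `metaboaging.lipids` | shorthand parsing, class totals, chain bins |
| `metaboaging.morphometry` | fiber size categories, seeded sampling |
| `metaboaging.synthetic` | generators with planted ground truth |
| `metaboaging.pipeline`, `metaboaging.cli` | orchestration and the `metaboaging` command |

See `docs/methods.md` for the statistical models, parameter defaults
and known limitations.
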