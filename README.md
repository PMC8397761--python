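# rhizodiel

Diel rhythm detection and co-occurrence network contrasts for soil
microbial community time series.

Rice rhizosphere microbiomes experience strong day/night cycling — root
exudation, oxygen, pH and dissolved organic carbon all swing with the
light — and part of the community keeps oscillating even in constant
darkness, driven by microbial circadian clocks. Disentangling
**entrained** rhythms (driven by the external light–dark cycle, gone in
constant dark) from **endogenous** ones (clock-driven, visible only once
the light driver is removed) requires a paired design: the same
community sampled every 12 h under a light–dark cycle (LD) and under
constant dark (DD). `rhizodiel` implements the full analysis for such
designs, for microbial ecologists working from genus-level 16S (cDNA)
count tables plus qPCR totals:

* **Absolute abundance scaling** — relative abundances × total 16S
  copies g⁻¹ soil, and DESeq-style median-of-ratios normalization
  (size factor per sample = median over genera of count/geometric mean,
  rescaled to geometric mean 1).
* **Circadian taxa** — a genus is circadian in a regime iff its AM vs PM
  abundance differs significantly (one-way ANOVA, α = 0.05) *and* every
  low-phase time point is strictly lower than its adjacent time points.
* **Indicator taxa** — AM/PM random-forest classification with
  out-of-bag mean-decrease-accuracy (MDA) importance, top-N ranking, and
  the overlap (and summed MDA) between indicator and circadian taxa.
* **Co-occurrence networks** — Spearman correlation networks per
  regime × compartment, denoised by Network Enhancement (doubly-
  stochastic diffusion), thresholded at the random-matrix-theory
  GOE→Poisson transition of the eigenvalue spacing distribution,
  with per-time-point subnetworks, Erdős–Rényi G(n, m) nulls, and
  topology metrics (degree, density, Louvain modules/modularity,
  normalized closeness/betweenness, clustering).
* **Synthetic benchmark** — a generator planting entrained / masked /
  robust / arrhythmic genera with known ground truth (negative-binomial
  overdispersion, exact multinomial depth, lognormal qPCR totals with a
  daytime activity boost under LD), so every stage has a recovery test.

See `docs/methods.md` for models, defaults and design decisions.

## Worked example

Run the full pipeline on the default synthetic study (2 regimes × 6 time
points × 7 replicates, 200 genera, both soil compartments):

```bash
rhizodiel detect --seed 1 --outdir run1
```

```
rhizosphere/LD: 32 circadian genera (16.0% of genera, 20.2% of abundance)
rhizosphere/DD: 27 circadian genera (13.5% of genera, 14.3% of abundance)
bulk/LD: 32 circadian genera (16.0% of genera, 20.3% of abundance)
bulk/DD: 24 circadian genera (12.0% of genera, 12.7% of abundance)
```

More genera oscillate under the light–dark cycle than in constant dark
(the entrained taxa stop cycling in DD, while the clock-driven taxa that
were masked by the community-wide light response emerge), and the
circadian share of total activity is larger than the genus-count share —
rhythmic genera tend to be abundant. The same run writes the indicator
and network reports (`rhizodiel run-all` prints all artifact names):

```
rhizosphere/LD: 25 circadian∩indicator genera, MDA sum 0.348
rhizosphere/DD: 21 circadian∩indicator genera, MDA sum 0.441
rhizosphere/LD: 200 nodes, 4505 edges, avg degree 45.05, 12 modules (Q=0.195)
rhizosphere/DD: 200 nodes, 134 edges, avg degree 1.34, 177 modules (Q=0.218)
```

Two signatures of the light driver: (i) under DD the indicator MDA mass
concentrates on the clock-driven taxa, so the circadian×indicator
overlap sum is *higher* than under LD, where the global daytime activity
boost makes every genus weakly informative; (ii) the LD network is far
denser with fewer modules — the shared light response couples the whole
community, while the DD network fragments into small clock-driven
clusters (isolated genera count as singleton modules).

The library mirrors the CLI one-to-one:

```python
from rhizodiel import (SimulationConfig, simulate_community,
                       normalize_counts, detect_circadian_taxa)

counts, meta, qpcr, truth = simulate_community(SimulationConfig(seed=1))
res = detect_circadian_taxa(normalize_counts(counts), meta, regime="LD")
print(len(res.circadian_genera), round(100 * res.fraction_genus_count, 1))
```

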