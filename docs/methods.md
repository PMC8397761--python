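# Methods

`rhizodiel` implements an analysis chain for diel (day/night) rhythms in
soil microbial community time series: activity-weighted abundance tables
sampled every 12 h under a light–dark cycle (LD) and under constant dark
(DD), circadian-taxon classification, random-forest indicator ranking,
and co-occurrence network contrasts. This note records the models,
defaults and design choices, and what the synthetic benchmark can and
cannot show.

## Study design and data model

The reference design is 2 regimes × 6 time points × 7 replicates per soil
compartment (rhizosphere, bulk): harvests alternate between 8 am (AM, end
of dark) and 8 pm (PM, end of light), so "day" is the PM group. Counts
are genus-level 16S cDNA amplicon reads (samples × genera); a qPCR assay
provides total 16S cDNA copies g⁻¹ soil per sample, which converts
relative abundances to absolute, activity-weighted copy numbers
(`absolute_abundance`: row proportions × qPCR total, so output row sums
equal the totals exactly).

Two scalings coexist deliberately:

* **median-of-ratios normalized counts** (`size_factors_median_of_ratios`,
  geometric-mean-1 factors; reference set = genera present in all samples,
  with a `pseudocount=1` fallback) remove sequencing depth and
  community-wide compositional shifts;
* **absolute copies** re-introduce the community-level activity rhythm
  (total activity is higher by day under LD).

The circadian test runs on normalized counts by default. On the absolute
scale a community-wide day/night activity shift multiplies every genus
equally, so every genus would test "rhythmic" — the genus-level rule is
only meaningful after compositional normalization. Indicator ranking and
network construction, by contrast, run on absolute abundances: there the
community-level activity rhythm is part of the biology being summarised
(`detection_scale` and the network inputs are configurable).

## Circadian-taxon rule

Per genus and regime: pool AM vs PM samples, one-way ANOVA (two groups —
equivalent to a pooled-variance t test; a six-group per-time-point
variant is available via `test="timepoint"`). A genus is circadian iff
the p-value is below alpha (default 0.05, no multiplicity correction by
default; Benjamini–Hochberg behind `bh_correct=True`) **and** the trend
is consistent: every time point of the low phase (the phase with the
smaller pooled mean) lies strictly below all of its adjacent time points;
ends compare against their single neighbour; any tie fails. Degenerate
zero-variance groups use the conventions p=1 (equal means) / p=0
(unequal means), which makes noise-free square waves exactly decidable.

Calibration measured under the null (no planted rhythms, 20 seeds × 200
genera): the significance-only rate is ≈ 0.053 and the composite rate
≈ 0.038 — below the nominal 0.05, but far above the α ×
P(trend-consistent) ≈ 0.009 one would get if the two conditions were
independent. They are not: a genus that reaches significance by chance
already has separated phase means, which makes an alternating
time-point profile likely (P(trend | significant) ≈ 0.73 at T=6, n=7).
Consequence: with 160 null genera, a handful of composite false
positives per regime is expected, and occasionally a truly LD-only
(entrained) genus is also called under DD. Exact disjointness of the LD
and DD call sets outside the robust oscillators is therefore a
statistical event, not a guarantee of the rule; the BH-corrected variant
comes close to it.

## Synthetic diel community

`simulate_community` plants four genus classes — entrained (oscillate in
LD only), endogenous-masked (DD only), endogenous-robust (both),
arrhythmic — as square waves at the 12-h sampling resolution (two
phases per cycle are observed, so finer waveform shape is
unidentifiable). Expected abundance = lognormal baseline (log-sd 1) ×
2^(±amplitude/2); defaults: 200 genera, 20/15/5 oscillators,
amplitude_log2 = 3. Counts: gamma multipliers (dispersion 0.1, i.e.
negative-binomial marginals) on expectations, then one multinomial draw
per sample at fixed depth 50 000 — depth is exact by construction and
biological overdispersion is preserved. qPCR totals are lognormal
(log-sd 0.2) around 10⁹ copies g⁻¹, doubled (1 log2 unit) in LD-PM
samples — the community-wide daytime activity elevation.

Peak phases are assigned deterministically in snake order
(day, night, night, day, …) over the baseline-sorted members of each
class. This balances both the total day- vs night-peaking oscillator
mass and its second moment. The alternative (random signs) leaks a
community-wide phase shift into every arrhythmic genus through the
compositional closure of the multinomial draw — an imbalanced
oscillating mass makes all other proportions counter-oscillate — and
even first-moment-only balancing leaves a Jensen-type day-high tilt via
the phase-asymmetric variance of the community total. With snake
assignment the measured arrhythmic phase tilt is ≈ 0 (|mean log2
PM/AM| < 0.003) and arrhythmic genera are called exactly at the
composite null rate.

The environment series (O₂ relaxing between ~5 and ~200 µmol L⁻¹ with a
3-h time constant, pH 6.4↔6.0 with a 1-h lag, DOC day/night levels at
the centres of the observed 231–270 / 161–201 mg kg⁻¹ ranges; flat
O₂ ≈ 5, pH drift to 6.8 and DOC decay to ~140 under DD) are
deterministic descriptive covariates; they do not feed back into counts.

What the generator does **not** emulate: taxon–taxon ecological
interactions (co-occurrence beyond shared drivers), phylogenetic
structure, zero inflation beyond multinomial sampling, unequal replicate
numbers, or within-phase waveform shape. Passing recovery tests
therefore shows the statistical machinery is correct under the stated
noise model, not that the rule is well-powered on real soil data.

## Indicator taxa (random forest MDA)

AM/PM classification per regime by a bagged ensemble of CART trees
(default 1000 trees, √p candidate features per split, unlimited depth;
trees are scikit-learn, the bagging/OOB layer is ours so that a single
integer seed drives every draw). Importance is classical mean decrease
accuracy: per tree, (OOB accuracy − OOB accuracy with one genus's values
permuted among that tree's OOB samples), averaged over trees; reported
raw (not SD-normalized) with a per-tree standard error. One permutation
per tree is drawn and applied to each genus column independently; the
per-genus batch is predicted in a single call. Top-N indicators (30
rhizosphere / 40 bulk by default) are intersected with the circadian
calls and the shared MDA mass is summed. Under LD the qPCR day boost
makes *every* genus informative, spreading MDA thinly; under DD only the
clock-driven taxa carry signal, concentrating MDA on them — hence the DD
overlap sum exceeds the LD sum, reproducing the direction reported for
the original experiment.

## Co-occurrence networks

Per meta-community (regime × compartment, all 42 samples): Spearman
correlations on absolute abundances (zero-variance genera excluded).
Network Enhancement denoises |r|: k-NN localization (k = min(20, ⌈n/10⌉))
with a self-link per node, symmetric Sinkhorn scaling to a
doubly-stochastic transition matrix (row/column sums 1 ± 1e-10), then the
closed-form diffusion λ → (1−α)λ/(1−αλ²) (α = 0.9) through the
eigen-decomposition; output symmetric, non-negative, zero-diagonal. The
correlation sign is kept as an edge attribute.

The edge cutoff comes from random-matrix theory: scan thresholds
0.30–0.95 (step 0.01); at each, the nearest-neighbour spacing
distribution of the degeneracy-collapsed, Gaussian-kernel-unfolded
(Silverman bandwidth) eigenvalues is chi-squared-tested against Poisson
(exponential) and GOE (Wigner surmise); the chosen threshold is the
smallest with Poisson consistency (p > 0.05), i.e. the GOE→Poisson
transition. Degenerate cases return the grid maximum with a warning
flag. The pipeline estimates **one cutoff per compartment from the
pooled samples** and applies it to both regime networks
(`threshold_scope="compartment"`): per-group cutoffs adapt to each
group's correlation level (the LD cutoff rises because the shared light
driver keeps collective GOE-like structure alive longer) and would
confound the LD/DD topology comparison. Group networks retain all
genera as nodes (`keep_isolated_nodes=True`), matching the "genera
present" node convention; isolated genera count as singleton modules,
which is exactly how fragmentation shows up in the module count.

Topology: average degree 2m/n, density, seeded Louvain modules and
modularity (edge-weighted), mean closeness normalized per connected
component ((n_c−1)/Σd), mean betweenness normalized by (n−1)(n−2)/2
(both on unweighted shortest paths; Louvain is a heuristic — on small
graphs it attains the exhaustive-partition maximum in ≈ 90% of random
instances, and the returned Q is always the exact modularity of the
returned partition). Null model: G(n, m) Erdős–Rényi graphs matching
both node and edge counts (matching only nodes would make every metric
comparison meaningless), 20 per subnetwork by default.

## Determinism and numerics

A single global seed determines everything; stage seeds derive as
(seed·100003 + crc32(stage name)) mod 2³¹ and are recorded in the run
manifest. Tukey HSD for two groups uses the exact studentized-range ↔ t
identity (q = √2|t|) rather than numeric integration, so the two-group
Tukey p equals the ANOVA p to machine precision; k ≥ 3 uses
scipy's studentized range (Tukey–Kramer for unbalanced groups).
Chao1 is bias-corrected by default (finite at F2 = 0); Shannon uses
natural log. Sinkhorn scaling runs to 1e-10 with a hard iteration cap;
small negative diffusion outputs are clipped to zero.

## Problem sizes

The shipped tests and the acceptance script run the full default design
(200 genera, 168 samples across both compartments, 1000-tree forests,
20 ER nulls per subnetwork); the complete pipeline takes ~2 minutes on
one CPU. Null calibration uses 20 replicate simulations; the
brute-force topology oracles enumerate all paths and partitions on
graphs of ≤ 8 nodes.

## Known limitations

* The composite circadian rule's false-positive behaviour (dependence of
  trend on significance) is intrinsic; see calibration above.
* Spearman-on-absolute correlations inherit the compositional and
  common-driver coupling of the data; SparCC-style compositional
  correlations are out of scope.
* The RMT scan needs ≥ 20 genera and enough non-degenerate eigenvalues;
  very sparse thresholded matrices are reported as diagnostically
  invalid rather than forced.
* Module counts include singleton components by design; interpret them
  jointly with average degree.
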