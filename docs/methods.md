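# Methods

This note documents the models and numerical choices behind `wgdwave`,
in the order the pipeline runs them.

## Homeolog selection from Ks distributions

A species' most recent WGD appears as a peak in the distribution of Ks
(synonymous substitutions per synonymous site) over its duplicate gene
pairs, on top of a roughly exponentially decaying background of
small-scale duplications (SSD). Two selection routes are implemented.

**Anchor route.** Anchor pairs live on collinear duplicated segments.
The unit of filtering is the segment: a segment is accepted iff the
median Ks over its anchor pairs lies inside the configured peak window
`[ks_low, ks_high]`, and then *all* its pairs are accepted, even those
whose individual Ks falls outside the window. The rationale is that a
segment is a single historical object — its median dates the duplication
event; per-pair filtering would truncate the within-segment rate
variation asymmetrically. Peak windows are configuration inputs, not
detected automatically: choosing them requires inspecting the Ks
distribution, which is curation.

**Peak-based route.** Without positional information, duplicate pairs
are taken from the peak window directly. Because several paralog pairs
can descend from one duplication (through later duplications), gene
family trees are midpoint rooted and each internal node is dated by the
median Ks over its *cross-subtree* terminal pairs; one representative
pair per qualifying node is drawn uniformly at random. Only spanning
pairs enter the node median — pairs within one child subtree measure
younger duplications. Candidate pairs are sorted lexicographically
before the seeded draw, and midpoint ties are broken toward the
lexicographically smallest leaf pair, so results are platform
independent.

Ks values above a saturation cap (default 5.0, configurable) are
excluded from medians but flagged rather than dropped: saturated
estimates carry no reliable age signal but their existence is part of
the record.

## Consensus WGD age: KDE mode with ranked-bootstrap CI

Given per-homeolog absolute ages (mya) for one species and one source
(anchor or peak-based — never pooled; their shapes differ), the
consensus age is the mode of a Gaussian KDE. Bandwidths are selected by
the diffusion plug-in ("improved Sheather–Jones", Botev et al. 2010),
solved by bracketed root finding on the fixed-point equation in the DCT
domain of the binned data; Silverman's rule is the fallback when the
fixed point cannot be bracketed (tiny or heavily discretized samples).
Densities are evaluated by binned Gaussian convolution on a regular grid
of 2^14 points spanning `[max(0, min − 3h), max + 3h]`; the binning
error is far below the CI width. Ages are not reflected at zero, so for
very young WGDs a little mass can leak below the grid — a known,
documented bias.

The 90% CI is a ranked bootstrap: B = 1000 resamples with replacement,
bandwidth re-selected and mode re-estimated per resample, modes sorted
ascending, bounds at the 1-based ranks `ceil(0.05·B)+1` and
`B − ceil(0.05·B) − 1` — the 51st and 949th of 1000. The bounds are
order statistics, so the interval need not bracket the point estimate.
Simulation (see the acceptance tests) puts the realized coverage at
~92% for n = 250 normal samples.

Why the mode: peak-based sets contain a minority of SSD pairs whose ages
follow a younger-biased power law. This contaminant drags the mean ~10
my young at 30% contamination while the density peak stays on the WGD
age; anchor and peak-based modes for the same WGD agree within about two
bandwidths on matched synthetic data.

## Independent events

A WGD shared by several descendant species must be counted once in the
event-level analyses. Event membership is an explicit curated map
(species → event), not inferred from the species tree: shared-WGD
assignments rest on published phylogenomic evidence. Per species the
anchor-based estimate is preferred (peak-based only where no anchor
estimate exists) and the event age is the arithmetic mean over member
species. The analysis window 0–100 mya is closed at both ends
(configurable); identification and dating of older events is too
uncertain to include.

## Clustering test against the lineages-through-time null

The null model of "random WGD occurrence" makes the probability of a
WGD at time t proportional to the number of contemporaneous lineages
N(t), read off a dated ultrametric species tree as the number of
branches crossing t (Δt = 0.1 my discretization — far finer than any
branching-time uncertainty). Null event sets are drawn by inverse-CDF
sampling on the piecewise-constant density, using a counter-based Philox
generator so the 10^6-sample stream is reproducible and chunkable.

The clustering statistic is the median distance among event ages, with
two readings implemented behind the `statistic_kind` flag:

* `median_nearest_neighbor` (the packaged headline analysis): the median
  over each event's distance to its closest other event;
* `median_pairwise`: the median over all C(n, 2) absolute differences.

The nearest-neighbor reading is used for the headline analysis because
the all-pairs median has essentially no power against the alternative
this test exists for: when event ages are bimodal — a wave plus a
younger background, which is exactly what the mixture analysis finds —
more than half of all pairs are between-cluster pairs, the all-pairs
median measures the gap between clusters, and tight within-cluster
packing barely changes it. The nearest-neighbor median responds directly
to local packing. Both statistics pass the same calibration checks
(uniform p under the null; type-I error 0.042 at α = 0.05 over 500
simulations).

The p-value is the plain fraction of null statistics at or below the
observed one; a (+1)/(N+1) pseudo-count variant is available by flag.

## Gaussian mixtures and AIC

Event ages are modelled as a univariate Gaussian mixture with free
weights and unequal, unconstrained variances; k = 3m − 1 parameters for
m components; AIC = 2k − 2 ln L; ties in AIC go to the smaller m. The
m = 1 fit is the closed-form MLE (biased variance, n denominator). For
m ≥ 2, EM runs from 50 seeded restarts (means at data quantiles with
0.5·SD Gaussian jitter, variances at total variance / m, uniform
weights), converging when the relative log-likelihood change falls below
1e-8 (max 1000 iterations); the log-likelihood is asserted
non-decreasing at every step.

Unequal-variance mixtures have an unbounded likelihood — a component can
collapse onto one or two close points. Two safeguards are applied:
variances are floored at 1e-6 of the total variance, and restarts are
ranked in three tiers: (0) every component carries at least two
effective points *and* the min/max variance ratio is at least 1e-2 (a
Hathaway-style bound); (1) supported but ratio-collapsed, i.e. a
genuinely tight cluster next to a broad one; (2) singleton spikes,
admissible only when nothing else is found (true point-mass data). The
best log-likelihood within the best available tier wins. Without this,
AIC prefers spurious m ≥ 2 spikes on pure-noise samples of n = 20.
A consequence worth knowing: on data containing a very tight cluster,
whether a tier-0 m = 3 solution is found can depend on restart luck, so
AIC(m = 3) can vary by a few units across seeds; AIC(m = 1) and
AIC(m = 2) are stable.

A robustness helper refits after excluding named events (bundled: the
banana event, whose single Ks peak most likely merges two WGDs in close
succession) and reports both runs side by side.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical *structure* of the real inputs:

* Yule (pure-birth) species trees by sequential exponential waiting
  times — no extinction, so LTT curves are monotone;
* anchor age samples as Normal(true age, σ) truncated at 0 (rejection),
  with σ defaulting to 8 my — the per-orthogroup dispersion of Bayesian
  node-age point estimates is a free knob, not an observed value;
* peak-based samples as that Normal mixed (default 20%) with a bounded
  power law of density ∝ (age + ε)^(−a) on [0, true age], a = 2,
  ε = 15 my. The offset ε sets how sharply the contaminant concentrates
  toward the present; an offset on the order of the signature peak's age
  span reproduces the observed denser-left-flank shape. A much smaller ε
  would put most contaminant mass within a couple of my of the present,
  which contradicts how these pairs are obtained (selected from the Ks
  signature peak, hence bounded away from age 0);
* Ks tables as an Exp(1.5) SSD background plus segments of ≥ 3 anchor
  pairs scattered (SD 0.05) around segment-level draws from a lognormal
  peak (median Ks 0.8, σ_log 0.15); 10% of segments are decoys centered
  on background draws, emulating spurious collinear regions;
* event sets as a truncated-normal cluster (default: 66 ± 5 mya,
  half the events) plus LTT-proportional background draws.

Not emulated: sequence evolution, MCMC behavior of the dating step,
correlated errors among orthogroups of one species, extinction, and
fossil-calibration uncertainty. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated — not that any
particular biological dataset satisfies the generators' assumptions.

## Bundled compendium

`wgdwave/data/` ships three files labelled *synthetic*: 31 species-level
WGD age estimates across 41 green-plant species, their assignment to 20
independent events, and a dated ultrametric chronogram. They are a
curated stand-in assembled from published plant WGD datings and standard
angiosperm divergence times — a handful of entries are exact published
values (the four Faboideae legume estimates, poplar, apple and pear);
the rest are representative literature values, and the chronogram's node
ages are rounded consensus divergence times. Event-level quantities
computed from these files (the clustering p-value, mixture AICs and
component locations) are faithful outputs of the method on a
realistically structured input, but exact numeric agreement with any
specific published analysis should not be expected, since the input is a
reconstruction. On this compendium the analysis yields p ≈ 0.038
(nearest-neighbor statistic, 10^6 null samples), a two-component mixture
with the dominant component at ≈ 59.4 mya (weight 0.65), and a
one-component AIC of 189.27.

## Problem sizes and tolerances

Defaults: 1000 bootstrap replicates, 10^6 null samples, 50 EM restarts,
2^14-point KDE grids, Δt = 0.1 my. The test suite scales these down
(120–250 bootstrap replicates on 2^10–2^11 grids, 2·10^3–2·10^5 null
samples, 5–20 restarts) — sizes chosen so each statistical property is
still resolved several standard errors away from its failure boundary.
All tests and the acceptance script are fully seeded; reruns are
bit-identical.

## Known limitations

* The LTT null counts only the lineages present in the supplied tree; a
  broader species count would flatten or steepen the null density.
* No boundary correction at age 0 in the KDE; consensus ages of very
  young WGDs (< ~3 bandwidths) are biased slightly old.
* The ranked-bootstrap CI is a percentile-type interval for a mode — a
  slowly converging estimator; its realized coverage (~92% in our
  simulations) depends mildly on n and the underlying shape.
* Event membership and peak windows are curated inputs; the package
  deliberately refuses to infer either.
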