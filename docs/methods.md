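# Methods

This note documents the models, decision rules, parameter defaults and
numerical conventions implemented in `cycleage`, and what the
synthetic-data generators do and do not emulate.

## The cyclical-aging model

The design is four ages — 3, 11, 14 and 19 months — chosen to span
pre-, peri- and post-menopausal-equivalent stages of the mouse mammary
gland, with 5 replicates per age per genotype.  *Linear* aging predicts
monotone trends across the three adjacent transitions
(3→11, 11→14, 14→19).  *Cyclical* aging predicts phase pairing: the
11- and 19-month states resemble each other, as do the 3- and 14-month
states, so per-feature trajectories zigzag.

### Cyclic gene calling

For each gene and each adjacent transition the package computes
log2FC = mean(t₊₁) − mean(tᵢ) over replicates, a two-sided unpaired t
p-value and a BH q-value adjusted across genes *within* each
transition.  Welch (unequal-variance) t is the default because
replicate variances are not assumed equal; pooled-variance Student t is
a flag.  Degenerate zero-variance comparisons use the convention p = 1
for equal means (p = 0 otherwise).

A gene is called cyclic when its three transition signs alternate and
every |log2FC| ≥ τ and every q ≤ q_max.  Both phases are supported and
recorded: U-D-U (up at 11 and 19 months) and D-U-D.  The narrative the
analysis encodes — 11/19-month phase matching — does not privilege a
direction, so the default calls both and reports the orientation per
gene.  Defaults: τ = 1 log2 unit and q_max = 0.05.  The q cutoff
follows the proteomics convention (q < 0.05); the amplitude threshold
has no documented counterpart upstream, so it is an exposed, logged
parameter.  Calls are monotone in both thresholds: raising τ or
lowering q_max never adds a call.

### Cyclic protein calling

ECM proteomics tables carry missing values (failed detections).  A
protein is *detected* at a timepoint when at least k replicates are
non-missing and above the intensity floor; k defaults to the replicate
majority ⌈n_rep/2⌉ since no peptide-level detection threshold is
standard here.  The cyclic call is presence/absence logic: detected at
11 and 19 months in the designated genotype, not detected at 3 or 14
months there, and not detected at any timepoint of the other genotype.
The call is invariant to replicate order and to intensity rescaling
above the floor.  Differential intensity testing (unpaired t on log2
intensities, BH across tested proteins, q < 0.05) reports proteins with
fewer than 2 non-missing replicates per side as *untested* rather than
silently dropping them.

With 5 replicates, 20 % missing-completely-at-random dropout and k = 3,
the per-timepoint detection probability of a truly present protein is
P(Binom(5, 0.8) ≥ 3) = 0.942, so the expected recovery of a planted
cyclic protein (which must be detected at both 11 and 19 months) is
0.942² ≈ 0.89.  The acceptance script reports this measured
sensitivity; the trade-off of k against false presence calls is the
user's to configure.

### Timepoint clustering

Per-age mean profiles are clustered with average linkage on correlation
distance (1 − Pearson across genes), the standard clustergram choice;
metric and linkage are options.  The 2-cluster cut is returned as an
unordered partition of age labels.  Merge ties break deterministically
lowest-index-first (SciPy's order).  Constant profiles make correlation
undefined and are rejected with the profile named.  On cyclical data
the cut is {3m, 14m} vs {11m, 19m}; on equal-step monotone-drift data
the farthest endpoint ({3m}) splits off instead, which the test suite
uses as the negative control.

## Cell-type annotation

The four mammary epithelial populations are gated from marker panels:
HS (Prlr, Pgr, Esr1, Cited1, Prom1), AV (Mfge8, Trf, Csn3, Wfdc18,
Ltf), ME (Krt17, Krt14, Krt5), plus proliferation (Cenpe, Ccna2, Ccnb2,
Mcm6, Ccnf, Bud1 — "Bud1" kept verbatim from the source list although
nonstandard; absent genes are warned and skipped) and a
regulon panel of 14 transcription factors.  Where the original analysis
identified clusters interactively, this package uses a deterministic
rule so results are reproducible: per-cell panel score
s = log2(1 + Σ panel counts); a cell is labelled by its best lineage
panel among those reaching the threshold.  The threshold default reuses
the half-of-maximum convention (half the panel's max score across
cells), the only cutoff convention documented upstream.  The mixed
HS-AV label is assigned when HS and AV scores both qualify and differ
by at most a relative margin (default 25 % — an explicit package choice,
exposed in config, since the mixed lineage has no documented
operational definition; an imported cluster-label path is available as
an alternative).  The PPBC-like gate is the conjunction of the
proliferation and regulon half-max gates.  Composition ratios divide
each type count by LE = #HS + #AV + #HS-AV, so the three luminal ratios
sum to 1 by construction.  The half-max gates are deliberately *not*
invariant to count rescaling (the cut is data-relative); the test suite
asserts this rather than hiding it.

## Signature scoring and stratification

ssGSEA score of a sample: rank all genes by decreasing expression (ties
broken by the stable input gene order), weight the gene at descending
position i by (N + 1 − i)^α, and accumulate
score = Σᵢ [P_in(i) − P_out(i)] where P_in is the cumulative normalised
weight mass of set genes and P_out the cumulative uniform mass of
non-set genes.  The *sum* of deviations (ssGSEA convention) is used
rather than the maximum (GSEA convention).  α defaults to 0.25, the
common ssGSEA practice; the weighting scheme is not documented upstream
so both α and the rank-weight convention are stated here and logged.
Scores are rank-based, hence invariant to strictly increasing
transforms, and no cross-sample rescaling is applied by default (the
tertile split is rank-based; a min-max flag exists for plotting).

Stratification labels the top ⌈n/3⌉ samples by score "high" and the
rest "low"; boundary ties resolve by stable sample order with a
warning.  Mouse-to-human translation of signatures goes through a
user-supplied two-column ortholog table; no ortholog database is
bundled.  Over-representation of a query list in GMT collections is a
hypergeometric upper tail with BH across sets — a local, offline
replacement for web enrichment services.

## Cohort statistics

**Dip.** The Hartigan–Hartigan dip is the minimal sup-norm distance
between the empirical CDF and the nearest unimodal CDF.  The
implementation scans candidate modal splits: for each split, the least
feasible band half-width on the left is half the largest gap between
the empirical CDF's step values and the greatest convex minorant of its
left step corners; the right side mirrors this with the least concave
majorant.  Splits between sample points and at a point (the mode may
carry an atom) are both scanned; the dip is the minimum over splits of
the larger side.  The scan is O(T²) in the number of distinct values
and numba-compiled.  For n distinct values the dip lies in
[1/(2n), 1/4]; tied samples collapse to CDF steps and a pure point mass
has dip 0.  The test suite proves the implementation against an
independent linear-programming oracle (minimise the band half-width
subject to convexity/concavity/monotonicity constraints per split) on
1000 random samples.

**Dip p-value.** Monte-Carlo calibration against the classical
Uniform(0,1) null: p = (1 + #{dip(U_b) ≥ dip(x)})/(n_boot + 1),
seedable and free of packaged lookup tables.  The uniform null is
conservative for lighter-tailed unimodal data such as the normal
(measured null rejection at α = 0.05 is well below 0.05).

**Survival.** Kaplan–Meier product-limit with censored subjects
leaving the risk set after their time; at tied times events precede
censorings.  The two-group log-rank statistic sums O − E over event
times with the hypergeometric variance (ties grouped), referred to
χ²(1).  Both are hand-implemented to the textbook definitions and
cross-checked against `lifelines` in the test suite; time units are
whatever the input uses.

**Fisher.** Two-sided p by the point-probability rule (sum of
hypergeometric probabilities ≤ that of the observed table, with a 1e-7
relative tolerance); the tail-doubling rule is a flag.  A zero margin
returns p = 1 with a warning.

**Age densities.** Shared histogram bins across groups plus a
Gaussian KDE (Silverman bandwidth) evaluated on a common grid; the
output is a plot-ready table, rendering optional.

## Synthetic data: what it emulates and what it does not

Generators are seed-deterministic and plant known truth so every
detector has a parameter-recovery test.

* **Timecourse**: per-gene baselines N(6, 1) on the log2 scale, planted
  mean profiles with alternating ±amplitude transitions (U-D-U, D-U-D),
  monotone three-step profiles, flat nulls; i.i.d. Gaussian replicate
  noise.  Defaults follow the study design (4 ages, 5 replicates) with
  amplitude 2 (4-fold) and noise sd 0.5.  Expression is simulated on
  log2; linear export is 2^x.
* **Proteome**: two genotypes, background proteins present everywhere,
  planted cyclic proteins with intensity only at 11/19 months of one
  genotype; log2 intensities N(20, 1); dropout is
  missing-completely-at-random by default (the simplest null a
  presence-caller must survive), with an optional intensity-dependent
  dropout slope, off by default.
* **Single cell**: cells draw Poisson(marker_rate) counts on their own
  panel (HS-AV on both luminal panels) over a Poisson background;
  per-sample type counts follow the planted composition exactly
  (largest-remainder apportionment), so with zero background the
  annotation and ratio stages recover the truth exactly.  Defaults
  plant the composition cycle (higher HS/LE at 3/14 than at 11/19
  months, 1000 cells × 3 samples per age).
* **Cohort**: high-group ages from a normal mixture (default
  0.5·N(45, 3²) + 0.5·N(65, 3²), the bimodal pattern of interest),
  low-group ages N(65, 8²); survival exponential with per-group hazards
  (defaults 0.10 vs 0.05 per year, hazard ratio 2) under independent
  exponential censoring (0.04/year), which keeps the KM/log-rank
  oracles valid; signature genes (default 79) shifted +2 log2 units in
  high samples among ~1000 genes.

Not emulated: realistic scRNA-seq noise (ZINB overdispersion, ambient
RNA, doublets), batch effects, intensity-dependent MS artefacts beyond
the optional dropout slope, and covariate-dependent censoring.  Passing
recovery tests therefore demonstrates correctness of the decision rules
and statistics under their stated assumptions, not robustness to every
real-data pathology.

## Problem sizes and determinism

The test-suite simulations use 2000 genes × 100 planted cyclic,
100-seed replications for recovery rates, 200/500-seed replications for
dip power and level (n_boot 499/199; the smallest attainable Monte-
Carlo p is 1/(n_boot+1)), and 1000 null simulations for log-rank
type-I error — sizes at which the Monte-Carlo standard errors are small
relative to the thresholds being checked.  The pipeline derives each
stage's seed from one top-level seed via named `SeedSequence`
substreams, and a run's manifest reproduces it byte-identically.

## Known limitations

* The cyclic-gene caller requires exactly 4 timepoints; longer designs
  would need a generalised alternation test (cosinor/harmonic methods
  are out of scope).
* The dip test's uniform-null calibration is conservative for
  light-tailed unimodal alternatives; calibrating against a fitted null
  would sharpen level at the cost of a parametric assumption.
* With 5 replicates, BH-corrected per-transition testing at q ≤ 0.05
  has limited per-gene power at amplitude/noise = 4; joint modelling of
  the three transitions would be more powerful than requiring all three
  to pass marginally.
* Marker gating assumes panels discriminate lineages; heavily
  contaminated or low-depth data will push cells to `unassigned`.
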