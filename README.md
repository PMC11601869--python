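# cycleage

Tools for detecting **cyclical aging** patterns in the mouse mammary
gland and relating them to breast-cancer cohorts.

The scientific question: over four ages spanning reproductive life
(3, 11, 14 and 19 months), does a tissue alternate between two states —
the 11- and 19-month glands resembling each other and the 3- and
14-month glands resembling each other — rather than regressing
monotonically?  `cycleage` turns that question into testable,
reproducible operations for people analysing time-course bulk
expression, ECM proteomics with missing values, marker-gated
single-cell counts, and clinical cohorts:

* **Cyclic gene calling** — for each gene, the three adjacent-age
  transitions get a log2 fold change, a two-sided Welch t p-value and a
  Benjamini–Hochberg q (within each transition).  A gene is *cyclic*
  when its transition signs alternate (U-D-U or D-U-D), every
  |log2FC| ≥ τ (default 1) and every q ≤ 0.05.
* **Cyclic protein calling** — a protein is called when it is detected
  (≥ ⌈n/2⌉ non-missing replicates above the floor) at 11 and 19 months
  in one genotype, absent at 3 and 14 months there, and absent
  everywhere in the other genotype.
* **Phase pairing** — average-linkage hierarchical clustering of
  per-age profiles on correlation distance; cyclical data cut into
  {3m, 14m} vs {11m, 19m}.
* **Cell annotation** — mammary epithelial types (HS, AV, HS-AV, ME)
  from marker panels by log2 feature-sum gating with the half-of-maximum
  cutoff convention; composition ratios use total luminal epithelial
  cells (LE = HS + AV + HS-AV) as denominator.
* **Signature scoring** — per-sample ssGSEA (sum of the running-sum
  deviations, rank weight `(N+1-i)^alpha`, α = 0.25), top-tertile
  high/low stratification.
* **Cohort statistics** — Hartigan–Hartigan dip statistic with a
  seeded Monte-Carlo Uniform(0,1) calibration for age-at-diagnosis
  bimodality, Kaplan–Meier curves, the two-group log-rank test, and
  two-sided Fisher exact tests.

A synthetic-data module generates all four data kinds with planted
structure (zigzag genes, 11/19-month-only proteins, composition cycles,
bimodal-age cohorts with group-dependent exponential survival), so the
entire pipeline is exercised end to end without downloads.

## Worked example

```python
import cycleage as ca

cfg = ca.TimecourseConfig(n_genes=2000, n_cyclic_udu=50, n_cyclic_dud=50,
                          amplitude=2.0, noise_sd=0.5, seed=1)
tc, truth = ca.gen_timecourse(cfg)
calls = ca.call_cyclic_genes(ca.transition_stats(tc), tau=1.0, q_max=0.05)
planted = set(truth.index[truth.pattern.isin(["udu", "dud"])])
print(len(calls), len(set(calls.genes) & planted))

part = ca.cluster_timepoints(tc.replicate_means().rename(columns=lambda t: f"{t}m"))
print(sorted(sorted(s) for s in part.partition_sets()))
```

prints

```
63 63
[['11m', '19m'], ['14m', '3m']]
```

63 of the 100 planted zigzag genes pass all three per-transition
q ≤ 0.05 and |log2FC| ≥ 1 filters at this noise level, with no false
calls among the 1900 null genes, and the per-age mean profiles pair
3-with-14 months and 11-with-19 months — the cyclical signature.

On the cohort side:

```python
co, expr, sig = ca.gen_cohort(ca.CohortConfig(n_samples=300, seed=5))
scores = ca.score_samples(expr, ca.GeneSet("sig", tuple(sig)))
groups = ca.tertile_stratify(scores)
hi, lo = co[groups == "high"], co[groups == "low"]
print(ca.dip_test(hi.age_years, n_boot=499, seed=7).p,   # 0.002  (bimodal 45/65)
      ca.dip_test(lo.age_years, n_boot=499, seed=8).p)   # 0.908  (unimodal 65)
lr = ca.logrank_test(hi.os_time, hi.os_event, lo.os_time, lo.os_event)
print(round(lr.chi_square, 1), lr.p)                     # 36.0 2.02e-09
```

The signature-high tertile reproduces the planted bimodal age
distribution (dip test rejects unimodality) and shows worse overall
survival (log-rank).

## Command line

```bash
cycleage simulate timecourse --out data/ --seed 1
cycleage cyclic-genes --expr data/expression.csv --tau 1.0 --qmax 0.05 --out calls.tsv
cycleage cyclic-proteins --proteome prot.csv --genotype nzb --out cyclic.txt
cycleage annotate --mtx cells/ --out ann.tsv
cycleage score --expr expr.csv --gmt sig.gmt --out scores.tsv
cycleage cohort --table cohort.tsv --dip-boot 2000 --seed 7 --out results.json
cycleage run --out run1/           # full demo pipeline with manifest
cycleage rerun --manifest run1/manifest.json --out run2/   # byte-identical
```

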