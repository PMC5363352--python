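# segdupcnv

Paralog-aware copy-number analysis of a two-unit segmental duplication, built
around the low-affinity Fcγ-receptor (FCGR) locus problem: two ~16-kb repeat
units ("paralog A" and "paralog B") at ~98.5% identity recombine by nonallelic
homologous recombination (NAHR), producing deletion alleles (one chimeric
A/B unit) and reciprocal duplication alleles (three units). Because array-CGH
probes cross-hybridize between the paralogs, total copy number alone cannot
say *which* gene was lost — yet that distinction (FCGR3B-type vs FCGR3A-type
deletion) is what matters for disease association.

The package is aimed at statistical geneticists and method developers who
want a fully simulated, truth-annotated testbed for this class of locus. It
provides:

* **`segdupcnv.locus` / `segdupcnv.cohort`** — a generative model of the
  locus: paralog references with an explicit paralog-sequence-variant (PSV)
  catalog, NAHR deletion/duplication and gene-conversion alleles, fosmid-like
  contigs, and an aCGH log2-ratio matrix in which a probe designed to paralog
  *T* responds to a genotype with *m* matched and *u* mismatched units as
  `log2(max(m + γu, floor) / (2 + 2γ)) + cohort offset + noise`, with
  cross-hybridization weight γ ∈ [0, 1].
* **`segdupcnv.assign`** — contig-to-paralog assignment by the fraction of
  matching aligned bases, weighted-interval-scheduling selection of
  non-overlapping alignments, and PSV-state profiling.
* **`segdupcnv.breakpoints`** — switch detection on PSV profiles, NAHR
  breakpoint localization to inter-PSV intervals, gene-conversion tract
  calling, identity-by-descent comparison of alleles, and an A/B
  separability statistic.
* **`segdupcnv.mixture`** — `OrientedPC1` (first principal component with a
  deletions-score-high sign convention) and `CohortGaussianMixture`
  (`y_i ~ N(μ_z + β_cohort, σ_z²)`, EM with the reference-cohort offset fixed
  at zero), both scikit-learn-style estimators; three-component fits give
  loss/normal/gain calls with posteriors.
* **`segdupcnv.classify`** — `DeletionTypeClassifier`: exclude deletion
  homozygotes by a PC1 threshold, restrict to the 20 probes between the two
  NAHR hotspots (the deletion-determining region), and split heterozygous
  deletions into A-type and B-type with a two-component mixture using
  case/control status as the offset factor.
* **`segdupcnv.assoc`** — exact 2×2 association: cross-product and
  conditional-MLE odds ratios, two-sided Fisher p (point-probability rule),
  and the exact conditional confidence interval by inverting the noncentral
  hypergeometric distribution.

## Worked example

Exact association from published carrier counts (79 case carriers, 82
control carriers, 1,903 / 3,189 noncarriers):

```python
from segdupcnv import ContingencyTable, associate

r = associate(ContingencyTable(79, 82, 1903, 3189))
print(f"OR (sample)      {r.or_sample:.2f}")
print(f"OR (cond. MLE)   {r.or_cmle:.2f}")
print(f"P (two-sided)    {r.p_two_sided:.1e}")
print(f"95% CI           ({r.ci[0]:.2f}, {r.ci[1]:.2f})")
```

prints

```
OR (sample)      1.61
OR (cond. MLE)   1.61
P (two-sided)    2.9e-03
95% CI           (1.16, 2.24)
```

i.e. deletion carriage is associated with case status at odds ratio 1.61,
and the exact interval excludes 1.

The full simulated pipeline (the same thing `segdupcnv run-all` does):

```python
from segdupcnv import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
stages = report["stages"]
print(stages["call_cn"]["class_counts"])
print(stages["classify_ab"]["known_carrier_concordance_pct"])
print(stages["map_breakpoints"]["het_b"]["breakpoints"])
```

prints

```
{'normal': 335, 'loss': 33, 'gain': 32}
100.0
[{'start': 13296, 'end': 13382, 'hotspot': 'distal'}]
```

— of 400 simulated samples, 33 are flagged as deletions and 32 as
duplications; after excluding 3 deletion homozygotes, the two-component
classifier types all 15 planted known-type carriers correctly (100%
concordance); and the B-type exemplar allele's breakpoint is localized to an
87-bp inter-PSV interval inside the generating distal hotspot.

A CLI mirrors the library (`segdupcnv simulate|assign|map-breakpoints|
call-cn|classify-ab|associate|run-all`), e.g.

```sh
segdupcnv associate --counts 79 82 1903 3189
segdupcnv run-all --seed 1 --outdir out/
```

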