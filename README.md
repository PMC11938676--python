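# strscreen

Tandem-repeat (TR) expansion disorders — Huntington disease, Friedreich
ataxia, myotonic dystrophy, and dozens more — are caused by repeat tracts
growing past a locus-specific pathogenic threshold. Population-scale
sequencing cohorts now yield TR genotypes for thousands of presumably
unaffected individuals, and a recurring, consequential observation is that
*pathogenic genotypes* (PGs) appear in such cohorts far more often than
disease prevalence predicts. Quantifying that excess carefully — per locus,
under the correct inheritance model, with conservative allele estimates and
honest confidence intervals — is what this package does.

`strscreen` is a Python library (with a thin CLI) for:

- **Locus catalogs** — loading and validating curated disease-locus records
  (per-build coordinates, motifs with benign/pathogenic/uncertain classes,
  size thresholds in repeat units, inheritance mode, prevalence, evidence
  counts), summarizing them, and exporting plain BED plus TRGT
  repeat-definition BED (`ID=...;MOTIFS=...;STRUC=...`).
- **Motif tools** — canonical minimal-rotation normalization so that
  `CAG`/`AGC`/`GCA` compare equal, reverse complements for minus-strand
  loci, and classification of genotyped motifs against the curation.
- **Genotype classification** — per-individual calls labelled
  `pathogenic` / `carrier` / `none` / `excluded` under the locus inheritance
  mode, with conservative lower-bound allele sizes and a pathogenic-motif
  requirement.
- **Cohort statistics** — PG and carrier percentages with 95% Wilson score
  intervals, sex/population stratification, and concordance against
  literature prevalence.
- **Synthetic cohorts** — a generator with Hardy–Weinberg ground truth and
  realistic lower-bound noise, so the whole pipeline is testable end to end
  without any cohort download.

## The model in brief

For an individual with alleles $a_1, a_2$ (one allele when hemizygous) at a
locus with pathogenic threshold $p_\min$, an allele is **pathogenic** iff
its (lower-bound) size satisfies $a \ge p_\min$ *and* its genotyped motif
matches a curated pathogenic motif up to cyclic rotation. With $P$ the
number of pathogenic alleles:

| inheritance | pathogenic genotype | carrier |
|---|---|---|
| AD, XLD | $P \ge 1$ | — |
| AR | $P = 2$ | $P = 1$ |
| XLR, male (hemizygous) | $P = 1$ | — |
| XLR, female | $P = 2$ | $P = 1$ |

The cohort PG percentage is $100\,x/n$ with $x$ PGs among $n$ individuals
genotyped at the locus, and its 95% CI is the Wilson score interval

$$\frac{\hat p + \tfrac{z^2}{2n} \pm z\sqrt{\tfrac{\hat p(1-\hat p)}{n} + \tfrac{z^2}{4n^2}}}{1 + z^2/n},\qquad z = 1.96 .$$

A cohort estimate is *concordant* with an external estimate when the latter
lies within (or within 0.001 percentage points of) this interval.

## Worked example

`examples/03_cohort_summary.py` rebuilds a screening of an X-linked
recessive dystrophin-locus cohort: 429 hemizygous males (28 with an
expanded allele ≥ 59 repeats) and 446 diploid females (4 with two expanded
alleles, 21 with one):

```
female: 4/446 PG = 0.90% (95% CI 0.35-2.28%), carriers 4.71%
male: 28/429 PG = 6.53% (95% CI 4.55-9.27%), carriers 0.00%
male PG vs prevalence 0.01%: concordant=False, fold difference 653x
```

Reading: 6.53% of males carry a "pathogenic" genotype at a locus whose
disease affects fewer than 1 in 10,000 males — a 653-fold excess, flatly
discordant with the clinical prevalence, which is evidence against the
repeat being disease-causing at this locus. Females show the recessive
pattern: PGs are rare (0.90%) while single-allele carriers are common
(4.71%).

The other examples cover catalog operations and exports
(`01_catalog_operations.py`), single-call classification with advisory
flags (`02_classify_genotypes.py`), and simulation-based parameter recovery
(`04_simulate_and_recover.py`).

## Command line

```bash
strscreen validate catalog.json
strscreen bed catalog.json --build hg38 --out loci.bed
strscreen trgt catalog.json --build hg38 --out repeats.trgt.bed
strscreen simulate --config sim.json --seed 7 --out calls.tsv --truth truth.tsv
strscreen classify --genotypes calls.tsv --catalog catalog.json --out classified.tsv
strscreen summarize --genotypes calls.tsv --catalog catalog.json --stratify sex
```

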