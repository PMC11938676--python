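# Methods

This note documents the models, conventions and numerical choices behind
`strscreen`, and what its synthetic-data validation does and does not
demonstrate.

## Locus catalog

A catalog is a JSON document of curated TR disease loci (schema shipped at
`src/strscreen/data/catalog.schema.json`, version 1.0, generated from the
pydantic models that enforce it). Conventions:

- **Coordinates** are 0-based half-open per genome build (`hg19`, `hg38`,
  `T2T-chm13`; `hg37`/`GRCh37` are accepted as aliases of `hg19`). A file
  written 1-based declares `"coordinate_system": "1-based-closed"` and is
  converted on load. Storing BED-native coordinates makes BED emission a
  formatting step with nothing to get wrong.
- **Size thresholds** (`benign_max < intermediate_min ≤ intermediate_max <
  pathogenic_min ≤ pathogenic_max`) are stored in repeat units;
  `pathogenic_min` is the smallest pathogenic allele size. Sources quoting
  bp are converted through `motif_len` at curation time
  (`bp_to_repeats`/`repeats_to_bp`).
- **Prevalence** is a fraction in [0, 1]; unknown prevalence is absent,
  never 0, because 0 is a meaningful estimate. Textual statements
  ("1 in 20,000", "0.0106–0.0137%", "1–2 per 100,000") are parsed and
  ranges averaged to a single value.
- **`locus_structure`** is opaque pass-through text: no machine-readable
  grammar for repeat composition is imposed, it is only echoed into TRGT
  definitions.
- Unknown fields are preserved verbatim, so load → serialize → load is
  lossless; validation collects *all* violations before failing.
- Minus-strand loci can carry motifs in gene orientation;
  `populate_reverse_complement` adds reference-orientation twins with the
  same class (idempotent).

## Motif normalization

Motifs are compared up to cyclic rotation via the lexicographically
smallest rotation (`CAG → AGC`). A plain character sort is *not* used as
the default normalization because sorting conflates motifs that are not
rotations of one another (`AGC` and `ACG` both sort to `ACG`) — exactly the
benign/pathogenic distinctions the analysis depends on. Both behaviours are
available (`normalize(..., method="rotation"|"sorted")`) so either
convention can be reproduced. For periodic motifs the minimal rotation is
reached at several rotation indices; the smallest index is recorded and the
canonical form remains a full-length rotation of the input. Matching is
rotation-only by default; reverse-complement matching is opt-in because
catalogs store both strand orientations explicitly. Motifs containing `N`
(degenerate calls such as `CNG`) are never matched — calls carrying them
are excluded, as such calls inflate allele estimates through sequence
non-specificity.

## Genotype classification

- **Effective allele size** is the genotyper's lower-bound estimate by
  default (`ClassificationPolicy.use_lower_bound`), because short-read
  genotypers overestimate when they err; the point estimate is used when no
  lower bound is reported. This choice is conservative by construction: on
  any fixed input, switching to point estimates can only increase the PG
  count (property-tested).
- **"Exceeds the threshold"** is implemented as `size ≥ pathogenic_min`,
  with `pathogenic_min` the smallest pathogenic size (e.g. threshold 40 for
  a locus where >39 repeats is pathogenic; 59-repeat alleles count at a
  locus with threshold 59).
- **Pathogenic allele** = pathogenic size AND curated pathogenic motif.
  Expanded alleles with uncertain/unknown motifs are not pathogenic but
  raise an `uncertain_motif` advisory; intermediate-band alleles raise
  `intermediate_range`. `pathogenic_max`, where curated, is advisory only
  (`above_pathogenic_max`), never an upper gate.
- **Inheritance**: dominant (AD/XLD) needs one pathogenic allele; autosomal
  recessive needs two, one making a carrier; X-linked recessive males are
  hemizygous and need one, females two (one → carrier). Ambiguous-mode loci
  carry a single effective inheritance in the catalog, overridable per
  locus via `ClassificationPolicy.inheritance_override`.
- **Edge cases routed, not dropped**: unknown sex at an X locus and
  single-allele calls at AR loci (the recessive rule is defined for two
  genotyped alleles) go to an `unclassifiable` bucket that is counted and
  reported. A diploid male call at an X locus raises `ploidy_warning` and
  is treated as hemizygous for the larger effective allele.
- **Exclusions** (degenerate-motif calls; loci flagged unreliable after
  manual review; contraction-mechanism loci, since the screen addresses
  expansions only) label the call `excluded`; excluded calls never reach
  any denominator.
- Missing per-allele motif defaults to the locus reference motif (common in
  short-read catalogs); `missing_motif="strict"` treats it as unknown
  instead.
- `pathogenic_min_override` re-runs the whole analysis under an alternate
  threshold table with a single policy substitution, for cross-study
  threshold-matching comparisons.

## Cohort statistics

`n_genotyped = n_pg + n_carrier + n_none` is the denominator of every
percentage; `n_excluded` and `n_unclassifiable` are reported alongside but
sit in no denominator. Percentages are kept at full precision internally
and rounded only for presentation.

The 95% CI is the **Wilson score interval without continuity correction**.
The choice is pinned by a published anchor: for 2 successes at the
~18.5k-individual scale the Wilson bounds round to (0.003%, 0.039%) —
verified for n ∈ [18,460, 18,650] — while Clopper–Pearson's lower bound
rounds to 0.001% everywhere in that window. Clopper–Pearson remains
available (`method="clopper-pearson"`) for sensitivity analysis. Bounds at
x = 0 and x = n are snapped to the analytically exact 0%/100%. Exact
coverage of the Wilson interval at the regimes used in validation is
95.2–95.6%, inside the conventional 94–96% band.

Concordance with an external prevalence estimate: concordant iff the
estimate (in percent) lies within the cohort CI widened by 0.001 percentage
points on each side; the fold difference `pg_pct / prevalence_pct` is
reported either way.

## Synthetic cohorts

The generator emulates the call structure of a short-read population
cohort, not its biology:

- Alleles are drawn independently (random mating); males are hemizygous at
  X loci. Sex is Bernoulli with `sex_ratio` (default 0.5); unknown sex is
  not simulated by default.
- A fraction `pathogenic_allele_freq` of alleles is pathogenic-sized:
  `pathogenic_size_min + Geometric` (mean excess `pathogenic_size_dispersion`,
  default 5 repeat units). Normal alleles are a rounded Gaussian around
  `normal_size_mode` (default dispersion 2), truncated *below* the
  pathogenic threshold — the truncation makes the Hardy–Weinberg truth
  expectations exact rather than approximate.
- Motifs are drawn per allele from `motif_mixture`, independently of size;
  the effective pathogenic allele frequency is therefore
  `pathogenic_allele_freq × (mixture mass on pathogenic-class motifs)`,
  and `expected_frequencies` returns the resulting closed forms per
  inheritance mode.
- **Lower-bound noise**: with probability `p_identical` per allele the
  lower bound equals the point estimate (defaults 0.9702 for allele 1,
  0.9413 for allele 2, matching observed short-read discordance rates);
  otherwise the bound falls short by a shifted-geometric offset ≥ 1
  calibrated to the observed medians (6 for allele 1, truncated at 251;
  5 for allele 2, truncated at 267) and floored at zero. The geometric
  family is a modelling choice — the data pin only median, range and mean —
  and is configurable. Allele-level noise probabilities are applied
  independently per allele index after sorting alleles ascending (the
  caller convention).
- Identical config + seed ⇒ byte-identical output.

Truth labels are recomputed from the *true* (pre-noise) alleles by a
straight-line statement of the inheritance rule, and the test suite checks
that feeding true alleles through the real classifier reproduces them
exactly.

**What passing these tests shows** — that classification, aggregation and
intervals are correct for calls with this statistical structure — and what
it does not: real cohorts add somatic mosaicism, interruption effects,
locus-specific genotyping artefacts, ancestry structure and
non-independent alleles, none of which the generator models. Mutational
dynamics (anticipation) and read-level simulation are out of scope.

## Problem sizes in validation

Fixture cohorts use the published category counts directly (429/446 and
52/48 individuals). Simulation-based checks run at 18,500 individuals (the
population-cohort scale) for point recovery and 4,000 per inheritance mode
for the per-mode recovery tests; interval coverage at the 1,000-individual
size is computed exactly over the binomial support (the deterministic
expectation of any replicate study) rather than by Monte Carlo, with a
seeded 2,000-replicate Monte Carlo retained at the 18,500 scale. Noise
calibration is measured on 100,000 simulated alleles per allele index.

## Known limitations

- Classification trusts the catalog's single effective inheritance mode per
  locus; compound heterozygosity with non-TR variants is invisible.
- No liftover: coordinates must be supplied per build.
- The PG/prevalence comparison treats literature prevalence as a point
  value; its own uncertainty is not propagated.
- `summarize_catalog` counts a locus once per annotated genomic context, so
  context-stratified counts can exceed the locus count when transcripts
  disagree.
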