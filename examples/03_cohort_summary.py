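"""Cohort pathogenic-genotype frequencies at an X-linked recessive locus.

Reconstructs a published-style DMD screening: 429 males of whom 28 carry an
expanded allele, and 446 females with 4 expanded-homozygous and 21
expanded-heterozygous genotypes. Classification respects X-linked recessive
inheritance (hemizygous males need one pathogenic allele, females two; one
makes a carrier), and each percentage gets a 95% Wilson interval.
Run:  python examples/03_cohort_summary.py
"""

from strscreen import (
    GenotypeCall,
    LocusRecord,
    MotifEntry,
    classify_cohort,
    compare_to_prevalence,
    stratify,
)

dmd = LocusRecord(
    locus_id="DMD_DMD", gene="DMD", chrom="chrX", strand="-",
    motif_len=3, reference_motif="GAA",
    motifs=[MotifEntry(motif="GAA", orientation="reference", motif_class="pathogenic")],
    inheritance="XLR", pathogenic_min=59,
)

calls = []
for i in range(429):  # males, hemizygous
    size = 69 if i < 28 else 20
    calls.append(GenotypeCall(f"m{i}", "DMD_DMD", sex="male",
                              allele1_size=size, allele1_lower=size, allele1_motif="GAA"))
for i in range(446):  # females, diploid
    sizes = (69, 69) if i < 4 else ((20, 69) if i < 25 else (20, 20))
    calls.append(GenotypeCall(f"f{i}", "DMD_DMD", sex="female",
                              allele1_size=sizes[0], allele1_lower=sizes[0], allele1_motif="GAA",
                              allele2_size=sizes[1], allele2_lower=sizes[1], allele2_motif="GAA"))

summary = stratify(classify_cohort(calls, dmd), "sex", dmd)
for sex, sub in summary.strata.items():
    print(
        f"{sex}: {sub.n_pg}/{sub.n_genotyped} PG = {sub.pg_pct:.2f}% "
        f"(95% CI {sub.ci_low:.2f}-{sub.ci_high:.2f}%), carriers {sub.carrier_pct:.2f}%"
    )

# Compare the male PG percentage with the clinical prevalence (< 1 in 10,000
# males = 0.01%): a huge excess argues against the locus causing disease.
males = summary.strata["male"]
record = compare_to_prevalence(males, prevalence_pct=0.01)
print(
    f"male PG vs prevalence 0.01%: concordant={record.concordant}, "
    f"fold difference {record.fold_difference:.0f}x"
)
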