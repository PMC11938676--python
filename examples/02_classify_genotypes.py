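"""Classify individual tandem-repeat genotype calls at a dominant locus.

Builds a Huntington-like CAG locus (pathogenic from 40 repeats, intermediate
27-35) and classifies a handful of calls. The conservative default uses each
allele's lower-bound estimate and requires a curated pathogenic motif.
Run:  python examples/02_classify_genotypes.py
"""

from strscreen import GenotypeCall, LocusRecord, MotifEntry, classify_genotype

htt = LocusRecord(
    locus_id="HTT_HD",
    gene="HTT",
    chrom="chr4",
    strand="+",
    motif_len=3,
    reference_motif="CAG",
    motifs=[
        MotifEntry(motif="CAG", orientation="reference", motif_class="pathogenic"),
        MotifEntry(motif="CAA", orientation="reference", motif_class="benign"),
    ],
    inheritance="AD",
    benign_max=26,
    intermediate_min=27,
    intermediate_max=35,
    pathogenic_min=40,
)

calls = [
    # clearly expanded allele with the pathogenic motif -> pathogenic genotype
    GenotypeCall("P1", "HTT_HD", sex="female", allele1_size=17, allele1_lower=17,
                 allele2_size=45, allele2_lower=42, allele1_motif="CAG", allele2_motif="CAG"),
    # point estimate 41 but lower bound 38: conservative call stays non-pathogenic
    GenotypeCall("P2", "HTT_HD", sex="male", allele1_size=18, allele1_lower=18,
                 allele2_size=41, allele2_lower=38, allele1_motif="CAG", allele2_motif="CAG"),
    # expanded size but benign CAA motif: the motif gate blocks pathogenicity
    GenotypeCall("P3", "HTT_HD", sex="female", allele1_size=20, allele1_lower=20,
                 allele2_size=44, allele2_lower=44, allele1_motif="CAG", allele2_motif="CAA"),
    # intermediate-range allele: non-pathogenic, flagged for review
    GenotypeCall("P4", "HTT_HD", sex="female", allele1_size=21, allele1_lower=21,
                 allele2_size=30, allele2_lower=30, allele1_motif="CAG", allele2_motif="CAG"),
    # degenerate CNG-style motif call: excluded from analysis entirely
    GenotypeCall("P5", "HTT_HD", sex="male", allele1_size=19, allele1_lower=19,
                 allele2_size=50, allele2_lower=50, allele1_motif="CAG", allele2_motif="CNG"),
]

for call in calls:
    result = classify_genotype(call, htt)
    flags = ", ".join(sorted(result.advisory_flags)) or "-"
    sizes = [f.effective_size for f in result.allele_flags]
    print(f"{call.sample_id}: genotype={result.genotype:<12} effective sizes={sizes} flags: {flags}")

# Expected output: P1 pathogenic; P2 none (lower bound below threshold);
# P3 none (benign motif); P4 none + intermediate_range; P5 excluded (CNG).
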