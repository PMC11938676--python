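"""Load a disease-locus catalog, summarize it, and export genotyper inputs.

Uses the small six-locus catalog shipped with the test suite. Run from the
repository root:  python examples/01_catalog_operations.py
"""

from pathlib import Path

from strscreen import (
    emit_bed,
    emit_trgt_definitions,
    filter_by_evidence,
    load_catalog,
    prevalence_to_fraction,
    summarize_catalog,
)

catalog = load_catalog(Path(__file__).parent.parent / "tests" / "data" / "catalog_mini.json")
print(f"loaded {len(catalog)} loci:", ", ".join(r.locus_id for r in catalog))

# Catalog-level counts: how many loci can present in childhood, and the
# motif-length x genomic-context breakdown.
summary = summarize_catalog(catalog)
print(
    f"pediatric onset documented at {summary['pediatric_onset_count']}/{summary['n_loci']} loci "
    f"({100 * summary['pediatric_onset_fraction']:.0f}%)"
)
for (motif_len, context), count in sorted(summary["by_motif_len_and_context"].items()):
    print(f"  {motif_len} bp motif, {context}: {count} loci")

# Evidence filtering: loci below two independent observations lack
# literature consensus and are dropped from figure-level analyses.
kept = filter_by_evidence(catalog, min_independent_obs=2)
dropped = {r.locus_id for r in catalog} - {r.locus_id for r in kept}
print(f"evidence filter (>= 2 observations) removes: {sorted(dropped)}")

# Prevalence statements are normalized to a single fraction (ranges are
# averaged), e.g. the Huntington-disease literature range:
frac = prevalence_to_fraction("0.0106-0.0137%")
print(f"prevalence '0.0106-0.0137%' -> fraction {frac:.4g} (= {100 * frac:.4f}%)")

# BED and TRGT repeat-definition exports for one genome build.
print("\nhg38 BED:")
print(emit_bed(catalog, "hg38"), end="")
print("\nTRGT definitions (first two lines):")
print("".join(emit_trgt_definitions(catalog, "hg38").splitlines(keepends=True)[:2]), end="")
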