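"""Genotype classification under locus thresholds, motifs, and inheritance.

The central check is oracle equivalence: an independent straight-line
reference implementation of the inheritance rules, written here from the
genetics (dominant: one pathogenic allele; recessive: two, one makes a
carrier; hemizygous males at X loci: one), is compared with
``classify_genotype`` over the exhaustive grid of inheritance x sex x
ploidy x allele size band x motif class.
"""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strscreen import (
    ClassificationPolicy,
    GenotypeCall,
    MotifEntry,
    allele_category,
    apply_locus_exclusions,
    classify_allele,
    classify_genotype,
    effective_allele_size,
)
from strscreen.classify import AbsentAlleleError, read_genotype_table, write_genotype_table

from .conftest import make_locus


def xlr_locus(**overrides):
    kwargs = dict(
        locus_id="DMD_DMD",
        gene="DMD",
        chrom="chrX",
        inheritance="XLR",
        pathogenic_min=59,
        benign_max=None,
        intermediate_min=None,
        intermediate_max=None,
        motifs=[MotifEntry(motif="GAA", orientation="reference", motif_class="pathogenic")],
        reference_motif="GAA",
    )
    kwargs.update(overrides)
    return make_locus(**kwargs)


def call_for(locus, sizes, motifs=None, sex="female", lowers=None):
    motifs = motifs or [locus.reference_motif] * len(sizes)
    lowers = lowers or sizes
    kwargs = dict(
        sample_id="s",
        locus_id=locus.locus_id,
        sex=sex,
        allele1_size=sizes[0],
        allele1_lower=lowers[0],
        allele1_motif=motifs[0],
    )
    if len(sizes) == 2:
        kwargs.update(
            allele2_size=sizes[1], allele2_lower=lowers[1], allele2_motif=motifs[1]
        )
    return GenotypeCall(**kwargs)


class TestEffectiveAlleleSize:
    def test_lower_bound_preferred(self):
        call = GenotypeCall(
            sample_id="s", locus_id="L", allele1_size=45, allele1_lower=42
        )
        assert effective_allele_size(call, 1, use_lower_bound=True) == 42
        assert effective_allele_size(call, 1, use_lower_bound=False) == 45

    def test_identical_estimates(self):
        call = GenotypeCall(sample_id="s", locus_id="L", allele1_size=45, allele1_lower=45)
        assert effective_allele_size(call, 1) == 45

    def test_missing_lower_falls_back_to_point(self):
        call = GenotypeCall(sample_id="s", locus_id="L", allele1_size=45)
        assert effective_allele_size(call, 1, use_lower_bound=True) == 45

    def test_absent_allele_errors(self):
        call = GenotypeCall(sample_id="s", locus_id="L", allele1_size=45)
        with pytest.raises(AbsentAlleleError):
            effective_allele_size(call, 2)


class TestAlleleCategory:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (42, "pathogenic_size"),
            (40, "pathogenic_size"),  # threshold is inclusive
            (39, "normal"),  # just below
            (30, "intermediate"),
            (26, "normal"),
        ],
    )
    def test_htt_like_bands(self, size, expected):
        assert allele_category(size, make_locus()) == expected

    def test_dmd_boundary(self):
        assert allele_category(59, xlr_locus()) == "pathogenic_size"
        assert allele_category(58, xlr_locus()) == "normal"


class TestClassifyAllele:
    @pytest.mark.parametrize(
        "motif,size,pathogenic,advisory",
        [
            ("CAG", 45, True, set()),
            ("CAA", 45, False, set()),  # benign motif gates pathogenicity
            ("CCG", 45, False, {"uncertain_motif"}),  # unknown motif + expanded size
            ("CCG", 20, False, set()),  # unknown motif, normal size: no advisory
            ("CAG", 30, False, {"intermediate_range"}),
        ],
    )
    def test_size_and_motif_gate(self, motif, size, pathogenic, advisory):
        locus = make_locus()
        call = call_for(locus, [size], motifs=[motif], sex="female")
        flags, advisories = classify_allele(call, 1, locus)
        assert flags.pathogenic is pathogenic
        assert advisories == advisory

    def test_truth_table_over_category_and_motif_class(self):
        """Pathogenic iff (pathogenic size) AND (pathogenic motif class):
        checked against explicit enumeration of the 3x4 grid."""
        locus = make_locus(
            motifs=[
                MotifEntry(motif="CAG", orientation="reference", motif_class="pathogenic"),
                MotifEntry(motif="CAA", orientation="reference", motif_class="benign"),
                MotifEntry(motif="CGA", orientation="reference", motif_class="uncertain"),
            ]
        )
        sizes = {"normal": 10, "intermediate": 30, "pathogenic_size": 45}
        motifs = {"pathogenic": "CAG", "benign": "CAA", "uncertain": "CGA", "unknown": "CCG"}
        for (cat, size), (mclass, motif) in itertools.product(sizes.items(), motifs.items()):
            flags, _ = classify_allele(call_for(locus, [size], motifs=[motif]), 1, locus)
            assert flags.pathogenic == (cat == "pathogenic_size" and mclass == "pathogenic")
            assert flags.category == cat
            assert flags.motif_class == mclass

    def test_missing_motif_reference_vs_strict(self):
        locus = make_locus()
        call = GenotypeCall(
            sample_id="s", locus_id=locus.locus_id, sex="female", allele1_size=45, allele1_lower=45
        )
        flags, _ = classify_allele(call, 1, locus, ClassificationPolicy(missing_motif="reference"))
        assert flags.pathogenic
        flags, _ = classify_allele(call, 1, locus, ClassificationPolicy(missing_motif="strict"))
        assert not flags.pathogenic and flags.motif_class == "unknown"


def reference_classifier(inheritance, sex, n_alleles, n_pathogenic):
    """Independent straight-line statement of the inheritance rules."""
    if inheritance in ("AD", "XLD"):
        return "pathogenic" if n_pathogenic >= 1 else "none"
    if inheritance == "AR":
        if n_alleles < 2:
            return "unclassifiable"
        if n_pathogenic == 2:
            return "pathogenic"
        if n_pathogenic == 1:
            return "carrier"
        return "none"
    # XLR
    if sex == "male":
        return "pathogenic" if n_pathogenic >= 1 else "none"
    if n_alleles < 2:
        return "unclassifiable"
    if n_pathogenic == 2:
        return "pathogenic"
    if n_pathogenic == 1:
        return "carrier"
    return "none"


class TestClassifyGenotype:
    def test_exhaustive_grid_matches_reference(self):
        """classify_genotype equals the independent reference over all
        inheritance x sex x ploidy x pathogenic-allele-count combinations."""
        checked = 0
        for inheritance in ("AD", "AR", "XLD", "XLR"):
            x_linked = inheritance in ("XLD", "XLR")
            locus = (
                xlr_locus(inheritance=inheritance)
                if x_linked
                else make_locus(inheritance=inheritance)
            )
            pmin = locus.pathogenic_min
            for sex in ("male", "female"):
                for n_alleles in (1, 2):
                    if x_linked and sex == "male" and n_alleles == 2:
                        continue  # handled by the ploidy-warning test
                    for n_patho in range(n_alleles + 1):
                        sizes = [pmin + 5] * n_patho + [10] * (n_alleles - n_patho)
                        sizes.sort()
                        call = call_for(locus, sizes, sex=sex)
                        got = classify_genotype(call, locus).genotype
                        assert got == reference_classifier(
                            inheritance, sex, n_alleles, n_patho
                        ), (inheritance, sex, n_alleles, n_patho)
                        checked += 1
        assert checked >= 24

    def test_xlr_male_one_allele_pathogenic(self):
        locus = xlr_locus()
        cg = classify_genotype(call_for(locus, [70], sex="male"), locus)
        assert cg.genotype == "pathogenic"

    def test_xlr_female_one_pathogenic_allele_is_carrier(self):
        locus = xlr_locus()
        cg = classify_genotype(call_for(locus, [20, 70], sex="female"), locus)
        assert cg.genotype == "carrier"

    def test_unknown_sex_at_x_locus_unclassifiable(self):
        locus = xlr_locus()
        call = call_for(locus, [70, 70], sex="unknown")
        assert classify_genotype(call, locus).genotype == "unclassifiable"

    def test_diploid_male_at_x_locus_uses_larger_allele(self):
        locus = xlr_locus()
        call = call_for(locus, [20, 70], sex="male")
        cg = classify_genotype(call, locus)
        assert cg.genotype == "pathogenic"
        assert "ploidy_warning" in cg.advisory_flags
        assert len(cg.allele_flags) == 1 and cg.allele_flags[0].effective_size == 70

    def test_intermediate_advisory_propagates(self):
        locus = make_locus()
        cg = classify_genotype(call_for(locus, [30, 45], sex="female"), locus)
        assert cg.genotype == "pathogenic"
        assert "intermediate_range" in cg.advisory_flags

    def test_inheritance_override(self):
        locus = make_locus(inheritance="AR")
        policy = ClassificationPolicy(inheritance_override={locus.locus_id: "AD"})
        cg = classify_genotype(call_for(locus, [20, 45], sex="female"), locus, policy)
        assert cg.genotype == "pathogenic"

    def test_pathogenic_min_override(self):
        locus = make_locus()
        policy = ClassificationPolicy(pathogenic_min_override={locus.locus_id: 36})
        cg = classify_genotype(call_for(locus, [20, 38], sex="female"), locus, policy)
        assert cg.genotype == "pathogenic"

    @given(
        st.integers(min_value=0, max_value=100),
        st.integers(min_value=0, max_value=100),
        st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=150, derandomize=True)
    def test_monotone_in_allele_size(self, s1, s2, bump):
        """Growing any allele never moves the label away from pathogenic."""
        rank = {"none": 0, "carrier": 1, "pathogenic": 2}
        locus = make_locus(inheritance="AR")
        lo, hi = sorted((s1, s2))
        base = classify_genotype(call_for(locus, [lo, hi]), locus).genotype
        grown = classify_genotype(call_for(locus, sorted([lo, hi + bump])), locus).genotype
        assert rank[grown] >= rank[base]

    def test_lower_bounds_never_increase_pg(self):
        locus = make_locus()
        call = call_for(locus, [45, 45], lowers=[38, 45])
        with_lower = classify_genotype(call, locus, ClassificationPolicy(use_lower_bound=True))
        with_point = classify_genotype(call, locus, ClassificationPolicy(use_lower_bound=False))
        n_lower = sum(f.pathogenic for f in with_lower.allele_flags)
        n_point = sum(f.pathogenic for f in with_point.allele_flags)
        assert n_lower <= n_point


class TestExclusions:
    def test_degenerate_motif_call_excluded(self):
        locus = make_locus()
        call = call_for(locus, [45, 45], motifs=["CNG", "CAG"])
        cg = classify_genotype(call, locus)
        assert cg.genotype == "excluded"
        assert "excluded_CNG" in cg.advisory_flags

    def test_config_excluded_locus(self):
        locus = make_locus()
        policy = ClassificationPolicy(excluded_locus_ids=frozenset({locus.locus_id}))
        cg = classify_genotype(call_for(locus, [45, 45]), locus, policy)
        assert cg.genotype == "excluded"
        assert "excluded_unreliable_locus" in cg.advisory_flags

    def test_contraction_locus_skipped(self):
        locus = make_locus(flags={"contraction_locus"})
        cg = classify_genotype(call_for(locus, [45, 45]), locus)
        assert cg.genotype == "excluded"
        assert "contraction_locus_skipped" in cg.advisory_flags

    def test_ordinary_call_passes_prefilter(self):
        locus = make_locus()
        calls = [
            call_for(locus, [45, 45], motifs=["CNG", "CAG"]),
            call_for(locus, [20, 20]),
        ]
        out = apply_locus_exclusions(calls, locus)
        assert getattr(out[0], "genotype", None) == "excluded"
        assert out[1] is calls[1]


class TestGenotypeTableIO:
    def test_round_trip(self, tmp_path):
        locus = make_locus()
        calls = [
            call_for(locus, [20, 45], sex="female"),
            GenotypeCall(sample_id="m1", locus_id=locus.locus_id, sex="male", allele1_size=41),
        ]
        path = tmp_path / "calls.tsv"
        write_genotype_table(calls, path)
        assert read_genotype_table(path) == calls

    def test_missing_optional_columns_tolerated(self, tmp_path):
        path = tmp_path / "minimal.tsv"
        path.write_text("sample_id\tlocus_id\tallele1_size\ns1\tHTT_HD\t45\n")
        calls = read_genotype_table(path)
        assert calls[0].sex == "unknown" and calls[0].allele2_size is None

    def test_missing_required_column_errors(self, tmp_path):
        path = tmp_path / "broken.tsv"
        path.write_text("sample_id\tallele1_size\ns1\t45\n")
        with pytest.raises(ValueError, match="locus_id"):
            read_genotype_table(path)
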