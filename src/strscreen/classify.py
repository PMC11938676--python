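"""Inheritance-aware classification of per-individual tandem-repeat genotypes.

A genotype call carries, per allele, a point estimate of repeat count, a
lower-bound estimate, and the genotyped motif. Classification is conservative
by default: the lower bound is used (short-read genotypers tend to
overestimate when they err), and an allele only counts as pathogenic when its
size reaches the locus pathogenic threshold AND its motif matches a curated
pathogenic motif. Genotype-level labels then follow the locus inheritance
mode:

* AD / XLD: one pathogenic allele suffices.
* AR: two pathogenic alleles; exactly one makes a carrier.
* XLR: one pathogenic allele in hemizygous males; females need two
  (one makes a carrier).

Calls at loci flagged unreliable, with degenerate ("CNG"-style) motif calls,
or at contraction-mechanism loci are marked excluded and never reach the
cohort denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd

from .catalog import LocusRecord
from .motifs import MotifClass, classify_motif, is_excluded_motif

logger = logging.getLogger(__name__)

Sex = Literal["male", "female", "unknown"]
AlleleCategory = Literal["normal", "intermediate", "pathogenic_size"]
GenotypeLabel = Literal["pathogenic", "carrier", "none", "excluded", "unclassifiable"]

ADVISORY_FLAGS = (
    "intermediate_range",
    "uncertain_motif",
    "excluded_CNG",
    "excluded_unreliable_locus",
    "contraction_locus_skipped",
    "above_pathogenic_max",
    "ploidy_warning",
)


class AbsentAlleleError(ValueError):
    """Requested allele is not present on the call (hemizygous)."""


@dataclass(frozen=True)
class GenotypeCall:
    """One individual x locus tandem-repeat call.

    Sizes are repeat units. ``allele2_*`` fields are None for hemizygous
    calls (e.g. male X). ``allele*_lower`` is the genotyper's lower-bound
    estimate; None means not reported.
    """

    sample_id: str
    locus_id: str
    sex: Sex = "unknown"
    population: Optional[str] = None
    allele1_size: int = 0
    allele1_lower: Optional[int] = None
    allele2_size: Optional[int] = None
    allele2_lower: Optional[int] = None
    allele1_motif: Optional[str] = None
    allele2_motif: Optional[str] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.allele1_size < 0 or (self.allele2_size is not None and self.allele2_size < 0):
            raise ValueError("allele sizes must be >= 0")
        if self.allele1_lower is not None and self.allele1_lower > self.allele1_size:
            raise ValueError("allele1_lower exceeds allele1_size")
        if (
            self.allele2_lower is not None
            and self.allele2_size is not None
            and self.allele2_lower > self.allele2_size
        ):
            raise ValueError("allele2_lower exceeds allele2_size")
        if self.allele2_size is None and self.allele2_lower is not None:
            raise ValueError("allele2_lower given for an absent allele 2")

    @property
    def is_hemizygous(self) -> bool:
        return self.allele2_size is None

    def allele_indices(self) -> tuple[int, ...]:
        return (1,) if self.is_hemizygous else (1, 2)


@dataclass(frozen=True)
class ClassificationPolicy:
    """Tunable classification behaviour.

    use_lower_bound
        Use the allele lower-bound estimate instead of the point estimate
        (conservative default).
    allow_revcomp
        Accept reverse-complement motif matches (off by default: catalogs
        carry both orientations explicitly).
    missing_motif
        "reference": an allele without a genotyped motif is assumed to carry
        the locus reference motif (common for short-read catalogs that omit
        per-allele motif); "strict": treated as unknown, hence never
        pathogenic.
    excluded_locus_ids
        Loci whose calls are excluded wholesale after manual review.
    pathogenic_min_override / inheritance_override
        Per-locus substitutions, e.g. for re-running under another study's
        thresholds or resolving ambiguous inheritance.
    """

    use_lower_bound: bool = True
    allow_revcomp: bool = False
    missing_motif: Literal["reference", "strict"] = "reference"
    excluded_locus_ids: frozenset[str] = frozenset()
    pathogenic_min_override: dict[str, int] = field(default_factory=dict)
    inheritance_override: dict[str, str] = field(default_factory=dict)

    def pathogenic_min(self, locus: LocusRecord) -> int:
        return self.pathogenic_min_override.get(locus.locus_id, locus.pathogenic_min)

    def inheritance(self, locus: LocusRecord) -> str:
        return self.inheritance_override.get(locus.locus_id, locus.inheritance)


DEFAULT_POLICY = ClassificationPolicy()


@dataclass(frozen=True)
class AlleleFlags:
    """Per-allele classification outcome."""

    allele_index: int
    effective_size: int
    category: AlleleCategory
    motif_class: MotifClass
    pathogenic: bool


@dataclass(frozen=True)
class ClassifiedGenotype:
    """Genotype-level classification with per-allele detail and advisories."""

    sample_id: str
    locus_id: str
    sex: Sex
    population: Optional[str]
    genotype: GenotypeLabel
    allele_flags: tuple[AlleleFlags, ...] = ()
    advisory_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.genotype == "excluded" and not (
            self.advisory_flags
            & {"excluded_CNG", "excluded_unreliable_locus", "contraction_locus_skipped"}
        ):
            raise ValueError("excluded genotype requires an exclusion flag")


def effective_allele_size(
    call: GenotypeCall, allele_index: int, use_lower_bound: bool = True
) -> int:
    """Size used for classification: the lower bound when requested and
    reported, else the point estimate (with a logged fallback)."""
    if allele_index == 1:
        size, lower = call.allele1_size, call.allele1_lower
    elif allele_index == 2:
        if call.allele2_size is None:
            raise AbsentAlleleError(
                f"{call.sample_id}@{call.locus_id}: allele 2 absent (hemizygous call)"
            )
        size, lower = call.allele2_size, call.allele2_lower
    else:
        raise ValueError(f"allele_index must be 1 or 2, got {allele_index}")
    if use_lower_bound:
        if lower is None:
            logger.debug(
                "%s@%s allele %d: no lower bound reported, using point estimate",
                call.sample_id,
                call.locus_id,
                allele_index,
            )
            return size
        return lower
    return size


def allele_category(size: int, locus: LocusRecord, pathogenic_min: Optional[int] = None) -> AlleleCategory:
    """Size band of an allele: pathogenic_size (>= pathogenic_min),
    intermediate (within the curated intermediate band), or normal."""
    pmin = locus.pathogenic_min if pathogenic_min is None else pathogenic_min
    if pmin is None:
        raise ValueError(f"locus {locus.locus_id}: pathogenic_min is required")
    if size >= pmin:
        return "pathogenic_size"
    if (
        locus.intermediate_min is not None
        and locus.intermediate_min <= size < pmin
        and (locus.intermediate_max is None or size <= locus.intermediate_max)
    ):
        return "intermediate"
    return "normal"


def _allele_motif(call: GenotypeCall, allele_index: int) -> Optional[str]:
    return call.allele1_motif if allele_index == 1 else call.allele2_motif


def classify_allele(
    call: GenotypeCall,
    allele_index: int,
    locus: LocusRecord,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> tuple[AlleleFlags, set[str]]:
    """Classify one allele; returns its flags and any advisories raised.

    Pathogenic requires pathogenic size AND a curated pathogenic motif.
    A pathogenic-sized allele with an uncertain/unknown motif is not
    pathogenic but raises the ``uncertain_motif`` advisory.
    """
    size = effective_allele_size(call, allele_index, policy.use_lower_bound)
    category = allele_category(size, locus, policy.pathogenic_min(locus))
    motif = _allele_motif(call, allele_index)
    if motif is None:
        if policy.missing_motif == "reference":
            logger.debug(
                "%s@%s allele %d: no motif genotyped, assuming locus reference motif",
                call.sample_id,
                call.locus_id,
                allele_index,
            )
            motif = locus.reference_motif
            motif_class = classify_motif(motif, locus, allow_revcomp=policy.allow_revcomp)
        else:
            motif_class = "unknown"
    else:
        motif_class = classify_motif(motif, locus, allow_revcomp=policy.allow_revcomp)

    pathogenic = category == "pathogenic_size" and motif_class == "pathogenic"
    advisories: set[str] = set()
    if category == "intermediate":
        advisories.add("intermediate_range")
    if category == "pathogenic_size" and motif_class in ("uncertain", "unknown"):
        advisories.add("uncertain_motif")
    if locus.pathogenic_max is not None and size > locus.pathogenic_max:
        advisories.add("above_pathogenic_max")
    return AlleleFlags(allele_index, size, category, motif_class, pathogenic), advisories


def _check_exclusion(
    call: GenotypeCall, locus: LocusRecord, policy: ClassificationPolicy
) -> Optional[str]:
    if locus.locus_id in policy.excluded_locus_ids or "excluded_unreliable" in locus.flags:
        return "excluded_unreliable_locus"
    if "contraction_locus" in locus.flags:
        return "contraction_locus_skipped"
    motifs = [m for m in (call.allele1_motif, call.allele2_motif) if m is not None]
    if any(is_excluded_motif(m) for m in motifs):
        return "excluded_CNG"
    return None


def classify_genotype(
    call: GenotypeCall,
    locus: LocusRecord,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> ClassifiedGenotype:
    """Classify one genotype call under the locus inheritance mode.

    Exclusion rules are evaluated first. Unknown sex at an X-linked locus is
    routed to the ``unclassifiable`` bucket (counted, never silently
    dropped), as is a single-allele call at an autosomal recessive locus
    (the recessive rule is defined for individuals with two genotyped
    alleles). A diploid male call at an X locus raises a ploidy warning and
    is treated as hemizygous for the larger effective allele.
    """
    if call.locus_id != locus.locus_id:
        raise ValueError(f"call locus {call.locus_id!r} != catalog locus {locus.locus_id!r}")

    exclusion = _check_exclusion(call, locus, policy)
    if exclusion is not None:
        return ClassifiedGenotype(
            sample_id=call.sample_id,
            locus_id=call.locus_id,
            sex=call.sex,
            population=call.population,
            genotype="excluded",
            advisory_flags=frozenset({exclusion}),
        )

    inheritance = policy.inheritance(locus)
    x_linked = inheritance in ("XLD", "XLR")
    advisories: set[str] = set()

    if x_linked and call.sex == "unknown":
        return ClassifiedGenotype(
            sample_id=call.sample_id,
            locus_id=call.locus_id,
            sex=call.sex,
            population=call.population,
            genotype="unclassifiable",
            advisory_flags=frozenset(),
        )

    effective_call = call
    if x_linked and call.sex == "male" and not call.is_hemizygous:
        advisories.add("ploidy_warning")
        s1 = effective_allele_size(call, 1, policy.use_lower_bound)
        s2 = effective_allele_size(call, 2, policy.use_lower_bound)
        keep = 1 if s1 >= s2 else 2
        effective_call = replace(
            call,
            allele1_size=call.allele1_size if keep == 1 else call.allele2_size,
            allele1_lower=call.allele1_lower if keep == 1 else call.allele2_lower,
            allele1_motif=call.allele1_motif if keep == 1 else call.allele2_motif,
            allele2_size=None,
            allele2_lower=None,
            allele2_motif=None,
        )

    flags: list[AlleleFlags] = []
    for idx in effective_call.allele_indices():
        af, adv = classify_allele(effective_call, idx, locus, policy)
        flags.append(af)
        advisories |= adv

    n_alleles = len(flags)
    p = sum(f.pathogenic for f in flags)

    if inheritance == "AD" or inheritance == "XLD":
        genotype: GenotypeLabel = "pathogenic" if p >= 1 else "none"
    elif inheritance == "AR":
        if n_alleles < 2:
            genotype = "unclassifiable"
        elif p == 2:
            genotype = "pathogenic"
        elif p == 1:
            genotype = "carrier"
        else:
            genotype = "none"
    elif inheritance == "XLR":
        if call.sex == "male":
            genotype = "pathogenic" if p >= 1 else "none"
        else:  # female
            if n_alleles < 2:
                genotype = "unclassifiable"
            elif p == 2:
                genotype = "pathogenic"
            elif p == 1:
                genotype = "carrier"
            else:
                genotype = "none"
    else:  # pragma: no cover - inheritance is validated at catalog load
        raise ValueError(f"unknown inheritance mode {inheritance!r}")

    return ClassifiedGenotype(
        sample_id=call.sample_id,
        locus_id=call.locus_id,
        sex=call.sex,
        population=call.population,
        genotype=genotype,
        allele_flags=tuple(flags),
        advisory_flags=frozenset(advisories),
    )


def apply_locus_exclusions(
    calls: Iterable[GenotypeCall],
    locus: LocusRecord,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> list[ClassifiedGenotype | GenotypeCall]:
    """Pre-pass exclusion filter: returns excluded ClassifiedGenotypes for
    calls hitting an exclusion rule and the original calls otherwise."""
    out: list[ClassifiedGenotype | GenotypeCall] = []
    for call in calls:
        reason = _check_exclusion(call, locus, policy)
        if reason is None:
            out.append(call)
        else:
            out.append(
                ClassifiedGenotype(
                    sample_id=call.sample_id,
                    locus_id=call.locus_id,
                    sex=call.sex,
                    population=call.population,
                    genotype="excluded",
                    advisory_flags=frozenset({reason}),
                )
            )
    return out


def classify_cohort(
    calls: Iterable[GenotypeCall],
    loci: dict[str, LocusRecord] | LocusRecord,
    policy: ClassificationPolicy = DEFAULT_POLICY,
) -> list[ClassifiedGenotype]:
    """Classify a batch of calls against one locus or a locus_id -> record map."""
    if isinstance(loci, LocusRecord):
        loci = {loci.locus_id: loci}
    return [classify_genotype(call, loci[call.locus_id], policy) for call in calls]


# ---------------------------------------------------------------------------
# TSV interchange

GENOTYPE_COLUMNS = [
    "sample_id",
    "sex",
    "population",
    "locus_id",
    "allele1_size",
    "allele1_lower",
    "allele2_size",
    "allele2_lower",
    "allele1_motif",
    "allele2_motif",
    "quality",
]

_OPTIONAL_COLUMNS = {
    "sex": "unknown",
    "population": None,
    "allele1_lower": None,
    "allele2_size": None,
    "allele2_lower": None,
    "allele1_motif": None,
    "allele2_motif": None,
    "quality": None,
}


def read_genotype_table(path: str | Path) -> list[GenotypeCall]:
    """Read genotype calls from the documented TSV dialect; missing optional
    columns are tolerated and filled with their defaults."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    missing_required = {"sample_id", "locus_id", "allele1_size"} - set(df.columns)
    if missing_required:
        raise ValueError(f"genotype table lacks required columns: {sorted(missing_required)}")
    for col, default in _OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            GenotypeCall(
                sample_id=str(row.sample_id),
                locus_id=str(row.locus_id),
                sex=row.sex if pd.notna(row.sex) else "unknown",
                population=row.population if pd.notna(row.population) else None,
                allele1_size=int(row.allele1_size),
                allele1_lower=int(row.allele1_lower) if pd.notna(row.allele1_lower) else None,
                allele2_size=int(row.allele2_size) if pd.notna(row.allele2_size) else None,
                allele2_lower=int(row.allele2_lower) if pd.notna(row.allele2_lower) else None,
                allele1_motif=row.allele1_motif if pd.notna(row.allele1_motif) else None,
                allele2_motif=row.allele2_motif if pd.notna(row.allele2_motif) else None,
                quality=float(row.quality) if pd.notna(row.quality) else None,
            )
        )
    return calls


def genotype_table_to_frame(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls], columns=GENOTYPE_COLUMNS)


def write_genotype_table(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    genotype_table_to_frame(calls).to_csv(path, sep="\t", index=False)


def classified_to_frame(classified: Iterable[ClassifiedGenotype]) -> pd.DataFrame:
    """Flatten classified genotypes to a table (one row per call)."""
    rows = []
    for cg in classified:
        by_idx = {f.allele_index: f for f in cg.allele_flags}
        rows.append(
            {
                "sample_id": cg.sample_id,
                "locus_id": cg.locus_id,
                "sex": cg.sex,
                "population": cg.population,
                "genotype": cg.genotype,
                "n_pathogenic_alleles": sum(f.pathogenic for f in cg.allele_flags),
                "allele1_category": by_idx[1].category if 1 in by_idx else None,
                "allele2_category": by_idx[2].category if 2 in by_idx else None,
                "advisory_flags": ",".join(sorted(cg.advisory_flags)),
            }
        )
    return pd.DataFrame(rows)


def write_classified_table(classified: Iterable[ClassifiedGenotype], path: str | Path) -> None:
    classified_to_frame(classified).to_csv(path, sep="\t", index=False)
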