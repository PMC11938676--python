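"""Reading, validating, summarizing, and exporting disease-locus catalogs.

The catalog is a JSON document of curated tandem-repeat disease loci in the
style of STRchive: per-build coordinates, strand, curated motifs with
pathogenicity classes, allele-size thresholds in repeat units, inheritance
mode, prevalence, and evidence counts. Coordinates are stored 0-based
half-open (BED-native); files written 1-based declare it via the
``coordinate_system`` header field and are converted at load.

Size thresholds are stored canonically in repeat units. Literature sources
often quote them in bp; :func:`bp_to_repeats` / :func:`repeats_to_bp` convert
via the motif length.
"""

from __future__ import annotations

import json
import logging
import math
import re
from collections import Counter
from pathlib import Path
from typing import Any, Iterable, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .motifs import MOTIF_ALPHABET, canonical_rotation, reverse_complement

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

Build = Literal["hg19", "hg38", "T2T-chm13"]
BUILDS: tuple[str, ...] = ("hg19", "hg38", "T2T-chm13")
# "hg37" appears in some sources as an alias for GRCh37/hg19
_BUILD_ALIASES = {"hg37": "hg19", "GRCh37": "hg19", "GRCh38": "hg38", "chm13": "T2T-chm13"}

Inheritance = Literal["AD", "AR", "XLD", "XLR"]
GenomicContext = Literal["coding", "5'UTR", "3'UTR", "intronic", "promoter", "intergenic"]
LocusFlag = Literal[
    "preliminary", "conflicting_evidence", "contraction_locus", "excluded_unreliable"
]


class CatalogError(Exception):
    """Base class for catalog problems."""


class CatalogParseError(CatalogError):
    """File does not parse as the documented catalog schema."""


class CatalogValidationError(CatalogError):
    """One or more records violate the schema; lists every violation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            f"{len(violations)} catalog validation error(s):\n  " + "\n  ".join(violations)
        )


class MotifEntry(BaseModel):
    """One curated motif at a locus with its clinical classification."""

    model_config = ConfigDict(extra="allow", populate_by_name=True)

    motif: str = Field(min_length=1)
    orientation: Literal["reference", "gene"] = "reference"
    motif_class: Literal["benign", "pathogenic", "uncertain", "unknown"] = Field(
        alias="class", default="unknown"
    )

    @model_validator(mode="after")
    def _check_alphabet(self) -> "MotifEntry":
        self.motif = self.motif.upper()
        bad = set(self.motif) - MOTIF_ALPHABET
        if bad:
            raise ValueError(f"motif {self.motif!r} has invalid characters {sorted(bad)}")
        return self


class LocusRecord(BaseModel):
    """One curated tandem-repeat disease locus.

    Coordinates are 0-based half-open per genome build. Thresholds
    (``benign_max``, ``intermediate_min``/``max``, ``pathogenic_min``/``max``)
    are in repeat units; ``pathogenic_min`` is the smallest allele size
    classified as pathogenic. Unknown input fields are preserved (pydantic
    ``extra="allow"``) so a load -> serialize -> load round trip is lossless.
    """

    model_config = ConfigDict(extra="allow", populate_by_name=True)

    locus_id: str
    gene: str
    chrom: str
    start_by_build: dict[str, int] = Field(default_factory=dict)
    end_by_build: dict[str, int] = Field(default_factory=dict)
    strand: Literal["+", "-"]
    motif_len: int = Field(ge=1)
    reference_motif: str
    motifs: list[MotifEntry] = Field(default_factory=list)
    locus_structure: str = ""  # opaque repeat-composition pattern, pass-through
    inheritance: Inheritance
    benign_max: Optional[int] = None
    intermediate_min: Optional[int] = None
    intermediate_max: Optional[int] = None
    pathogenic_min: int = Field(ge=1)
    pathogenic_max: Optional[int] = None
    prevalence_fraction: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    prevalence_note: str = ""
    independent_observations: int = Field(default=0, ge=0)
    onset_min_years: Optional[float] = None
    onset_max_years: Optional[float] = None
    typical_onset_min: Optional[float] = None
    typical_onset_max: Optional[float] = None
    genomic_context: list[GenomicContext] = Field(default_factory=list)
    flags: set[LocusFlag] = Field(default_factory=set)

    @model_validator(mode="after")
    def _validate(self) -> "LocusRecord":
        problems: list[str] = []
        self.start_by_build = {_BUILD_ALIASES.get(b, b): v for b, v in self.start_by_build.items()}
        self.end_by_build = {_BUILD_ALIASES.get(b, b): v for b, v in self.end_by_build.items()}
        for build in self.start_by_build:
            if build not in BUILDS:
                problems.append(f"unknown build {build!r}")
        for build, start in self.start_by_build.items():
            end = self.end_by_build.get(build)
            if end is None:
                problems.append(f"build {build}: start without end")
                continue
            if start < 0:
                problems.append(f"build {build}: negative start {start}")
            if not start < end:
                problems.append(f"build {build}: start {start} !< end {end}")
            elif end - start < self.motif_len:
                problems.append(
                    f"build {build}: interval {end - start} bp shorter than motif ({self.motif_len} bp)"
                )
        for build in self.end_by_build:
            if build not in self.start_by_build:
                problems.append(f"build {build}: end without start")

        # threshold ordering: benign_max < intermediate_min <= intermediate_max < pathogenic_min
        chain = [
            ("benign_max", self.benign_max, True),
            ("intermediate_min", self.intermediate_min, False),
            ("intermediate_max", self.intermediate_max, True),
            ("pathogenic_min", self.pathogenic_min, False),
        ]
        present = [(name, v, strict) for name, v, strict in chain if v is not None]
        for (n1, v1, _), (n2, v2, strict) in zip(present, present[1:]):
            ok = v1 < v2 if strict else v1 <= v2
            if not ok:
                problems.append(f"thresholds out of order: {n1}={v1} vs {n2}={v2}")
        if self.pathogenic_max is not None and self.pathogenic_min > self.pathogenic_max:
            problems.append(
                f"thresholds out of order: pathogenic_min={self.pathogenic_min} "
                f"> pathogenic_max={self.pathogenic_max}"
            )

        self.reference_motif = self.reference_motif.upper()
        if len(self.reference_motif) != self.motif_len:
            problems.append(
                f"reference_motif {self.reference_motif!r} length != motif_len {self.motif_len}"
            )
        if set(self.reference_motif) - set("ACGT"):
            problems.append(f"reference_motif {self.reference_motif!r} not over A/C/G/T")

        if "conflicting_evidence" not in self.flags and not any(
            m.motif_class == "pathogenic" for m in self.motifs
        ):
            problems.append("no pathogenic motif entry (and no conflicting_evidence flag)")

        if problems:
            raise ValueError("; ".join(problems))
        return self

    def coordinates(self, build: str) -> Optional[tuple[int, int]]:
        build = _BUILD_ALIASES.get(build, build)
        if build in self.start_by_build and build in self.end_by_build:
            return self.start_by_build[build], self.end_by_build[build]
        return None

    def pathogenic_motifs(self) -> list[str]:
        return [m.motif for m in self.motifs if m.motif_class == "pathogenic"]


def catalog_json_schema() -> dict[str, Any]:
    """JSON Schema for the catalog file format (the version shipped in
    ``data/catalog.schema.json`` is generated from this)."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "strscreen locus catalog",
        "version": SCHEMA_VERSION,
        "type": "object",
        "required": ["loci"],
        "properties": {
            "schema_version": {"type": "string"},
            "coordinate_system": {
                "enum": ["0-based-half-open", "1-based-closed"],
                "default": "0-based-half-open",
            },
            "loci": {"type": "array", "items": LocusRecord.model_json_schema()},
        },
    }


def validate_locus(record: dict[str, Any] | LocusRecord) -> LocusRecord:
    """Validate one record, raising :class:`CatalogValidationError` with all problems."""
    if isinstance(record, LocusRecord):
        return record
    try:
        return LocusRecord.model_validate(record)
    except ValidationError as exc:
        rid = record.get("locus_id", "<missing locus_id>") if isinstance(record, dict) else "?"
        msgs = [f"{rid}: {e['msg']}" for e in exc.errors()]
        raise CatalogValidationError(msgs) from exc


def load_catalog(path: str | Path) -> list[LocusRecord]:
    """Load and validate a catalog file; records returned in file order.

    The file is either a JSON list of locus records or an object with keys
    ``schema_version``, ``coordinate_system`` (``"0-based-half-open"`` or
    ``"1-based-closed"``; 1-based sources are converted at load) and ``loci``.
    All schema violations are collected and reported together.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CatalogParseError(f"{path}: not valid JSON at line {exc.lineno}: {exc.msg}") from exc

    one_based = False
    if isinstance(doc, dict):
        records = doc.get("loci")
        if records is None:
            raise CatalogParseError(f"{path}: catalog object lacks a 'loci' list")
        coord = doc.get("coordinate_system", "0-based-half-open")
        if coord == "1-based-closed":
            one_based = True
        elif coord != "0-based-half-open":
            raise CatalogParseError(f"{path}: unknown coordinate_system {coord!r}")
    elif isinstance(doc, list):
        records = doc
    else:
        raise CatalogParseError(f"{path}: top level must be a list or an object with 'loci'")

    violations: list[str] = []
    loci: list[LocusRecord] = []
    for i, raw in enumerate(records):
        if one_based and isinstance(raw, dict):
            raw = dict(raw)
            raw["start_by_build"] = {
                b: s - 1 for b, s in (raw.get("start_by_build") or {}).items()
            }
        try:
            loci.append(validate_locus(raw))
        except CatalogValidationError as exc:
            violations.extend(f"record {i}: {v}" for v in exc.violations)
    if violations:
        raise CatalogValidationError(violations)
    return loci


def dump_catalog(catalog: Iterable[LocusRecord], path: str | Path) -> None:
    """Serialize a catalog back to the 0-based JSON dialect (round-trip safe)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "coordinate_system": "0-based-half-open",
        "loci": [
            json.loads(rec.model_dump_json(by_alias=True, exclude_none=True))
            for rec in catalog
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False, default=sorted) + "\n")


def populate_reverse_complement(record: LocusRecord) -> LocusRecord:
    """For minus-strand loci, add reference-orientation reverse-complement twins
    of every gene-orientation motif (same class). Plus-strand records and
    records whose twins already exist are returned unchanged; idempotent."""
    if record.strand == "+":
        return record
    existing = {(canonical_rotation(m.motif).canonical, m.orientation) for m in record.motifs}
    new_entries: list[MotifEntry] = []
    for entry in record.motifs:
        if entry.orientation != "gene":
            continue
        twin = reverse_complement(entry.motif)
        key = (canonical_rotation(twin).canonical, "reference")
        if key in existing:
            continue
        existing.add(key)
        new_entries.append(
            MotifEntry(motif=twin, orientation="reference", **{"class": entry.motif_class})
        )
    if not new_entries:
        return record
    updated = record.model_copy(deep=True)
    updated.motifs.extend(new_entries)
    return updated


def emit_bed(catalog: Iterable[LocusRecord], build: str) -> str:
    """Four-column BED text (chrom, start, end, locus_id), sorted by
    (chrom, start). Loci without coordinates for *build* are skipped with a
    logged warning."""
    rows: list[tuple[str, int, int, str]] = []
    for rec in catalog:
        coords = rec.coordinates(build)
        if coords is None:
            logger.warning("locus %s has no %s coordinates; skipped", rec.locus_id, build)
            continue
        rows.append((rec.chrom, coords[0], coords[1], rec.locus_id))
    rows.sort(key=lambda r: (r[0], r[1]))
    return "".join(f"{c}\t{s}\t{e}\t{i}\n" for c, s, e, i in rows)


def emit_trgt_definitions(catalog: Iterable[LocusRecord], build: str) -> str:
    """TRGT v1 repeat-definition BED: one line per locus with INFO string
    ``ID=<locus_id>;MOTIFS=<comma-joined reference-orientation motifs>;STRUC=<locus_structure>``."""
    rows: list[tuple[str, int, int, str]] = []
    for rec in catalog:
        coords = rec.coordinates(build)
        if coords is None:
            logger.warning("locus %s has no %s coordinates; skipped", rec.locus_id, build)
            continue
        motifs = [m.motif for m in rec.motifs if m.orientation == "reference"]
        if not motifs:
            raise CatalogError(f"locus {rec.locus_id}: no reference-orientation motifs for TRGT")
        struc = rec.locus_structure or f"({motifs[0]})n"
        info = f"ID={rec.locus_id};MOTIFS={','.join(motifs)};STRUC={struc}"
        rows.append((rec.chrom, coords[0], coords[1], info))
    rows.sort(key=lambda r: (r[0], r[1]))
    return "".join(f"{c}\t{s}\t{e}\t{i}\n" for c, s, e, i in rows)


def bp_to_repeats(size_bp: int, motif_len: int) -> float:
    """Convert a size in bp to repeat units (exact division not required)."""
    if motif_len < 1:
        raise ValueError(f"motif_len must be >= 1, got {motif_len}")
    repeats = size_bp / motif_len
    if size_bp % motif_len:
        logger.debug("size %d bp is not a whole number of %d-bp motifs", size_bp, motif_len)
    return repeats


def repeats_to_bp(n: int, motif_len: int) -> int:
    if motif_len < 1:
        raise ValueError(f"motif_len must be >= 1, got {motif_len}")
    return n * motif_len


def filter_by_evidence(
    catalog: Iterable[LocusRecord],
    min_independent_obs: int = 2,
    drop_ids: set[str] = frozenset(),
) -> list[LocusRecord]:
    """Retain loci with enough independent observations, minus explicit drops.

    Mirrors the figure-level filtering: loci documented by fewer than two
    unrelated cases/pedigrees lack literature consensus; some loci (e.g. POLG,
    expanded commonly in healthy controls) are dropped by id regardless.
    Order preserved; identity at min=0 with an empty drop set.
    """
    return [
        rec
        for rec in catalog
        if rec.independent_observations >= min_independent_obs and rec.locus_id not in drop_ids
    ]


def summarize_catalog(catalog: Iterable[LocusRecord]) -> dict[str, Any]:
    """Aggregate counts over a catalog.

    Returns motif-length x genomic-context counts, pediatric (< 18 y) and
    first-year (< 1 y) onset counts and fractions, and the number of loci
    with enough evidence (>= 10 independent observations) to carry a
    literature-based typical onset range.
    """
    catalog = list(catalog)
    n = len(catalog)
    ctx_counts: Counter[tuple[int, str]] = Counter()
    for rec in catalog:
        for ctx in rec.genomic_context or ["intergenic"]:
            ctx_counts[(rec.motif_len, ctx)] += 1
    pediatric = sum(
        1 for r in catalog if r.onset_min_years is not None and r.onset_min_years < 18
    )
    infantile = sum(1 for r in catalog if r.onset_min_years is not None and r.onset_min_years < 1)
    typical = sum(
        1
        for r in catalog
        if r.independent_observations >= 10
        and r.typical_onset_min is not None
        and r.typical_onset_max is not None
    )
    return {
        "n_loci": n,
        "by_motif_len_and_context": dict(ctx_counts),
        "pediatric_onset_count": pediatric,
        "pediatric_onset_fraction": pediatric / n if n else math.nan,
        "first_year_onset_count": infantile,
        "first_year_onset_fraction": infantile / n if n else math.nan,
        "typical_onset_range_count": typical,
    }


_NUM = r"[\d,]+(?:\.\d+)?"


def _to_float(s: str) -> float:
    return float(s.replace(",", ""))


def prevalence_to_fraction(text: str | float | tuple[float, float]) -> float:
    """Parse a literature prevalence statement into a single fraction in [0, 1].

    Accepts "1 in 20,000", "0.0106%", "0.0106-0.0137%", "1-2 per 100,000",
    a bare number (interpreted as a fraction), or a (low, high) fraction pair.
    Ranges are averaged to a single value.
    """
    if isinstance(text, tuple):
        lo, hi = text
        return (lo + hi) / 2
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip().replace("–", "-").replace("—", "-")

    m = re.fullmatch(rf"({_NUM})\s+in\s+({_NUM})", s, re.IGNORECASE)
    if m:
        return _to_float(m.group(1)) / _to_float(m.group(2))
    m = re.fullmatch(rf"({_NUM})(?:\s*-\s*({_NUM}))?\s*%", s)
    if m:
        lo = _to_float(m.group(1)) / 100
        hi = _to_float(m.group(2)) / 100 if m.group(2) else lo
        return (lo + hi) / 2
    m = re.fullmatch(rf"({_NUM})(?:\s*-\s*({_NUM}))?\s+per\s+({_NUM})", s, re.IGNORECASE)
    if m:
        denom = _to_float(m.group(3))
        lo = _to_float(m.group(1)) / denom
        hi = _to_float(m.group(2)) / denom if m.group(2) else lo
        return (lo + hi) / 2
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"cannot parse prevalence statement: {text!r}") from None
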