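"""Canonicalization, comparison, and classification of tandem-repeat motifs.

A repeat motif is only defined up to cyclic rotation: a run of ``CAGCAGCAG...``
can equally be read as ``AGC`` or ``GCA`` repeats depending on where the
genotyper anchors it. Before motifs from different callers or catalog entries
can be compared they are mapped to a canonical representative — here the
lexicographically smallest cyclic rotation, which is unique as a string (for
periodic motifs several rotation indices reach it; the smallest is recorded).

A plain character sort (``CAG`` -> ``ACG``) is also provided for reproduction
studies, but it is not the default: sorting conflates motifs that are not
rotations of each other (``AGC`` and ``ACG`` both sort to ``ACG``), erasing
exactly the benign/pathogenic distinctions the screening analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

if TYPE_CHECKING:  # pragma: no cover
    from .catalog import LocusRecord

MOTIF_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MotifClass = Literal["benign", "pathogenic", "uncertain", "unknown"]


class MotifAlphabetError(ValueError):
    """Motif contains characters outside A/C/G/T/N."""


def _check_alphabet(motif: str) -> str:
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    bad = set(motif) - MOTIF_ALPHABET
    if bad:
        raise MotifAlphabetError(
            f"motif {motif!r} contains invalid characters {sorted(bad)}; "
            "allowed alphabet is A, C, G, T, N"
        )
    return motif


@dataclass(frozen=True)
class CanonicalMotif:
    """Canonical (minimal-rotation) form of a motif.

    Attributes
    ----------
    canonical : str
        Lexicographically smallest cyclic rotation of ``source``.
    source : str
        The motif as given (upper-cased).
    rotations : int
        Left-rotation count mapping ``source`` onto ``canonical`` (smallest
        such count for periodic motifs).
    """

    canonical: str
    source: str
    rotations: int


def canonical_rotation(motif: str) -> CanonicalMotif:
    """Return the lexicographically smallest cyclic rotation of *motif*.

    Deterministic and idempotent: the canonical form of a canonical form is
    itself with zero rotations.
    """
    motif = _check_alphabet(motif)
    doubled = motif + motif
    n = len(motif)
    best = min(range(n), key=lambda i: doubled[i : i + n])
    return CanonicalMotif(canonical=doubled[best : best + n], source=motif, rotations=best)


def primitive_period(motif: str) -> str:
    """Smallest substring whose repetition reconstructs *motif* (e.g. CAGCAG -> CAG)."""
    motif = _check_alphabet(motif)
    n = len(motif)
    for p in range(1, n + 1):
        if n % p == 0 and motif[:p] * (n // p) == motif:
            return motif[:p]
    return motif  # pragma: no cover - loop always terminates at p=n


def reverse_complement(motif: str) -> str:
    """Standard reverse complement; N maps to N. Involution."""
    motif = _check_alphabet(motif)
    return motif.translate(_COMPLEMENT)[::-1]


def normalize(motif: str, method: Literal["rotation", "sorted"] = "rotation") -> str:
    """Normalize a motif for comparison.

    ``rotation`` (default) returns the minimal cyclic rotation; ``sorted``
    returns the characters in alphabetical order (lossy; provided only to
    reproduce analyses that normalized by sorting).
    """
    if method == "rotation":
        return canonical_rotation(motif).canonical
    if method == "sorted":
        return "".join(sorted(_check_alphabet(motif)))
    raise ValueError(f"unknown normalization method {method!r}")


def motifs_equivalent(
    a: str,
    b: str,
    allow_revcomp: bool = False,
    method: Literal["rotation", "sorted"] = "rotation",
) -> bool:
    """True iff *a* and *b* denote the same repeat motif.

    Equivalence is rotation-based by default; with ``allow_revcomp`` the
    reverse complement of *b* is also accepted. Motifs of different lengths
    are never equivalent.
    """
    if not a or not b:
        return False
    if len(a) != len(b):
        return False
    if normalize(a, method) == normalize(b, method):
        return True
    if allow_revcomp:
        return normalize(a, method) == normalize(reverse_complement(b), method)
    return False


def is_excluded_motif(motif: str) -> bool:
    """True for degenerate IUPAC motif calls (any 'N'), e.g. the ``CNG`` calls
    that inflate allele estimates through sequence non-specificity."""
    return "N" in motif.upper()


def classify_motif(
    motif: str,
    locus: "LocusRecord",
    allow_revcomp: bool = False,
    method: Literal["rotation", "sorted"] = "rotation",
) -> MotifClass:
    """Class of the first curated motif entry equivalent to *motif*.

    Returns ``"unknown"`` when no curated entry matches — the common case for
    rare motifs, whose phenotypic consequence is undocumented.
    """
    for entry in locus.motifs:
        if motifs_equivalent(motif, entry.motif, allow_revcomp=allow_revcomp, method=method):
            return entry.motif_class
    return "unknown"
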