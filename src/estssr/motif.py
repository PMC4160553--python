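"""Repeat-unit (motif) algebra.

A microsatellite unit is a short DNA word (here 2-10 bp). Units that are
cyclic rotations of one another describe the same tandem array read from a
different phase, and a unit and its reverse complement describe the same
array read from the opposite strand. Counting therefore happens on
*canonical motif classes*: the equivalence classes of primitive units under
rotation and reverse complementation, each named by its lexicographically
smallest member (e.g. AC = CA = GT = TG, named "AC").

A unit is *primitive* if it is not itself a whole number of copies of a
shorter unit; non-primitive units ("ATAT", and in particular homopolymer
units like "AA") never name a class, which is also how mononucleotide
repeats are excluded from the analysis.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

MIN_UNIT = 2
MAX_UNIT = 10

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class MotifError(ValueError):
    """Raised for words that are not valid repeat units."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_motif(motif: str) -> str:
    """Return ``motif`` uppercased, or raise :class:`MotifError`.

    Valid motifs are A/C/G/T words of length 2-10.
    """
    if not isinstance(motif, str):
        raise MotifError(f"motif must be a string, got {type(motif).__name__}")
    m = motif.upper()
    if not (MIN_UNIT <= len(m) <= MAX_UNIT):
        raise MotifError(f"motif length must be in [{MIN_UNIT}, {MAX_UNIT}]: {motif!r}")
    if not _ALPHABET.issuperset(m):
        raise MotifError(f"motif contains characters outside ACGT: {motif!r}")
    return m


def is_primitive(motif: str) -> bool:
    """True iff ``motif`` is not a concatenation of >=2 copies of a shorter word.

    Homopolymer units (period 1, e.g. "AAA") are non-primitive by this
    definition, so primitivity filtering subsumes mononucleotide exclusion.
    """
    m = validate_motif(motif)
    n = len(m)
    for d in range(1, n):
        if n % d == 0 and m == m[:d] * (n // d):
            return False
    return True


def rotations(motif: str):
    """All cyclic rotations of ``motif`` (length-many words, with duplicates
    for non-primitive input)."""
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def canonical_label(motif: str) -> str:
    """Lexicographically smallest word among all rotations of ``motif`` and of
    its reverse complement. No primitivity requirement (internal helper)."""
    rc = reverse_complement(motif)
    return min(min(rotations(motif)), min(rotations(rc)))


@lru_cache(maxsize=None)
def _canonical_cached(motif: str) -> str:
    if not is_primitive(motif):
        raise MotifError(f"motif is not primitive: {motif!r}")
    return canonical_label(motif)


def canonical_class(motif: str) -> str:
    """Canonical class name of a primitive motif.

    The class contains all cyclic rotations of the motif and of its reverse
    complement; the name is the lexicographically smallest member, so the
    map is constant on the class and idempotent.
    """
    return _canonical_cached(validate_motif(motif))


def class_members(canonical: str) -> frozenset[str]:
    """All motifs belonging to the class named by ``canonical``."""
    c = validate_motif(canonical)
    if not is_primitive(c):
        raise MotifError(f"class name must be primitive: {canonical!r}")
    members = frozenset(rotations(c)) | frozenset(rotations(reverse_complement(c)))
    return members


@lru_cache(maxsize=None)
def enumerate_canonical_classes(unit_length: int) -> tuple[str, ...]:
    """Sorted names of every primitive canonical class of a given unit length.

    There are 4 dimer classes (AC, AG, AT, CG) and 10 trimer classes.
    """
    if not (MIN_UNIT <= unit_length <= MAX_UNIT):
        raise MotifError(f"unit length must be in [{MIN_UNIT}, {MAX_UNIT}]")
    seen = set()
    for tup in product("ACGT", repeat=unit_length):
        m = "".join(tup)
        if is_primitive(m):
            seen.add(canonical_label(m))
    return tuple(sorted(seen))
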