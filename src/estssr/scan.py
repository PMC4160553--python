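"""Perfect and compound microsatellite detection.

The scanner reports perfect SSRs: maximal exact tandem arrays of a 2-10 bp
unit, counted in complete copies, that reach a class-specific minimum
repeat number (dimers need 10 copies, trimers 7, tetramers 5, pentamers
and hexamers 4, heptamers through nonamers 3, decamers 2 — so every
reported locus is a class I repeat of >= 20 bp). Mononucleotide repeats
are excluded by requiring primitive units. Loci closer than 100 bp are
merged into compound events; a perfect event has exactly one member.

Run semantics, per unit length: the output is the leftmost-greedy tiling
of maximal complete-copy extensions. Starting from the left, the first
position (past the previous run's end) where >=2 complete copies of an
admissible unit begin opens a run, which extends as far as complete copies
reach. This makes the output well defined even where a periodic region
supports equal-copy runs in more than one phase (e.g. CATATATAG), and runs
of one unit length never overlap. Loci whose span is fully contained in
another reported locus are suppressed (longer span wins, then smaller
unit, then leftmost). N breaks every run; characters outside A/C/G/T/N
reject the record.

:func:`brute_force_oracle_scan` re-implements the same semantics by naive
substring comparison and serves as the reference in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import (
    MAX_UNIT,
    MIN_UNIT,
    canonical_label,
    is_primitive,
    validate_motif,
)
from .partition import Fraction

#: SSRLocator-style minimum complete-copy counts per unit length.
DEFAULT_MIN_REPEATS: Mapping[int, int] = {
    2: 10,
    3: 7,
    4: 5,
    5: 4,
    6: 4,
    7: 3,
    8: 3,
    9: 3,
    10: 2,
}

_VALID_BYTES = frozenset(b"ACGT")
_SCAN_BYTES = frozenset(b"ACGTN")


class ScanError(ValueError):
    """Raised for sequences or configurations the scanner rejects."""


@dataclass(frozen=True)
class ScanConfig:
    """Scanner thresholds.

    min_repeats
        Minimum complete copies per unit length; the defaults give every
        admissible locus a total length of at least 20 bp (class I).
    max_compound_spacer
        Exclusive upper bound on the gap between loci of one compound
        event: gaps strictly below this merge.
    exclude_nonprimitive / exclude_mononucleotide
        Unit filters; with primitivity filtering on (default) homopolymer
        units are already excluded.
    """

    min_repeats: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_compound_spacer: int = 100
    exclude_mononucleotide: bool = True
    exclude_nonprimitive: bool = True

    def __post_init__(self) -> None:
        for k, r in self.min_repeats.items():
            if not (MIN_UNIT <= k <= MAX_UNIT):
                raise ScanError(f"unit length {k} outside [{MIN_UNIT}, {MAX_UNIT}]")
            if r < 2:
                raise ScanError(f"min_repeats[{k}] must be >= 2, got {r}")
        if self.max_compound_spacer < 1:
            raise ScanError("max_compound_spacer must be positive")

    def unit_lengths(self) -> list[int]:
        return sorted(self.min_repeats)

    def unit_admissible(self, unit: str) -> bool:
        if self.exclude_nonprimitive:
            return is_primitive(unit)
        if self.exclude_mononucleotide and len(set(unit)) == 1:
            return False
        return True


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat on a (fraction) sequence.

    Coordinates are 0-based half-open on the sequence that was scanned;
    ``repeat_count`` counts complete units only, so
    ``length_bp == unit_length * repeat_count``.
    """

    seq_id: str
    fraction: Fraction
    start: int
    end: int
    motif_as_found: str
    canonical: str
    unit_length: int
    repeat_count: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_length * self.repeat_count:
            raise ScanError(
                f"inconsistent locus: span {self.end - self.start} != "
                f"{self.unit_length} x {self.repeat_count}"
            )


class EventKind(str, Enum):
    PERFECT = "PERFECT"
    COMPOUND = "COMPOUND"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class SSREvent:
    """A perfect locus, or a chain of loci closer than the compound spacer.

    Events are the counting unit for density; member loci feed the
    motif-size and motif-class composition tables.
    """

    kind: EventKind
    members: tuple[SSRLocus, ...]
    spacers: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].start, self.members[-1].end

    @property
    def seq_id(self) -> str:
        return self.members[0].seq_id

    @property
    def fraction(self) -> Fraction:
        return self.members[0].fraction

    @property
    def repeat_bp(self) -> int:
        """Total bp inside member loci (spacers excluded)."""
        return sum(m.length_bp for m in self.members)


def _canonical_of(unit: str, config: ScanConfig) -> str:
    # canonical_label tolerates non-primitive units, used when the
    # primitivity filter is switched off
    return canonical_label(unit)


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not _SCAN_BYTES.issuperset(seq.encode("ascii", errors="replace")):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ScanError(f"sequence contains invalid characters: {bad!r}")
    return seq


def _runs_for_unit(
    seq: str, arr: np.ndarray, valid: np.ndarray, k: int, require_primitive: bool
) -> list[tuple[int, int, str, int]]:
    L = len(seq)
    if L < 2 * k:
        return []
    match = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
    if not match.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], match, [False])).view(np.int8)))
    starts, ends = edges[0::2], edges[1::2]  # stretches of True in match space
    runs: list[tuple[int, int, str, int]] = []
    cursor = 0
    for a, b in zip(starts.tolist(), ends.tolist()):
        if b - a < k:
            continue  # fewer than 2 complete copies anywhere in this stretch
        i = max(a, cursor)
        if i > b - k:
            continue
        unit = seq[i : i + k]
        if require_primitive and not is_primitive(unit):
            continue  # primitivity is phase-invariant: whole stretch inadmissible
        copies = 1 + (b - i) // k
        end = i + copies * k
        runs.append((i, end, unit, copies))
        cursor = end
    return runs


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)  # A C G T
    return arr, valid


def scan_unit_runs(
    sequence: str, unit_length: int, require_primitive: bool = True
) -> list[tuple[int, int, str, int]]:
    """Maximal complete-copy tandem runs of one unit length.

    Returns ``(start, end, unit, copies)`` tuples with ``copies >= 2``,
    sorted by start, following the leftmost-greedy tiling semantics
    described in the module docstring. Runs never cross N or sequence ends.
    """
    if not (MIN_UNIT <= unit_length <= MAX_UNIT):
        raise ScanError(f"unit length {unit_length} outside [{MIN_UNIT}, {MAX_UNIT}]")
    seq = _check_sequence(sequence)
    arr, valid = _encode(seq)
    return _runs_for_unit(seq, arr, valid, unit_length, require_primitive)


def _resolve_containment(loci: list[SSRLocus]) -> list[SSRLocus]:
    """Suppress loci fully contained in another reported locus.

    Priority: longer span, then smaller unit length, then leftmost.
    """
    order = sorted(loci, key=lambda l: (-(l.end - l.start), l.unit_length, l.start))
    kept: list[SSRLocus] = []
    for loc in order:
        if any(k.start <= loc.start and loc.end <= k.end for k in kept):
            continue
        kept.append(loc)
    kept.sort(key=lambda l: (l.start, l.unit_length))
    return kept


def scan_perfect_ssrs(
    sequence: str,
    config: ScanConfig | None = None,
    seq_id: str = "",
    fraction: Fraction = Fraction.UNPARTITIONED,
) -> list[SSRLocus]:
    """All perfect SSR loci of a sequence under the configured thresholds."""
    config = config or ScanConfig()
    seq = _check_sequence(sequence)
    arr, valid = _encode(seq)
    candidates: list[SSRLocus] = []
    for k in config.unit_lengths():
        for start, end, unit, copies in _runs_for_unit(
            seq, arr, valid, k, config.exclude_nonprimitive
        ):
            if copies < config.min_repeats[k]:
                continue
            if not config.unit_admissible(unit):
                continue
            candidates.append(
                SSRLocus(
                    seq_id=seq_id,
                    fraction=fraction,
                    start=start,
                    end=end,
                    motif_as_found=unit,
                    canonical=_canonical_of(unit, config),
                    unit_length=k,
                    repeat_count=copies,
                )
            )
    return _resolve_containment(candidates)


def brute_force_oracle_scan(
    sequence: str,
    config: ScanConfig | None = None,
    seq_id: str = "",
    fraction: Fraction = Fraction.UNPARTITIONED,
) -> list[SSRLocus]:
    """Reference scanner by naive substring comparison (test oracle).

    Implements the same leftmost-greedy semantics as
    :func:`scan_perfect_ssrs` with character-by-character extension and an
    O(n^2) containment pass; intended for short test sequences.
    """
    config = config or ScanConfig()
    seq = _check_sequence(sequence)
    L = len(seq)
    candidates: list[SSRLocus] = []
    for k in config.unit_lengths():
        cursor = 0
        i = 0
        while i <= L - 2 * k:
            if i < cursor:
                i += 1
                continue
            unit = seq[i : i + k]
            if set(unit) <= set("ACGT") and config.unit_admissible(unit):
                copies = 1
                while seq[i + copies * k : i + (copies + 1) * k] == unit:
                    copies += 1
                if copies >= 2:
                    cursor = i + copies * k
                    if copies >= config.min_repeats[k]:
                        candidates.append(
                            SSRLocus(
                                seq_id=seq_id,
                                fraction=fraction,
                                start=i,
                                end=cursor,
                                motif_as_found=unit,
                                canonical=_canonical_of(unit, config),
                                unit_length=k,
                                repeat_count=copies,
                            )
                        )
                    i = cursor
                    continue
            i += 1
    # containment resolution, quadratic on purpose
    kept: list[SSRLocus] = []
    for loc in candidates:
        contained = False
        for other in candidates:
            if other is loc:
                continue
            if other.start <= loc.start and loc.end <= other.end:
                o_len, l_len = other.end - other.start, loc.end - loc.start
                if o_len > l_len:
                    contained = True
                elif o_len == l_len and (
                    (other.unit_length, other.start) < (loc.unit_length, loc.start)
                ):
                    contained = True
            if contained:
                break
        if not contained:
            kept.append(loc)
    kept.sort(key=lambda l: (l.start, l.unit_length))
    return kept


def merge_compound(
    loci: Sequence[SSRLocus], config: ScanConfig | None = None
) -> list[SSREvent]:
    """Group loci separated by less than the compound spacer into events.

    Input loci must be sorted, non-overlapping and from one sequence and
    fraction. Chaining is transitive: a run of loci each within the spacer
    of the next forms one compound event.
    """
    config = config or ScanConfig()
    loci = list(loci)
    if not loci:
        return []
    ids = {(l.seq_id, l.fraction) for l in loci}
    if len(ids) > 1:
        raise ScanError("merge_compound requires loci from a single sequence fraction")
    for prev, nxt in zip(loci, loci[1:]):
        if nxt.start < prev.end:
            raise ScanError(
                f"overlapping or unsorted loci: [{prev.start},{prev.end}) then "
                f"[{nxt.start},{nxt.end})"
            )
    events: list[SSREvent] = []
    group: list[SSRLocus] = [loci[0]]
    spacers: list[int] = []
    for nxt in loci[1:]:
        gap = nxt.start - group[-1].end
        if gap < config.max_compound_spacer:
            spacers.append(gap)
            group.append(nxt)
        else:
            events.append(_make_event(group, spacers))
            group, spacers = [nxt], []
    events.append(_make_event(group, spacers))
    return events


def _make_event(group: list[SSRLocus], spacers: list[int]) -> SSREvent:
    kind = EventKind.PERFECT if len(group) == 1 else EventKind.COMPOUND
    return SSREvent(kind=kind, members=tuple(group), spacers=tuple(spacers))


def scan_events(
    sequence: str,
    config: ScanConfig | None = None,
    seq_id: str = "",
    fraction: Fraction = Fraction.UNPARTITIONED,
) -> list[SSREvent]:
    """Scan a sequence and merge the loci into perfect/compound events."""
    config = config or ScanConfig()
    loci = scan_perfect_ssrs(sequence, config, seq_id=seq_id, fraction=fraction)
    return merge_compound(loci, config) if loci else []


def events_to_frame(events: Iterable[SSREvent]) -> pd.DataFrame:
    """Flat member-level table of events (one row per member locus)."""
    rows = []
    for event_id, ev in enumerate(events):
        for m in ev.members:
            rows.append(
                {
                    "seq_id": m.seq_id,
                    "fraction": str(m.fraction),
                    "start0": m.start,
                    "end0": m.end,
                    "unit_length": m.unit_length,
                    "motif": m.motif_as_found,
                    "canonical": m.canonical,
                    "repeats": m.repeat_count,
                    "length_bp": m.length_bp,
                    "event_kind": str(ev.kind),
                    "event_id": event_id,
                }
            )
    columns = [
        "seq_id",
        "fraction",
        "start0",
        "end0",
        "unit_length",
        "motif",
        "canonical",
        "repeats",
        "length_bp",
        "event_kind",
        "event_id",
    ]
    return pd.DataFrame(rows, columns=columns)
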