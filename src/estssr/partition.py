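"""Orientation and 5'UTR / ORF / 3'UTR partitioning of EST sequences.

Each EST is assigned a single coding region and split into three
sub-sequences: the untranslated leader (5'UTR), the open reading frame
(ORF, ATG through an in-frame stop, stop included), and the untranslated
trailer (3'UTR). The ORF is found by a deterministic longest-ORF rule over
all six reading frames; when a transcript carries several candidate ORFs
the longest one is taken as the true coding region and the flanking
sequence becomes UTR. If the winning ORF lies on the reverse strand the
sequence is reverse-complemented first, so every partitioned sequence is
reported in its forward-coding orientation.

External ORF annotations (GFF3 or BED) can replace the heuristic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .motif import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_ORF_BP = 90

_STOP_CODONS = ("TAA", "TAG", "TGA")
_START_RE = re.compile(r"(?=ATG)")
_STOP_RE = re.compile(r"(?=TAA|TAG|TGA)")


class Fraction(str, Enum):
    """Genomic fraction label of a sub-sequence or repeat locus."""

    FIVE_UTR = "5UTR"
    ORF = "ORF"
    THREE_UTR = "3UTR"
    UNPARTITIONED = "UNPARTITIONED"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class OrfCall:
    """A single ORF on the oriented (forward-coding) sequence.

    ``start``/``end`` are 0-based half-open and include the stop codon.
    ``source_strand`` records which input strand the ORF was found on.
    """

    seq_id: str
    start: int
    end: int
    source_strand: Strand = Strand.FORWARD
    frame: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid ORF span [{self.start}, {self.end})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FractionedSequence:
    """An EST in forward-coding orientation with its three fraction spans."""

    seq_id: str
    oriented_residues: str
    spans: Mapping[Fraction, tuple[int, int]]

    def __post_init__(self) -> None:
        L = len(self.oriented_residues)
        u5 = self.spans[Fraction.FIVE_UTR]
        orf = self.spans[Fraction.ORF]
        u3 = self.spans[Fraction.THREE_UTR]
        if not (0 == u5[0] and u5[1] == orf[0] and orf[1] == u3[0] and u3[1] == L):
            raise ValueError(f"fraction spans not contiguous for {self.seq_id}")

    def fraction_seq(self, fraction: Fraction) -> str:
        s, e = self.spans[fraction]
        return self.oriented_residues[s:e]

    def fraction_length(self, fraction: Fraction) -> int:
        s, e = self.spans[fraction]
        return e - s


def _frame_positions(pattern: re.Pattern, seq: str) -> list[np.ndarray]:
    """Start positions of pattern matches, split by frame (pos % 3)."""
    pos = np.fromiter((m.start() for m in pattern.finditer(seq)), dtype=np.int64)
    return [pos[pos % 3 == f] for f in range(3)]


def _longest_orf_one_strand(seq: str, min_orf_bp: int):
    """Best (length, start, end, frame) ATG->stop span on one strand, or None.

    For each ATG the ORF runs to the nearest in-frame stop; the longest
    candidate wins, ties to the leftmost start.
    """
    starts_by_frame = _frame_positions(_START_RE, seq)
    stops_by_frame = _frame_positions(_STOP_RE, seq)
    best = None
    for frame in range(3):
        atgs = starts_by_frame[frame]
        stops = stops_by_frame[frame]
        if atgs.size == 0 or stops.size == 0:
            continue
        # nearest stop at or after atg+3 (an ATG never overlaps a stop in-frame)
        idx = np.searchsorted(stops, atgs + 3, side="left")
        ok = idx < stops.size
        if not ok.any():
            continue
        a = atgs[ok]
        e = stops[idx[ok]] + 3
        lengths = e - a
        k = int(np.argmax(lengths))  # argmax takes the first maximum: leftmost
        if lengths[k] >= min_orf_bp:
            cand = (int(lengths[k]), int(a[k]), int(e[k]), frame)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
    return best


def find_longest_orf(
    sequence: str, min_orf_bp: int = DEFAULT_MIN_ORF_BP, seq_id: str = ""
) -> OrfCall | None:
    """Longest ATG->stop ORF over all six reading frames.

    Returns the call with coordinates on the oriented sequence (the reverse
    complement when the ORF is on the reverse strand). Ties are broken in
    favour of the forward strand, then the leftmost start. ``None`` when no
    ORF reaches ``min_orf_bp``.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        return None
    fwd = _longest_orf_one_strand(seq, min_orf_bp)
    rev = _longest_orf_one_strand(reverse_complement(seq), min_orf_bp)
    if fwd is None and rev is None:
        return None
    if rev is None or (fwd is not None and fwd[0] >= rev[0]):
        length, start, end, frame = fwd
        strand = Strand.FORWARD
    else:
        length, start, end, frame = rev
        strand = Strand.REVERSE
    return OrfCall(seq_id=seq_id, start=start, end=end, source_strand=strand, frame=frame)


def partition_by_orf(sequence: str, orf: OrfCall) -> FractionedSequence:
    """Split a sequence into 5'UTR / ORF / 3'UTR around an ORF call.

    Reverse-strand calls flip the sequence to forward-coding orientation
    first; the call's coordinates are always on the oriented sequence.
    """
    seq = sequence.upper()
    if orf.source_strand is Strand.REVERSE:
        seq = reverse_complement(seq)
    L = len(seq)
    if orf.end > L:
        raise ValueError(f"ORF span [{orf.start}, {orf.end}) out of bounds (L={L})")
    spans = {
        Fraction.FIVE_UTR: (0, orf.start),
        Fraction.ORF: (orf.start, orf.end),
        Fraction.THREE_UTR: (orf.end, L),
    }
    return FractionedSequence(seq_id=orf.seq_id, oriented_residues=seq, spans=spans)


def partition_sequence(
    sequence: str, seq_id: str, min_orf_bp: int = DEFAULT_MIN_ORF_BP
) -> FractionedSequence | None:
    """Orient and partition one EST; ``None`` when no ORF is called
    (the sequence is then treated as UNPARTITIONED upstream)."""
    orf = find_longest_orf(sequence, min_orf_bp=min_orf_bp, seq_id=seq_id)
    if orf is None:
        return None
    return partition_by_orf(sequence, orf)


# ---------------------------------------------------------------------------
# external annotations


def _gff3_records(path: Path) -> Iterable[tuple[str, int, int, Strand]]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "ORF"):
            continue
        strand = Strand.REVERSE if feat.strand == "-" else Strand.FORWARD
        # GFF3 is 1-based inclusive
        yield feat.seqid, feat.start - 1, feat.end, strand


def _bed_records(path: Path) -> Iterable[tuple[str, int, int, Strand]]:
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: skipping malformed BED line", path, line_no)
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                logger.warning("%s:%d: non-integer BED coordinates", path, line_no)
                continue
            strand = Strand.REVERSE if len(fields) >= 6 and fields[5] == "-" else Strand.FORWARD
            yield fields[0], start, end, strand


def load_orf_annotations(
    path: str | Path, known_ids: set[str] | None = None
) -> dict[str, OrfCall]:
    """Read CDS/ORF spans from a GFF3 or BED file as per-sequence ORF calls.

    Coordinates are converted to 0-based half-open. When a sequence has
    several records, the longest span is kept (longest-ORF rule). Records
    with unknown sequence ids (when ``known_ids`` is given) or invalid
    coordinates are logged and skipped.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3", ".gtf"):
        records = _gff3_records(path)
    elif suffix == ".bed":
        records = _bed_records(path)
    else:
        raise ValueError(f"unsupported annotation format: {path}")
    calls: dict[str, OrfCall] = {}
    for seq_id, start, end, strand in records:
        if end <= start or start < 0:
            logger.warning("rejecting annotation with bad span [%d, %d) for %s", start, end, seq_id)
            continue
        if known_ids is not None and seq_id not in known_ids:
            logger.warning("annotation references unknown sequence id %r", seq_id)
            continue
        call = OrfCall(seq_id=seq_id, start=start, end=end, source_strand=strand, frame=start % 3)
        prev = calls.get(seq_id)
        if prev is None or call.length_bp > prev.length_bp:
            calls[seq_id] = call
    return calls
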