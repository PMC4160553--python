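"""Greedy redundancy removal at a fractional identity cutoff.

EST collections contain many near-duplicate reads of the same transcript;
before repeat densities are computed the collection is reduced to cluster
representatives at 90% identity (CD-HIT's outer scheme: sort longest
first, assign each sequence to the first representative it matches at or
above the cutoff, otherwise promote it to a new representative). Identity
is the fraction of matching columns in a semi-global alignment of the
shorter sequence against the longer one (match 1, mismatch 0, unit gap
cost), after a shared 8-mer prescreen that lets obviously unrelated pairs
short-circuit below the cutoff. The stage is optional and off by default
for inputs that are already non-redundant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib

PRESCREEN_K = 8
DEFAULT_CUTOFF = 0.90


@dataclass(frozen=True)
class ClusterAssignment:
    seq_id: str
    representative_id: str
    identity_to_representative: float

    @property
    def is_representative(self) -> bool:
        return self.seq_id == self.representative_id


def _kmer_set(seq: str, k: int = PRESCREEN_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def estimate_identity(a: str, b: str) -> float:
    """Fractional identity of the shorter sequence aligned within the longer.

    Sequences sharing no 8-mer are reported as identity 0 without
    alignment (prescreen short-circuit, always below any sensible cutoff).
    """
    if not a or not b:
        raise ValueError("estimate_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    if min(len(query), PRESCREEN_K) >= PRESCREEN_K and not (
        _kmer_set(query) & _kmer_set(target)
    ):
        return 0.0
    res = edlib.align(query, target, mode="HW", task="path")
    matches = 0
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
    return matches / columns if columns else 0.0


def greedy_cluster(
    sequences: Sequence[tuple[str, str]], cutoff: float = DEFAULT_CUTOFF
) -> list[ClusterAssignment]:
    """Cluster ``(seq_id, sequence)`` pairs at the given identity cutoff.

    Deterministic: sequences are visited longest-first (ties in input
    order) and each joins the first representative reaching the cutoff.
    Representatives map to themselves with identity 1.0.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i][1]), i))
    reps: list[tuple[str, str]] = []
    assignments: dict[int, ClusterAssignment] = {}
    for idx in order:
        seq_id, seq = sequences[idx]
        placed = False
        for rep_id, rep_seq in reps:
            ident = estimate_identity(seq, rep_seq)
            if ident >= cutoff:
                assignments[idx] = ClusterAssignment(seq_id, rep_id, ident)
                placed = True
                break
        if not placed:
            reps.append((seq_id, seq))
            assignments[idx] = ClusterAssignment(seq_id, seq_id, 1.0)
    return [assignments[i] for i in range(len(sequences))]


def representatives(
    sequences: Sequence[tuple[str, str]], assignments: Sequence[ClusterAssignment]
) -> list[tuple[str, str]]:
    """Subset of input sequences that were kept as cluster representatives,
    in input order."""
    rep_ids = {a.representative_id for a in assignments}
    return [(sid, s) for sid, s in sequences if sid in rep_ids]
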