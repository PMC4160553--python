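"""EST simulator with planted microsatellites and exact ground truth.

Each synthetic EST is built in forward-coding orientation as
5'UTR + ORF + 3'UTR. The ORF is a genuine reading frame (ATG, stop-free
random codons, terminal stop) guarded by a short triple-frame stop
barrier at the end of the 5'UTR so the planted ORF is the unambiguous
longest ORF of the sequence. SSR events are planted at Poisson-distributed
counts to hit per-fraction target densities, mutually separated by more
than the compound spacer (100 bp) of repeat-free background; compound
events carry two members of distinct canonical classes separated by a
short spacer below 100 bp. Backgrounds are rejection-resampled until the
scanner finds nothing in them, and every assembled sequence is verified:
the ORF caller must recover the planted ORF exactly and the scanner must
recover exactly the planted loci. Recovery of a feasible specification is
therefore exact by construction, which is what makes precision/recall
tests sharp rather than probabilistic.

ORF-planted events use unit lengths divisible by 3 and are inserted at
codon boundaries with a repeat phase whose in-frame codons are stop-free,
so planting never breaks the reading frame — mirroring the codon
constraint that shapes real coding-region microsatellites. A configurable
share of sequences is emitted reverse-complemented to exercise
orientation calling; ground truth stays in forward-coding coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .motif import canonical_class, class_members, reverse_complement
from .partition import (
    DEFAULT_MIN_ORF_BP,
    Fraction,
    FractionedSequence,
    find_longest_orf,
)
from .scan import (
    EventKind,
    ScanConfig,
    SSREvent,
    merge_compound,
    scan_perfect_ssrs,
)

_STOPS = frozenset(("TAA", "TAG", "TGA"))
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
#: stops in all three frames, no ATG, no G at all; appended to the 5'UTR so
#: no upstream start can read through into the planted ORF
_FRAME_BARRIER = "CTAACTAACTAA"


class InfeasibleSpecError(ValueError):
    """Raised when planted events cannot satisfy density and separation."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genus.

    Densities are planted event rates per Mbp of each fraction;
    ``motif_weights`` is a probability map over canonical classes (ORF
    planting renormalizes it over unit lengths divisible by 3);
    repeat counts are class minimum + Geometric(``repeat_geom_p``) - 1.
    """

    genus: str = "Synthea"
    n_sequences: int = 300
    length_min: int = 600
    length_max: int = 1200
    gc_content: float = 0.5
    orf_fraction_of_length: float = 0.5
    utr5_share: float = 0.4  # share of the non-ORF length given to the 5'UTR
    density_per_mbp: Mapping[Fraction, float] = field(
        default_factory=lambda: {
            Fraction.FIVE_UTR: 800.0,
            Fraction.ORF: 350.0,
            Fraction.THREE_UTR: 550.0,
        }
    )
    motif_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "AG": 0.26,
            "AT": 0.14,
            "AC": 0.08,
            "CG": 0.01,
            "AAG": 0.12,
            "AAC": 0.05,
            "ACC": 0.05,
            "ATC": 0.05,
            "AGG": 0.04,
            "ACG": 0.01,
            "AAAT": 0.04,
            "AAAG": 0.03,
            "AAAAG": 0.02,
            "AACGGC": 0.04,
            "AAGGAG": 0.03,
            "AAGCTC": 0.02,
            "AACCCTC": 0.005,
            "AACGCTAC": 0.005,
            "AACGATCGT": 0.0,
            "AACGATCGTG": 0.0,
        }
    )
    repeat_geom_p: float = 0.6
    max_extra_repeats: int = 10
    compound_proportion: float = 0.05
    compound_spacer_range: tuple[int, int] = (2, 99)  # inclusive, below 100
    antisense_probability: float = 0.3
    genome_size_pg: float = 1.0
    min_orf_bp: int = DEFAULT_MIN_ORF_BP
    seed: int = 0
    scan_config: ScanConfig = field(default_factory=ScanConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise InfeasibleSpecError("gc_content must be in (0, 1)")
        if self.length_min < 150 or self.length_max < self.length_min:
            raise InfeasibleSpecError("length range must satisfy 150 <= min <= max")
        total = sum(self.motif_weights.values())
        if total <= 0 or abs(total - 1.0) > 1e-6:
            raise InfeasibleSpecError("motif_weights must sum to 1")
        for m, w in self.motif_weights.items():
            if w < 0:
                raise InfeasibleSpecError(f"negative weight for {m}")
            if canonical_class(m) != m:
                raise InfeasibleSpecError(f"motif weight key {m!r} is not canonical")
        lo, hi = self.compound_spacer_range
        if not (0 <= lo <= hi < self.scan_config.max_compound_spacer):
            raise InfeasibleSpecError("compound spacers must stay below the merge bound")
        if not (0.0 <= self.compound_proportion <= 1.0):
            raise InfeasibleSpecError("compound_proportion must be in [0, 1]")
        for fr, d in self.density_per_mbp.items():
            if d < 0:
                raise InfeasibleSpecError(f"negative density for {fr}")


@dataclass(frozen=True)
class PlantedMember:
    motif: str
    canonical: str
    repeat_count: int
    start: int  # fraction-local, 0-based half-open
    end: int


@dataclass(frozen=True)
class PlantedEvent:
    seq_id: str
    fraction: Fraction
    kind: EventKind
    members: tuple[PlantedMember, ...]
    start_global: int  # on the oriented (forward-coding) sequence
    end_global: int

    @property
    def span_local(self) -> tuple[int, int]:
        return self.members[0].start, self.members[-1].end


@dataclass
class TruthManifest:
    genus: str
    seed: int
    events: list[PlantedEvent]
    fraction_bp: dict[Fraction, int]
    n_sequences: int = 0

    def to_json(self) -> str:
        payload = {
            "genus": self.genus,
            "seed": self.seed,
            "n_sequences": self.n_sequences,
            "fraction_bp": {str(k): v for k, v in self.fraction_bp.items()},
            "events": [
                {
                    "seq_id": e.seq_id,
                    "fraction": str(e.fraction),
                    "kind": str(e.kind),
                    "start_global": e.start_global,
                    "end_global": e.end_global,
                    "members": [
                        {
                            "motif": m.motif,
                            "canonical": m.canonical,
                            "repeat_count": m.repeat_count,
                            "start": m.start,
                            "end": m.end,
                        }
                        for m in e.members
                    ],
                }
                for e in self.events
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        events = [
            PlantedEvent(
                seq_id=e["seq_id"],
                fraction=Fraction(e["fraction"]),
                kind=EventKind(e["kind"]),
                start_global=e["start_global"],
                end_global=e["end_global"],
                members=tuple(
                    PlantedMember(
                        motif=m["motif"],
                        canonical=m["canonical"],
                        repeat_count=m["repeat_count"],
                        start=m["start"],
                        end=m["end"],
                    )
                    for m in e["members"]
                ),
            )
            for e in raw["events"]
        ]
        return cls(
            genus=raw["genus"],
            seed=raw["seed"],
            events=events,
            fraction_bp={Fraction(k): v for k, v in raw["fraction_bp"].items()},
            n_sequences=raw.get("n_sequences", 0),
        )


@dataclass(frozen=True)
class RecoveryReport:
    """Span-level precision/recall plus field agreement over matched pairs."""

    precision: float
    recall: float
    fraction_agreement: float
    canonical_agreement: float
    repeat_count_agreement: float
    n_planted: int
    n_detected: int
    n_matched: int
    zero_detections: bool = False


# ---------------------------------------------------------------------------
# low-level generation


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return arr.tobytes().decode("ascii")


def generate_background(
    length: int, gc: float, rng: np.random.Generator | int, config: ScanConfig | None = None
) -> str:
    """Repeat-free i.i.d. background of the requested GC content.

    Any window the scanner flags as a threshold-passing SSR is resampled
    until the sequence is clean; deterministic for a fixed generator state.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    config = config or ScanConfig()
    seq = list(_random_bases(rng, length, gc))
    for _ in range(100):
        loci = scan_perfect_ssrs("".join(seq), config)
        if not loci:
            return "".join(seq)
        for loc in loci:
            patch = _random_bases(rng, loc.end - loc.start, gc)
            seq[loc.start : loc.end] = patch
    raise InfeasibleSpecError("background cleaning did not converge")


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _clean_codons(rng: np.random.Generator, n: int, config: ScanConfig) -> str:
    """Stop-free codon background with no threshold-passing SSR."""
    if n <= 0:
        return ""
    seq = _random_codons(rng, n)
    for _ in range(100):
        loci = scan_perfect_ssrs(seq, config)
        if not loci:
            return seq
        chars = list(seq)
        for loc in loci:
            c0, c1 = loc.start // 3, (loc.end + 2) // 3
            chars[c0 * 3 : c1 * 3] = _random_codons(rng, c1 - c0)
        seq = "".join(chars)
    raise InfeasibleSpecError("codon background cleaning did not converge")


def _orf_phase(canonical: str) -> str | None:
    """A class member whose in-frame codons are stop-free, for codon-aligned
    planting; None when the unit length is not divisible by 3."""
    if len(canonical) % 3 != 0:
        return None
    for member in sorted(class_members(canonical)):
        codons = {member[i : i + 3] for i in range(0, len(member), 3)}
        if not (codons & _STOPS):
            return member
    return None


def _draw_class(rng, classes: Sequence[str], probs: np.ndarray) -> str:
    return classes[int(rng.choice(len(classes), p=probs))]


@dataclass(frozen=True)
class _MemberPlan:
    motif: str
    copies: int

    @property
    def length(self) -> int:
        return len(self.motif) * self.copies

    def render(self) -> str:
        return self.motif * self.copies


@dataclass(frozen=True)
class _EventPlan:
    members: tuple[_MemberPlan, ...]
    spacers: tuple[int, ...]

    @property
    def length(self) -> int:
        return sum(m.length for m in self.members) + sum(self.spacers)


def _plan_events(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    fraction: Fraction,
    n_events: int,
) -> list[_EventPlan]:
    cfg = spec.scan_config
    in_orf = fraction is Fraction.ORF
    items = [
        (c, w)
        for c, w in spec.motif_weights.items()
        if w > 0 and (not in_orf or _orf_phase(c) is not None)
    ]
    if n_events and not items:
        raise InfeasibleSpecError(f"no admissible motif classes for {fraction}")
    classes = [c for c, _ in items]
    probs = np.array([w for _, w in items])
    probs = probs / probs.sum()
    plans = []
    for _ in range(n_events):
        compound = rng.random() < spec.compound_proportion
        n_members = 2 if compound else 1
        chosen: list[str] = []
        while len(chosen) < n_members:
            c = _draw_class(rng, classes, probs)
            if c not in chosen:
                chosen.append(c)
            elif len(classes) == 1:
                break
        members = []
        for c in chosen:
            k = len(c)
            copies = cfg.min_repeats[k] + min(
                int(rng.geometric(spec.repeat_geom_p)) - 1, spec.max_extra_repeats
            )
            motif = _orf_phase(c) if in_orf else c
            members.append(_MemberPlan(motif=motif, copies=copies))
        spacers = []
        for _ in range(len(members) - 1):
            lo, hi = spec.compound_spacer_range
            sp = int(rng.integers(lo, hi + 1))
            if in_orf:
                sp = max(3, (sp // 3) * 3)  # codon-aligned spacer, still < 100
            spacers.append(sp)
        plans.append(_EventPlan(members=tuple(members), spacers=tuple(spacers)))
    return plans


def _guard_char(rng: np.random.Generator, *forbidden: str) -> str:
    choices = [b for b in "ACGT" if b not in forbidden]
    return choices[int(rng.integers(0, len(choices)))]


def _render_event(rng, plan: _EventPlan, spec: SyntheticSpec, in_orf: bool) -> tuple[str, list[tuple[int, _MemberPlan]]]:
    """Event block string and member offsets within it; spacer backgrounds
    get guard characters so they cannot extend the flanking arrays."""
    parts: list[str] = []
    offsets: list[tuple[int, _MemberPlan]] = []
    pos = 0
    for i, member in enumerate(plan.members):
        if i > 0:
            sp = plan.spacers[i - 1]
            if in_orf:
                bg = _random_codons(rng, sp // 3)
            else:
                bg = _random_bases(rng, sp, spec.gc_content)
            prev_unit = plan.members[i - 1].motif
            bg = list(bg)
            bg[0] = _guard_char(rng, prev_unit[0])
            bg[-1] = _guard_char(rng, member.motif[-1])
            if in_orf:
                bg = _fix_stops(rng, bg)
            bg = "".join(bg)
            parts.append(bg)
            pos += len(bg)
        offsets.append((pos, member))
        parts.append(member.render())
        pos += member.length
    return "".join(parts), offsets


def _fix_stops(rng, chars: list[str]) -> list[str]:
    """Remove stop codons created by guard-character edits (codon-aligned
    char list)."""
    for c in range(0, len(chars) - 2, 3):
        while "".join(chars[c : c + 3]) in _STOPS:
            chars[c + 1] = _guard_char(rng, chars[c + 1])
    return chars


def _assemble_fraction(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    fraction: Fraction,
    planned_len: int,
    plans: Sequence[_EventPlan],
) -> tuple[str, list[tuple[int, _EventPlan, list[tuple[int, _MemberPlan]]]]]:
    """Interleave event blocks with clean background inside ``planned_len``.

    The background is generated and repeat-cleaned once per fraction and
    sliced into the gaps (a slice of a clean string is clean), then guard
    characters at the block junctions stop the planted arrays from
    extending into the background. Separation between consecutive events
    exceeds the compound spacer. Returns the fraction string (exactly
    ``planned_len`` bp, codon-aligned for the ORF interior) and each
    event's offset.
    """
    in_orf = fraction is Fraction.ORF
    unit = 3 if in_orf else 1
    slots = planned_len // unit
    min_gap_slots = math.ceil(101 / unit)
    margin = 1  # keep blocks off the fraction edges
    rendered = []
    for plan in plans:
        block, offsets = _render_event(rng, plan, spec, in_orf)
        rendered.append((block, plan, offsets))
    block_slots = sum(len(b) // unit for b, _, _ in rendered)
    n = len(rendered)
    free = slots - block_slots - min_gap_slots * max(0, n - 1) - 2 * margin
    if free < 0:
        raise InfeasibleSpecError(
            f"{fraction}: cannot fit {n} events in {planned_len} bp with >100 bp separation"
        )
    extra = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1))) if n else None
    gap_slots = (
        [margin + int(extra[0])]
        + [min_gap_slots + int(extra[i]) for i in range(1, n)]
        + [margin + int(extra[n])]
        if n
        else [slots]
    )
    total_bg_slots = sum(gap_slots)
    if in_orf:
        pool = _clean_codons(rng, total_bg_slots, spec.scan_config)
    else:
        pool = generate_background(
            max(1, total_bg_slots), spec.gc_content, rng, spec.scan_config
        )[:total_bg_slots]
    pool_pos = 0

    def take(nslots: int) -> str:
        nonlocal pool_pos
        piece = pool[pool_pos * unit : (pool_pos + nslots) * unit]
        pool_pos += nslots
        return piece

    parts: list[str] = []
    placed = []
    pos = 0
    for i, (block, plan, offsets) in enumerate(rendered):
        bg = take(gap_slots[i])
        if bg:
            bg = list(bg)
            bg[-1] = _guard_char(rng, plan.members[0].motif[-1])
            if i > 0:
                prev_unit = rendered[i - 1][1].members[-1].motif
                bg[0] = _guard_char(rng, prev_unit[0])
            if in_orf:
                bg = _fix_stops(rng, bg)
            bg = "".join(bg)
        parts.append(bg)
        pos += len(bg)
        placed.append((pos, plan, offsets))
        parts.append(block)
        pos += len(block)
    bg = take(gap_slots[-1]) if n else pool
    if bg and rendered:
        bg = list(bg)
        bg[0] = _guard_char(rng, rendered[-1][1].members[-1].motif[0])
        if in_orf:
            bg = _fix_stops(rng, bg)
        bg = "".join(bg)
    parts.append(bg)
    seq = "".join(parts)
    if len(seq) != slots * unit:
        raise AssertionError("fraction assembly length mismatch")
    return seq, placed


def _expected_loci(placed, offset: int):
    """(start, end, motif, copies) tuples the scanner must report, given the
    fraction-local offset of each event block."""
    out = []
    for pos, plan, offsets in placed:
        for off, member in offsets:
            start = offset + pos + off
            out.append((start, start + member.length, member.motif, member.copies))
    return sorted(out)


def _verify_fraction(seq: str, expected, config: ScanConfig) -> bool:
    found = [
        (l.start, l.end, l.motif_as_found, l.repeat_count)
        for l in scan_perfect_ssrs(seq, config)
    ]
    return found == sorted(expected)


# ---------------------------------------------------------------------------
# sequence- and genus-level generation


@dataclass(frozen=True)
class SyntheticEST:
    seq_id: str
    emitted: str  # as written to FASTA (possibly reverse-complemented)
    oriented: str  # forward-coding orientation
    antisense: bool
    spans: Mapping[Fraction, tuple[int, int]]
    events: tuple[PlantedEvent, ...]


def _plan_lengths(rng, spec: SyntheticSpec) -> tuple[int, int, int]:
    L = int(rng.integers(spec.length_min, spec.length_max + 1))
    orf_len = max(spec.min_orf_bp, int(round(spec.orf_fraction_of_length * L / 3)) * 3)
    orf_len = max(orf_len, 18)
    rest = L - orf_len
    u5 = max(len(_FRAME_BARRIER) + 4, int(round(spec.utr5_share * rest)))
    u3 = max(4, rest - u5)
    return u5, orf_len, u3


def _body_capacity(fraction: Fraction, planned: int) -> int:
    """Plantable bp inside a fraction (after barrier / start / stop)."""
    if fraction is Fraction.ORF:
        return ((planned - 6) // 3) * 3
    if fraction is Fraction.FIVE_UTR:
        return planned - len(_FRAME_BARRIER)
    return planned


def _shed_to_capacity(
    plans: list[_EventPlan], fraction: Fraction, planned: int
) -> list[_EventPlan]:
    capacity = _body_capacity(fraction, planned)
    unit = 3 if fraction is Fraction.ORF else 1
    min_gap = math.ceil(101 / unit) * unit
    margin = 2 * unit
    while plans:
        need = sum(p.length for p in plans) + min_gap * (len(plans) - 1) + margin
        if need <= capacity:
            break
        plans = plans[:-1]
    return plans


def _generate_sequence(spec: SyntheticSpec, index: int) -> SyntheticEST:
    seq_id = f"{spec.genus}_est{index:05d}"
    # the event plan is drawn once, independent of assembly retries, so
    # verification failures cannot select against event-rich sequences
    plan_rng = np.random.default_rng([spec.seed % (2**31), index, 1_000_003])
    u5_len, orf_len, u3_len = _plan_lengths(plan_rng, spec)
    lengths = {
        Fraction.FIVE_UTR: u5_len,
        Fraction.ORF: orf_len,
        Fraction.THREE_UTR: u3_len,
    }
    plans: dict[Fraction, list[_EventPlan]] = {}
    for fraction, planned in lengths.items():
        density = spec.density_per_mbp.get(fraction, 0.0)
        n_events = int(plan_rng.poisson(density * planned / 1e6))
        drawn = _plan_events(plan_rng, spec, fraction, n_events)
        plans[fraction] = _shed_to_capacity(drawn, fraction, planned)
    antisense = bool(plan_rng.random() < spec.antisense_probability)
    for attempt in range(60):
        rng = np.random.default_rng([spec.seed % (2**31), index, 2_000_003 + attempt])
        est = _try_generate(rng, spec, seq_id, lengths, plans, antisense)
        if est is not None:
            return est
    raise InfeasibleSpecError(f"could not realize sequence {seq_id} under the spec")


def _try_generate(
    rng,
    spec: SyntheticSpec,
    seq_id: str,
    lengths: Mapping[Fraction, int],
    plans: Mapping[Fraction, list[_EventPlan]],
    antisense: bool,
) -> SyntheticEST | None:
    cfg = spec.scan_config
    frac_seqs: dict[Fraction, str] = {}
    frac_events: dict[Fraction, list] = {}
    for fraction in (Fraction.FIVE_UTR, Fraction.ORF, Fraction.THREE_UTR):
        planned = lengths[fraction]
        frac_plans = list(plans[fraction])
        while True:
            try:
                if fraction is Fraction.ORF:
                    interior, placed = _assemble_fraction(
                        rng, spec, fraction, planned - 6, frac_plans
                    )
                    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
                    seq = "ATG" + interior + stop
                    offset = 3
                elif fraction is Fraction.FIVE_UTR:
                    body, placed = _assemble_fraction(
                        rng, spec, fraction, planned - len(_FRAME_BARRIER), frac_plans
                    )
                    seq = body + _FRAME_BARRIER
                    offset = 0
                else:
                    seq, placed = _assemble_fraction(rng, spec, fraction, planned, frac_plans)
                    offset = 0
                break
            except InfeasibleSpecError:
                if not frac_plans:
                    raise
                frac_plans = frac_plans[:-1]  # safety net; plans are pre-shed
        expected = _expected_loci(placed, offset)
        if not _verify_fraction(seq, expected, cfg):
            return None
        frac_seqs[fraction] = seq
        frac_events[fraction] = [(pos, plan, offsets, offset) for pos, plan, offsets in placed]
    oriented = frac_seqs[Fraction.FIVE_UTR] + frac_seqs[Fraction.ORF] + frac_seqs[Fraction.THREE_UTR]
    u5 = len(frac_seqs[Fraction.FIVE_UTR])
    orf_end = u5 + len(frac_seqs[Fraction.ORF])
    call = find_longest_orf(oriented, min_orf_bp=spec.min_orf_bp, seq_id=seq_id)
    if call is None or (call.start, call.end, call.source_strand.value) != (u5, orf_end, "+"):
        return None
    spans = {
        Fraction.FIVE_UTR: (0, u5),
        Fraction.ORF: (u5, orf_end),
        Fraction.THREE_UTR: (orf_end, len(oriented)),
    }
    events: list[PlantedEvent] = []
    for fraction in (Fraction.FIVE_UTR, Fraction.ORF, Fraction.THREE_UTR):
        frac_start = spans[fraction][0]
        for pos, plan, offsets, offset in frac_events[fraction]:
            members = []
            for off, mp in offsets:
                start = offset + pos + off
                members.append(
                    PlantedMember(
                        motif=mp.motif,
                        canonical=canonical_class(mp.motif),
                        repeat_count=mp.copies,
                        start=start,
                        end=start + mp.length,
                    )
                )
            kind = EventKind.PERFECT if len(members) == 1 else EventKind.COMPOUND
            events.append(
                PlantedEvent(
                    seq_id=seq_id,
                    fraction=fraction,
                    kind=kind,
                    members=tuple(members),
                    start_global=frac_start + members[0].start,
                    end_global=frac_start + members[-1].end,
                )
            )
    emitted = reverse_complement(oriented) if antisense else oriented
    if antisense:
        # the flipped record must re-orient to the same planted ORF
        call2 = find_longest_orf(emitted, min_orf_bp=spec.min_orf_bp, seq_id=seq_id)
        if call2 is None or (call2.start, call2.end, call2.source_strand.value) != (
            u5,
            orf_end,
            "-",
        ):
            return None
    return SyntheticEST(
        seq_id=seq_id,
        emitted=emitted,
        oriented=oriented,
        antisense=antisense,
        spans=spans,
        events=tuple(sorted(events, key=lambda e: e.start_global)),
    )


@dataclass
class SimulatedGenus:
    spec: SyntheticSpec
    sequences: list[SyntheticEST]
    manifest: TruthManifest

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for est in self.sequences:
                fh.write(f">{est.seq_id}\n")
                for i in range(0, len(est.emitted), 70):
                    fh.write(est.emitted[i : i + 70] + "\n")
        return path

    def write_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.manifest.to_json())
        return path

    def write_metadata(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("genus\tgenome_size_pg\n")
            fh.write(f"{self.spec.genus}\t{self.spec.genome_size_pg:g}\n")
        return path


def generate_genus_dataset(spec: SyntheticSpec) -> SimulatedGenus:
    """Generate a full synthetic genus: sequences plus truth manifest.

    Fully reproducible from ``spec.seed``; two specs differing only in
    seed give different sequences with the same expected densities.
    """
    sequences = [_generate_sequence(spec, i) for i in range(spec.n_sequences)]
    fraction_bp: dict[Fraction, int] = {f: 0 for f in (Fraction.FIVE_UTR, Fraction.ORF, Fraction.THREE_UTR)}
    events: list[PlantedEvent] = []
    for est in sequences:
        for f in fraction_bp:
            s, e = est.spans[f]
            fraction_bp[f] += e - s
        events.extend(est.events)
    manifest = TruthManifest(
        genus=spec.genus,
        seed=spec.seed,
        events=events,
        fraction_bp=fraction_bp,
        n_sequences=spec.n_sequences,
    )
    return SimulatedGenus(spec=spec, sequences=sequences, manifest=manifest)


def plant_fraction(
    fraction: Fraction,
    planned_len: int,
    spec: SyntheticSpec,
    rng: np.random.Generator | int,
    n_events: int | None = None,
) -> tuple[str, list[tuple[int, int, str, int]]]:
    """Build one fraction sequence with planted events (testing helper).

    Returns the fraction string and the planted loci as
    ``(start, end, motif, copies)`` tuples; ``n_events`` overrides the
    Poisson draw from the spec's density.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    density = spec.density_per_mbp.get(fraction, 0.0)
    if n_events is None:
        n_events = int(rng.poisson(density * planned_len / 1e6))
    plans = _plan_events(rng, spec, fraction, n_events)
    seq, placed = _assemble_fraction(rng, spec, fraction, planned_len, plans)
    return seq, _expected_loci(placed, 0)


# ---------------------------------------------------------------------------
# recovery evaluation


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def evaluate_recovery(
    manifest: TruthManifest,
    detected: Sequence[SSREvent],
    fractions: Mapping[str, FractionedSequence],
) -> RecoveryReport:
    """Match detected events against planted truth.

    Events match by >=50% reciprocal span overlap on the oriented
    sequence. Precision is matched/detected (reported as 1 with a flag
    when nothing was detected), recall matched/planted; field agreement
    rates are over matched pairs.
    """
    det_global: list[tuple[str, tuple[int, int], SSREvent]] = []
    for ev in detected:
        fs = fractions.get(ev.seq_id)
        if fs is not None and ev.fraction in fs.spans:
            off = fs.spans[ev.fraction][0]
        else:
            off = 0
        s, e = ev.span
        det_global.append((ev.seq_id, (s + off, e + off), ev))
    by_seq: dict[str, list[int]] = {}
    for i, (sid, _, _) in enumerate(det_global):
        by_seq.setdefault(sid, []).append(i)
    used: set[int] = set()
    matched: list[tuple[PlantedEvent, SSREvent]] = []
    for pl in manifest.events:
        span_p = (pl.start_global, pl.end_global)
        best, best_ov = None, 0
        for i in by_seq.get(pl.seq_id, ()):
            if i in used:
                continue
            _, span_d, ev = det_global[i]
            ov = _overlap(span_p, span_d)
            if (
                ov * 2 >= (span_p[1] - span_p[0])
                and ov * 2 >= (span_d[1] - span_d[0])
                and ov > best_ov
            ):
                best, best_ov = i, ov
        if best is not None:
            used.add(best)
            matched.append((pl, det_global[best][2]))
    n_planted = len(manifest.events)
    n_detected = len(detected)
    n_matched = len(matched)
    if matched:
        frac_ok = sum(1 for pl, ev in matched if pl.fraction == ev.fraction) / n_matched
        canon_ok = (
            sum(
                1
                for pl, ev in matched
                if tuple(m.canonical for m in pl.members)
                == tuple(m.canonical for m in ev.members)
            )
            / n_matched
        )
        reps_ok = (
            sum(
                1
                for pl, ev in matched
                if tuple(m.repeat_count for m in pl.members)
                == tuple(m.repeat_count for m in ev.members)
            )
            / n_matched
        )
    else:
        frac_ok = canon_ok = reps_ok = 1.0 if n_planted == 0 else 0.0
    return RecoveryReport(
        precision=n_matched / n_detected if n_detected else 1.0,
        recall=n_matched / n_planted if n_planted else 1.0,
        fraction_agreement=frac_ok,
        canonical_agreement=canon_ok,
        repeat_count_agreement=reps_ok,
        n_planted=n_planted,
        n_detected=n_detected,
        n_matched=n_matched,
        zero_detections=n_detected == 0,
    )


# ---------------------------------------------------------------------------
# presets


def angiosperm_preset(seed: int = 0, **overrides) -> SyntheticSpec:
    """UTR-dense, AG-rich profile typical of angiosperm EST collections."""
    base = dict(
        genus="AngioSim",
        gc_content=0.50,
        density_per_mbp={
            Fraction.FIVE_UTR: 900.0,
            Fraction.ORF: 400.0,
            Fraction.THREE_UTR: 600.0,
        },
        genome_size_pg=0.6,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


def gymnosperm_preset(seed: int = 0, **overrides) -> SyntheticSpec:
    """AT-rich, 3'UTR-dominant profile typical of gymnosperm EST
    collections (larger genomes, lower overall density)."""
    weights = {
        "AT": 0.22,
        "AG": 0.14,
        "AC": 0.07,
        "CG": 0.005,
        "AAT": 0.10,
        "AAG": 0.08,
        "AAC": 0.05,
        "ATC": 0.04,
        "ACC": 0.03,
        "ACG": 0.005,
        "AAAT": 0.05,
        "AAAG": 0.02,
        "AAAAT": 0.02,
        "AATGCC": 0.07,
        "AAGGAG": 0.05,
        "AAGCTC": 0.04,
        "AACCCTC": 0.005,
        "AACGCTAC": 0.005,
    }
    base = dict(
        genus="GymnoSim",
        gc_content=0.42,
        motif_weights=weights,
        density_per_mbp={
            Fraction.FIVE_UTR: 280.0,
            Fraction.ORF: 200.0,
            Fraction.THREE_UTR: 380.0,
        },
        genome_size_pg=15.0,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)
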