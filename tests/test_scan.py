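"""Scanner semantics: thresholds, runs, containment, compound merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estssr.partition import Fraction
from estssr.scan import (
    DEFAULT_MIN_REPEATS,
    EventKind,
    ScanConfig,
    ScanError,
    SSRLocus,
    brute_force_oracle_scan,
    merge_compound,
    scan_events,
    scan_perfect_ssrs,
    scan_unit_runs,
)


def locus(start, motif, copies, seq_id="s", fraction=Fraction.UNPARTITIONED):
    return SSRLocus(
        seq_id=seq_id,
        fraction=fraction,
        start=start,
        end=start + len(motif) * copies,
        motif_as_found=motif,
        canonical=motif,
        unit_length=len(motif),
        repeat_count=copies,
    )


class TestUnitRuns:
    def test_dimer_run(self):
        runs = scan_unit_runs("TA" * 10, 2)
        assert runs == [(0, 20, "TA", 10)]

    def test_trimer_run(self):
        runs = scan_unit_runs("ACG" * 7, 3)
        assert runs == [(0, 21, "ACG", 7)]

    def test_homopolymer_is_not_a_dimer_run(self):
        assert scan_unit_runs("A" * 12, 2) == []

    def test_partial_trailing_unit_excluded(self):
        # 4 complete copies plus "A C" partial
        runs = scan_unit_runs("ACGT" * 4 + "AC", 4)
        assert runs == [(0, 16, "ACGT", 4)]

    def test_n_breaks_runs(self):
        runs = scan_unit_runs("TA" * 5 + "N" + "TA" * 5, 2)
        assert [(s, e) for s, e, _, _ in runs] == [(0, 10), (11, 21)]

    def test_empty_sequence(self):
        assert scan_unit_runs("", 2) == []

    def test_invalid_character_rejected(self):
        with pytest.raises(ScanError):
            scan_unit_runs("ACGTX", 2)

    def test_same_unit_length_runs_do_not_overlap(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("AT"), size=60))
            for k in (2, 3, 4):
                runs = scan_unit_runs(seq, k)
                for (s1, e1, *_), (s2, e2, *_) in zip(runs, runs[1:]):
                    assert e1 <= s2


class TestPerfectScan:
    def test_flanked_dimer_ten_copies(self):
        seq = "GGCGGCATC" + "TA" * 10 + "CCGGTACTG"
        loci = scan_perfect_ssrs(seq)
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.unit_length, l.repeat_count) == (9, 29, 2, 10)
        assert l.canonical == "AT"
        assert l.length_bp == 20

    def test_eight_copy_dimer_below_threshold(self):
        assert scan_perfect_ssrs("TATATATATATATATA") == []

    def test_mononucleotide_excluded(self):
        assert scan_perfect_ssrs("A" * 40) == []

    @pytest.mark.parametrize("k,min_rep", sorted(DEFAULT_MIN_REPEATS.items()))
    def test_class_minimum_boundary(self, k, min_rep):
        """Exactly the minimum count is reported; one fewer is not."""
        unit = "AG" if k == 2 else "AACGATCGTG"[:k]
        at_min = scan_perfect_ssrs(unit * min_rep)
        assert any(
            l.unit_length == k and l.repeat_count == min_rep for l in at_min
        )
        below = scan_perfect_ssrs(unit * (min_rep - 1))
        assert not any(l.unit_length == k for l in below)

    def test_contained_locus_suppressed(self):
        """Full containment keeps the longer span; span ties keep the
        smaller unit (visible at permissive thresholds)."""
        cfg = ScanConfig(min_repeats={k: 2 for k in range(2, 11)})
        # "ACACAC" is AC x3 and also ACA x2 over the same span
        loci = scan_perfect_ssrs("ACACAC", cfg)
        assert [(l.unit_length, l.start, l.end) for l in loci] == [(2, 0, 6)]
        # a longer span wins over a contained shorter one
        loci = scan_perfect_ssrs("AGAGAGAGAGCGCGC", cfg)
        spans = {(l.start, l.end) for l in loci}
        assert (0, 10) in spans  # AG x5
        assert not any(
            a != b and b[0] <= a[0] and a[1] <= b[1] for a in spans for b in spans
        )

    def test_no_reported_locus_contained_in_another(self, rng):
        cfg = ScanConfig(min_repeats={k: 2 for k in range(2, 11)})
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=80, p=[0.4, 0.1, 0.1, 0.4]))
            loci = scan_perfect_ssrs(seq, cfg)
            for a in loci:
                for b in loci:
                    if a is not b:
                        assert not (b.start <= a.start and a.end <= b.end)

    def test_rejects_invalid_characters(self):
        with pytest.raises(ScanError):
            scan_perfect_ssrs("ACGT-ACGT")

    def test_lowercase_accepted(self):
        assert len(scan_perfect_ssrs(("ta" * 10))) == 1


class TestOracleEquivalence:
    @given(st.integers(0, 10_000))
    @settings(max_examples=300)
    def test_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 300))
        gc = float(rng.uniform(0.2, 0.8))
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = "".join(rng.choice(list("ACGT"), size=L, p=p))
        if seed % 3 == 0:  # adversarial planted repeat
            unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
            reps = int(rng.integers(2, 14))
            pos = int(rng.integers(0, max(1, L - len(unit) * reps)))
            seq = (seq[:pos] + unit * reps + seq[pos + len(unit) * reps :])[:L]
        if seed % 7 == 0:
            seq = seq[: L // 2] + "N" + seq[L // 2 :]
        assert scan_perfect_ssrs(seq) == brute_force_oracle_scan(seq)

    def test_oracle_deterministic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500, p=[0.4, 0.1, 0.1, 0.4]))
        assert brute_force_oracle_scan(seq) == brute_force_oracle_scan(seq)

    def test_empty(self):
        assert brute_force_oracle_scan("") == []


class TestCompoundMerge:
    def test_adjacent_loci_merge(self):
        loci = [locus(0, "TA", 10), locus(20, "GT", 10)]
        events = merge_compound(loci)
        assert len(events) == 1
        assert events[0].kind is EventKind.COMPOUND
        assert events[0].spacers == (0,)

    def test_gap_100_does_not_merge(self):
        loci = [locus(0, "TA", 10), locus(120, "GT", 10)]
        events = merge_compound(loci)
        assert [e.kind for e in events] == [EventKind.PERFECT, EventKind.PERFECT]

    def test_gap_99_merges(self):
        loci = [locus(0, "TA", 10), locus(119, "GT", 10)]
        events = merge_compound(loci)
        assert [e.kind for e in events] == [EventKind.COMPOUND]
        assert events[0].spacers == (99,)

    def test_transitive_chaining(self):
        loci = [locus(0, "TA", 10), locus(70, "GT", 10), locus(140, "AG", 10)]
        events = merge_compound(loci)
        assert len(events) == 1
        assert len(events[0].members) == 3

    def test_overlap_rejected(self):
        with pytest.raises(ScanError):
            merge_compound([locus(0, "TA", 10), locus(10, "GT", 10)])

    def test_conservation(self, rng):
        """Members over all events equal the input loci exactly."""
        for _ in range(50):
            n = int(rng.integers(1, 8))
            pos, loci = 0, []
            for _ in range(n):
                pos += int(rng.integers(0, 220))
                loci.append(locus(pos, "TA", 10))
                pos += 20
            events = merge_compound(loci)
            assert [m for e in events for m in e.members] == loci

    def test_paper_style_ta_gt_example(self):
        """[TA]n directly followed by [GT]n is one compound event."""
        seq = "CGC" + "TA" * 10 + "GT" * 10 + "CGG"
        events = scan_events(seq)
        assert len(events) == 1
        assert events[0].kind is EventKind.COMPOUND
        assert [m.canonical for m in events[0].members] == ["AT", "AC"]


class TestConfig:
    def test_default_min_repeats_reach_class_one_bound(self):
        assert all(k * r >= 20 for k, r in DEFAULT_MIN_REPEATS.items())

    def test_min_repeats_below_two_rejected(self):
        with pytest.raises(ScanError):
            ScanConfig(min_repeats={2: 1})

    def test_custom_spacer(self):
        cfg = ScanConfig(max_compound_spacer=50)
        loci = [locus(0, "TA", 10), locus(80, "GT", 10)]  # gap 60
        events = merge_compound(loci, cfg)
        assert [e.kind for e in events] == [EventKind.PERFECT, EventKind.PERFECT]
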