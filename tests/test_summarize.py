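"""Densities, length summaries, and the heterogeneity/length statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from estssr.partition import Fraction
from estssr.scan import EventKind, SSREvent, SSRLocus
from estssr.summarize import (
    StatsError,
    chi2_fraction_heterogeneity,
    counts_per_mbp,
    genome_size_association,
    pearson_chi2,
    summarize_fraction,
    summarize_genus,
    table2_frame,
    table3_frame,
    tukey_hsd_lengths,
)


def perfect_event(start, motif, copies, fraction=Fraction.ORF, seq_id="s"):
    loc = SSRLocus(
        seq_id=seq_id,
        fraction=fraction,
        start=start,
        end=start + len(motif) * copies,
        motif_as_found=motif,
        canonical=motif,
        unit_length=len(motif),
        repeat_count=copies,
    )
    return SSREvent(kind=EventKind.PERFECT, members=(loc,), spacers=())


def compound_event(start, specs, gap=10, fraction=Fraction.ORF, seq_id="s"):
    members, spacers, pos = [], [], start
    for i, (motif, copies) in enumerate(specs):
        if i:
            spacers.append(gap)
            pos += gap
        members.append(
            SSRLocus(
                seq_id=seq_id,
                fraction=fraction,
                start=pos,
                end=pos + len(motif) * copies,
                motif_as_found=motif,
                canonical=motif,
                unit_length=len(motif),
                repeat_count=copies,
            )
        )
        pos = members[-1].end
    return SSREvent(kind=EventKind.COMPOUND, members=tuple(members), spacers=tuple(spacers))


class TestCountsPerMbp:
    @pytest.mark.parametrize(
        "count,bp,expected", [(5, 10_000, 500.0), (0, 10**6, 0.0), (247, 10**6, 247.0)]
    )
    def test_values(self, count, bp, expected):
        assert counts_per_mbp(count, bp) == expected

    def test_zero_bp_rejected(self):
        with pytest.raises(StatsError):
            counts_per_mbp(1, 0)


class TestSummarizeFraction:
    def test_hand_computed_mean_sd(self):
        events = [
            perfect_event(0, "AT", 10),  # 20 bp
            perfect_event(200, "AC", 10),  # 20 bp
            perfect_event(400, "AAG", 8),  # 24 bp
            perfect_event(600, "AT", 14),  # 28 bp
        ]
        fs = summarize_fraction(events, total_bp=100_000)
        assert fs.mean_length_bp == pytest.approx(23.0)
        assert fs.sd_length_bp == pytest.approx(3.83, abs=0.005)  # n-1 SD
        assert fs.counts_per_mbp == pytest.approx(40.0)

    def test_percent_compound(self):
        events = [
            compound_event(0, [("AT", 10), ("AC", 10)]),
            perfect_event(500, "AT", 10),
            perfect_event(900, "AAG", 8),
            perfect_event(1300, "AC", 12),
        ]
        fs = summarize_fraction(events, total_bp=10_000)
        assert fs.percent_compound == pytest.approx(25.0)
        # compound members feed the member-level tallies
        assert fs.member_count == 5
        assert fs.event_count == 4

    def test_empty_events(self):
        fs = summarize_fraction([], total_bp=1000, fraction=Fraction.ORF)
        assert fs.counts_per_mbp == 0.0
        assert math.isnan(fs.mean_length_bp)
        assert math.isnan(fs.sd_length_bp)

    def test_mixed_fraction_rejected(self):
        events = [perfect_event(0, "AT", 10, fraction=Fraction.ORF),
                  perfect_event(50, "AT", 10, fraction=Fraction.THREE_UTR)]
        with pytest.raises(StatsError):
            summarize_fraction(events, total_bp=1000)

    def test_density_scale_invariance(self):
        """Doubling the dataset (events and bp) leaves densities unchanged."""
        events = [perfect_event(0, "AT", 10), perfect_event(300, "AAG", 8)]
        doubled = events + [
            perfect_event(0, "AT", 10, seq_id="s2"),
            perfect_event(300, "AAG", 8, seq_id="s2"),
        ]
        one = summarize_fraction(events, total_bp=5000)
        two = summarize_fraction(doubled, total_bp=10000)
        assert one.counts_per_mbp == pytest.approx(two.counts_per_mbp)
        assert one.counts_per_mbp_by_unit_length == two.counts_per_mbp_by_unit_length


class TestChi2:
    def _summary(self, ssr_bp, total_bp, fraction):
        return summarize_fraction(
            [perfect_event(0, "AT", ssr_bp // 2, fraction=fraction)] if ssr_bp else [],
            total_bp=total_bp,
            fraction=fraction,
        )

    def test_equal_proportions_give_zero(self):
        summaries = [
            self._summary(40, 4000, Fraction.FIVE_UTR),
            self._summary(40, 4000, Fraction.ORF),
            self._summary(40, 4000, Fraction.THREE_UTR),
        ]
        res = chi2_fraction_heterogeneity(summaries)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_matches_hand_computed_pearson(self):
        table = np.array([[30, 20, 10], [970, 980, 990]], dtype=float)
        # direct sum((O-E)^2 / E)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows @ cols / table.sum()
        by_hand = float(((table - expected) ** 2 / expected).sum())
        res = pearson_chi2(table)
        assert res.statistic == pytest.approx(by_hand, rel=1e-12)
        assert res.df == 2

    def test_column_order_invariance(self):
        t = np.array([[30, 20, 10], [970, 980, 990]], dtype=float)
        assert pearson_chi2(t).statistic == pytest.approx(
            pearson_chi2(t[:, ::-1]).statistic
        )

    def test_zero_bp_fraction_rejected(self):
        summaries = [
            self._summary(40, 4000, Fraction.FIVE_UTR),
            self._summary(40, 4000, Fraction.ORF),
        ]
        with pytest.raises(StatsError):
            chi2_fraction_heterogeneity(summaries)


class TestTukey:
    def test_identical_groups(self):
        groups = {"a": [5, 5, 5], "b": [5, 5, 5], "c": [5, 5, 5]}
        res = tukey_hsd_lengths(groups)
        assert res.p_value == pytest.approx(1.0)
        assert all(res.pairwise["p_adj"] == 1.0)
        assert all(res.pairwise["meandiff"] == 0.0)

    def test_matches_scipy_reference(self):
        """Pairwise adjusted p-values agree with an independent Tukey HSD
        implementation to 4 decimals on a fixed dataset."""
        groups = {
            "u5": [20.0, 22.0, 24.0, 20.0, 26.0, 21.0],
            "orf": [24.0, 27.0, 30.0, 24.0, 28.0, 30.0],
            "u3": [20.0, 23.0, 22.0, 25.0, 21.0, 24.0],
        }
        res = tukey_hsd_lengths(groups, use_ranks=False)
        ref = sps.tukey_hsd(*groups.values())
        names = list(groups)
        for _, row in res.pairwise.iterrows():
            i, j = names.index(row.group1), names.index(row.group2)
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-4)

    def test_rank_version_matches_reference_on_ranks(self):
        groups = {
            "a": [20.0, 22.0, 24.0, 23.0, 26.0],
            "b": [28.0, 27.0, 30.0, 24.0, 28.0],
            "c": [20.0, 23.0, 22.0, 25.0, 21.0],
        }
        res = tukey_hsd_lengths(groups, use_ranks=True)
        pooled = np.concatenate([groups["a"], groups["b"], groups["c"]])
        ranks = sps.rankdata(pooled)
        ranked = {
            "a": ranks[:5],
            "b": ranks[5:10],
            "c": ranks[10:],
        }
        ref = sps.tukey_hsd(*ranked.values())
        names = list(groups)
        for _, row in res.pairwise.iterrows():
            i, j = names.index(row.group1), names.index(row.group2)
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-4)

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            tukey_hsd_lengths({"a": [1, 2, 3]})

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            tukey_hsd_lengths({"a": [1, 2], "b": [3]})


class TestGenomeSizeAssociation:
    def _genus(self, name, pg, mean_len):
        ev = perfect_event(0, "AT", max(10, int(mean_len // 2)), fraction=Fraction.THREE_UTR)
        return summarize_genus(
            name,
            {Fraction.THREE_UTR: [ev]},
            {Fraction.FIVE_UTR: 1000, Fraction.ORF: 1000, Fraction.THREE_UTR: 1000},
            genome_size_pg=pg,
        )

    def test_perfectly_linear_metric(self):
        genera = [self._genus(f"g{i}", float(i + 1), 20 + 4 * i) for i in range(5)]
        res = genome_size_association(genera, metric="mean_length")
        assert res.statistic == pytest.approx(1.0)

    def test_too_few_genera_rejected(self):
        genera = [self._genus("a", 1.0, 20), self._genus("b", 2.0, 24)]
        with pytest.raises(StatsError):
            genome_size_association(genera)

    def test_null_metric_not_significant_on_average(self):
        """With the metric independent of genome size, |r| stays small and p
        large on average over reshuffled replicates."""
        rng = np.random.default_rng(5)
        rs, ps = [], []
        base_lengths = [20, 28, 24, 32, 22, 30, 26, 34]
        for _ in range(40):
            lengths = rng.permutation(base_lengths)
            genera = [
                self._genus(f"g{i}", float(i + 1), int(lengths[i])) for i in range(8)
            ]
            res = genome_size_association(genera, metric="mean_length")
            rs.append(abs(res.statistic))
            ps.append(res.p_value)
        assert np.mean(rs) < 0.45
        assert np.mean(ps) > 0.3


class TestTables:
    def test_table2_conserves_member_density(self):
        events = [
            perfect_event(0, "AT", 10),
            perfect_event(300, "AAG", 8),
            compound_event(700, [("AC", 10), ("AAC", 7)]),
        ]
        g = summarize_genus(
            "g",
            {Fraction.ORF: events},
            {Fraction.FIVE_UTR: 1000, Fraction.ORF: 100_000, Fraction.THREE_UTR: 1000},
        )
        t2 = table2_frame([g])
        orf_rows = t2[(t2["fraction"] == "ORF")]
        total_member_density = counts_per_mbp(4, 100_000)
        assert orf_rows["counts_per_mbp"].sum() == pytest.approx(total_member_density)

    def test_table3_rows_are_canonical_classes(self):
        g = summarize_genus(
            "g",
            {},
            {Fraction.FIVE_UTR: 1000, Fraction.ORF: 1000, Fraction.THREE_UTR: 1000},
        )
        t3 = table3_frame([g])
        dimers = set(t3[t3["canonical"].str.len() == 2]["canonical"])
        trimers = set(t3[t3["canonical"].str.len() == 3]["canonical"])
        assert dimers == {"AC", "AG", "AT", "CG"}
        assert len(trimers) == 10
        # empty fractions are zero-filled rows, not missing rows
        assert len(t3) == 3 * 14
        assert (t3["counts_per_mbp"] == 0).all()
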