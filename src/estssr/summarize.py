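"""Per-genus, per-fraction SSR summaries and heterogeneity statistics.

Densities are reported as events per Mbp of fraction sequence; a compound
event counts once in the event totals while each of its member loci
contributes to the motif-size (unit length 2-10) and motif-class
(canonical dimer/trimer) composition tables, which are therefore
member-level densities. Length summaries (mean, sample SD) are over
member-locus lengths.

Three tests mirror the analysis this package supports:

* a 2x3 Pearson chi-square for heterogeneity of repeat content across the
  5'UTR / ORF / 3'UTR fractions, on a table of bp inside vs outside SSR
  loci per fraction (df = 2);
* Tukey's HSD on SSR lengths between fractions, by default applied to
  global midranks so it behaves as a non-parametric comparison;
* Pearson correlation between genome size (pg) and a chosen per-genus
  metric (mean repeat length or density), p from the t transform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motif import enumerate_canonical_classes
from .partition import Fraction
from .scan import EventKind, SSREvent

REPORT_FRACTIONS = (Fraction.FIVE_UTR, Fraction.ORF, Fraction.THREE_UTR)
UNIT_LENGTHS = tuple(range(2, 11))


class StatsError(ValueError):
    """Raised for degenerate inputs (zero-length fractions, empty groups)."""


@dataclass(frozen=True)
class FractionSummary:
    """Totals for one genomic fraction of one genus."""

    fraction: Fraction
    total_bp: int
    event_count: int
    compound_count: int
    member_count: int
    ssr_bp: int
    mean_length_bp: float  # NaN when no events
    sd_length_bp: float  # NaN when < 2 member loci
    member_count_by_unit_length: Mapping[int, int] = field(default_factory=dict)
    member_count_by_canonical: Mapping[str, int] = field(default_factory=dict)

    @property
    def mbp(self) -> float:
        return self.total_bp / 1e6

    @property
    def counts_per_mbp(self) -> float:
        return counts_per_mbp(self.event_count, self.total_bp)

    @property
    def percent_compound(self) -> float:
        return 100.0 * self.compound_count / self.event_count if self.event_count else 0.0

    @property
    def counts_per_mbp_by_unit_length(self) -> dict[int, float]:
        return {
            k: counts_per_mbp(self.member_count_by_unit_length.get(k, 0), self.total_bp)
            for k in UNIT_LENGTHS
        }

    @property
    def counts_per_mbp_by_canonical(self) -> dict[str, float]:
        return {
            c: counts_per_mbp(n, self.total_bp)
            for c, n in sorted(self.member_count_by_canonical.items())
        }


@dataclass(frozen=True)
class GenusSummary:
    genus: str
    genome_size_pg: float | None
    fractions: Mapping[Fraction, FractionSummary]

    def dimer_trimer_ratio(self, fraction: Fraction) -> float:
        fs = self.fractions[fraction]
        dimers = sum(
            n for c, n in fs.member_count_by_canonical.items() if len(c) == 2
        )
        trimers = sum(
            n for c, n in fs.member_count_by_canonical.items() if len(c) == 3
        )
        return dimers / trimers if trimers else math.nan


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: float
    p_value: float
    pairwise: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def counts_per_mbp(event_count: int, total_bp: int) -> float:
    """Events per megabase: ``count * 1e6 / total_bp``."""
    if total_bp <= 0:
        raise StatsError("counts_per_mbp undefined for total_bp <= 0")
    return event_count * 1e6 / total_bp


def summarize_fraction(
    events: Sequence[SSREvent], total_bp: int, fraction: Fraction | None = None
) -> FractionSummary:
    """Aggregate one fraction's events into a :class:`FractionSummary`."""
    if total_bp <= 0:
        raise StatsError("summarize_fraction requires total_bp > 0")
    events = list(events)
    labels = {e.fraction for e in events}
    if len(labels) > 1:
        raise StatsError(f"events span multiple fractions: {labels}")
    if fraction is None:
        fraction = labels.pop() if labels else Fraction.UNPARTITIONED
    members = [m for e in events for m in e.members]
    lengths = np.array([m.length_bp for m in members], dtype=float)
    by_unit: dict[int, int] = {}
    by_canon: dict[str, int] = {}
    for m in members:
        by_unit[m.unit_length] = by_unit.get(m.unit_length, 0) + 1
        by_canon[m.canonical] = by_canon.get(m.canonical, 0) + 1
    return FractionSummary(
        fraction=fraction,
        total_bp=total_bp,
        event_count=len(events),
        compound_count=sum(1 for e in events if e.kind is EventKind.COMPOUND),
        member_count=len(members),
        ssr_bp=int(lengths.sum()) if members else 0,
        mean_length_bp=float(lengths.mean()) if members else math.nan,
        sd_length_bp=float(lengths.std(ddof=1)) if len(members) >= 2 else math.nan,
        member_count_by_unit_length=by_unit,
        member_count_by_canonical=by_canon,
    )


def chi2_fraction_heterogeneity(
    summaries: Sequence[FractionSummary],
) -> TestResult:
    """2x3 Pearson chi-square for heterogeneity of repeat content.

    Columns are the three fractions; rows are bp inside SSR loci vs bp
    outside, so the column margins are the fraction sizes and df = 2.
    """
    if len(summaries) != 3:
        raise StatsError("chi2_fraction_heterogeneity expects exactly three fractions")
    inside = [s.ssr_bp for s in summaries]
    outside = [s.total_bp - s.ssr_bp for s in summaries]
    if any(s.total_bp <= 0 for s in summaries):
        raise StatsError("all fractions must have total_bp > 0")
    table = np.array([inside, outside], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("degenerate contingency table (zero margin)")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(method="chi2_heterogeneity_2x3", statistic=float(chi2), df=float(df), p_value=float(p))


def pearson_chi2(table: np.ndarray) -> TestResult:
    """Pearson chi-square of an arbitrary contingency table (no continuity
    correction)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("degenerate contingency table (zero margin)")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(method="pearson_chi2", statistic=float(chi2), df=float(df), p_value=float(p))


def tukey_hsd_lengths(
    groups: Mapping[str, Sequence[float]], use_ranks: bool = True
) -> TestResult:
    """Tukey HSD on SSR lengths between labelled groups.

    With ``use_ranks`` (default) observations are replaced by their global
    midranks first, giving a rank-based (non-parametric) comparison; the
    classic test on raw lengths is available with ``use_ranks=False``.
    The omnibus statistic reported is the one-way F on the (possibly
    ranked) data; the pairwise table carries Tukey-adjusted p-values.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2:
        raise StatsError("tukey_hsd_lengths requires at least two groups")
    labels: list[str] = []
    values: list[float] = []
    for name, obs in groups.items():
        obs = list(obs)
        if len(obs) < 2:
            raise StatsError(f"group {name!r} has fewer than 2 observations")
        labels.extend([name] * len(obs))
        values.extend(float(v) for v in obs)
    data = np.asarray(values)
    if use_ranks:
        data = sps.rankdata(data)
    arrays = [
        data[np.asarray(labels) == name] for name in groups
    ]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all observations identical: no dispersion, nothing to compare
        pairs = [
            {"group1": g1, "group2": g2, "meandiff": 0.0, "p_adj": 1.0}
            for i, g1 in enumerate(groups)
            for g2 in list(groups)[i + 1 :]
        ]
        return TestResult(
            method="tukey_hsd" + ("_ranks" if use_ranks else ""),
            statistic=0.0,
            df=float(len(data) - len(groups)),
            p_value=1.0,
            pairwise=pd.DataFrame(pairs),
        )
    f_stat, f_p = sps.f_oneway(*arrays)
    res = pairwise_tukeyhsd(endog=data, groups=np.asarray(labels), alpha=0.05)
    from itertools import combinations

    pairs = list(combinations(res.groupsunique.tolist(), 2))
    table = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "meandiff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
        }
    )
    return TestResult(
        method="tukey_hsd" + ("_ranks" if use_ranks else ""),
        statistic=float(f_stat),
        df=float(len(data) - len(groups)),
        p_value=float(f_p),
        pairwise=table,
    )


def genome_size_association(
    genera: Sequence[GenusSummary],
    metric: str = "mean_length",
    fraction: Fraction = Fraction.THREE_UTR,
) -> TestResult:
    """Pearson correlation of genome size (pg) against a per-genus metric.

    ``metric`` is ``"mean_length"`` or ``"counts_per_mbp"``; two-sided p
    from the t transform with n-2 df.
    """
    if metric not in ("mean_length", "counts_per_mbp"):
        raise StatsError(f"unknown metric {metric!r}")
    xs, ys = [], []
    for g in genera:
        if g.genome_size_pg is None:
            continue
        fs = g.fractions[fraction]
        y = fs.mean_length_bp if metric == "mean_length" else fs.counts_per_mbp
        if not math.isnan(y):
            xs.append(g.genome_size_pg)
            ys.append(y)
    if len(xs) < 3:
        raise StatsError("genome_size_association requires >= 3 genera with data")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        method=f"pearson_r[{metric}]", statistic=float(r), df=float(len(x) - 2), p_value=float(p)
    )


# ---------------------------------------------------------------------------
# genus assembly and report rendering


def summarize_genus(
    genus: str,
    events_by_fraction: Mapping[Fraction, Sequence[SSREvent]],
    total_bp_by_fraction: Mapping[Fraction, int],
    genome_size_pg: float | None = None,
) -> GenusSummary:
    """Build a :class:`GenusSummary` from per-fraction events and sizes.

    Fractions with zero total bp are recorded with zero counts (their
    densities are undefined and rendered as zero-filled rows)."""
    fractions = {}
    for fr in REPORT_FRACTIONS:
        total_bp = int(total_bp_by_fraction.get(fr, 0))
        events = list(events_by_fraction.get(fr, ()))
        if total_bp > 0:
            fractions[fr] = summarize_fraction(events, total_bp, fraction=fr)
        else:
            fractions[fr] = FractionSummary(
                fraction=fr,
                total_bp=0,
                event_count=0,
                compound_count=0,
                member_count=0,
                ssr_bp=0,
                mean_length_bp=math.nan,
                sd_length_bp=math.nan,
            )
    return GenusSummary(genus=genus, genome_size_pg=genome_size_pg, fractions=fractions)


def _fmt(x: float, nd: int = 2) -> str:
    return "NA" if (isinstance(x, float) and math.isnan(x)) else f"{x:.{nd}f}"


def _density_or_zero(fs: FractionSummary, count: int) -> float:
    return counts_per_mbp(count, fs.total_bp) if fs.total_bp > 0 else 0.0


def table1_frame(genera: Sequence[GenusSummary]) -> pd.DataFrame:
    """Per-fraction mean(SD) length and event counts per Mbp, one row per
    genus (the length/density overview table)."""
    rows = []
    for g in genera:
        row: dict[str, object] = {"genus": g.genus, "genome_size_pg": g.genome_size_pg}
        for fr in REPORT_FRACTIONS:
            fs = g.fractions[fr]
            pre = str(fr)
            row[f"{pre}_mean_length_bp"] = _fmt(fs.mean_length_bp)
            row[f"{pre}_sd_length_bp"] = _fmt(fs.sd_length_bp)
            row[f"{pre}_counts_per_mbp"] = _fmt(
                fs.counts_per_mbp if fs.total_bp > 0 else 0.0
            )
            row[f"{pre}_percent_compound"] = _fmt(fs.percent_compound)
        rows.append(row)
    return pd.DataFrame(rows)


def table2_frame(genera: Sequence[GenusSummary]) -> pd.DataFrame:
    """Member-locus counts per Mbp by motif size (unit length 2-10), long
    format: one row per genus x fraction x unit length."""
    rows = []
    for g in genera:
        for fr in REPORT_FRACTIONS:
            fs = g.fractions[fr]
            for k in UNIT_LENGTHS:
                rows.append(
                    {
                        "genus": g.genus,
                        "fraction": str(fr),
                        "unit_length": k,
                        "counts_per_mbp": _density_or_zero(
                            fs, fs.member_count_by_unit_length.get(k, 0)
                        ),
                    }
                )
    return pd.DataFrame(rows)


def table3_frame(genera: Sequence[GenusSummary]) -> pd.DataFrame:
    """Member-locus counts per Mbp for the 4 canonical dimer and 10
    canonical trimer classes, long format."""
    dimers = enumerate_canonical_classes(2)
    trimers = enumerate_canonical_classes(3)
    rows = []
    for g in genera:
        for fr in REPORT_FRACTIONS:
            fs = g.fractions[fr]
            for motif in (*dimers, *trimers):
                rows.append(
                    {
                        "genus": g.genus,
                        "fraction": str(fr),
                        "canonical": motif,
                        "counts_per_mbp": _density_or_zero(
                            fs, fs.member_count_by_canonical.get(motif, 0)
                        ),
                    }
                )
    return pd.DataFrame(rows)


def genus_summary_dict(g: GenusSummary) -> dict:
    out: dict = {"genus": g.genus, "genome_size_pg": g.genome_size_pg, "fractions": {}}
    for fr in REPORT_FRACTIONS:
        fs = g.fractions[fr]
        out["fractions"][str(fr)] = {
            "total_bp": fs.total_bp,
            "event_count": fs.event_count,
            "member_count": fs.member_count,
            "compound_count": fs.compound_count,
            "ssr_bp": fs.ssr_bp,
            "counts_per_mbp": fs.counts_per_mbp if fs.total_bp else None,
            "member_counts_per_mbp": (
                counts_per_mbp(fs.member_count, fs.total_bp) if fs.total_bp else None
            ),
            "mean_length_bp": None if math.isnan(fs.mean_length_bp) else fs.mean_length_bp,
            "sd_length_bp": None if math.isnan(fs.sd_length_bp) else fs.sd_length_bp,
            "percent_compound": fs.percent_compound,
            "counts_per_mbp_by_unit_length": (
                {str(k): v for k, v in fs.counts_per_mbp_by_unit_length.items()}
                if fs.total_bp
                else {}
            ),
            "counts_per_mbp_by_canonical": (
                fs.counts_per_mbp_by_canonical if fs.total_bp else {}
            ),
        }
        ratio = g.dimer_trimer_ratio(fr)
        out["fractions"][str(fr)]["dimer_trimer_ratio"] = None if math.isnan(ratio) else ratio
    return out


def render_reports(genera: Sequence[GenusSummary], outdir: str | Path) -> dict[str, Path]:
    """Write the three composition tables and a JSON bundle to ``outdir``.

    Returns the paths written: table1.tsv, table2.tsv, table3.tsv,
    summary.json.
    """
    if not genera:
        raise StatsError("render_reports requires at least one genus")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "table1.tsv": table1_frame(genera),
        "table2.tsv": table2_frame(genera),
        "table3.tsv": table3_frame(genera),
    }
    for name, frame in frames.items():
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
        paths[name] = path
    bundle = {"genera": [genus_summary_dict(g) for g in genera]}
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
    paths["summary.json"] = json_path
    return paths
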