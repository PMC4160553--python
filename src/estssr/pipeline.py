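"""End-to-end workflow: cluster -> partition -> scan -> summarize -> tests.

One pipeline run takes one or more genera (each a multi-FASTA of EST
sequences), optionally removes redundancy, orients and partitions every
sequence into 5'UTR / ORF / 3'UTR, scans each fraction for perfect SSRs,
merges compound events, and writes per-genus locus tables, fraction
tables, the three summary tables and a JSON bundle of test results.
All outputs are deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .cluster import greedy_cluster, representatives
from .metadata import DEMO_GENOME_SIZES_PG, load_genome_sizes
from .partition import DEFAULT_MIN_ORF_BP, Fraction, FractionedSequence, load_orf_annotations, partition_by_orf, partition_sequence
from .scan import ScanConfig, SSREvent, events_to_frame, merge_compound, scan_perfect_ssrs
from .summarize import (
    GenusSummary,
    REPORT_FRACTIONS,
    chi2_fraction_heterogeneity,
    genome_size_association,
    render_reports,
    summarize_genus,
    tukey_hsd_lengths,
)

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "dimer_min": (2, int),
    "trimer_min": (3, int),
    "tetramer_min": (4, int),
    "pentamer_min": (5, int),
    "hexamer_min": (6, int),
    "heptamer_min": (7, int),
    "octamer_min": (8, int),
    "nonamer_min": (9, int),
    "decamer_min": (10, int),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and paths for one run; defaults are the standard
    settings (dimer-10 ... decamer-2, 100 bp spacer, 90% identity)."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    min_orf_bp: int = DEFAULT_MIN_ORF_BP
    cluster_identity: float = 0.0  # 0 disables the redundancy stage
    genome_sizes: Mapping[str, float] = field(default_factory=lambda: dict(DEMO_GENOME_SIZES_PG))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_orf_bp < 3:
            raise ValueError("min_orf_bp must be >= 3")
        if not (0.0 <= self.cluster_identity <= 1.0):
            raise ValueError("cluster_identity must be in [0, 1]")


def parse_config(path: str | Path) -> PipelineConfig:
    """Read a ``key=value`` configuration file; unknown keys are rejected.

    Recognized keys: ``dimer_min`` ... ``decamer_min``, ``compound_spacer``,
    ``min_orf_bp``, ``cluster_identity``, ``genome_sizes`` (path), ``seed``.
    An empty file yields all defaults.
    """
    min_repeats = dict(ScanConfig().min_repeats)
    spacer = ScanConfig().max_compound_spacer
    kwargs: dict = {}
    genome_sizes = None
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{line_no}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            if key in _CONFIG_KEYS:
                unit, cast = _CONFIG_KEYS[key]
                min_repeats[unit] = cast(value)
            elif key == "compound_spacer":
                spacer = int(value)
            elif key == "min_orf_bp":
                kwargs["min_orf_bp"] = int(value)
            elif key == "cluster_identity":
                kwargs["cluster_identity"] = float(value)
            elif key == "seed":
                kwargs["seed"] = int(value)
            elif key == "genome_sizes":
                genome_sizes = load_genome_sizes(value)
            else:
                raise ValueError(f"{path}:{line_no}: unknown configuration key {key!r}")
        except ValueError as exc:
            if "unknown configuration key" in str(exc):
                raise
            raise ValueError(f"{path}:{line_no}: bad value for {key!r}: {value!r}") from exc
    scan = ScanConfig(min_repeats=min_repeats, max_compound_spacer=spacer)
    if genome_sizes is not None:
        kwargs["genome_sizes"] = genome_sizes
    return PipelineConfig(scan=scan, **kwargs)


@dataclass
class GenusResult:
    genus: str
    summary: GenusSummary
    events: list[SSREvent]
    fractions: dict[str, FractionedSequence]
    n_input: int
    n_kept: int
    n_unpartitioned: int
    rejected: list[str]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def process_genus(
    genus: str,
    sequences: Sequence[tuple[str, str]],
    config: PipelineConfig,
    annotations: Mapping[str, "OrfCall"] | None = None,
) -> GenusResult:
    """Run the per-genus stages on in-memory sequences."""
    rejected: list[str] = []
    clean: list[tuple[str, str]] = []
    for seq_id, seq in sequences:
        if set(seq) <= set("ACGTN"):
            clean.append((seq_id, seq))
        else:
            rejected.append(seq_id)
            logger.error("%s: rejected %s (non-ACGTN characters)", genus, seq_id)
    n_input = len(sequences)
    if config.cluster_identity > 0 and clean:
        assignments = greedy_cluster(clean, cutoff=config.cluster_identity)
        clean = representatives(clean, assignments)
    fractions: dict[str, FractionedSequence] = {}
    n_unpartitioned = 0
    events: list[SSREvent] = []
    for seq_id, seq in clean:
        if annotations and seq_id in annotations:
            fs = partition_by_orf(seq, annotations[seq_id])
        else:
            fs = partition_sequence(seq, seq_id, min_orf_bp=config.min_orf_bp)
        if fs is None:
            n_unpartitioned += 1
            loci = scan_perfect_ssrs(
                seq, config.scan, seq_id=seq_id, fraction=Fraction.UNPARTITIONED
            )
            if loci:
                events.extend(merge_compound(loci, config.scan))
            continue
        fractions[seq_id] = fs
        for fr in REPORT_FRACTIONS:
            sub = fs.fraction_seq(fr)
            if not sub:
                continue
            loci = scan_perfect_ssrs(sub, config.scan, seq_id=seq_id, fraction=fr)
            if loci:
                events.extend(merge_compound(loci, config.scan))
    total_bp = {
        fr: sum(fs.fraction_length(fr) for fs in fractions.values())
        for fr in REPORT_FRACTIONS
    }
    by_fraction = {fr: [e for e in events if e.fraction is fr] for fr in REPORT_FRACTIONS}
    summary = summarize_genus(
        genus,
        by_fraction,
        total_bp,
        genome_size_pg=config.genome_sizes.get(genus),
    )
    return GenusResult(
        genus=genus,
        summary=summary,
        events=events,
        fractions=fractions,
        n_input=n_input,
        n_kept=len(clean),
        n_unpartitioned=n_unpartitioned,
        rejected=rejected,
    )


def _fractions_frame(result: GenusResult) -> pd.DataFrame:
    rows = []
    for seq_id in sorted(result.fractions):
        fs = result.fractions[seq_id]
        for fr in REPORT_FRACTIONS:
            s, e = fs.spans[fr]
            rows.append(
                {"seq_id": seq_id, "fraction": str(fr), "start0": s, "end0": e, "length": e - s}
            )
    return pd.DataFrame(rows, columns=["seq_id", "fraction", "start0", "end0", "length"])


def _genus_tests(result: GenusResult) -> dict:
    out: dict = {}
    summaries = [result.summary.fractions[fr] for fr in REPORT_FRACTIONS]
    try:
        out["chi2_heterogeneity"] = chi2_fraction_heterogeneity(summaries).to_dict()
    except ValueError as exc:
        out["chi2_heterogeneity"] = {"error": str(exc)}
    groups = {
        str(fr): [m.length_bp for e in result.events if e.fraction is fr for m in e.members]
        for fr in REPORT_FRACTIONS
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    try:
        if len(groups) < 2:
            raise ValueError("insufficient groups for length comparison")
        out["tukey_hsd_ranks"] = tukey_hsd_lengths(groups, use_ranks=True).to_dict()
    except ValueError as exc:
        out["tukey_hsd_ranks"] = {"error": str(exc)}
    return out


def run_pipeline(
    fasta_by_genus: Mapping[str, str | Path],
    config: PipelineConfig | None = None,
    outdir: str | Path = "estssr_out",
    annotations_path: str | Path | None = None,
) -> dict:
    """Execute the full workflow and write the report bundle to ``outdir``.

    Returns a summary dict (also written as ``run.json``). Outputs per
    genus: ``<genus>.loci.tsv`` and ``<genus>.fractions.tsv``; globally:
    ``table1.tsv``, ``table2.tsv``, ``table3.tsv``, ``summary.json``,
    ``tests.json`` and ``run.json``.
    """
    config = config or PipelineConfig()
    if not fasta_by_genus:
        raise ValueError("run_pipeline needs at least one genus")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = None
    if annotations_path is not None:
        annotations = load_orf_annotations(annotations_path)
    results: list[GenusResult] = []
    for genus in sorted(fasta_by_genus):
        sequences = read_fasta(fasta_by_genus[genus])
        if not sequences:
            logger.warning("%s: empty FASTA", genus)
        result = process_genus(genus, sequences, config, annotations=annotations)
        results.append(result)
        events_to_frame(result.events).to_csv(
            outdir / f"{genus}.loci.tsv", sep="\t", index=False
        )
        _fractions_frame(result).to_csv(
            outdir / f"{genus}.fractions.tsv", sep="\t", index=False
        )
    render_reports([r.summary for r in results], outdir)
    tests: dict = {g.genus: _genus_tests(g) for g in results}
    if len(results) >= 3:
        for metric in ("mean_length", "counts_per_mbp"):
            try:
                tests[f"genome_size_vs_{metric}"] = genome_size_association(
                    [r.summary for r in results], metric=metric
                ).to_dict()
            except ValueError as exc:
                tests[f"genome_size_vs_{metric}"] = {"error": str(exc)}
    (outdir / "tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True))
    run_info = {
        "genera": {
            r.genus: {
                "n_input": r.n_input,
                "n_kept": r.n_kept,
                "n_unpartitioned": r.n_unpartitioned,
                "n_rejected": len(r.rejected),
                "rejected_ids": r.rejected,
                "n_events": len(r.events),
            }
            for r in results
        },
        "config": {
            "min_repeats": {str(k): v for k, v in sorted(config.scan.min_repeats.items())},
            "max_compound_spacer": config.scan.max_compound_spacer,
            "min_orf_bp": config.min_orf_bp,
            "cluster_identity": config.cluster_identity,
            "seed": config.seed,
        },
    }
    (outdir / "run.json").write_text(json.dumps(run_info, indent=2, sort_keys=True))
    return run_info
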