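"""Genus metadata: genome sizes used as the covariate in association tests.

Genome sizes are haploid DNA contents in picograms (1C values). Users
supply their own two-column TSV (``genus<TAB>genome_size_pg``); a small
demonstration table of mean 1C values for common angiosperm and
gymnosperm tree genera is bundled for example runs. Gymnosperm genomes
are 1-2 orders of magnitude larger than angiosperm ones, which is what
makes the genome-size association interesting in this clade.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Demonstration mean 1C genome sizes (pg) per genus.
DEMO_GENOME_SIZES_PG: dict[str, float] = {
    # angiosperm tree genera
    "Populus": 0.52,
    "Eucalyptus": 0.60,
    "Betula": 0.62,
    "Fagus": 0.56,
    "Quercus": 0.87,
    "Citrus": 0.44,
    "Prunus": 0.57,
    "Fraxinus": 0.93,
    # gymnosperm genera
    "Picea": 18.1,
    "Pinus": 26.4,
    "Cryptomeria": 11.2,
    "Gnetum": 3.4,
    "Cycas": 14.7,
    "Zamia": 17.0,
    "Ginkgo": 11.8,
}


def load_genome_sizes(path: str | Path) -> dict[str, float]:
    """Read a ``genus<TAB>genome_size_pg`` table (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"genome-size table needs two columns: {path}")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        name, value = str(row[0]).strip(), str(row[1]).strip()
        if name.lower() in ("genus", "name"):
            continue  # header row
        out[name] = float(value)
    return out


def write_genome_sizes(sizes: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genus\tgenome_size_pg\n")
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]:g}\n")
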