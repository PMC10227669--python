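"""Reading and writing the package's delimited text formats.

* Genotype tables: columns ``id``, ``genotype`` (canonical 5-locus string),
  optional ``weight`` (positive integer, default 1); tab- or comma-separated
  with a header row, UTF-8.
* Haplotype-frequency tables: CSV with columns ``haplotype`` (five alleles
  joined by ``~`` in fixed locus order) and ``frequency``.
* Bw4 allele lists: plain text, one A/B allele per line.
* Coverage edge lists: sparse ``donor_id  patient_id  metadata`` audit dumps.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .matching import CoverageSets
from .model import (
    Genotype,
    GenotypePool,
    ParseError,
    PoolRole,
    parse_allele,
    parse_genotype,
    serialize_genotype,
)
from .population import Bw4Table, Haplotype, HaplotypeFrequencyTable

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_bw4_table",
    "write_bw4_table",
    "write_coverage_edges",
]


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_genotype_table(path: str | Path, role: PoolRole) -> GenotypePool:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    required = {"id", "genotype"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path} lacks required columns {sorted(required)}")
    weights = (
        df["weight"].astype(int).to_numpy()
        if "weight" in df.columns
        else np.ones(len(df), dtype=int)
    )
    if np.any(weights <= 0):
        raise ParseError(f"{path} contains non-positive weights")
    merged: dict[Genotype, int] = {}
    for text, w in zip(df["genotype"], weights):
        g = parse_genotype(text)
        merged[g] = merged.get(g, 0) + int(w)
    return GenotypePool(tuple(merged.items()), role)


def write_genotype_table(pool: GenotypePool, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "genotype", "weight"])
        for idx, (g, w) in enumerate(pool):
            writer.writerow([f"{pool.role.value[0].upper()}{idx}", serialize_genotype(g), w])


def write_haplotype_table(table: HaplotypeFrequencyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["haplotype", "frequency"])
        for h, f in zip(table.haplotypes, table.frequencies):
            writer.writerow(["~".join(a.name for a in h), f"{f:.17g}"])


def read_haplotype_table(path: str | Path) -> HaplotypeFrequencyTable:
    df = pd.read_csv(path, dtype={"haplotype": str, "frequency": float})
    haplotypes: list[Haplotype] = []
    for text in df["haplotype"]:
        haplotypes.append(tuple(parse_allele(tok) for tok in text.split("~")))
    return HaplotypeFrequencyTable(tuple(haplotypes), df["frequency"].to_numpy())


def write_bw4_table(table: Bw4Table, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for allele in sorted(table.alleles):
            fh.write(allele.name + "\n")


def read_bw4_table(path: str | Path) -> Bw4Table:
    alleles = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                alleles.append(parse_allele(line))
    return Bw4Table(frozenset(alleles))


def write_coverage_edges(cov: CoverageSets, path: str | Path) -> None:
    """Sparse audit dump: one row per (donor/variant, covered patient)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["donor_id", "patient_index", "ab_matches", "knockout"])
        for key in cov.ids:
            mc = cov.match_counts.get(key, {}) if cov.match_counts else {}
            for i in sorted(cov.sets[key]):
                writer.writerow([key, i, mc.get(i, ""), int(cov.is_knockout[key])])
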