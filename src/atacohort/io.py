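"""Readers and writers for the plain-text formats the pipeline exchanges.

BED files are 0-based half-open.  Tabular files (sample sheet, footprints,
matrices, result tables) are delimited text with a header row, handled by
pandas.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .regions import GenomicRegion, PeakSet


class BedParseError(ValueError):
    """Raised with the offending file and line when a BED record is malformed."""


def read_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read intervals from a BED file (first three columns; extra columns ignored)."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                region = GenomicRegion(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            regions.append(region)
    return regions


def write_bed(
    regions: Sequence[GenomicRegion],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
) -> None:
    if names is not None and len(names) != len(regions):
        raise ValueError("names must match regions in length")
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if names is None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{names[i]}\n")


def read_peak_set(path: str | os.PathLike, sample_id: str) -> PeakSet:
    return PeakSet(sample_id=sample_id, regions=read_bed(path))


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Sample sheet: sample_id, patient_id, ighv_homology_percent (may be blank)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    sheet = pd.read_csv(path, sep=sep)
    required = {"sample_id", "patient_id", "ighv_homology_percent"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id values")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    sheet.to_csv(path, sep=sep, index=False)


def read_footprints(path: str | os.PathLike) -> pd.DataFrame:
    """Footprint table: tf, chrom, start, end, purity (header row required)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    fp = pd.read_csv(path, sep=sep)
    required = {"tf", "chrom", "start", "end", "purity"}
    missing = required - set(fp.columns)
    if missing:
        raise ValueError(f"{path}: footprint table missing columns {sorted(missing)}")
    bad = (fp["purity"] <= 0) | (fp["purity"] > 1)
    if bad.any():
        raise ValueError(f"{path}: purity values outside (0,1] at rows {list(fp.index[bad])[:5]}")
    return fp


def write_footprints(fp: pd.DataFrame, path: str | os.PathLike) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    fp.to_csv(path, sep=sep, index=False, float_format="%.6f")


def read_gene_models(path: str | os.PathLike) -> pd.DataFrame:
    """Gene model table: gene_id, chrom, start, end, strand; TSS derived from strand."""
    sep = "," if str(path).endswith(".csv") else "\t"
    genes = pd.read_csv(path, sep=sep)
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    genes = genes.copy()
    genes["tss"] = genes.apply(
        lambda g: g["start"] if g["strand"] == "+" else g["end"] - 1, axis=1
    )
    return genes


def write_gene_models(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["gene_id", "chrom", "start", "end", "strand"]
    sep = "," if str(path).endswith(".csv") else "\t"
    genes[cols].to_csv(path, sep=sep, index=False)


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Region-by-sample matrix with region IDs as the index column."""
    matrix.to_csv(path, sep="\t", index_label="region_id")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region_id")


def write_bedgraph(
    chroms: Sequence[str],
    starts: Sequence[int],
    ends: Sequence[int],
    values: Sequence[float],
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        for c, s, e, v in zip(chroms, starts, ends, values):
            fh.write(f"{c}\t{s}\t{e}\t{v:g}\n")
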