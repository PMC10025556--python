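"""Quantitative insertion-table I/O, validation, normalization and filtering.

An insertion table records one transposon integration event per row:
chromosome, 0-based TTAA position, transposon orientation (strand), the
screen sample it came from, and its sequencing-read support.  Read counts
proxy clonal abundance; normalizing them to the per-sample top hit yields
the ``norm_coverage`` fraction used by the clonality analyses.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical internal column order
COLUMNS = ["chrom", "pos", "strand", "sample", "reads"]

TSV_COLUMNS = {"chrom", "pos", "strand", "sample", "reads"}


@dataclass(frozen=True)
class DonorLocus:
    """Transposon donor concatemer; a +/- `radius` window around its
    midpoint is excluded from analysis (local hopping area)."""

    chrom: str
    pos: int
    radius: int = 3_000_000

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("donor radius must be > 0")


@dataclass
class InsertionTable:
    """Per-sample genomic insertions with orientation and read coverage.

    ``data`` columns: chrom (str), pos (int, 0-based), strand ('+'/'-'),
    sample (str), reads (int >= 1), and after :func:`normalize_coverage`
    a float ``norm_coverage`` in (0, 1].
    """

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def samples(self) -> set[str]:
        return set(self.data["sample"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def log(self, message: str) -> None:
        self.provenance.append(message)
        logger.info(message)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted insertion positions on one chromosome (pooled samples)."""
        return np.sort(self.data.loc[self.data["chrom"] == chrom, "pos"].to_numpy())

    def chromosomes(self) -> list[str]:
        return sorted(self.data["chrom"].unique())

    def copy_with(self, data: pd.DataFrame, message: str) -> "InsertionTable":
        out = InsertionTable(data.reset_index(drop=True), list(self.provenance))
        out.log(message)
        return out


def _validate_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad_pos = df.index[df["pos"] < 0].tolist()
    if bad_pos:
        raise ValidationError(f"{source}: negative position in rows {bad_pos}")
    bad_reads = df.index[df["reads"] < 1].tolist()
    if bad_reads:
        raise ValidationError(f"{source}: read_count < 1 in rows {bad_reads}")
    bad_strand = df.index[~df["strand"].isin(["+", "-"])].tolist()
    if bad_strand:
        raise ValidationError(f"{source}: strand not in {{+,-}} in rows {bad_strand}")
    return df


def read_insertion_table(path: str, dialect: str = "tsv") -> InsertionTable:
    """Read a TSV (header: chrom, pos, strand, sample, reads) or BED6
    (name=sample, score=reads) insertion table.

    Malformed rows raise :class:`FormatError` / :class:`ValidationError`
    with row indices, so offending lines can be located in the source file.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
        missing = TSV_COLUMNS - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        df = df[COLUMNS + [c for c in df.columns if c not in COLUMNS]]
    elif dialect == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
        df = pd.DataFrame({
            "chrom": df["chrom"], "pos": df["start"], "strand": df["strand"],
            "sample": df["name"].astype(str), "reads": df["score"],
        })
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    for col in ("pos", "reads"):
        if len(df) and not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise FormatError(f"{path}: non-numeric {col} in rows {bad}")
    df["pos"] = df["pos"].astype(np.int64)
    df["reads"] = df["reads"].astype(np.int64)
    df["sample"] = df["sample"].astype(str)
    _validate_frame(df, path)
    table = InsertionTable(df.reset_index(drop=True))
    table.log(f"read {len(df)} insertions ({len(table.samples)} samples) from {path}")
    return table


def write_insertion_table(table: InsertionTable, path: str, dialect: str = "tsv") -> None:
    """Write TSV mirror of internal fields or BED6 (score = round(1000*norm_coverage)
    when normalized, else raw reads capped for BED compliance)."""
    if dialect == "tsv":
        table.data.to_csv(path, sep="\t", index=False)
    elif dialect == "bed":
        df = table.data
        if "norm_coverage" in df.columns:
            score = (1000 * df["norm_coverage"]).round().astype(int)
        else:
            score = df["reads"].clip(upper=1000)
        bed = pd.DataFrame({
            "chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 4,
            "name": df["sample"], "score": score, "strand": df["strand"],
        })
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def deduplicate(table: InsertionTable) -> InsertionTable:
    """Collapse to one record per (chrom, pos, sample); read counts of
    duplicates are summed so total evidence is preserved."""
    df = table.data
    grouped = (
        df.groupby(["chrom", "pos", "sample"], as_index=False, sort=False)
        .agg(strand=("strand", "first"), reads=("reads", "sum"))
    )
    grouped = grouped[COLUMNS]
    n_collapsed = len(df) - len(grouped)
    return table.copy_with(grouped, f"deduplicate: collapsed {n_collapsed} duplicate records")


def normalize_coverage(table: InsertionTable) -> InsertionTable:
    """Per sample, divide read counts by that sample's top hit.

    After normalization max(norm_coverage) == 1.0 in every sample.
    Idempotent: re-running recomputes the same values from raw reads.
    """
    df = table.data.copy()
    if len(df) == 0:
        warnings.warn("normalize_coverage: empty table")
        df["norm_coverage"] = pd.Series(dtype=float)
        return table.copy_with(df, "normalize_coverage: empty table")
    top = df.groupby("sample")["reads"].transform("max")
    df["norm_coverage"] = df["reads"] / top
    return table.copy_with(df, f"normalize_coverage: {df['sample'].nunique()} samples")


def exclude_donor_window(table: InsertionTable, donor: DonorLocus) -> InsertionTable:
    """Drop insertions within `donor.radius` bp of the donor midpoint on the
    donor chromosome (local hopping area, default 3 Mb each side)."""
    df = table.data
    near = (df["chrom"] == donor.chrom) & ((df["pos"] - donor.pos).abs() <= donor.radius)
    return table.copy_with(
        df[~near],
        f"exclude_donor_window: removed {int(near.sum())} insertions within "
        f"{donor.radius} bp of {donor.chrom}:{donor.pos}",
    )


def extract_flanks(
    table: InsertionTable,
    flank: int = 200,
    subset: str = "all",
    genes=None,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Intervals ``[pos - flank, pos + flank)`` around insertions, clipped at
    chromosome ends, as a BED-like frame for external motif tools.

    ``subset='intergenic'`` keeps insertions not overlapping any
    protein-coding/IG gene in ``genes`` (a :class:`regcis.annotation.GeneModel`).
    """
    if flank <= 0:
        raise ValidationError("flank must be > 0")
    df = table.data
    if subset == "intergenic":
        if genes is None:
            raise ValidationError("subset='intergenic' requires a gene model")
        keep = [
            not genes.overlaps_genic(row.chrom, row.pos, row.pos + 1)
            for row in df.itertuples()
        ]
        df = df[np.asarray(keep, dtype=bool)]
    elif subset != "all":
        raise ValidationError(f"unknown subset {subset!r}")
    start = (df["pos"] - flank).clip(lower=0)
    end = df["pos"] + flank
    if chrom_sizes:
        end = np.minimum(end, df["chrom"].map(chrom_sizes).fillna(np.inf))
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": start.astype(int), "end": end.astype(int),
        "name": df["sample"], "score": 0, "strand": df["strand"],
    })
    return out.reset_index(drop=True)
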