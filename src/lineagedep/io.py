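"""Readers and writers for the standard formats the pipeline consumes.

Formats: ENCODE narrowPeak (BED6+4) for peak calls, BED6 for read
intervals, the DepMap gene-effect CSV dialect (header cells
``"SYMBOL (entrezid)"``), cell-line annotation / mutation CSVs, a TSV gene
model table with differential-expression labels, and a binary
regions x samples accessibility matrix stored as a BED of regions plus a
TSV of 0/1 values.

Every reader/writer pair round-trips on canonical files.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import ConsensusPeak, GeneRecord, GenomicInterval, Peak

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

_NARROWPEAK_NCOL = 10


def _fmt_float(x: float) -> str:
    """Canonical float formatting: shortest representation that round-trips."""
    return repr(float(x))


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file into :class:`Peak` records.

    Column 10 is the summit offset from ``start``; records with offset -1
    (no summit called) are skipped and counted in a single warning.
    Column 9 is the q-value as -log10.
    """
    peaks: list[Peak] = []
    n_no_summit = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _NARROWPEAK_NCOL:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_NARROWPEAK_NCOL} "
                    f"tab-separated columns, found {len(fields)}"
                )
            try:
                chrom, start, end, name, score, strand = (
                    fields[0], int(fields[1]), int(fields[2]), fields[3],
                    int(fields[4]), fields[5],
                )
                signal, neg_log10_p, neg_log10_q = (
                    float(fields[6]), float(fields[7]), float(fields[8]),
                )
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if offset == -1:
                n_no_summit += 1
                continue
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit=start + offset,
                    neg_log10_q=neg_log10_q,
                    name=name,
                    score=score,
                    signal=signal,
                    neg_log10_p=neg_log10_p,
                )
            )
    if n_no_summit:
        logger.warning("%s: skipped %d records without a summit (offset -1)", path, n_no_summit)
    return peaks


def write_narrowpeak(peaks: list[Peak] | list[ConsensusPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if isinstance(p, ConsensusPeak):
                row = (
                    p.interval.chrom, p.interval.start, p.interval.end, p.source_peak,
                    0, ".", _fmt_float(0.0), _fmt_float(-1.0),
                    _fmt_float(p.neg_log10_q), p.summit - p.interval.start,
                )
            else:
                row = (
                    p.interval.chrom, p.interval.start, p.interval.end, p.name,
                    p.score, p.interval.strand, _fmt_float(p.signal),
                    _fmt_float(p.neg_log10_p), _fmt_float(p.neg_log10_q),
                    p.summit - p.interval.start,
                )
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# BED6 reads
# ---------------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file of read intervals into a DataFrame."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BED6_COLUMNS,
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "name": str, "score": np.int64, "strand": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not a valid BED6 file: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=BED6_COLUMNS)
    bad = ~df["strand"].isin(["+", "-", "."])
    if bad.any():
        raise ParseError(f"{path}: invalid strand values at rows {list(df.index[bad][:5])}")
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# DepMap gene-effect CSV
# ---------------------------------------------------------------------------

_DEPMAP_HEADER_RE = re.compile(r"^(?P<symbol>\S+)(?:\s+\((?P<entrez>\d+)\))?$")


def read_dependency_csv(path: str | Path) -> pd.DataFrame:
    """Read a DepMap-dialect gene-effect matrix: cell lines x genes.

    Header cells are ``"SYMBOL (entrezid)"``; the gene symbol is the token
    before the space. Empty cells become NaN and are excluded pairwise from
    all downstream means and tests. Duplicate gene symbols are an error.
    """
    df = pd.read_csv(path, index_col=0)
    symbols = []
    for col in df.columns:
        m = _DEPMAP_HEADER_RE.match(col.strip())
        if m is None:
            raise ParseError(f"{path}: malformed gene header {col!r}")
        symbols.append(m.group("symbol"))
    dup = pd.Index(symbols)[pd.Index(symbols).duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate gene symbols: {sorted(set(dup))}")
    df.columns = symbols
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                row = df.index[bad][0]
                raise ParseError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            df[col] = coerced
    return df.astype(float)


def write_dependency_csv(ceres: pd.DataFrame, path: str | Path,
                         entrez: dict[str, int] | None = None) -> None:
    """Write a gene-effect matrix in the DepMap header dialect."""
    out = ceres.copy()
    if entrez is None:
        entrez = {g: i + 1 for i, g in enumerate(out.columns)}
    out.columns = [f"{g} ({entrez[g]})" for g in out.columns]
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Annotations, mutations, TF lists
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Cell-line lineage annotations: columns cell_line, lineage."""
    df = pd.read_csv(path, dtype=str)
    missing = {"cell_line", "lineage"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["cell_line"].duplicated().any():
        raise ParseError(f"{path}: a cell line maps to more than one lineage")
    return df[["cell_line", "lineage"]]


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[["cell_line", "lineage"]].to_csv(path, index=False)


MUTATION_COLUMNS = [
    "cell_line", "gene", "variant_classification",
    "is_deleterious", "is_tcga_hotspot", "is_cosmic_hotspot",
]


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("is_deleterious", "is_tcga_hotspot", "is_cosmic_hotspot"):
        df[col] = df[col].astype(bool)
    return df[MUTATION_COLUMNS]


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    df[MUTATION_COLUMNS].to_csv(path, index=False)


def read_tf_list(path: str | Path) -> list[str]:
    """One transcription-factor symbol per line; blanks ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_tf_list(tfs: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in tfs:
            fh.write(tf + "\n")


# ---------------------------------------------------------------------------
# Gene model table
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "de_status", "log2fc", "padj"]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene model TSV: gene_id, chrom, tss, strand, de_status, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["tss"] = df["tss"].astype(np.int64)
    return df[GENE_COLUMNS]


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%g")


def gene_records(df: pd.DataFrame) -> list[GeneRecord]:
    """Materialise a gene table into validated :class:`GeneRecord` objects."""
    out = []
    for row in df.itertuples(index=False):
        out.append(GeneRecord(
            gene_id=row.gene_id, chrom=row.chrom, tss=int(row.tss),
            strand=row.strand, de_status=row.de_status,
            log2fc=None if pd.isna(row.log2fc) else float(row.log2fc),
            padj=None if pd.isna(row.padj) else float(row.padj),
        ))
    return out


# ---------------------------------------------------------------------------
# Binary accessibility profiles
# ---------------------------------------------------------------------------

def read_profile_matrix(bed_path: str | Path, tsv_path: str | Path):
    """Read a regions BED3 plus a binary TSV (region rows x sample columns)."""
    from .clustering import ProfileMatrix  # local import to avoid a cycle

    regions = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    values = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if len(values) != len(regions):
        raise ParseError(
            f"{tsv_path}: {len(values)} rows but {bed_path} has {len(regions)} regions"
        )
    arr = values.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ParseError(f"{tsv_path}: profile values must be 0/1")
    return ProfileMatrix(
        regions=regions, samples=list(values.columns), values=arr.astype(np.uint8)
    )


def write_profile_matrix(matrix, bed_path: str | Path, tsv_path: str | Path) -> None:
    matrix.regions[["chrom", "start", "end"]].to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    pd.DataFrame(
        matrix.values,
        index=[f"r{i}" for i in range(matrix.values.shape[0])],
        columns=matrix.samples,
    ).to_csv(tsv_path, sep="\t", index_label="region")
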