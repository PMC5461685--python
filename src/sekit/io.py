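"""Readers and writers for the flat genomic formats the pipeline touches.

BED, narrowPeak and bedGraph are tab-separated and 0-based half-open, so
they map directly onto :class:`~sekit.intervals.GenomicInterval`. Gene
models are accepted either as BED12 or as a minimal refFlat-like TSV
(name, chrom, strand, txStart, txEnd). The SE table is the pipeline's
primary output: a TSV with a fixed header that round-trips exactly.

All readers return records sorted chromosome-major, then by start, so
downstream code can assume deterministic order regardless of file order.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .errors import InputError, ParseError, UsageError
from .intervals import GeneModel, GenomicInterval, Peak, Read

_SKIP_PREFIXES = ("track", "browser", "#")

SE_TABLE_COLUMNS = [
    "rank",
    "chrom",
    "start",
    "end",
    "n_subpeaks",
    "count",
    "is_SE",
    "closest_gene",
    "tss_distance",
    "enhancer_type",
    "percentage_outs",
    "closeness",
]


def _data_lines(path: str) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-empty lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_interval(fields: list[str], path: str, lineno: int) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"non-integer coordinates: {exc}", path, lineno) from exc
    try:
        return GenomicInterval(fields[0], start, end)
    except ValueError as exc:
        raise ParseError(str(exc), path, lineno) from exc


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file as sorted intervals.

    Extra columns beyond the first three are ignored; track/browser/comment
    lines are skipped. Malformed coordinates raise :class:`ParseError`
    naming the line.
    """
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"expected >=3 tab-separated fields, got {len(fields)}", path, lineno)
        out.append(_parse_interval(fields, path, lineno))
    out.sort()
    return out


def read_narrowpeak(path: str) -> list[Peak]:
    """Read a MACS narrowPeak (BED6+4) file as sorted peaks.

    Column 7 (signalValue) becomes the peak pileup. Fewer than 10 columns
    or a negative signalValue is a parse error.
    """
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 10:
            raise ParseError(f"narrowPeak needs 10 columns, got {len(fields)}", path, lineno)
        interval = _parse_interval(fields, path, lineno)
        try:
            signal = float(fields[6])
        except ValueError as exc:
            raise ParseError(f"non-numeric signalValue {fields[6]!r}", path, lineno) from exc
        if signal < 0:
            raise ParseError(f"negative signalValue {signal}", path, lineno)
        name = fields[3] if fields[3] not in (".", "") else None
        out.append(Peak(interval, pileup=signal, name=name))
    out.sort(key=lambda p: p.interval)
    return out


def read_gene_models(path: str, dialect: str = "refflat_tsv") -> list[GeneModel]:
    """Read gene models from BED12 or a refFlat-like TSV.

    The TSV dialect is ``name, chrom, strand, txStart, txEnd`` (a header
    line starting with ``name`` is tolerated). The TSS is the strand-resolved
    5' end: txStart for ``+``, txEnd - 1 for ``-``.
    """
    if dialect not in ("bed12", "refflat_tsv"):
        raise UsageError(f"unknown gene model dialect {dialect!r}")
    out = []
    for lineno, fields in _data_lines(path):
        if dialect == "bed12":
            if len(fields) < 6:
                raise ParseError(f"BED12 needs >=6 columns, got {len(fields)}", path, lineno)
            span = _parse_interval(fields, path, lineno)
            name, strand = fields[3], fields[5]
        else:
            if fields[0] == "name" and lineno == 1:
                continue
            if len(fields) < 5:
                raise ParseError(f"gene TSV needs 5 columns, got {len(fields)}", path, lineno)
            name, strand = fields[0], fields[2]
            span = _parse_interval([fields[1], fields[3], fields[4]], path, lineno)
        if strand not in ("+", "-"):
            raise ParseError(f"unknown strand symbol {strand!r}", path, lineno)
        tss = span.start if strand == "+" else span.end - 1
        out.append(GeneModel(name=name, strand=strand, tss=tss, span=span))
    out.sort(key=lambda g: (g.chrom, g.span.start, g.name))
    return out


def read_reads(path: str, format: str = "bed") -> list[Read]:
    """Read aligned reads as intervals, from BED or (optionally) BAM.

    Unmapped BAM records are skipped. Anything but ``bed``/``bam`` is a
    usage error.
    """
    if format == "bed":
        return [Read(iv) for iv in read_bed(path)]
    if format == "bam":
        import pysam  # deferred: BAM support is optional

        out = []
        with pysam.AlignmentFile(path, "rb") as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                out.append(
                    Read(GenomicInterval(rec.reference_name, rec.reference_start, rec.reference_end))
                )
        out.sort(key=lambda r: r.interval)
        return out
    raise UsageError(f"unsupported read format {format!r} (expected 'bed' or 'bam')")


def read_bedgraph(path: str) -> list[tuple[str, int, int, float]]:
    """Read bedGraph rows as (chrom, start, end, value), sorted.

    Negative values are rejected: pileup tracks are non-negative by
    construction.
    """
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"bedGraph needs 4 columns, got {len(fields)}", path, lineno)
        iv = _parse_interval(fields, path, lineno)
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"non-numeric value {fields[3]!r}", path, lineno) from exc
        if value < 0:
            raise InputError(f"negative bedGraph value {value} at {path}:{lineno}")
        rows.append((iv.chrom, iv.start, iv.end, value))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return rows


def write_bedgraph(rows: Iterable[tuple[str, int, int, float]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def write_narrowpeak(peaks: Iterable[Peak], path: str) -> None:
    """Write peaks as BED6+4 narrowPeak; pileup goes to signalValue."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}\t0\t.\t"
                f"{p.pileup!r}\t-1\t-1\t-1\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_gene_models(genes: Iterable[GeneModel], path: str) -> None:
    """Write the refFlat-like TSV dialect (name, chrom, strand, txStart, txEnd)."""
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstrand\ttxStart\ttxEnd\n")
        for g in genes:
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.span.start}\t{g.span.end}\n")


def write_se_table(rows: pd.DataFrame | Iterable[dict], path: str) -> None:
    """Write the ranked SE table as TSV with the fixed column set.

    Rows are sorted rank-ascending. ``read_se_table`` of the written file
    reproduces the table exactly.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty:
        df = pd.DataFrame(columns=SE_TABLE_COLUMNS)
    missing = [c for c in SE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"SE table rows missing columns: {missing}")
    df = df[SE_TABLE_COLUMNS].sort_values("rank", kind="stable")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_se_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ParseError("SE table not found", path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in SE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"SE table missing columns: {missing}", path)
    return df
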