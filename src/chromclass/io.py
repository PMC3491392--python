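"""Readers and writers for the plain-text genomic formats the pipeline uses.

Supported: chrom.sizes, BED3/BED6, narrowPeak, bedGraph, wiggle
(fixedStep/variableStep), GTF transcript/exon lines, and tab-delimited
expression matrices.  Everything is converted to the internal 0-based
half-open convention on read (GTF is 1-based inclusive on disk).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .genome import (
    Annotation,
    BinGrid,
    GenomeSpec,
    Interval,
    PeakSet,
    SignalTrack,
    Transcript,
)


class ParseError(ValueError):
    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _open(path, mode="r"):
    if hasattr(path, "read") or hasattr(path, "write"):
        return path, False
    return open(path, mode), True


# -- chrom sizes ------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeSpec:
    fh, close = _open(path)
    names, lengths = [], []
    try:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected two tab-separated columns", i)
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(f"bad length {parts[1]!r}", i) from None
            names.append(parts[0])
            lengths.append(length)
    finally:
        if close:
            fh.close()
    return GenomeSpec(tuple(names), tuple(lengths))


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    fh, close = _open(path, "w")
    try:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
    finally:
        if close:
            fh.close()


# -- BED / narrowPeak -------------------------------------------------------

def read_bed(path) -> list[Interval]:
    """Read BED3/BED6; score column (5) becomes the interval value."""
    fh, close = _open(path)
    out = []
    try:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise ParseError("BED needs >= 3 columns", i)
            try:
                start, end = int(p[1]), int(p[2])
            except ValueError:
                raise ParseError("non-integer coordinates", i) from None
            name = p[3] if len(p) > 3 and p[3] != "." else None
            value = None
            if len(p) > 4 and p[4] not in (".", ""):
                value = float(p[4])
            strand = p[5] if len(p) > 5 and p[5] in ("+", "-") else None
            try:
                out.append(Interval(p[0], start, end, strand=strand, value=value, name=name))
            except ValueError as exc:
                raise ParseError(str(exc), i) from None
    finally:
        if close:
            fh.close()
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    fh, close = _open(path, "w")
    try:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.value is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
                cols.append(repr(iv.value) if iv.value is not None else ".")
                cols.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(cols) + "\n")
    finally:
        if close:
            fh.close()


def read_narrowpeak(path, trf: str = "", cell_line: str = "") -> PeakSet:
    """Read ENCODE narrowPeak (BED6+4); signalValue (column 7) becomes value."""
    fh, close = _open(path)
    peaks = []
    try:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) < 10:
                raise ParseError("narrowPeak needs 10 columns", i)
            strand = p[5] if p[5] in ("+", "-") else None
            try:
                peaks.append(
                    Interval(
                        p[0], int(p[1]), int(p[2]),
                        strand=strand,
                        value=float(p[6]),
                        name=p[3] if p[3] != "." else None,
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), i) from None
    finally:
        if close:
            fh.close()
    return PeakSet(trf=trf, cell_line=cell_line, peaks=peaks)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    fh, close = _open(path, "w")
    try:
        for k, iv in enumerate(peakset.peaks):
            name = iv.name if iv.name is not None else f"{peakset.trf}_{k}"
            sig = iv.value if iv.value is not None else 0.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                f"{iv.strand or '.'}\t{sig:g}\t-1\t-1\t-1\n"
            )
    finally:
        if close:
            fh.close()


# -- bedGraph / wiggle ------------------------------------------------------

def read_bedgraph(path) -> list[Interval]:
    fh, close = _open(path)
    out = []
    try:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) != 4:
                raise ParseError("bedGraph needs 4 columns", i)
            try:
                out.append(Interval(p[0], int(p[1]), int(p[2]), value=float(p[3])))
            except ValueError as exc:
                raise ParseError(str(exc), i) from None
    finally:
        if close:
            fh.close()
    return out


def write_bedgraph(intervals: Iterable[Interval], path) -> None:
    fh, close = _open(path, "w")
    try:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value:g}\n")
    finally:
        if close:
            fh.close()


def write_track_bedgraph(track: SignalTrack, path, *, omit_zero: bool = True) -> None:
    """Write a per-bin track as bedGraph, merging runs of equal value."""
    fh, close = _open(path, "w")
    grid = track.grid
    try:
        for chrom in grid.genome.chrom_names:
            off = grid.chrom_offset(chrom)
            n = grid.chrom_nbins(chrom)
            vals = track.values[off : off + n]
            length = grid.genome.length(chrom)
            i = 0
            while i < n:
                j = i
                while j + 1 < n and vals[j + 1] == vals[i]:
                    j += 1
                if not (omit_zero and vals[i] == 0):
                    s = i * grid.width
                    e = min((j + 1) * grid.width, length)
                    fh.write(f"{chrom}\t{s}\t{e}\t{vals[i]:g}\n")
                i = j + 1
    finally:
        if close:
            fh.close()


def read_track_bedgraph(path, grid: BinGrid, assay: str = "", cell_line: str = "") -> SignalTrack:
    """Read a bedGraph written at bin resolution back into a SignalTrack."""
    values = np.zeros(grid.n_bins)
    for iv in read_bedgraph(path):
        idx = grid.bins_in_range(iv.chrom, iv.start, iv.end)
        values[idx] = iv.value
    return SignalTrack(grid, values, assay=assay, cell_line=cell_line)


def read_wiggle(path, default_span: int = 1) -> list[Interval]:
    """Read wiggle fixedStep/variableStep sections into valued intervals."""
    fh, close = _open(path)
    out: list[Interval] = []
    mode = None
    chrom = ""
    start = 0
    step = 1
    span = default_span
    try:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "fixed"
                chrom = fields["chrom"]
                start = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", default_span))
                continue
            if line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "variable"
                chrom = fields["chrom"]
                span = int(fields.get("span", default_span))
                continue
            if mode is None:
                raise ParseError("data line before any step declaration", i)
            try:
                if mode == "fixed":
                    out.append(Interval(chrom, start, start + span, value=float(line)))
                    start += step
                else:
                    pos_s, val_s = line.split()
                    pos = int(pos_s) - 1
                    out.append(Interval(chrom, pos, pos + span, value=float(val_s)))
            except ValueError as exc:
                raise ParseError(str(exc), i) from None
    finally:
        if close:
            fh.close()
    return out


def write_wiggle_fixed(track: SignalTrack, path) -> None:
    """Write a per-bin track as fixedStep wiggle (one section per chromosome)."""
    fh, close = _open(path, "w")
    grid = track.grid
    try:
        for chrom in grid.genome.chrom_names:
            off = grid.chrom_offset(chrom)
            n = grid.chrom_nbins(chrom)
            fh.write(f"fixedStep chrom={chrom} start=1 step={grid.width} span={grid.width}\n")
            for v in track.values[off : off + n]:
                fh.write(f"{v:g}\n")
    finally:
        if close:
            fh.close()


# -- GTF --------------------------------------------------------------------

def _gtf_attributes(field: str, line_number: int) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            raise ParseError(f"malformed attribute {part!r}", line_number)
        key, val = part.split(" ", 1)
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> Annotation:
    """Build an Annotation from GTF exon lines (1-based inclusive on disk)."""
    fh, close = _open(path)
    exons: dict[str, dict] = {}
    try:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) != 9:
                raise ParseError("GTF needs 9 columns", i)
            if p[2] != "exon":
                continue
            attrs = _gtf_attributes(p[8], i)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError("exon without transcript_id", i)
            try:
                start, end = int(p[3]) - 1, int(p[4])
            except ValueError:
                raise ParseError("non-integer coordinates", i) from None
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": p[0],
                    "strand": p[6],
                    "biotype": attrs.get("gene_type", attrs.get("gene_biotype", "protein_coding")),
                    "exons": [],
                },
            )
            rec["exons"].append((start, end))
    finally:
        if close:
            fh.close()
    transcripts = [
        Transcript(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        for tid, rec in exons.items()
    ]
    return Annotation(transcripts)


def write_gtf(annotation: Annotation, path) -> None:
    fh, close = _open(path, "w")
    try:
        for t in annotation.transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_type "{t.biotype}";'
            )
            fh.write(
                f"{t.chrom}\tchromclass\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tchromclass\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
    finally:
        if close:
            fh.close()


# -- expression matrices ----------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Tab-delimited expression table: rows transcripts, MultiIndex columns
    (cell_line, assay)."""
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [(a, b) for a, b in df.columns], names=["cell_line", "assay"]
    )
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
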