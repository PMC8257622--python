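"""Readers and writers for the plain-text exchange formats.

BED and BEDPE are consumed verbatim (already 0-based half-open); GTF input
is converted to half-open at the boundary.  bedGraph records are binned into
:class:`~sescreen.signal.SignalTrack` values as coverage-weighted means, so
bases not covered by any record count as zero.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, IntervalSet
from .loops import Loop
from .signal import DEFAULT_BIN_WIDTH, SignalTrack, n_bins
from .specificity import ExpressionMatrix

PathLike = Union[str, Path]

_SKIP_PREFIXES = ("#", "track", "browser")


class ParseError(ValueError):
    """A malformed record, reported with file and line number."""


def _records(path: PathLike):
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split()


def _parse_int(text: str, path: PathLike, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: non-integer {what}: {text!r}"
        ) from None


def _parse_score(text: str) -> Optional[float]:
    if text in (".", ""):
        return None
    return float(text)


def read_bed(path: PathLike) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet, preserving file order.

    Columns 4-6 map to label, score ('.' = absent) and strand.  Malformed
    coordinates (non-integer, or start >= end) raise :class:`ParseError`
    naming the offending line.
    """
    intervals: List[GenomicInterval] = []
    for lineno, cols in _records(path):
        if len(cols) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
        start = _parse_int(cols[1], path, lineno, "start")
        end = _parse_int(cols[2], path, lineno, "end")
        label = cols[3] if len(cols) > 3 and cols[3] != "." else None
        try:
            score = _parse_score(cols[4]) if len(cols) > 4 else None
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric score {cols[4]!r}"
            ) from None
        strand = cols[5] if len(cols) > 5 else "."
        try:
            intervals.append(
                GenomicInterval(cols[0], start, end, strand, score, label)
            )
        except ValueError as err:
            raise ParseError(f"{path}: line {lineno}: {err}") from None
    return IntervalSet(intervals, provenance=str(path))


def write_bed(intervals: Union[IntervalSet, Sequence[GenomicInterval]], path: PathLike) -> None:
    """Write BED3 when no interval carries name/score/strand, else BED6."""
    ivs = list(intervals)
    bare = all(
        iv.label is None and iv.score is None and iv.strand == "." for iv in ivs
    )
    with open(path, "w") as out:
        for iv in ivs:
            if bare:
                out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if iv.score is None else format(iv.score, "g")
                name = iv.label if iv.label is not None else "."
                out.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    genome: Dict[str, int] = {}
    for lineno, cols in _records(path):
        if len(cols) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        genome[cols[0]] = _parse_int(cols[1], path, lineno, "chromosome length")
    return genome


def write_chrom_sizes(genome: Dict[str, int], path: PathLike) -> None:
    with open(path, "w") as out:
        for chrom, length in genome.items():
            out.write(f"{chrom}\t{length}\n")


def read_bedgraph(
    path: PathLike,
    genome: Dict[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> SignalTrack:
    """Bin a bedGraph file into a SignalTrack.

    Each bin's value is the coverage-weighted mean of the records touching
    it (uncovered bases count as 0, so an empty file gives an all-zero
    track).  Records exceeding the chromosome length are an error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    acc = {c: np.zeros(n_bins(l, bin_width)) for c, l in genome.items()}
    for lineno, cols in _records(path):
        if len(cols) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        chrom = cols[0]
        if chrom not in genome:
            raise ParseError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
        start = _parse_int(cols[1], path, lineno, "start")
        end = _parse_int(cols[2], path, lineno, "end")
        try:
            value = float(cols[3])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric value {cols[3]!r}"
            ) from None
        if not (0 <= start < end):
            raise ParseError(f"{path}: line {lineno}: invalid record coordinates")
        if end > genome[chrom]:
            raise ParseError(
                f"{path}: line {lineno}: record end {end} exceeds "
                f"{chrom} length {genome[chrom]}"
            )
        b0 = start // bin_width
        b1 = (end - 1) // bin_width
        starts = np.arange(b0, b1 + 1) * bin_width
        ends = np.minimum(starts + bin_width, genome[chrom])
        cover = np.minimum(ends, end) - np.maximum(starts, start)
        acc[chrom][b0 : b1 + 1] += value * cover

    values: Dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        starts = np.arange(n_bins(length, bin_width)) * bin_width
        spans = np.minimum(starts + bin_width, length) - starts
        values[chrom] = acc[chrom] / spans
    return SignalTrack(bin_width=bin_width, genome=dict(genome), values=values)


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    """Write non-zero bins, merging equal-valued consecutive runs."""
    with open(path, "w") as out:
        for chrom in track.genome:
            v = track.values[chrom]
            bw = track.bin_width
            length = track.genome[chrom]
            run_start = 0
            for i in range(1, len(v) + 1):
                if i < len(v) and v[i] == v[run_start]:
                    continue
                if v[run_start] != 0.0:
                    start = run_start * bw
                    end = min(i * bw, length)
                    out.write(f"{chrom}\t{start}\t{end}\t{float(v[run_start])!r}\n")
                run_start = i


def read_bedpe(path: PathLike) -> List[Loop]:
    """Read paired-interval records; an optional 7th column is the score.

    Anchors are normalized so anchor1 sorts first.  Fewer than 6 columns,
    or invalid anchor coordinates, raise :class:`ParseError`.
    """
    loops: List[Loop] = []
    for lineno, cols in _records(path):
        if len(cols) < 6:
            raise ParseError(f"{path}: line {lineno}: expected >= 6 columns")
        coords = [_parse_int(c, path, lineno, "anchor coordinate") for c in cols[1:3] + cols[4:6]]
        try:
            a1 = GenomicInterval(cols[0], coords[0], coords[1])
            a2 = GenomicInterval(cols[3], coords[2], coords[3])
        except ValueError as err:
            raise ParseError(f"{path}: line {lineno}: {err}") from None
        score = None
        if len(cols) > 6:
            try:
                score = _parse_score(cols[6])
            except ValueError:
                score = None  # 7th column was a name, not a score
        try:
            loops.append(Loop(a1, a2, score))
        except ValueError as err:
            raise ParseError(f"{path}: line {lineno}: {err}") from None
    return loops


def write_bedpe(loops: Sequence[Loop], path: PathLike) -> None:
    with open(path, "w") as out:
        for loop in loops:
            a1, a2 = loop.anchor1, loop.anchor2
            fields = [
                a1.chrom, str(a1.start), str(a1.end),
                a2.chrom, str(a2.start), str(a2.end),
            ]
            if loop.score is not None:
                fields.append(repr(loop.score))
            out.write("\t".join(fields) + "\n")


_GTF_GENE_ID = re.compile(r'gene_id\s+"?([^";]+)"?')


def read_genes(path: PathLike, fmt: Optional[str] = None) -> List[GeneModel]:
    """Read gene models from 6-column BED or minimal GTF.

    For BED, the name column is the gene id and the TSS is ``start`` (+ or
    unstranded) or ``end - 1`` (-).  For GTF (1-based inclusive; converted
    here), rows with feature ``gene`` are used when present — otherwise the
    first row per ``gene_id`` — and the ``gene_id`` attribute is required.
    """
    if fmt is None:
        fmt = "gtf" if str(path).lower().endswith((".gtf", ".gff")) else "bed"
    if fmt == "bed":
        genes = []
        for lineno, cols in _records(path):
            if len(cols) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: gene BED needs >= 4 columns"
                )
            start = _parse_int(cols[1], path, lineno, "start")
            end = _parse_int(cols[2], path, lineno, "end")
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            strand = cols[5] if len(cols) > 5 else "."
            tss = start if strand in ("+", ".") else end - 1
            genes.append(GeneModel(cols[3], cols[0], tss, strand))
        return genes
    if fmt != "gtf":
        raise ValueError(f"unknown gene annotation format {fmt!r}")

    rows = []
    for lineno, cols in _records(path):
        if len(cols) < 9:
            raise ParseError(f"{path}: line {lineno}: GTF needs 9 columns")
        attrs = " ".join(cols[8:])
        match = _GTF_GENE_ID.search(attrs)
        if match is None:
            raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
        start1 = _parse_int(cols[3], path, lineno, "start")
        end1 = _parse_int(cols[4], path, lineno, "end")
        rows.append((cols[2], match.group(1), cols[0], start1 - 1, end1, cols[6]))

    has_gene_rows = any(feature == "gene" for feature, *_ in rows)
    seen: Dict[str, GeneModel] = {}
    for feature, gene_id, chrom, start0, end0, strand in rows:
        if has_gene_rows and feature != "gene":
            continue
        if gene_id in seen:
            continue
        strand = strand if strand in ("+", "-") else "."
        tss = start0 if strand in ("+", ".") else end0 - 1
        seen[gene_id] = GeneModel(gene_id, chrom, tss, strand)
    return list(seen.values())


def write_genes_bed(genes: Sequence[GeneModel], path: PathLike, body: int = 1000) -> None:
    """Write gene models as BED6; the record spans ``body`` bp from the TSS."""
    with open(path, "w") as out:
        for g in genes:
            if g.strand == "-":
                start, end = max(0, g.tss + 1 - body), g.tss + 1
            else:
                start, end = g.tss, g.tss + body
            out.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t.\t{g.strand}\n")


def read_expression_matrix(
    values_path: PathLike, groups_path: Optional[PathLike] = None
) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column = gene id) and an optional
    2-column sample -> group map TSV (no header)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = None
    if groups_path is not None:
        gmap = pd.read_csv(
            groups_path, sep="\t", header=None, names=["sample", "group"]
        )
        groups = pd.Series(gmap["group"].values, index=gmap["sample"].values)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_matrix(
    expr: ExpressionMatrix,
    values_path: PathLike,
    groups_path: Optional[PathLike] = None,
) -> None:
    expr.values.to_csv(values_path, sep="\t", float_format="%.6g")
    if groups_path is not None:
        if expr.groups is None:
            raise ValueError("matrix has no group labels to write")
        with open(groups_path, "w") as out:
            for sample, group in expr.groups.items():
                out.write(f"{sample}\t{group}\n")
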