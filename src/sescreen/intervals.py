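"""Genomic interval primitives shared by every pipeline stage.

Coordinates are 0-based half-open ``[start, end)`` throughout, the native BED
convention; readers for 1-based dialects (GTF) convert at the parsing
boundary.  Two intervals overlap when their intersection is at least
``min_overlap_bp`` (default 1) bases long, so half-open adjacency
(``[100,200)`` vs ``[200,300)``) never counts as overlap.  Strand affects
only TSS derivation, never overlap arithmetic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

PROXIMAL = "promoter-proximal"
DISTAL = "distal"
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region with optional score and label.

    Invariants: ``0 <= start < end``; intervals sort by ``(chrom, start,
    end)``; ``score`` is non-negative when present.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("start/end must be integers")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.score is not None and not self.score >= 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length

    @property
    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __lt__(self, other: "GenomicInterval") -> bool:
        return self.sort_key < other.sort_key

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        return self.overlap_length(other) >= min_overlap_bp

    def contains(self, other: "GenomicInterval") -> bool:
        """True when `other` lies fully inside this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __repr__(self) -> str:  # compact, log-friendly
        extra = "" if self.label is None else f" {self.label}"
        return f"<{self.chrom}:{self.start}-{self.end}({self.strand}){extra}>"


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with overlap queries.

    Query results are identical to an all-pairs brute-force scan; an interval
    tree per chromosome is built lazily the first time a query runs.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], provenance: str = ""):
        self.intervals: List[GenomicInterval] = list(intervals)
        self.provenance = provenance
        self._trees: Optional[Dict[str, IntervalTree]] = None

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(sorted(self.intervals), provenance=self.provenance)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = defaultdict(list)
        for iv in self.intervals:
            out[iv.chrom].append(iv)
        return dict(out)

    def _ensure_trees(self) -> Dict[str, IntervalTree]:
        if self._trees is None:
            trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
            for iv in self.intervals:
                trees[iv.chrom].addi(iv.start, iv.end, iv)
            self._trees = dict(trees)
        return self._trees

    def overlapping(
        self, query: GenomicInterval, min_overlap_bp: int = 1
    ) -> List[GenomicInterval]:
        """All members overlapping `query` by >= min_overlap_bp, in sort order."""
        trees = self._ensure_trees()
        tree = trees.get(query.chrom)
        if tree is None:
            return []
        hits = [
            node.data
            for node in tree.overlap(query.start, query.end)
            if node.data.overlap_length(query) >= min_overlap_bp
        ]
        return sorted(hits)

    def any_overlap(self, query: GenomicInterval, min_overlap_bp: int = 1) -> bool:
        trees = self._ensure_trees()
        tree = trees.get(query.chrom)
        if tree is None:
            return False
        return any(
            node.data.overlap_length(query) >= min_overlap_bp
            for node in tree.overlap(query.start, query.end)
        )

    def merged(self) -> "IntervalSet":
        """Union of members as maximal disjoint intervals (labels dropped)."""
        out: List[GenomicInterval] = []
        for chrom, ivs in sorted(self.by_chrom().items()):
            ivs = sorted(ivs)
            cur_start, cur_end = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_end:
                    cur_end = max(cur_end, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_start, cur_end))
                    cur_start, cur_end = iv.start, iv.end
            out.append(GenomicInterval(chrom, cur_start, cur_end))
        return IntervalSet(out, provenance=f"merged({self.provenance})")

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.merged())

    def __repr__(self) -> str:
        src = f" from {self.provenance!r}" if self.provenance else ""
        return f"IntervalSet({len(self.intervals)} intervals{src})"


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its transcription start site.

    ``tss`` equals the annotation record's start for + strand genes and
    ``end - 1`` for - strand genes (unstranded records behave like +).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def tss_window(self, window: int) -> GenomicInterval:
        """The promoter window ``[tss - window, tss + window + 1)``."""
        return GenomicInterval(
            self.chrom,
            max(0, self.tss - window),
            self.tss + window + 1,
            strand=self.strand,
            label=self.gene_id,
        )


def tss_windows(genes: Sequence[GeneModel], window: int) -> IntervalSet:
    return IntervalSet(
        [g.tss_window(window) for g in genes], provenance=f"tss+-{window}"
    )


def overlaps(
    a: IntervalSet, b: IntervalSet, min_overlap_bp: int = 1
) -> List[List[GenomicInterval]]:
    """For each interval of `a` (in order), the overlapping intervals of `b`.

    A pair is reported iff the half-open intersection is at least
    ``min_overlap_bp`` bases; the result does not depend on the internal
    order of either set.
    """
    return [b.overlapping(iv, min_overlap_bp=min_overlap_bp) for iv in a]


def classify_tss_proximity(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    window: int = 2500,
) -> Tuple[List[str], Dict[str, float]]:
    """Label each peak promoter-proximal or distal relative to gene TSSs.

    A peak is promoter-proximal iff it overlaps ``[tss - window,
    tss + window + 1)`` of any gene; with ``window=0`` only peaks covering
    the TSS base itself qualify.  Returns the per-peak labels (in peak
    order) and the fraction of peaks per class.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    wins = tss_windows(genes, window)
    labels = [PROXIMAL if wins.any_overlap(p) else DISTAL for p in peaks]
    n = len(labels)
    fractions = {
        PROXIMAL: (sum(1 for l in labels if l == PROXIMAL) / n) if n else 0.0,
        DISTAL: (sum(1 for l in labels if l == DISTAL) / n) if n else 0.0,
    }
    return labels, fractions


def _check_disjoint_states(states: IntervalSet) -> None:
    for chrom, ivs in states.by_chrom().items():
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        max_end = -1
        max_label: Optional[str] = None
        for iv in ivs:
            if iv.start < max_end and iv.label != max_label:
                raise ValueError(
                    f"overlapping state segments with different labels on "
                    f"{chrom} near {iv.start} ({max_label!r} vs {iv.label!r})"
                )
            if iv.end > max_end:
                max_end, max_label = iv.end, iv.label
    return None


def state_distribution(
    peaks: IntervalSet, states: IntervalSet
) -> Dict[str, float]:
    """Fraction of peak bases falling in each chromatin-state label.

    The segmentation must be disjoint across labels (same-label overlaps are
    merged); genome not covered by any segment contributes to the
    ``unannotated`` label.  Fractions sum to 1 to within 1e-9.
    """
    if len(peaks) == 0:
        raise ValueError("state distribution is undefined for an empty peak set")
    _check_disjoint_states(states)

    by_label: Dict[str, List[GenomicInterval]] = defaultdict(list)
    for iv in states:
        by_label[iv.label if iv.label is not None else UNANNOTATED].append(iv)
    merged_by_label = {
        lab: IntervalSet(ivs).merged() for lab, ivs in by_label.items()
    }

    base_counts: Dict[str, int] = defaultdict(int)
    total = 0
    for peak in peaks:
        total += peak.length
        annotated = 0
        for lab, segset in merged_by_label.items():
            for seg in segset.overlapping(peak):
                ov = seg.overlap_length(peak)
                base_counts[lab] += ov
                annotated += ov
        base_counts[UNANNOTATED] += peak.length - annotated

    fractions = {lab: cnt / total for lab, cnt in base_counts.items() if cnt > 0}
    if not fractions:
        fractions = {UNANNOTATED: 0.0}
    return fractions
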