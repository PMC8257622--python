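"""Chromatin-loop filtering and enhancer-to-gene association.

Loops (e.g. HiChIP interactions called upstream) are pairs of anchor
intervals with an optional significance score.  The post-processing
implemented here keeps only loops whose both anchors fall on active
(H3K27ac-marked) chromatin, then assigns enhancer regions — typically
super-enhancers — to genes whenever one anchor overlaps the enhancer and
the other overlaps a gene's TSS window.  Assignment is loop-evidence-only:
there is no nearest-gene fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .intervals import GeneModel, GenomicInterval, IntervalSet, tss_windows


@dataclass(frozen=True)
class Loop:
    """A paired-anchor chromatin interaction.

    Anchors are normalized so ``anchor1 <= anchor2`` in (chrom, start, end)
    sort order; ``score`` is a significance value (e.g. an FDR q-value)
    in [0, 1] when present.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"loop score must be in [0, 1], got {self.score}")
        if self.anchor2.sort_key < self.anchor1.sort_key:
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)

    @property
    def anchors(self) -> Tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor1, self.anchor2)

    def swapped(self) -> "Loop":
        """The same loop with anchor fields exchanged (re-normalizes)."""
        return Loop(self.anchor2, self.anchor1, self.score)


@dataclass(frozen=True)
class SEGeneAssociation:
    """One (enhancer region, gene, loop) triple with the supporting evidence.

    ``evidence`` records which anchor hit the enhancer and which hit the TSS
    window; same-anchor hits are never emitted as associations.
    """

    se: GenomicInterval
    gene_id: str
    loop: Loop
    evidence: str

    @property
    def pair(self) -> Tuple[Tuple[str, int, int], str]:
        return ((self.se.chrom, self.se.start, self.se.end), self.gene_id)


def filter_active_loops(
    loops: Sequence[Loop],
    h3k27ac: IntervalSet,
    max_score: Optional[float] = None,
    min_overlap_bp: int = 1,
) -> List[Loop]:
    """Keep loops whose BOTH anchors are H3K27ac-marked.

    A loop is retained iff each anchor overlaps at least one H3K27ac
    interval by >= ``min_overlap_bp`` bases and, when ``max_score`` is
    given, its score is <= ``max_score`` (scoreless loops pass).  Input
    order is preserved and the filter is idempotent.
    """
    kept: List[Loop] = []
    for loop in loops:
        if max_score is not None and loop.score is not None and loop.score > max_score:
            continue
        if h3k27ac.any_overlap(loop.anchor1, min_overlap_bp) and h3k27ac.any_overlap(
            loop.anchor2, min_overlap_bp
        ):
            kept.append(loop)
    return kept


def associate_se_genes(
    loops: Sequence[Loop],
    ses: IntervalSet,
    genes: Sequence[GeneModel],
    tss_window: int = 2500,
    min_overlap_bp: int = 1,
) -> List[SEGeneAssociation]:
    """Assign enhancer regions to genes through loop anchors.

    For every loop both orientations are tested: (enhancer on anchor1 and
    TSS window on anchor2) and the swap.  One association is emitted per
    (enhancer, gene, loop) triple; a loop whose enhancer and TSS hits fall
    on the same anchor only contributes nothing.  The result is invariant
    under exchanging ``anchor1``/``anchor2`` of any input loop.
    """
    windows = tss_windows(genes, tss_window)
    out: List[SEGeneAssociation] = []
    for loop in loops:
        for se_anchor, tss_anchor, tag in (
            (loop.anchor1, loop.anchor2, "se@anchor1;tss@anchor2"),
            (loop.anchor2, loop.anchor1, "se@anchor2;tss@anchor1"),
        ):
            se_hits = ses.overlapping(se_anchor, min_overlap_bp)
            if not se_hits:
                continue
            gene_hits = windows.overlapping(tss_anchor, min_overlap_bp)
            for se in se_hits:
                for win in gene_hits:
                    out.append(
                        SEGeneAssociation(
                            se=se, gene_id=win.label, loop=loop, evidence=tag
                        )
                    )
    return out


def unique_pairs(
    associations: Iterable[SEGeneAssociation],
) -> List[Tuple[Tuple[str, int, int], str]]:
    """Deduplicated, sorted (enhancer coordinates, gene_id) pairs."""
    return sorted({a.pair for a in associations})


def se_gene_set(associations: Iterable[SEGeneAssociation]) -> List[str]:
    """Unique gene ids with loop-supported enhancer association, sorted."""
    return sorted({a.gene_id for a in associations})
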