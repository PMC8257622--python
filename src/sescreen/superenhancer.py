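"""ROSE-style super-enhancer calling and SE-set comparison.

The caller stitches H3K27ac peaks whose gaps are at most a fixed distance
(12.5 kb by convention), quantifies each stitched region by a factor's
background-subtracted signal, sorts regions by ascending signal, and places
the cutoff where the min-max-scaled signal curve first rises faster than the
diagonal (forward difference quotient > 1, scanned from the left).  Regions
strictly above the cutoff signal are super-enhancers.  Because the geometry
runs on the min-max-scaled curve, the SE set is invariant under any positive
affine rescaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GeneModel, GenomicInterval, IntervalSet, tss_windows
from .signal import SignalTrack, aggregate_signal

DEFAULT_STITCH_DISTANCE = 12500
DEFAULT_TSS_EXCLUDE_WINDOW = 2500


@dataclass
class StitchedRegion:
    """A maximal run of stitched peaks with its quantified factor signal."""

    interval: GenomicInterval
    constituents: List[GenomicInterval]
    signal: Optional[float] = None
    rank: Optional[int] = None  # 1 = highest signal


@dataclass
class SECallResult:
    """Ranked stitched regions with the hockey-stick cutoff applied.

    ``regions`` are sorted ascending by signal (genomic order on ties);
    ``se_flags[i]`` is True iff ``regions[i].signal > cutoff_signal``.
    """

    regions: List[StitchedRegion]
    cutoff_signal: float
    se_flags: np.ndarray
    factor: str = "factor"

    @property
    def n_superenhancers(self) -> int:
        return int(self.se_flags.sum())

    @property
    def superenhancers(self) -> IntervalSet:
        ivs = [
            replace_score(r.interval, r.signal, self.factor)
            for r, flag in zip(self.regions, self.se_flags)
            if flag
        ]
        return IntervalSet(ivs, provenance=f"SE({self.factor})")

    def to_table(self):
        import pandas as pd

        rows = [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "n_constituents": len(r.constituents),
                "signal": r.signal,
                "rank": r.rank,
                "is_superenhancer": bool(flag),
            }
            for r, flag in zip(self.regions, self.se_flags)
        ]
        return pd.DataFrame(rows)


def replace_score(
    iv: GenomicInterval, score: Optional[float], label: Optional[str]
) -> GenomicInterval:
    return GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, score, label)


def stitch(
    peaks: IntervalSet,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclude: Optional[Tuple[Sequence[GeneModel], int]] = None,
) -> List[StitchedRegion]:
    """Transitively merge peaks whose gap is <= ``stitch_distance`` bp.

    The gap between consecutive peaks is ``next.start - prev.end``; a gap
    exactly equal to the stitch distance still merges.  With
    ``tss_exclude=(genes, window)``, peaks lying fully inside any
    ``TSS +- window`` promoter window are dropped before stitching.
    Output regions are pairwise disjoint and sorted; each records its
    constituent peaks.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    kept = list(peaks)
    if tss_exclude is not None:
        genes, window = tss_exclude
        windows = tss_windows(genes, window)
        kept = [
            p
            for p in kept
            if not any(w.contains(p) for w in windows.overlapping(p))
        ]

    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for p in kept:
        by_chrom.setdefault(p.chrom, []).append(p)

    regions: List[StitchedRegion] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        run = [ivs[0]]
        run_end = ivs[0].end
        for iv in ivs[1:]:
            if iv.start - run_end <= stitch_distance:
                run.append(iv)
                run_end = max(run_end, iv.end)
            else:
                regions.append(_close_run(chrom, run))
                run, run_end = [iv], iv.end
        regions.append(_close_run(chrom, run))
    return regions


def _close_run(chrom: str, run: List[GenomicInterval]) -> StitchedRegion:
    start = min(p.start for p in run)
    end = max(p.end for p in run)
    return StitchedRegion(
        interval=GenomicInterval(chrom, start, end), constituents=list(run)
    )


def rank_regions(
    stitched: Sequence[StitchedRegion],
    factor_track: SignalTrack,
    input_track: Optional[SignalTrack] = None,
) -> List[StitchedRegion]:
    """Fill region signal and rank from a factor track (minus optional input).

    signal = max(0, total(factor) - total(input)); regions are returned
    sorted ascending by signal with ties broken by genomic order, and rank 1
    assigned to the highest-signal region.
    """
    if input_track is not None and (
        input_track.genome != factor_track.genome
        or input_track.bin_width != factor_track.bin_width
    ):
        raise ValueError("factor and input tracks must share genome and bin width")
    intervals = [r.interval for r in stitched]
    totals = aggregate_signal(factor_track, intervals, mode="total")
    if input_track is not None:
        totals = totals - aggregate_signal(input_track, intervals, mode="total")
    totals = np.maximum(totals, 0.0)

    order = sorted(
        range(len(stitched)),
        key=lambda i: (totals[i], intervals[i].sort_key),
    )
    n = len(order)
    out: List[StitchedRegion] = []
    for pos, i in enumerate(order):
        out.append(
            replace(stitched[i], signal=float(totals[i]), rank=n - pos)
        )
    return out


def se_cutoff(ranked_signals: Sequence[float]) -> Tuple[float, np.ndarray]:
    """Locate the hockey-stick cutoff on an ascending signal curve.

    Rank index and signal are each min-max scaled to [0, 1]; scanning from
    the left, the cutoff sits at the first index whose forward difference
    quotient exceeds 1.  Returns the unscaled cutoff signal and per-region
    SE flags (signal strictly above the cutoff).  A flat curve — or one
    that never rises faster than the diagonal — yields zero SEs.
    """
    s = np.asarray(ranked_signals, dtype=float)
    n = s.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions to place a cutoff")
    if np.any(np.diff(s) < 0):
        raise ValueError("ranked_signals must be ascending")
    smin, smax = float(s[0]), float(s[-1])
    if smax == smin:
        return smax, np.zeros(n, dtype=bool)
    y = (s - smin) / (smax - smin)
    quotients = np.diff(y) * (n - 1)  # x step is 1 / (n - 1)
    above = np.nonzero(quotients > 1.0)[0]
    if above.size == 0:
        return smax, np.zeros(n, dtype=bool)
    cutoff = float(s[above[0]])
    return cutoff, s > cutoff


def call_superenhancers(
    h3k27ac_peaks: IntervalSet,
    factor_track: SignalTrack,
    input_track: Optional[SignalTrack] = None,
    factor: str = "factor",
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclude: Optional[Tuple[Sequence[GeneModel], int]] = None,
) -> SECallResult:
    """stitch -> rank_regions -> se_cutoff, with provenance retained."""
    if len(h3k27ac_peaks) == 0:
        raise ValueError("cannot call super-enhancers on an empty peak set")
    stitched = stitch(h3k27ac_peaks, stitch_distance, tss_exclude)
    ranked = rank_regions(stitched, factor_track, input_track)
    cutoff, flags = se_cutoff([r.signal for r in ranked])
    return SECallResult(
        regions=ranked, cutoff_signal=cutoff, se_flags=flags, factor=factor
    )


@dataclass
class SEOverlapResult:
    """Pairwise / multi-way overlap statistics between SE sets.

    ``shared_fraction[f]`` is the fraction of f's SEs overlapping the union
    of all other sets; ``pairwise_fraction[(f, g)]`` the fraction of f's SEs
    overlapping g's.  ``venn`` counts connected components of the pooled SE
    regions keyed by the sorted tuple of factors present in the component.
    """

    n: Dict[str, int]
    pairwise_fraction: Dict[Tuple[str, str], float]
    shared_fraction: Dict[str, float]
    venn: Dict[Tuple[str, ...], int]


def _as_se_set(obj) -> Tuple[str, IntervalSet]:
    if isinstance(obj, SECallResult):
        return obj.factor, obj.superenhancers
    if isinstance(obj, tuple) and len(obj) == 2:
        name, ivs = obj
        return name, ivs if isinstance(ivs, IntervalSet) else IntervalSet(ivs)
    raise TypeError("expected SECallResult or (name, IntervalSet)")


def se_overlap(a, b, c=None, min_overlap_bp: int = 1) -> SEOverlapResult:
    """Compare two or three SE sets by >= 1 bp interval overlap."""
    named = [_as_se_set(x) for x in (a, b, c) if x is not None]
    names = [name for name, _ in named]
    if len(set(names)) != len(names):
        raise ValueError("SE sets must carry distinct factor names")
    sets = dict(named)

    n = {name: len(ivs) for name, ivs in named}
    pairwise: Dict[Tuple[str, str], float] = {}
    shared: Dict[str, float] = {}
    for name, ivs in named:
        others = [o for o in names if o != name]
        for other in others:
            hits = sum(
                1 for iv in ivs if sets[other].any_overlap(iv, min_overlap_bp)
            )
            pairwise[(name, other)] = hits / len(ivs) if len(ivs) else 0.0
        hits_any = sum(
            1
            for iv in ivs
            if any(sets[o].any_overlap(iv, min_overlap_bp) for o in others)
        )
        shared[name] = hits_any / len(ivs) if len(ivs) else 0.0

    venn = _venn_components(named, min_overlap_bp)
    return SEOverlapResult(
        n=n, pairwise_fraction=pairwise, shared_fraction=shared, venn=venn
    )


def _venn_components(
    named: List[Tuple[str, IntervalSet]], min_overlap_bp: int
) -> Dict[Tuple[str, ...], int]:
    """Connected components of the pooled SE regions, keyed by factors present."""
    pool = [
        (iv, name) for name, ivs in named for iv in ivs
    ]
    pool.sort(key=lambda item: item[0].sort_key)
    venn: Dict[Tuple[str, ...], int] = {}
    i = 0
    while i < len(pool):
        iv, name = pool[i]
        chrom, comp_end = iv.chrom, iv.end
        members = {name}
        j = i + 1
        while j < len(pool):
            nxt, nxt_name = pool[j]
            # components require actual overlap (>= min_overlap_bp), not adjacency
            if nxt.chrom != chrom or nxt.start > comp_end - min_overlap_bp:
                break
            members.add(nxt_name)
            comp_end = max(comp_end, nxt.end)
            j += 1
        key = tuple(sorted(members))
        venn[key] = venn.get(key, 0) + 1
        i = j
    return venn
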