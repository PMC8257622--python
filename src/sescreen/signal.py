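"""Binned signal tracks and region-level quantification.

A :class:`SignalTrack` stores one non-negative value per fixed-width bin per
chromosome (``ceil(length / bin_width)`` bins; the last bin may be shorter).
A bin's value applies uniformly to every base it covers, so per-base
accounting (``aggregate_signal``) is exact for partially covered bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet

DEFAULT_BIN_WIDTH = 50


def n_bins(chrom_length: int, bin_width: int) -> int:
    return -(-chrom_length // bin_width)  # ceil division


@dataclass
class SignalTrack:
    """Fixed-width binned coverage, one float array per chromosome."""

    bin_width: int
    genome: Dict[str, int]
    values: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be a positive integer")
        self.genome = dict(self.genome)
        for chrom, length in self.genome.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}")
            expected = n_bins(length, self.bin_width)
            arr = np.asarray(self.values.get(chrom), dtype=float)
            if arr.ndim != 1 or arr.shape[0] != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{chrom}: values must be finite and >= 0")
            self.values[chrom] = arr
        extra = set(self.values) - set(self.genome)
        if extra:
            raise ValueError(f"values for chromosomes absent from genome: {extra}")

    @classmethod
    def zeros(
        cls, genome: Mapping[str, int], bin_width: int = DEFAULT_BIN_WIDTH
    ) -> "SignalTrack":
        return cls(
            bin_width=bin_width,
            genome=dict(genome),
            values={
                c: np.zeros(n_bins(l, bin_width)) for c, l in genome.items()
            },
        )

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            bin_width=self.bin_width,
            genome=dict(self.genome),
            values={c: v.copy() for c, v in self.values.items()},
        )

    def scaled(self, factor: float) -> "SignalTrack":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return SignalTrack(
            bin_width=self.bin_width,
            genome=dict(self.genome),
            values={c: v * factor for c, v in self.values.items()},
        )

    def equals(self, other: "SignalTrack", atol: float = 0.0) -> bool:
        if self.bin_width != other.bin_width or self.genome != other.genome:
            return False
        return all(
            np.allclose(self.values[c], other.values[c], atol=atol, rtol=0.0)
            for c in self.genome
        )


def smooth_track(track: SignalTrack, window: int = 5) -> SignalTrack:
    """Centered moving average over `window` bins (window must be odd).

    At chromosome edges the window truncates to the bins that exist, so the
    output keeps the input length and a constant track is returned
    unchanged; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return track.copy()
    kernel = np.ones(window)
    smoothed: Dict[str, np.ndarray] = {}
    for chrom, v in track.values.items():
        sums = np.convolve(v, kernel, mode="same")
        counts = np.convolve(np.ones_like(v), kernel, mode="same")
        smoothed[chrom] = sums / counts
    return SignalTrack(bin_width=track.bin_width, genome=track.genome, values=smoothed)


def _check_region(track: SignalTrack, region: GenomicInterval) -> int:
    length = track.genome.get(region.chrom)
    if length is None:
        raise ValueError(f"region chromosome {region.chrom!r} not in track genome")
    if region.end > length:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {length}"
        )
    return length


def region_signal(
    track: SignalTrack, region: GenomicInterval, mode: str = "total"
) -> float:
    """Signal over one region: per-base total, or total / region length."""
    length = _check_region(track, region)
    bw = track.bin_width
    v = track.values[region.chrom]
    b0 = region.start // bw
    b1 = (region.end - 1) // bw
    starts = np.arange(b0, b1 + 1) * bw
    ends = np.minimum(starts + bw, length)
    cover = np.minimum(ends, region.end) - np.maximum(starts, region.start)
    total = float(np.dot(v[b0 : b1 + 1], cover))
    if mode == "total":
        return total
    if mode == "mean":
        return total / region.length
    raise ValueError(f"mode must be 'total' or 'mean', got {mode!r}")


def aggregate_signal(
    track: SignalTrack,
    regions: IntervalSet | Sequence[GenomicInterval],
    mode: str = "total",
) -> np.ndarray:
    """Per-region signal (see :func:`region_signal`), in region order."""
    return np.array([region_signal(track, r, mode=mode) for r in regions])
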