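"""Seeded synthetic-data generators with a ground-truth manifest.

Every input the pipeline consumes can be generated here offline:

* a multi-tissue normal expression matrix with a minority of
  tissue-restricted genes (log-normal baseline, one tissue multiplied by a
  fold factor, multiplicative log-normal noise);
* a tumor-cohort matrix with "subset-expressed" bimodal genes (high in a
  fixed fraction of samples, baseline elsewhere);
* a small regulatory genome: isolated enhancer peaks plus dense peak
  clusters carrying disproportionate factor signal (the hockey-stick
  landscape a super-enhancer caller expects), shared H3K27ac peaks and
  per-factor occupancy tracks, gene TSSs with promoter peaks;
* chromatin loops connecting planted cluster anchors to gene promoters,
  plus decoy loops placed far from any H3K27ac peak so an
  active-chromatin filter removes them unambiguously.

All generators are deterministic given (seed, parameters), and everything
planted is recorded in a :class:`GroundTruthManifest` so each pipeline stage
can be scored against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, IntervalSet
from .loops import Loop
from .signal import SignalTrack, n_bins
from .specificity import ExpressionMatrix

DEFAULT_GENOME = {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000}
DEFAULT_FACTORS = ("BRDT", "BRD4", "P63")


@dataclass
class GroundTruthManifest:
    """Machine-readable record of everything the generators planted."""

    seed: int
    params: Dict
    specific_genes: List[Dict] = field(default_factory=list)
    bimodal_genes: List[Dict] = field(default_factory=list)
    planted_ses: Dict[str, List[List]] = field(default_factory=dict)
    planted_pairs: List[Dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _gene_names(n_genes: int) -> List[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def simulate_tissue_expression(
    n_genes: int = 500,
    n_tissues: int = 10,
    n_specific: int = 4,
    fold: float = 8.0,
    noise_sd: float = 0.5,
    n_replicates: int = 10,
    seed: int = 0,
    gene_names: Optional[Sequence[str]] = None,
    specific_genes: Optional[Sequence[str]] = None,
) -> Tuple[ExpressionMatrix, List[Dict]]:
    """Normal-tissue expression with `n_specific` planted specific genes.

    Baseline abundance per gene is log-normal; each planted gene is
    multiplied by ``fold`` in one randomly chosen tissue; every measurement
    carries multiplicative log-normal noise of sd ``noise_sd`` (natural-log
    scale).  Returns the matrix and the manifest entries
    ``{"gene", "tissue", "fold"}``.
    """
    if not 0 <= n_specific <= n_genes:
        raise ValueError("need 0 <= n_specific <= n_genes")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if n_tissues < 2 or n_replicates < 1:
        raise ValueError("need >= 2 tissues and >= 1 replicate")
    rng = np.random.default_rng(seed)
    genes = list(gene_names) if gene_names is not None else _gene_names(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    tissues = [f"tissue{i + 1:02d}" for i in range(n_tissues)]

    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)
    if specific_genes is not None:
        planted_idx = np.array([genes.index(g) for g in specific_genes])
        if len(planted_idx) != n_specific:
            raise ValueError("specific_genes length must equal n_specific")
    else:
        planted_idx = rng.choice(n_genes, size=n_specific, replace=False)
    target_tissue = rng.integers(n_tissues, size=n_specific)

    n_samples = n_tissues * n_replicates
    mean = np.tile(base[:, None], (1, n_samples))
    sample_tissue = np.repeat(np.arange(n_tissues), n_replicates)
    for g, t in zip(planted_idx, target_tissue):
        mean[g, sample_tissue == t] *= fold
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=mean.shape)
    values = mean * noise

    samples = [
        f"{tissues[t]}_rep{r + 1}"
        for t in range(n_tissues)
        for r in range(n_replicates)
    ]
    df = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series([tissues[t] for t in sample_tissue], index=samples)
    manifest = [
        {"gene": genes[int(g)], "tissue": tissues[int(t)], "fold": float(fold)}
        for g, t in sorted(zip(planted_idx, target_tissue), key=lambda x: int(x[0]))
    ]
    return ExpressionMatrix(values=df, groups=groups), manifest


def simulate_cohort(
    n_genes: int = 500,
    n_samples: int = 30,
    n_bimodal: int = 4,
    fraction_on: float = 0.3,
    on_fold: float = 8.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    gene_names: Optional[Sequence[str]] = None,
    bimodal_genes: Optional[Sequence[str]] = None,
) -> Tuple[ExpressionMatrix, List[Dict]]:
    """Tumor-cohort expression with planted bimodal ("subset-on") genes.

    Each planted gene is high (baseline x ``on_fold``) in exactly
    ``round(fraction_on * n_samples)`` samples and baseline elsewhere.
    """
    if not 0.0 < fraction_on < 1.0:
        raise ValueError("fraction_on must lie strictly between 0 and 1")
    if not 0 <= n_bimodal <= n_genes:
        raise ValueError("need 0 <= n_bimodal <= n_genes")
    if n_samples < 2:
        raise ValueError("need >= 2 cohort samples")
    rng = np.random.default_rng(seed)
    genes = list(gene_names) if gene_names is not None else _gene_names(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    n_on = int(np.rint(fraction_on * n_samples))
    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)
    if bimodal_genes is not None:
        planted_idx = np.array([genes.index(g) for g in bimodal_genes], dtype=int)
        if len(planted_idx) != n_bimodal:
            raise ValueError("bimodal_genes length must equal n_bimodal")
    else:
        planted_idx = rng.choice(n_genes, size=n_bimodal, replace=False)

    mean = np.tile(base[:, None], (1, n_samples))
    manifest: List[Dict] = []
    for g in sorted(int(i) for i in planted_idx):
        on = rng.choice(n_samples, size=n_on, replace=False)
        mean[g, on] *= on_fold
        manifest.append(
            {
                "gene": genes[g],
                "fraction_on": float(fraction_on),
                "on_samples": sorted(int(s) for s in on),
            }
        )
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=mean.shape)
    values = mean * noise
    samples = [f"tumor{j + 1:03d}" for j in range(n_samples)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(values=df, groups=None), manifest


@dataclass
class RegulatoryGenome:
    """A simulated ChIP landscape: peaks, per-factor tracks, genes, truth."""

    genome: Dict[str, int]
    bin_width: int
    h3k27ac: IntervalSet
    tracks: Dict[str, SignalTrack]
    input_track: SignalTrack
    genes: List[GeneModel]
    cluster_spans: List[GenomicInterval]
    cluster_peaks: List[List[GenomicInterval]]
    occupied: Dict[str, List[int]]
    params: Dict

    def planted_ses(self, factor: str) -> List[GenomicInterval]:
        return [self.cluster_spans[i] for i in self.occupied[factor]]


def _place_sites(
    rng: np.random.Generator,
    genome: Dict[str, int],
    spans: Sequence[int],
    margin: int,
    grid: int,
    max_tries: int,
) -> List[Tuple[str, int]]:
    """Rejection-sample non-overlapping site positions (margin-expanded)."""
    chroms = list(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    out: List[Tuple[str, int]] = []
    for span in spans:
        for attempt in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            limit = (genome[chrom] - span - margin) // grid
            if limit <= margin // grid:
                continue
            start = int(rng.integers(margin // grid, limit)) * grid
            lo, hi = start - margin, start + span + margin
            if all(hi <= s or lo >= e for s, e in placed[chrom]):
                placed[chrom].append((lo, hi))
                out.append((chrom, start))
                break
        else:
            raise RuntimeError(
                f"could not place a {span} bp site after {max_tries} tries; "
                "genome too small for the requested site count"
            )
    return out


def simulate_regulatory_genome(
    genome: Optional[Dict[str, int]] = None,
    n_enhancers: int = 60,
    n_se_clusters: int = 10,
    peaks_per_cluster: int = 5,
    signal_gap_fold: float = 20.0,
    bin_width: int = 50,
    peak_width: int = 1000,
    cluster_gap: int = 2000,
    n_genes: int = 30,
    factors: Sequence[str] = DEFAULT_FACTORS,
    shared_fraction: float = 0.7,
    base_amplitude: float = 2.0,
    input_level: float = 0.05,
    bin_noise_sd: float = 0.05,
    margin: int = 15000,
    max_tries: int = 10000,
    seed: int = 0,
) -> RegulatoryGenome:
    """Simulate peaks, factor tracks and genes with planted SE clusters.

    Typical enhancers and gene promoters are isolated ``peak_width`` bp
    H3K27ac peaks; each SE cluster is ``peaks_per_cluster`` peaks separated
    by ``cluster_gap`` bp (stitchable into one region).  Per factor, every
    H3K27ac site draws a target signal total ``base_amplitude * peak_width
    * U(0.5, 1.5)``; clusters occupied by the factor are multiplied by
    ``signal_gap_fold``, producing the hockey-stick ranked-signal curve.
    The first factor occupies every cluster; each later factor occupies a
    random ``round(shared_fraction * n_se_clusters)``-subset of them.  All
    coordinates are multiples of ``bin_width``; sites are rejection-sampled
    at pairwise distance >= ``margin`` (which exceeds the default stitch
    distance, so no cross-site stitching can occur).
    """
    if genome is None:
        genome = dict(DEFAULT_GENOME)
    if peak_width % bin_width or cluster_gap % bin_width or margin % bin_width:
        raise ValueError("peak_width, cluster_gap and margin must be bin-aligned")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if peaks_per_cluster < 1 or n_se_clusters < 0 or n_enhancers < 0:
        raise ValueError("invalid site counts")
    params = {
        "genome": dict(genome),
        "n_enhancers": n_enhancers,
        "n_se_clusters": n_se_clusters,
        "peaks_per_cluster": peaks_per_cluster,
        "signal_gap_fold": signal_gap_fold,
        "bin_width": bin_width,
        "peak_width": peak_width,
        "cluster_gap": cluster_gap,
        "n_genes": n_genes,
        "factors": list(factors),
        "shared_fraction": shared_fraction,
        "base_amplitude": base_amplitude,
        "input_level": input_level,
        "bin_noise_sd": bin_noise_sd,
    }
    rng = np.random.default_rng(seed)

    cluster_span = peaks_per_cluster * peak_width + (peaks_per_cluster - 1) * cluster_gap
    spans = (
        [cluster_span] * n_se_clusters
        + [peak_width] * n_enhancers
        + [peak_width] * n_genes
    )
    positions = _place_sites(rng, genome, spans, margin, bin_width, max_tries)
    cluster_pos = positions[:n_se_clusters]
    enhancer_pos = positions[n_se_clusters : n_se_clusters + n_enhancers]
    promoter_pos = positions[n_se_clusters + n_enhancers :]

    cluster_peaks: List[List[GenomicInterval]] = []
    cluster_spans: List[GenomicInterval] = []
    for k, (chrom, start) in enumerate(cluster_pos):
        peaks = [
            GenomicInterval(
                chrom,
                start + j * (peak_width + cluster_gap),
                start + j * (peak_width + cluster_gap) + peak_width,
                label=f"SE{k + 1:02d}_p{j + 1}",
            )
            for j in range(peaks_per_cluster)
        ]
        cluster_peaks.append(peaks)
        cluster_spans.append(
            GenomicInterval(chrom, peaks[0].start, peaks[-1].end, label=f"SE{k + 1:02d}")
        )

    enhancers = [
        GenomicInterval(chrom, start, start + peak_width, label=f"enh{j + 1:03d}")
        for j, (chrom, start) in enumerate(enhancer_pos)
    ]
    genes: List[GeneModel] = []
    promoter_peaks: List[GenomicInterval] = []
    for j, (chrom, start) in enumerate(promoter_pos):
        gene_id = f"GENE{j + 1:03d}"
        strand = "+" if rng.integers(2) == 0 else "-"
        tss = start + peak_width // 2
        genes.append(GeneModel(gene_id, chrom, tss, strand))
        promoter_peaks.append(
            GenomicInterval(chrom, start, start + peak_width, label=f"prom_{gene_id}")
        )

    all_peaks = sorted(
        [p for peaks in cluster_peaks for p in peaks] + enhancers + promoter_peaks
    )
    h3k27ac = IntervalSet(all_peaks, provenance="simulated H3K27ac")

    # per-factor occupancy of the clusters
    occupied: Dict[str, List[int]] = {}
    for i, factor in enumerate(factors):
        if i == 0 or n_se_clusters == 0:
            occupied[factor] = list(range(n_se_clusters))
        else:
            k = int(np.rint(shared_fraction * n_se_clusters))
            occupied[factor] = sorted(
                int(c) for c in rng.choice(n_se_clusters, size=k, replace=False)
            )

    # factor tracks: one target total per (factor, site); clusters occupied
    # by the factor are boosted by signal_gap_fold
    sites: List[Tuple[List[GenomicInterval], Optional[int]]] = [
        (peaks, k) for k, peaks in enumerate(cluster_peaks)
    ] + [([iv], None) for iv in enhancers + promoter_peaks]
    base_total = base_amplitude * peak_width

    tracks: Dict[str, SignalTrack] = {}
    for factor in factors:
        track = SignalTrack.zeros(genome, bin_width)
        occ = set(occupied[factor])
        for peaks, cluster_idx in sites:
            u = rng.uniform(0.5, 1.5)
            boost = signal_gap_fold if (cluster_idx is not None and cluster_idx in occ) else 1.0
            site_bases = sum(p.length for p in peaks)
            amp = base_total * u * boost / site_bases
            for p in peaks:
                b0, b1 = p.start // bin_width, p.end // bin_width
                nb = b1 - b0
                noise = rng.lognormal(0.0, bin_noise_sd, size=nb) if bin_noise_sd > 0 else 1.0
                track.values[p.chrom][b0:b1] = amp * noise
        tracks[factor] = track

    input_track = SignalTrack(
        bin_width=bin_width,
        genome=dict(genome),
        values={
            c: np.full(n_bins(l, bin_width), input_level) for c, l in genome.items()
        },
    )
    return RegulatoryGenome(
        genome=dict(genome),
        bin_width=bin_width,
        h3k27ac=h3k27ac,
        tracks=tracks,
        input_track=input_track,
        genes=genes,
        cluster_spans=cluster_spans,
        cluster_peaks=cluster_peaks,
        occupied=occupied,
        params=params,
    )


def simulate_loops(
    reg: RegulatoryGenome,
    n_true_pairs: int = 8,
    n_decoy_loops: int = 5,
    anchor_width: int = 1000,
    decoy_clearance: int = 12500,
    max_tries: int = 10000,
    seed: int = 0,
) -> Tuple[List[Loop], List[Dict]]:
    """Loops linking planted SE clusters to gene promoters, plus decoys.

    True loops run from the first peak of a distinct planted cluster to a
    distinct gene's promoter peak.  Decoy loops connect random regions at
    least ``decoy_clearance`` bp away from every H3K27ac peak, so the
    active-chromatin filter removes exactly the decoys.  Returns the loops
    and the planted (SE span, gene) manifest entries.
    """
    n_clusters = len(reg.cluster_spans)
    if n_true_pairs > min(n_clusters, len(reg.genes)):
        raise ValueError(
            "n_true_pairs must not exceed the number of planted clusters or genes"
        )
    rng = np.random.default_rng(seed)
    loops: List[Loop] = []
    planted: List[Dict] = []

    cluster_choice = rng.choice(n_clusters, size=n_true_pairs, replace=False)
    gene_choice = rng.choice(len(reg.genes), size=n_true_pairs, replace=False)
    for ci, gi in zip(cluster_choice, gene_choice):
        cluster = reg.cluster_peaks[int(ci)]
        span = reg.cluster_spans[int(ci)]
        gene = reg.genes[int(gi)]
        a1 = GenomicInterval(cluster[0].chrom, cluster[0].start, cluster[0].end)
        half = anchor_width // 2
        a2 = GenomicInterval(gene.chrom, max(0, gene.tss - half), gene.tss + half)
        loops.append(Loop(a1, a2, score=float(rng.uniform(1e-6, 0.01))))
        planted.append(
            {"se": [span.chrom, span.start, span.end], "gene": gene.gene_id}
        )

    def random_decoy_anchor() -> GenomicInterval:
        chroms = list(reg.genome)
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, reg.genome[chrom] - anchor_width))
            iv = GenomicInterval(chrom, start, start + anchor_width)
            probe = GenomicInterval(
                chrom,
                max(0, start - decoy_clearance),
                start + anchor_width + decoy_clearance,
            )
            if not reg.h3k27ac.any_overlap(probe):
                return iv
        raise RuntimeError("could not place a decoy anchor clear of H3K27ac")

    for _ in range(n_decoy_loops):
        loops.append(
            Loop(
                random_decoy_anchor(),
                random_decoy_anchor(),
                score=float(rng.uniform(1e-6, 0.01)),
            )
        )
    return loops, planted


@dataclass
class SyntheticStudy:
    """All pipeline inputs for one seeded synthetic run, plus the manifest."""

    tissue_expr: ExpressionMatrix
    cohort: ExpressionMatrix
    reg_genome: RegulatoryGenome
    loops: List[Loop]
    manifest: GroundTruthManifest

    def write(self, outdir) -> None:
        from . import io as sio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_expression_matrix(
            self.tissue_expr,
            outdir / "tissue_expression.tsv",
            outdir / "tissue_groups.tsv",
        )
        sio.write_expression_matrix(self.cohort, outdir / "cohort_expression.tsv")
        sio.write_bed(self.reg_genome.h3k27ac, outdir / "h3k27ac_peaks.bed")
        sio.write_chrom_sizes(self.reg_genome.genome, outdir / "chrom.sizes")
        for factor, track in self.reg_genome.tracks.items():
            sio.write_bedgraph(track, outdir / f"{factor}.bedgraph")
        sio.write_bedgraph(self.reg_genome.input_track, outdir / "input.bedgraph")
        sio.write_genes_bed(self.reg_genome.genes, outdir / "genes.bed")
        sio.write_bedpe(self.loops, outdir / "loops.bedpe")
        self.manifest.write(outdir / "manifest.json")


def simulate_all(
    seed: int = 0,
    n_genes: int = 500,
    n_tissues: int = 10,
    n_specific: int = 4,
    fold: float = 8.0,
    n_samples: int = 30,
    fraction_on: float = 0.3,
    on_fold: float = 8.0,
    noise_sd: float = 0.5,
    n_true_pairs: int = 8,
    n_decoy_loops: int = 5,
    **genome_kwargs,
) -> SyntheticStudy:
    """Generate every pipeline input from one master seed.

    The same ``n_specific`` genes are planted as tissue-specific in the
    normal matrix and bimodal in the cohort, mirroring a candidate that is
    both restricted in normal tissue and subset-expressed in tumors.
    """
    master = np.random.default_rng(seed)
    sub = master.integers(2**31, size=4)
    genes = _gene_names(n_genes)
    planted = sorted(
        genes[int(i)]
        for i in master.choice(n_genes, size=n_specific, replace=False)
    )
    tissue_expr, specific_manifest = simulate_tissue_expression(
        n_genes=n_genes,
        n_tissues=n_tissues,
        n_specific=n_specific,
        fold=fold,
        noise_sd=noise_sd,
        seed=int(sub[0]),
        gene_names=genes,
        specific_genes=planted,
    )
    cohort, bimodal_manifest = simulate_cohort(
        n_genes=n_genes,
        n_samples=n_samples,
        n_bimodal=n_specific,
        fraction_on=fraction_on,
        on_fold=on_fold,
        noise_sd=noise_sd,
        seed=int(sub[1]),
        gene_names=genes,
        bimodal_genes=planted,
    )
    reg = simulate_regulatory_genome(seed=int(sub[2]), **genome_kwargs)
    loops, planted_pairs = simulate_loops(
        reg, n_true_pairs=n_true_pairs, n_decoy_loops=n_decoy_loops, seed=int(sub[3])
    )
    manifest = GroundTruthManifest(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_tissues": n_tissues,
            "n_specific": n_specific,
            "fold": fold,
            "n_samples": n_samples,
            "fraction_on": fraction_on,
            "on_fold": on_fold,
            "noise_sd": noise_sd,
            "n_true_pairs": n_true_pairs,
            "n_decoy_loops": n_decoy_loops,
            **reg.params,
        },
        specific_genes=specific_manifest,
        bimodal_genes=bimodal_manifest,
        planted_ses={
            factor: [[iv.chrom, iv.start, iv.end] for iv in reg.planted_ses(factor)]
            for factor in reg.tracks
        },
        planted_pairs=planted_pairs,
    )
    return SyntheticStudy(
        tissue_expr=tissue_expr,
        cohort=cohort,
        reg_genome=reg,
        loops=loops,
        manifest=manifest,
    )
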